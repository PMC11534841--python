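"""Core data container and tabular I/O for multi-observer volumetry.

The universal input of every analysis stage is an :class:`AnnotationMatrix`:
a complete n-subjects × m-observers grid of strictly positive tumor volumes
(mm³) together with per-subject metadata (cyst flag, laterality, demographics
and MRI acquisition parameters).

Annotation files are long ("tidy") delimited text — one row per
(subject, observer) measurement — because that is the natural provenance of
independent annotation sessions.  Metadata columns are per-subject and must
be constant within a subject.  A wide-format convenience constructor is
provided for matrices that already live in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationMatrix",
    "AnnotationError",
    "METADATA_COLUMNS",
    "read_annotations",
    "write_table",
    "read_table",
]

#: Recognised per-subject metadata columns.  ``cyst`` flags a peritumoral
#: cystic component; the acquisition fields mirror a contrast-enhanced
#: T1-weighted MRI protocol.  All are optional and may contain missing values.
METADATA_COLUMNS: tuple[str, ...] = (
    "cyst",
    "laterality",
    "sex",
    "age_at_followup",
    "followup_time",
    "date",
    "echo_time",
    "repetition_time",
    "flip_angle",
    "echo_train_length",
    "field_strength",
    "n_slices",
    "slice_thickness",
    "slice_spacing",
    "voxel_spacing",
)

#: Metadata fields that must be nonnegative where present.
_NONNEGATIVE_META: tuple[str, ...] = (
    "age_at_followup",
    "followup_time",
    "echo_time",
    "repetition_time",
    "flip_angle",
    "echo_train_length",
    "field_strength",
    "n_slices",
    "slice_thickness",
    "slice_spacing",
    "voxel_spacing",
)


class AnnotationError(ValueError):
    """Raised when an annotation table violates the completeness/positivity
    contract (missing cell, non-positive volume, inconsistent metadata)."""


@dataclass(frozen=True)
class AnnotationMatrix:
    """Complete n×m grid of volume measurements plus per-subject metadata.

    Parameters
    ----------
    volumes
        DataFrame indexed by subject id with one column per observer;
        every cell holds one strictly positive volume in mm³.
    metadata
        Optional DataFrame indexed by subject id (same order as ``volumes``)
        with per-subject covariates; missing values allowed.
    """

    volumes: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vols = self.volumes
        if vols.shape[0] < 2 or vols.shape[1] < 2:
            raise AnnotationError(
                f"need at least 2 subjects and 2 observers, got {vols.shape}"
            )
        if vols.index.has_duplicates:
            raise AnnotationError("duplicate subject identifiers")
        if vols.columns.has_duplicates:
            raise AnnotationError("duplicate observer identifiers")
        arr = vols.to_numpy(dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise AnnotationError(
                f"missing volume for subject {vols.index[i]!r}, "
                f"observer {vols.columns[j]!r}"
            )
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise AnnotationError(
                f"non-positive volume {arr[i, j]} for subject "
                f"{vols.index[i]!r}, observer {vols.columns[j]!r}"
            )
        meta = self.metadata
        if meta is None:
            meta = pd.DataFrame(index=vols.index)
            object.__setattr__(self, "metadata", meta)
        else:
            if not meta.index.equals(vols.index):
                meta = meta.reindex(vols.index)
                object.__setattr__(self, "metadata", meta)
            for col in _NONNEGATIVE_META:
                if col in meta.columns:
                    vals = pd.to_numeric(meta[col], errors="coerce")
                    if (vals.dropna() < 0).any():
                        raise AnnotationError(f"metadata column {col!r} negative")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_observers(self) -> int:
        return self.volumes.shape[1]

    @property
    def subject_ids(self) -> pd.Index:
        return self.volumes.index

    @property
    def observer_ids(self) -> pd.Index:
        return self.volumes.columns

    def to_array(self) -> np.ndarray:
        """Return the n×m volume grid as a float array."""
        return self.volumes.to_numpy(dtype=float)

    def subset(self, subjects: Sequence) -> "AnnotationMatrix":
        """Restrict to the given subjects, preserving their current order."""
        keep = [s for s in self.subject_ids if s in set(subjects)]
        return AnnotationMatrix(self.volumes.loc[keep], self.metadata.loc[keep])

    def scale(self, c: float) -> "AnnotationMatrix":
        """Multiply every volume by a positive constant (unit change)."""
        if c <= 0:
            raise AnnotationError("scale factor must be positive")
        return AnnotationMatrix(self.volumes * c, self.metadata)

    @classmethod
    def from_wide(
        cls,
        volumes,
        subject_ids: Sequence | None = None,
        observer_ids: Sequence | None = None,
        metadata: pd.DataFrame | None = None,
    ) -> "AnnotationMatrix":
        """Build from an in-memory n×m array (convenience wrapper)."""
        arr = np.asarray(volumes, dtype=float)
        if subject_ids is None:
            subject_ids = [f"S{i + 1}" for i in range(arr.shape[0])]
        if observer_ids is None:
            observer_ids = [f"O{j + 1}" for j in range(arr.shape[1])]
        vols = pd.DataFrame(arr, index=pd.Index(subject_ids), columns=pd.Index(observer_ids))
        return cls(vols, metadata)

    def to_long(
        self,
        subject_col: str = "subject",
        observer_col: str = "observer",
        volume_col: str = "volume",
    ) -> pd.DataFrame:
        """Melt back to the long (one row per annotation) layout, metadata
        repeated within subject."""
        long = (
            self.volumes.rename_axis(subject_col)
            .reset_index()
            .melt(id_vars=subject_col, var_name=observer_col, value_name=volume_col)
        )
        if len(self.metadata.columns):
            long = long.merge(
                self.metadata.rename_axis(subject_col).reset_index(),
                on=subject_col,
                how="left",
            )
        # stable subject-major order, observers in column order
        order = {s: i for i, s in enumerate(self.subject_ids)}
        oorder = {o: j for j, o in enumerate(self.observer_ids)}
        long = long.sort_values(
            by=[subject_col, observer_col],
            key=lambda s: s.map(order if s.name == subject_col else oorder),
            kind="stable",
        ).reset_index(drop=True)
        return long


def _first_appearance(values: pd.Series) -> list:
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = len(seen)
    return sorted(seen, key=seen.get)


def read_annotations(
    path,
    delimiter: str | None = None,
    subject_col: str = "subject",
    observer_col: str = "observer",
    volume_col: str = "volume",
) -> AnnotationMatrix:
    """Read a long-format annotation file into a validated matrix.

    The file must contain one row per (subject, observer) measurement with a
    header row.  Subject and observer order follow first appearance in the
    file.  Any extra columns are treated as per-subject metadata and must be
    constant within each subject.

    Raises
    ------
    AnnotationError
        If a (subject, observer) cell is missing or duplicated, a volume is
        non-positive, or metadata varies within a subject.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter)
    for col in (subject_col, observer_col, volume_col):
        if col not in df.columns:
            raise AnnotationError(f"required column {col!r} not found in {path}")

    subjects = _first_appearance(df[subject_col])
    observers = _first_appearance(df[observer_col])

    dup = df.duplicated(subset=[subject_col, observer_col])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise AnnotationError(
            f"duplicate measurement for subject {row[subject_col]!r}, "
            f"observer {row[observer_col]!r}"
        )
    vols = (
        df.pivot(index=subject_col, columns=observer_col, values=volume_col)
        .reindex(index=subjects, columns=observers)
    )
    if vols.isna().any().any():
        mask = vols.isna()
        i = mask.any(axis=1).idxmax()
        j = mask.loc[i].idxmax()
        raise AnnotationError(f"missing volume for subject {i!r}, observer {j!r}")

    meta_cols = [c for c in df.columns if c not in (subject_col, observer_col, volume_col)]
    metadata = None
    if meta_cols:
        grouped = df.groupby(subject_col, sort=False)[meta_cols]
        nun = grouped.nunique(dropna=False)
        if (nun > 1).any().any():
            bad_subject = nun.index[(nun > 1).any(axis=1)][0]
            bad_col = nun.columns[(nun.loc[bad_subject] > 1)][0]
            raise AnnotationError(
                f"metadata column {bad_col!r} is not constant within subject "
                f"{bad_subject!r}"
            )
        metadata = grouped.first().reindex(subjects)
        metadata.index.name = None
    vols.index.name = None
    vols.columns.name = None
    return AnnotationMatrix(vols, metadata)


def write_table(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a report table as delimited text at full float precision.

    Numbers round-trip exactly through :func:`read_table` (``repr``-level
    precision).  Refuses to write an empty table.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=delimiter, index=False)


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Inverse of :func:`write_table`."""
    return pd.read_csv(path, sep=delimiter)
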