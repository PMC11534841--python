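"""Quartile stratification by average observed volume and per-stratum reports.

Subjects are ranked by their average observed volume and split into four
contiguous blocks (I = smallest .. IV = largest).  Rank-based blocks rather
than interpolated quantile thresholds guarantee an exact 25/25/25/25 split
for a 100-subject cohort; any remainder goes to the lowest strata first.

The cyst-exclusion sensitivity analysis drops cyst-flagged subjects *within*
their full-cohort stratum — strata are never re-assigned after exclusion, so
an excluded stratum keeps its original label and the other strata are
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import LoamAgreement, LoamResult, subject_stats
from .data import AnnotationMatrix

__all__ = ["STRATUM_LABELS", "StratumAssignment", "stratify_quartiles", "stratum_report"]

STRATUM_LABELS: tuple[str, ...] = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class StratumAssignment:
    """Subject → volume-quartile label, plus the boundary volumes."""

    labels: pd.Series  # index: subject id, values in STRATUM_LABELS
    cut_volumes: tuple[float, float, float]  # largest mean volume of strata I..III

    def subjects_in(self, label: str) -> list:
        return list(self.labels.index[self.labels == label])

    @property
    def sizes(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in STRATUM_LABELS}


def stratify_quartiles(mean_volumes: pd.Series) -> StratumAssignment:
    """Assign each subject to a volume quartile stratum I–IV.

    Subjects are sorted ascending by mean volume (stable, so ties keep input
    order) and split into four contiguous blocks whose sizes differ by at
    most one; with n not divisible by 4 the extra subjects go to the lowest
    strata.

    Parameters
    ----------
    mean_volumes
        Per-subject average observed volume (e.g. the ``mean_volume`` column
        of :func:`~volagree.agreement.subject_stats`).
    """
    n = len(mean_volumes)
    if n < 4:
        raise ValueError(f"need at least 4 subjects to form quartiles, got {n}")
    order = np.argsort(mean_volumes.to_numpy(), kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if k < rem else 0) for k in range(4)]
    labels = np.empty(n, dtype=object)
    start = 0
    cuts = []
    for lab, size in zip(STRATUM_LABELS, sizes):
        block = order[start : start + size]
        labels[block] = lab
        if lab != "IV":
            cuts.append(float(mean_volumes.iloc[block[-1]]))
        start += size
    return StratumAssignment(
        labels=pd.Series(labels, index=mean_volumes.index, name="stratum"),
        cut_volumes=tuple(cuts),
    )


def stratum_report(
    matrix: AnnotationMatrix,
    assignment: StratumAssignment | None = None,
    exclude_cysts: bool = False,
    **loam_kwargs,
) -> pd.DataFrame:
    """Per-stratum agreement table (one reliability-table row per stratum).

    Runs the full :class:`~volagree.agreement.LoamAgreement` stack on each
    stratum's submatrix.  With ``exclude_cysts=True``, subjects whose
    metadata flags a peritumoral cyst are dropped within their stratum; a
    stratum reduced below 2 subjects is skipped with a warning.

    Returns a DataFrame with one row per reported stratum and the flattened
    :class:`~volagree.agreement.LoamResult` columns.
    """
    if assignment is None:
        assignment = stratify_quartiles(subject_stats(matrix)["mean_volume"])
    cyst = None
    if exclude_cysts:
        if "cyst" not in matrix.metadata.columns:
            cyst = pd.Series(False, index=matrix.subject_ids)
        else:
            cyst = matrix.metadata["cyst"].fillna(False).astype(bool)

    rows = []
    for lab in STRATUM_LABELS:
        members = assignment.subjects_in(lab)
        if not members:
            continue
        if exclude_cysts:
            members = [s for s in members if not cyst.loc[s]]
        if len(members) < 2:
            warnings.warn(
                f"stratum {lab} has fewer than 2 subjects after cyst exclusion; skipped"
            )
            continue
        sub = matrix.subset(members)
        res: LoamResult = LoamAgreement(**loam_kwargs).fit(sub).to_result()
        row = {"stratum": lab, "n_subjects": len(members)}
        row.update(res.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
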