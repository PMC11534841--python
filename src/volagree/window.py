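"""Sliding-window volume-dependent agreement limits and the LOAM% calculator.

Sorting subjects by average observed volume and sliding a width-w window
(step 1) across them yields a quasi-continuous curve of LOAM% against
volume.  The default width of 26 subjects matches the reliability-study
sample size, so each window is itself an adequately powered agreement study.

Two consumer operations sit on top of the curve:

* :func:`threshold_crossing` — the volume at which the curve (by default its
  CI upper bound) falls below a growth-cutoff line such as the conventional
  20% limit, using a persistence rule to ignore spurious early dips of a
  noisy curve;
* :func:`loam_lookup` — the per-tumor-volume calculator: log-volume
  piecewise-linear interpolation of LOAM% and its CI at any volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .agreement import LoamAgreement, subject_stats
from .data import AnnotationMatrix

__all__ = ["WindowCurve", "window_curve", "threshold_crossing", "loam_lookup", "SlidingWindowLoam"]

_CURVE_COLUMNS = [
    "window",
    "mean_volume",
    "loam_abs",
    "loam_abs_ci_low",
    "loam_abs_ci_high",
    "loam_pct",
    "loam_pct_ci_low",
    "loam_pct_ci_high",
    "sigma_o",
    "sigma_r",
    "icc",
    "observer_truncated",
]


@dataclass(frozen=True)
class WindowCurve:
    """Ordered sequence of per-window agreement results.

    ``table`` has one row per window (columns ``_CURVE_COLUMNS``);
    ``members`` lists each window's subject ids, consecutive in volume rank.
    """

    table: pd.DataFrame
    members: tuple[tuple, ...]
    width: int

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_table(cls, table: pd.DataFrame, width: int | None = None) -> "WindowCurve":
        """Rebuild a curve from a previously exported table (members lost)."""
        missing = {"mean_volume", "loam_pct"} - set(table.columns)
        if missing:
            raise ValueError(f"curve table lacks columns {sorted(missing)}")
        if width is None:
            width = int(table.attrs.get("width", 0)) or -1
        return cls(table=table.reset_index(drop=True), members=(), width=width)


def window_curve(
    matrix: AnnotationMatrix,
    width: int = 26,
    **loam_kwargs,
) -> WindowCurve:
    """LOAM results for every contiguous width-w block of volume-ranked subjects.

    Subjects are sorted ascending by their average observed volume; window k
    covers ranks k..k+w−1, so an n-subject cohort yields n−w+1 windows and
    consecutive windows differ by exactly one dropped and one added subject.
    The window's abscissa is the arithmetic mean of its members' subject
    means.
    """
    n = matrix.n_subjects
    if width < 4:
        raise ValueError("window width must be at least 4")
    if n < width:
        raise ValueError(f"cohort of {n} subjects is smaller than window width {width}")
    stats_df = subject_stats(matrix)
    order = np.argsort(stats_df["mean_volume"].to_numpy(), kind="stable")
    ids = list(stats_df.index[order])

    seed = loam_kwargs.pop("random_state", None)
    child_seeds = np.random.SeedSequence(seed).spawn(n - width + 1)

    rows = []
    members = []
    for k in range(n - width + 1):
        block = ids[k : k + width]
        sub = matrix.subset(block)
        est = LoamAgreement(
            random_state=np.random.default_rng(child_seeds[k]), **loam_kwargs
        ).fit(sub)
        rows.append(
            {
                "window": k,
                "mean_volume": est.group_mean_volume_,
                "loam_abs": est.loam_abs_,
                "loam_abs_ci_low": est.loam_abs_ci_[0],
                "loam_abs_ci_high": est.loam_abs_ci_[1],
                "loam_pct": est.loam_pct_,
                "loam_pct_ci_low": est.loam_pct_ci_[0],
                "loam_pct_ci_high": est.loam_pct_ci_[1],
                "sigma_o": est.sigma_o_,
                "sigma_r": est.sigma_r_,
                "icc": est.icc_,
                "observer_truncated": est.observer_truncated_,
            }
        )
        members.append(tuple(block))
    table = pd.DataFrame(rows, columns=_CURVE_COLUMNS)
    table.attrs["width"] = width
    return WindowCurve(table=table, members=tuple(members), width=width)


def _curve_table(curve) -> pd.DataFrame:
    if isinstance(curve, WindowCurve):
        return curve.table
    return curve


def threshold_crossing(
    curve,
    threshold_pct: float = 20.0,
    bound: str = "upper",
    rule: str = "persistent",
) -> float | None:
    """Volume (mm³) at which the LOAM% curve drops below a cutoff line.

    Parameters
    ----------
    curve : WindowCurve or curve table
    threshold_pct
        The reference agreement limit, e.g. the conventional 20% cutoff.
    bound : {"upper", "point"}
        Track the CI upper bound (conservative, default) or the point
        estimate.
    rule : {"persistent", "first", "bracket"}
        ``persistent`` (default) requires the tracked value to stay at or
        below the threshold for *all* larger-volume windows before the
        crossing counts — a noisy curve can dip below the line early and
        bounce back; ``first`` takes the first touch.  On a noisy curve the
        two readings bracket the underlying crossing from below and above;
        ``bracket`` returns their geometric mean as a low-bias point
        estimate.

    Returns the log-volume linear interpolation between the first qualifying
    window and its predecessor (the first window's mean volume if it already
    qualifies), or ``None`` when the curve never settles below the line.
    """
    table = _curve_table(curve)
    if len(table) == 0:
        raise ValueError("empty curve")
    if rule == "bracket":
        first = threshold_crossing(curve, threshold_pct, bound, "first")
        pers = threshold_crossing(curve, threshold_pct, bound, "persistent")
        if first is None or pers is None:
            return None
        return float(np.sqrt(first * pers))
    col = {"upper": "loam_pct_ci_high", "point": "loam_pct"}[bound]
    vals = table[col].to_numpy(dtype=float)
    vols = table["mean_volume"].to_numpy(dtype=float)

    ok = vals <= threshold_pct
    if rule == "persistent":
        # qualifying windows: below threshold from here onwards
        ok = np.logical_and.accumulate(ok[::-1])[::-1]
    elif rule != "first":
        raise ValueError(f"unknown rule {rule!r}")
    if not ok.any():
        return None
    k = int(np.argmax(ok))
    if k == 0:
        return float(vols[0])
    y0, y1 = vals[k - 1], vals[k]
    if y1 == y0:
        return float(vols[k])
    frac = (threshold_pct - y0) / (y1 - y0)
    log_v = np.log(vols[k - 1]) + frac * (np.log(vols[k]) - np.log(vols[k - 1]))
    return float(np.exp(log_v))


def loam_lookup(curve, volume: float) -> dict:
    """Interpolated LOAM% (with CI) at an individual tumor volume.

    Piecewise-linear interpolation of ``loam_pct`` and its CI bounds against
    log window mean volume.  Volumes outside the curve's range clamp to the
    nearest end and are flagged ``extrapolated``.
    """
    if volume <= 0:
        raise ValueError("volume must be positive (mm³)")
    table = _curve_table(curve)
    if len(table) == 0:
        raise ValueError("empty curve")
    vols = table["mean_volume"].to_numpy(dtype=float)
    logv = np.log(vols)
    x = np.log(volume)
    extrapolated = bool(x < logv[0] or x > logv[-1])
    out = {"volume": float(volume), "extrapolated": extrapolated}
    for key, col in (
        ("loam_pct", "loam_pct"),
        ("ci_low", "loam_pct_ci_low"),
        ("ci_high", "loam_pct_ci_high"),
    ):
        if col in table.columns:
            out[key] = float(np.interp(x, logv, table[col].to_numpy(dtype=float)))
    return out


class SlidingWindowLoam(BaseEstimator):
    """Volume-dependent agreement limits as a fit/predict estimator.

    ``fit`` builds the sliding-window curve from an annotation cohort and
    locates the threshold crossing; ``predict`` evaluates the per-volume
    LOAM% calculator at new tumor volumes.

    Parameters
    ----------
    width : int, default 26
        Window width in subjects; the default equals the reliability-study
        sample size so every window is adequately powered.
    threshold_pct : float, default 20.0
        Reference agreement-limit line used for ``crossing_volume_``.
    bound : {"upper", "point"}, rule : {"persistent", "first"}
        Passed to :func:`threshold_crossing`.
    alpha, n_boot, random_state
        Forwarded to the per-window :class:`~volagree.agreement.LoamAgreement`.

    Attributes
    ----------
    curve_ : WindowCurve
    crossing_volume_ : float or None
    """

    def __init__(
        self,
        width: int = 26,
        threshold_pct: float = 20.0,
        bound: str = "upper",
        rule: str = "persistent",
        alpha: float = 0.05,
        n_boot: int = 2_000,
        random_state=None,
    ):
        self.width = width
        self.threshold_pct = threshold_pct
        self.bound = bound
        self.rule = rule
        self.alpha = alpha
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None) -> "SlidingWindowLoam":
        if not isinstance(X, AnnotationMatrix):
            X = AnnotationMatrix.from_wide(np.asarray(X, dtype=float))
        self.curve_ = window_curve(
            X,
            width=self.width,
            alpha=self.alpha,
            n_boot=self.n_boot,
            random_state=self.random_state,
        )
        self.crossing_volume_ = threshold_crossing(
            self.curve_, self.threshold_pct, bound=self.bound, rule=self.rule
        )
        return self

    def predict(self, volumes) -> np.ndarray:
        """LOAM% point estimate at each tumor volume (mm³)."""
        return np.array([loam_lookup(self.curve_, v)["loam_pct"] for v in np.atleast_1d(volumes)])

    def predict_interval(self, volumes) -> pd.DataFrame:
        """LOAM% with CI bounds and extrapolation flag at each volume."""
        return pd.DataFrame([loam_lookup(self.curve_, v) for v in np.atleast_1d(volumes)])
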