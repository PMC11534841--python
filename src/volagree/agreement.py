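"""Limits of agreement with the mean (LOAM), variance components and ICC.

Model
-----
For subject i = 1..n and observer j = 1..m the observed volume is

    Y_ij = mu + a_i + b_j + e_ij,

with subject effects a_i (fixed — they cancel in deviations from the subject
mean), systematic observer offsets b_j ~ N(0, sigma_O^2) and random
measurement error e_ij ~ N(0, sigma_R^2).  The LOAM half-width quantifies how
far a single observer's measurement may stray from the m-observer mean of the
same subject:

    Var(Y_ij - Ybar_i.) = (m-1)/m * (sigma_O^2 + sigma_R^2)
    LOAM = z * sqrt((m-1)/m * (sigma_O^2 + sigma_R^2)),

the multi-observer generalization of Bland–Altman limits.  Components are
estimated from the classical two-way crossed ANOVA mean squares; the LOAM
confidence interval uses the modified large-sample (Graybill–Wang) interval
for the positive linear combination

    psi = sigma_O^2 + sigma_R^2 = (1/n) MS_O + ((n-1)/n) MS_R,

and the per-component SD intervals use a seeded parametric bootstrap of the
mean squares.  The ICC reported is the two-way random, absolute-agreement,
single-measure form with the standard F-based interval (Satterthwaite
denominator degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import AnnotationMatrix

__all__ = [
    "MeanSquares",
    "VarianceComponents",
    "LoamResult",
    "DegenerateDataError",
    "Z_95",
    "subject_stats",
    "anova_mean_squares",
    "variance_components",
    "loam_estimate",
    "loam_ci",
    "component_sd_cis",
    "icc_absolute_single",
    "LoamAgreement",
]

#: Exact standard-normal 0.975 quantile (not the rounded 1.96) so that point
#: estimates and CI end-points transform consistently.
Z_95: float = float(stats.norm.ppf(0.975))


class DegenerateDataError(ValueError):
    """Raised when a quantity (e.g. the ICC) is undefined for the data."""


@dataclass(frozen=True)
class MeanSquares:
    """Two-way crossed ANOVA summary (no interaction term)."""

    ms_subject: float
    ms_observer: float
    ms_residual: float
    n: int
    m: int

    @property
    def df_subject(self) -> int:
        return self.n - 1

    @property
    def df_observer(self) -> int:
        return self.m - 1

    @property
    def df_residual(self) -> int:
        return (self.n - 1) * (self.m - 1)


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments observer/residual variance components (mm⁶).

    ``sigma2_observer`` is truncated at zero; the raw (possibly negative)
    moment estimate is kept for diagnostics and ``observer_truncated`` is set
    when truncation occurred.
    """

    sigma2_observer: float
    sigma2_residual: float
    observer_truncated: bool
    sigma2_observer_raw: float

    @property
    def total(self) -> float:
        return self.sigma2_observer + self.sigma2_residual


@dataclass(frozen=True)
class LoamResult:
    """One agreement summary row for a subject group (one reliability-table row)."""

    group_mean_volume: float
    loam_abs: float
    loam_abs_ci: tuple[float, float]
    loam_pct: float
    loam_pct_ci: tuple[float, float]
    sigma_o: float
    sigma_o_ci: tuple[float, float]
    sigma_r: float
    sigma_r_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    n: int
    m: int
    observer_truncated: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("loam_abs_ci", "loam_pct_ci", "sigma_o_ci", "sigma_r_ci", "icc_ci"):
            lo, hi = d.pop(key)
            d[key.replace("_ci", "_ci_low")] = lo
            d[key.replace("_ci", "_ci_high")] = hi
        return d


# ----------------------------------------------------------------------
# per-subject statistics
# ----------------------------------------------------------------------

def subject_stats(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Per-subject mean volume, SD across observers and relative SD.

    ``sd_rel_pct`` (SD_V%) is the SD of a subject's m observed volumes —
    sample (m−1) denominator — divided by the subject's mean volume, ×100.
    """
    arr = matrix.to_array()
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    return pd.DataFrame(
        {
            "mean_volume": mean,
            "sd_volume": sd,
            "sd_rel_pct": 100.0 * sd / mean,
        },
        index=matrix.subject_ids,
    )


# ----------------------------------------------------------------------
# ANOVA and components
# ----------------------------------------------------------------------

def _as_array(X) -> np.ndarray:
    if isinstance(X, AnnotationMatrix):
        return X.to_array()
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an n×m measurement grid")
    return arr


def anova_mean_squares(X) -> MeanSquares:
    """Classical two-way crossed ANOVA mean squares for a complete grid."""
    arr = _as_array(X)
    n, m = arr.shape
    if n < 2 or m < 2:
        raise ValueError(f"need n ≥ 2 subjects and m ≥ 2 observers, got {arr.shape}")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ms_subject = m * float(((row_means - grand) ** 2).sum()) / (n - 1)
    ms_observer = n * float(((col_means - grand) ** 2).sum()) / (m - 1)
    resid = arr - row_means[:, None] - col_means[None, :] + grand
    ms_residual = float((resid**2).sum()) / ((n - 1) * (m - 1))
    return MeanSquares(ms_subject, ms_observer, ms_residual, n, m)


def variance_components(ms: MeanSquares) -> VarianceComponents:
    """Observer and residual variance components from the mean squares.

    sigma_R^2 = MS_R;  sigma_O^2 = (MS_O − MS_R)/n, truncated at 0 with a
    flag when the raw moment estimate is negative (small true observer
    variance and few observers make this common).
    """
    raw = (ms.ms_observer - ms.ms_residual) / ms.n
    truncated = raw < 0
    return VarianceComponents(
        sigma2_observer=max(0.0, raw),
        sigma2_residual=ms.ms_residual,
        observer_truncated=bool(truncated),
        sigma2_observer_raw=raw,
    )


def _finite_factor(m: int, finite_observer_correction: bool) -> float:
    return (m - 1) / m if finite_observer_correction else 1.0


def loam_estimate(
    vc: VarianceComponents,
    m: int,
    z: float = Z_95,
    finite_observer_correction: bool = True,
) -> float:
    """LOAM half-width z·sqrt((m−1)/m · (σ_O² + σ_R²)) in mm³.

    The (m−1)/m factor is the exact model variance of a single measurement's
    deviation from the m-observer mean; disable it only for sensitivity
    analysis against the infinite-observer convention.
    """
    if m < 2:
        raise ValueError("need m ≥ 2 observers")
    return z * math.sqrt(_finite_factor(m, finite_observer_correction) * vc.total)


def loam_ci(
    ms: MeanSquares,
    z: float = Z_95,
    alpha: float = 0.05,
    finite_observer_correction: bool = True,
) -> tuple[float, float]:
    """Graybill–Wang modified large-sample CI for the LOAM half-width.

    psi = σ_O² + σ_R² = (1/n)·MS_O + ((n−1)/n)·MS_R is a positive linear
    combination of independent mean squares; the MLS bounds are

        high = psi + sqrt(Σ (H_k c_k MS_k)²),  H_k = df_k/χ²(α/2; df_k) − 1
        low  = psi − sqrt(Σ (G_k c_k MS_k)²),  G_k = 1 − df_k/χ²(1−α/2; df_k)

    mapped through z·sqrt((m−1)/m · psi-bound); the interval is asymmetric
    about the point estimate.  The lower bound is clamped at 0.
    """
    n, m = ms.n, ms.m
    coeffs = np.array([1.0 / n, (n - 1) / n])
    mss = np.array([ms.ms_observer, ms.ms_residual])
    dfs = np.array([ms.df_observer, ms.df_residual], dtype=float)
    psi = float(coeffs @ mss)
    if psi == 0.0:
        return (0.0, 0.0)
    H = dfs / stats.chi2.ppf(alpha / 2, dfs) - 1.0
    G = 1.0 - dfs / stats.chi2.ppf(1 - alpha / 2, dfs)
    hi_psi = psi + math.sqrt(float(((H * coeffs * mss) ** 2).sum()))
    lo_psi = max(0.0, psi - math.sqrt(float(((G * coeffs * mss) ** 2).sum())))
    fac = _finite_factor(m, finite_observer_correction)
    return (z * math.sqrt(fac * lo_psi), z * math.sqrt(fac * hi_psi))


def component_sd_cis(
    ms: MeanSquares,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    random_state=None,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap percentile CIs for σ_O and σ_R (SD scale, mm³).

    Mean squares are resampled from their fitted scaled-χ² distributions
    (E[MS_O] = n·σ̂_O² + σ̂_R², E[MS_R] = σ̂_R²), components recomputed per
    resample with the same zero-truncation, and percentile intervals taken
    on the SD scale.  Lower bounds truncate at 0.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unstable percentile intervals")
    vc = variance_components(ms)
    rng = np.random.default_rng(random_state)
    e_ms_o = ms.n * vc.sigma2_observer + vc.sigma2_residual
    e_ms_r = vc.sigma2_residual
    ms_o_star = e_ms_o * rng.chisquare(ms.df_observer, n_boot) / ms.df_observer
    ms_r_star = e_ms_r * rng.chisquare(ms.df_residual, n_boot) / ms.df_residual
    sig_o2 = np.maximum(0.0, (ms_o_star - ms_r_star) / ms.n)
    sig_r2 = ms_r_star
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    lo_o, hi_o = np.percentile(np.sqrt(sig_o2), qs)
    lo_r, hi_r = np.percentile(np.sqrt(sig_r2), qs)
    return {
        "sigma_o_ci": (float(lo_o), float(hi_o)),
        "sigma_r_ci": (float(lo_r), float(hi_r)),
    }


def icc_absolute_single(ms: MeanSquares, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-way random, absolute-agreement, single-measure ICC with CI.

    ICC = (MS_S − MS_R) / (MS_S + (m−1)MS_R + (m/n)(MS_O − MS_R)); the CI is
    the standard F-based interval with Satterthwaite degrees of freedom for
    the denominator mean-square combination.
    """
    msr, msc, mse = ms.ms_subject, ms.ms_observer, ms.ms_residual
    n, k = ms.n, ms.m
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    # Satterthwaite df for a*MS_O + b*MS_R
    if icc >= 1.0:  # perfect agreement: CI collapses
        return 1.0, (1.0, 1.0)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else ms.df_residual
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(min(upper, 1.0)))


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------

class LoamAgreement(BaseEstimator):
    """Agreement analysis of one subject group: LOAM, components, ICC.

    A fit-shaped wrapper over the functional layer: ``fit`` accepts an
    :class:`~volagree.data.AnnotationMatrix`, DataFrame or n×m array and
    exposes every reliability-table quantity as a fitted attribute.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided level for every confidence interval (95% by default).
    z : float or None
        Normal quantile defining the agreement limits; ``None`` uses the
        exact 0.975 quantile matching ``alpha=0.05`` limits.
    finite_observer_correction : bool, default True
        Apply the exact (m−1)/m deviation-from-mean variance factor.
    n_boot : int, default 10000
        Parametric-bootstrap resamples for the component SD intervals.
    random_state : int, Generator or None
        Seed for the bootstrap; fixed seed gives identical CIs on re-fit.

    Attributes
    ----------
    mean_squares_, variance_components_ : model summaries
    loam_abs_, loam_abs_ci_ : half-width in mm³ and its CI
    loam_pct_, loam_pct_ci_ : half-width as percent of the group mean
    sigma_o_, sigma_o_ci_, sigma_r_, sigma_r_ci_ : component SDs (mm³)
    icc_, icc_ci_ : absolute-agreement single-measure ICC (NaN when the
        grid is totally degenerate)
    group_mean_volume_, n_, m_, observer_truncated_

    Examples
    --------
    >>> import numpy as np
    >>> est = LoamAgreement(random_state=0).fit(np.array([[10., 12.], [20., 18.], [30., 33.]]))
    >>> round(est.loam_abs_, 3)
    2.593
    """

    def __init__(
        self,
        alpha: float = 0.05,
        z: float | None = None,
        finite_observer_correction: bool = True,
        n_boot: int = 10_000,
        random_state=None,
    ):
        self.alpha = alpha
        self.z = z
        self.finite_observer_correction = finite_observer_correction
        self.n_boot = n_boot
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "LoamAgreement":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        arr = _as_array(X)
        z = Z_95 if self.z is None else float(self.z)
        ms = anova_mean_squares(arr)
        vc = variance_components(ms)

        self.n_, self.m_ = ms.n, ms.m
        self.mean_squares_ = ms
        self.variance_components_ = vc
        self.group_mean_volume_ = float(arr.mean())
        self.observer_truncated_ = vc.observer_truncated

        self.loam_abs_ = loam_estimate(vc, ms.m, z, self.finite_observer_correction)
        self.loam_abs_ci_ = loam_ci(ms, z, self.alpha, self.finite_observer_correction)
        # the CI is centred on the untruncated moment estimate of psi; keep
        # the interval enveloping the (possibly truncation-raised) point
        lo, hi = self.loam_abs_ci_
        self.loam_abs_ci_ = (min(lo, self.loam_abs_), max(hi, self.loam_abs_))

        gm = self.group_mean_volume_
        self.loam_pct_ = 100.0 * self.loam_abs_ / gm
        self.loam_pct_ci_ = tuple(100.0 * b / gm for b in self.loam_abs_ci_)

        self.sigma_o_ = math.sqrt(vc.sigma2_observer)
        self.sigma_r_ = math.sqrt(vc.sigma2_residual)
        cis = component_sd_cis(ms, self.alpha, self.n_boot, self.random_state)
        self.sigma_o_ci_ = cis["sigma_o_ci"]
        self.sigma_r_ci_ = cis["sigma_r_ci"]

        try:
            self.icc_, self.icc_ci_ = icc_absolute_single(ms, self.alpha)
        except DegenerateDataError:
            self.icc_, self.icc_ci_ = float("nan"), (float("nan"), float("nan"))
        return self

    def to_result(self) -> LoamResult:
        """Bundle the fitted attributes into a :class:`LoamResult` row."""
        return LoamResult(
            group_mean_volume=self.group_mean_volume_,
            loam_abs=self.loam_abs_,
            loam_abs_ci=tuple(self.loam_abs_ci_),
            loam_pct=self.loam_pct_,
            loam_pct_ci=tuple(self.loam_pct_ci_),
            sigma_o=self.sigma_o_,
            sigma_o_ci=tuple(self.sigma_o_ci_),
            sigma_r=self.sigma_r_,
            sigma_r_ci=tuple(self.sigma_r_ci_),
            icc=self.icc_,
            icc_ci=tuple(self.icc_ci_),
            n=self.n_,
            m=self.m_,
            observer_truncated=self.observer_truncated_,
        )
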