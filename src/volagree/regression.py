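"""Uni- and multivariable OLS of relative volume SD on covariates.

The response is the per-subject relative volume standard deviation SD_V%
(SD of the m observed volumes / their mean × 100).  Covariates are the MRI
acquisition parameters and tumor characteristics; each is first screened in
a single-covariate OLS, and covariates significant at the screening level
enter one joint ("adjusted") model — the classical univariable →
multivariable confounding workup.

Coding conventions: laterality L=0/R=1, cyst no=0/yes=1, acquisition date
as decimal years, field strength numeric in tesla.  Complete cases per
model; no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_COVARIATES",
    "build_regression_frame",
    "univariable_scan",
    "multivariable_fit",
    "regression_table",
]

#: Default covariate list: imaging parameters then tumor characteristics.
DEFAULT_COVARIATES: tuple[str, ...] = (
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
    "volume",
    "laterality",
    "cyst",
    "followup_time",
)

_COND_THRESHOLD = 1e8  # design-matrix condition number flagged as collinear


def _encode(col: pd.Series) -> pd.Series:
    """Numeric coding for the categorical covariates."""
    if col.dtype == bool:
        return col.astype(float)
    if col.dtype == object:
        mapping = {"L": 0.0, "R": 1.0, "left": 0.0, "right": 1.0,
                   "no": 0.0, "yes": 1.0, "M": 0.0, "F": 1.0,
                   False: 0.0, True: 1.0}
        return col.map(mapping).astype(float)
    return pd.to_numeric(col, errors="coerce")


def build_regression_frame(matrix, stats_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge per-subject agreement statistics with encoded metadata.

    ``volume`` is the average observed volume; the response column is
    ``sd_rel_pct``.
    """
    from .agreement import subject_stats

    if stats_df is None:
        stats_df = subject_stats(matrix)
    frame = pd.DataFrame(
        {"sd_rel_pct": stats_df["sd_rel_pct"], "volume": stats_df["mean_volume"]}
    )
    for col in matrix.metadata.columns:
        if col in ("sex",):
            continue
        frame[col] = _encode(matrix.metadata[col])
    return frame


def _ols_rows(y: pd.Series, X: pd.DataFrame, alpha: float, adjusted: bool) -> list[dict]:
    design = sm.add_constant(X, has_constant="add")
    cond = np.linalg.cond(design.to_numpy())
    flagged = cond > _COND_THRESHOLD
    if flagged:
        warnings.warn(
            f"collinear design (condition number {cond:.3g}); "
            "coefficients from a pseudo-inverse fit"
        )
    model = sm.OLS(y, design).fit()
    ci = model.conf_int(alpha)
    rows = []
    for name in X.columns:
        rows.append(
            {
                "covariate": name,
                "B": float(model.params[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
                "p_value": float(model.pvalues[name]),
                "n": int(model.nobs),
                "adjusted": adjusted,
                "estimable": True,
                "collinear": flagged,
            }
        )
    return rows


def univariable_scan(
    frame: pd.DataFrame,
    response: str = "sd_rel_pct",
    covariates=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One single-covariate OLS per covariate, intercept included.

    CIs and two-sided p-values from the t distribution; complete cases per
    covariate.  A covariate that is constant across its complete cases (or
    has fewer than 3 of them) is flagged inestimable.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in frame.columns]
    rows = []
    for cov in covariates:
        sub = frame[[response, cov]].dropna()
        x = sub[cov]
        if len(sub) < 3 or x.nunique() < 2:
            rows.append(
                {
                    "covariate": cov,
                    "B": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "n": int(len(sub)),
                    "adjusted": False,
                    "estimable": False,
                    "collinear": False,
                }
            )
            continue
        rows.extend(_ols_rows(sub[response], sub[[cov]], alpha, adjusted=False))
    return pd.DataFrame(rows)


def multivariable_fit(
    frame: pd.DataFrame,
    selected,
    response: str = "sd_rel_pct",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint OLS of the response on the selected covariates.

    With a single selected covariate the adjusted row coincides with the
    univariable row by construction; with none, an empty table is returned.
    Complete cases across all selected covariates.
    """
    selected = list(selected)
    if not selected:
        return pd.DataFrame(
            columns=["covariate", "B", "ci_low", "ci_high", "p_value", "n",
                     "adjusted", "estimable", "collinear"]
        )
    sub = frame[[response, *selected]].dropna()
    rows = _ols_rows(sub[response], sub[selected], alpha, adjusted=True)
    return pd.DataFrame(rows)


def regression_table(
    frame: pd.DataFrame,
    response: str = "sd_rel_pct",
    covariates=None,
    alpha: float = 0.05,
    selection_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full univariable + multivariable workup in one combined frame.

    Covariates with univariable p < ``selection_alpha`` enter the joint
    model; their adjusted coefficients are merged as ``B_adj``/``p_adj``
    columns (NaN for unselected covariates).
    """
    uni = univariable_scan(frame, response, covariates, alpha)
    sel = uni.loc[uni["estimable"] & (uni["p_value"] < selection_alpha), "covariate"]
    multi = multivariable_fit(frame, sel, response, alpha)
    merged = uni.drop(columns=["adjusted"]).rename(columns={"n": "n_uni"})
    adj = multi.set_index("covariate") if len(multi) else pd.DataFrame()
    for col_out, col_in in (
        ("B_adj", "B"),
        ("ci_low_adj", "ci_low"),
        ("ci_high_adj", "ci_high"),
        ("p_adj", "p_value"),
    ):
        merged[col_out] = (
            merged["covariate"].map(adj[col_in]) if len(adj) else np.nan
        )
    return merged
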