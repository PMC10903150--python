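"""Spirometric staging, cohort statistics and spatial line profiles.

Covers GOLD/PRISm classification from post-bronchodilator spirometry, the
5-year FEV1 decline slope and fast/slow progressor labelling, Spearman
correlations, forward-stepwise multivariable linear regression with a
compulsory covariate block, and straight-line profiles of tPRM fields
between a high- and a low-emphysema point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats

__all__ = [
    "gold_classify",
    "delta_fev1",
    "spearman",
    "RegressionResult",
    "stepwise_regression",
    "line_profile",
    "exclusion_summary",
]

FAST_PROGRESSOR_ML_YR = -60.0


def gold_classify(fev1_pct_pred: float, fev1_fvc_ratio: float) -> str:
    """Spirometric GOLD grade (or PRISm / at-risk GOLD 0).

    A preserved ratio (FEV1/FVC >= 0.7) with preserved FEV1 %predicted
    (>= 80) is "at-risk" GOLD 0; preserved ratio with reduced %predicted is
    PRISm.  Obstruction (ratio < 0.7) is graded 1-4 at the standard 80/50/30
    %predicted cut-points.
    """
    if fev1_pct_pred is None or fev1_fvc_ratio is None \
            or not np.isfinite(fev1_pct_pred) or not np.isfinite(fev1_fvc_ratio):
        raise ValueError("both FEV1 %predicted and FEV1/FVC are required")
    if fev1_fvc_ratio >= 0.7:
        return "GOLD0" if fev1_pct_pred >= 80.0 else "PRISm"
    if fev1_pct_pred >= 80.0:
        return "GOLD1"
    if fev1_pct_pred >= 50.0:
        return "GOLD2"
    if fev1_pct_pred >= 30.0:
        return "GOLD3"
    return "GOLD4"


def delta_fev1(fev1_y0_l: float, fev1_y5_l: float) -> tuple[float, str]:
    """Annualised 5-year FEV1 slope (ml/yr) and progressor label.

    delta = 1000 * (FEV1 at yr 5 - FEV1 at yr 0) / 5; the fast-progressor
    boundary is inclusive: delta <= -60 ml/yr is fast.
    """
    if fev1_y0_l is None or fev1_y5_l is None \
            or not np.isfinite(fev1_y0_l) or not np.isfinite(fev1_y5_l):
        raise ValueError("baseline and 5-year FEV1 (litres) are required")
    delta = 1000.0 * (fev1_y5_l - fev1_y0_l) / 5.0
    # tolerance keeps volumes printed to ml (e.g. 2.5 vs 2.2 L) exactly on
    # the boundary despite binary floating point
    label = "fast" if delta <= FAST_PROGRESSOR_ML_YR + 1e-9 else "slow"
    return delta, label


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank-order correlation with average-rank ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RegressionResult:
    """Final stepwise model: standardized betas, p-values and fit summary."""

    outcome: str
    retained: dict[str, tuple[float, float]]   # candidate -> (std beta, p)
    compulsory: dict[str, tuple[float, float]]  # covariate term -> (std beta, p)
    adj_r2: float
    se_estimate: float
    compulsory_covariates: list[str] = field(default_factory=list)


def _design(df: pd.DataFrame, cols: list[str], standardize: bool) -> pd.DataFrame:
    """Design matrix: z-scored continuous columns, reference-coded dummies."""
    parts = []
    for col in cols:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d)
        else:
            v = s.astype(float)
            if standardize:
                sd = v.std()
                if sd == 0:
                    raise ValueError(f"constant column {col!r} in design")
                v = (v - v.mean()) / sd
            parts.append(v.to_frame(col))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def _fit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear design matrix")
    return sm.OLS(y, Xc).fit()


def stepwise_regression(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    compulsory: list[str] = ("age", "sex", "race", "bmi", "pack_years", "ct_vendor"),
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> RegressionResult:
    """Forward-stepwise OLS with a forced compulsory covariate block.

    Candidates enter one at a time at the smallest p-value below ``entry_p``
    and are removed again if their p-value rises above ``removal_p``;
    compulsory covariates are never removed.  Standardized betas come from
    the z-scored fit; adjusted R^2 and the standard error of the estimate
    come from a parallel fit on the original outcome scale.
    """
    compulsory = list(compulsory)
    candidates = list(candidates)
    data = cohort.dropna(subset=[outcome] + candidates + compulsory)
    y_raw = data[outcome].astype(float).to_numpy()
    y_sd = y_raw.std()
    if y_sd == 0:
        raise ValueError("constant outcome")
    y_std = (y_raw - y_raw.mean()) / y_sd

    Xcomp = _design(data, compulsory, standardize=True)
    Xcand_all = _design(data, candidates, standardize=True)

    selected: list[str] = []
    while True:
        changed = False
        # forward step
        best_p, best_c = None, None
        for c in candidates:
            if c in selected:
                continue
            X = pd.concat([Xcomp, Xcand_all[selected + [c]]], axis=1)
            res = _fit(y_std, X)
            p = res.pvalues[c]
            if p < entry_p and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            selected.append(best_c)
            changed = True
        # backward step on candidates only
        if selected:
            X = pd.concat([Xcomp, Xcand_all[selected]], axis=1)
            res = _fit(y_std, X)
            worst = max(selected, key=lambda c: res.pvalues[c])
            if res.pvalues[worst] > removal_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    X_final = pd.concat([Xcomp, Xcand_all[selected]], axis=1)
    res_std = _fit(y_std, X_final)
    res_raw = _fit(y_raw, X_final)

    retained = {c: (float(res_std.params[c]), float(res_std.pvalues[c]))
                for c in selected}
    comp_terms = {c: (float(res_std.params[c]), float(res_std.pvalues[c]))
                  for c in Xcomp.columns}
    return RegressionResult(
        outcome=outcome,
        retained=retained,
        compulsory=comp_terms,
        adj_r2=float(res_raw.rsquared_adj),
        se_estimate=float(np.sqrt(res_raw.mse_resid)),
        compulsory_covariates=compulsory,
    )


def line_profile(
    field_a: np.ndarray,
    field_b: np.ndarray,
    point_hi,
    point_lo,
    spacing_mm,
    emph_field: np.ndarray | None = None,
    hi_threshold: float = 0.6,
    lo_threshold: float = 0.2,
):
    """Sample two fields along the segment from ``point_hi`` to ``point_lo``.

    Points are voxel coordinates; the profile is sampled at roughly one
    voxel per step (inclusive of both endpoints) and the distance axis is
    reported in centimetres from ``point_hi`` using the voxel spacing.  If
    an emphysema volume-density field is supplied, endpoints that violate
    the high/low V_Emph convention only raise a warning.

    Returns
    -------
    (distances_cm, values_a, values_b)
    """
    field_a = np.asarray(field_a, dtype=float)
    field_b = np.asarray(field_b, dtype=float)
    if field_a.shape != field_b.shape:
        raise ValueError("fields must share shape")
    p0 = np.asarray(point_hi, dtype=float)
    p1 = np.asarray(point_lo, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)

    if emph_field is not None:
        v_hi = float(emph_field[tuple(np.rint(p0).astype(int))])
        v_lo = float(emph_field[tuple(np.rint(p1).astype(int))])
        if v_hi <= hi_threshold:
            warnings.warn(
                f"high-emphysema endpoint has V_Emph={v_hi:.2f} <= {hi_threshold}")
        if v_lo >= lo_threshold:
            warnings.warn(
                f"low-emphysema endpoint has V_Emph={v_lo:.2f} >= {lo_threshold}")

    seg_vox = np.linalg.norm(p1 - p0)
    n = max(2, int(round(seg_vox)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    va = ndimage.map_coordinates(field_a, pts.T, order=1)
    vb = ndimage.map_coordinates(field_b, pts.T, order=1)
    phys_mm = np.linalg.norm((p1 - p0) * spacing)
    distances_cm = t * phys_mm / 10.0
    return distances_cm, va, vb


def exclusion_summary(total_enrolled: int, exclusions: dict[str, int]):
    """Cohort accounting: analysed sample size after itemised exclusions.

    Returns ``(n_analyzed, n_excluded)``.
    """
    n_excluded = int(sum(exclusions.values()))
    n_analyzed = int(total_enrolled) - n_excluded
    if n_analyzed < 0:
        raise ValueError("exclusions exceed the enrolled total")
    return n_analyzed, n_excluded
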