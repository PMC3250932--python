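"""Accuracy, bias, and blending statistics for cross-validated genomic predictions.

The headline statistic is the pooled accuracy of DGV,

    rho_hat = cov_pooled(DEBV, DGV) / sqrt(sigma_g^2 * var_pooled(DGV)),

with covariances and variances centered within contemporary groups (5-year
birth intervals) and pooled over groups by degrees of freedom, so that genetic
trend across birth cohorts does not inflate the correlation.  The genetic
variance is sigma_g^2 = h^2 * sigma_p^2 with sigma_p^2 from the full-data
training run.  Prediction bias is judged by the ordinary least-squares slope
of DEBV on DGV (expected value 1), and genomic-enhanced breeding values blend
the adjusted parent average with the DGV by multiple regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "genetic_variance",
    "contemporary_groups",
    "pooled_accuracy",
    "bias_slope",
    "blend_gebv",
    "summarize",
]


class ValidationError(ValueError):
    pass


def genetic_variance(h2: float, sp2: float) -> float:
    """Additive genetic variance sigma_g^2 = h^2 * sigma_p^2."""
    if not 0.0 < h2 <= 1.0:
        raise ValidationError(f"heritability {h2} outside (0, 1]")
    if sp2 <= 0:
        raise ValidationError(f"phenotypic variance {sp2} must be positive")
    return h2 * sp2


def contemporary_groups(birth_years, width: int = 5) -> np.ndarray:
    """Contemporary-group labels: ``width``-year birth bins anchored at the
    minimum birth year of the analyzed animals."""
    years = np.asarray(birth_years, dtype=float)
    if not np.all(np.isfinite(years)):
        raise ValidationError("birth years must be known for contemporary grouping")
    return ((years - years.min()) // width).astype(np.int64)


def _pooled_moments(x: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Within-group centered cross-products pooled by degrees of freedom.

    Groups with fewer than two members carry zero df and are dropped.
    Returns (cov, var_x, var_y, df).
    """
    sxy = sxx = syy = 0.0
    df = 0
    for g in np.unique(groups):
        sel = groups == g
        n_g = int(sel.sum())
        if n_g < 2:
            continue
        xc = x[sel] - x[sel].mean()
        yc = y[sel] - y[sel].mean()
        sxy += float(xc @ yc)
        sxx += float(xc @ xc)
        syy += float(yc @ yc)
        df += n_g - 1
    if df == 0:
        raise ValidationError("no contemporary group with at least two animals")
    return sxy / df, sxx / df, syy / df, df


def pooled_accuracy(debv, dgv, birth_years, sg2: float, width: int = 5) -> float:
    """Accuracy of DGV: pooled cov(DEBV, DGV) / sqrt(sigma_g^2 * pooled var(DGV))."""
    x = np.asarray(debv, dtype=float)
    y = np.asarray(dgv, dtype=float)
    groups = contemporary_groups(birth_years, width)
    cov, _, var_dgv, _ = _pooled_moments(x, y, groups)
    if var_dgv <= 0:
        raise ValidationError("pooled DGV variance is zero")
    if sg2 <= 0:
        raise ValidationError("genetic variance must be positive")
    return cov / np.sqrt(sg2 * var_dgv)


def bias_slope(debv, dgv) -> float:
    """OLS slope of DEBV on DGV (intercept included, no contemporary groups)."""
    x = np.asarray(dgv, dtype=float)
    y = np.asarray(debv, dtype=float)
    vx = np.var(x, ddof=1)
    if vx == 0:
        raise ValidationError("zero DGV variance: slope undefined")
    return float(np.cov(x, y, ddof=1)[0, 1] / vx)


def blend_gebv(
    debv,
    pa_adj,
    dgv,
    fold_groups,
    birth_years,
    sg2: float | None = None,
    width: int = 5,
) -> dict:
    """Blend PA_adj and DGV into GEBV = b1*PA_adj + b2*DGV.

    b1, b2 come from a multiple regression of DEBV on (PA_adj, DGV) with fixed
    effects for every (fold group x 5-year birth interval) class.  When
    ``sg2`` is given, pooled accuracies of PA_adj, DGV and GEBV are reported
    alongside the coefficients.
    """
    y = np.asarray(debv, dtype=float)
    x1 = np.asarray(pa_adj, dtype=float)
    x2 = np.asarray(dgv, dtype=float)
    r = np.corrcoef(x1, x2)[0, 1]
    if abs(r) > 0.9999:
        raise ValidationError("PA_adj and DGV are collinear; blending undefined")
    bins = contemporary_groups(birth_years, width)
    classes = pd.Categorical(
        [f"{g}:{b}" for g, b in zip(np.asarray(fold_groups), bins)]
    )
    F = pd.get_dummies(pd.Series(classes)).to_numpy(dtype=float)  # class indicators
    X = np.column_stack([F, x1, x2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b1, b2 = float(coef[-2]), float(coef[-1])
    gebv = b1 * x1 + b2 * x2
    out = {"b1": b1, "b2": b2, "gebv": gebv, "corr_pa_dgv": float(r)}
    if sg2 is not None:
        out["accuracy_pa_adj"] = pooled_accuracy(y, x1, birth_years, sg2, width)
        out["accuracy_dgv"] = pooled_accuracy(y, x2, birth_years, sg2, width)
        out["accuracy_gebv"] = pooled_accuracy(y, gebv, birth_years, sg2, width)
    return out


def summarize(report: pd.DataFrame, ndigits: int = 3) -> dict:
    """Cross-trait means of a per-trait validation report.

    Expects columns among {trait, accuracy, bias_slope, corr_pa_dgv, ...};
    returns arithmetic means rounded to ``ndigits``.
    """
    out = {}
    for col in report.columns:
        if col == "trait":
            continue
        vals = pd.to_numeric(report[col], errors="coerce").dropna()
        if len(vals):
            out[f"mean_{col}"] = round(float(vals.mean()), ndigits)
    return out
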