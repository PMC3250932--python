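"""Deregression of EBV: remove parent-average information, undo shrinkage, weight records.

EBV published as expected progeny differences (EPD) are doubled to the EBV
scale and BIF accuracies are converted to reliabilities, r2 = 1 - (1 - BIF)^2.

Deregression views an animal's EBV as the solution of a two-equation mixed
model over (parent average, individual).  With lambda = (1 - h2)/h2 the
coefficient matrix is

    C = [[Z'Z_PA + 4*lambda, -2*lambda],
         [-2*lambda,          Z'Z_i + 2*lambda]]

where the unknown effective data contents Z'Z_PA and Z'Z_i are solved so the
model-implied reliabilities match the published ones:

    r2_PA = 0.5 - lambda * (C^-1)_11      (PA reliability against sigma_g^2;
                                           the PA effect itself has variance
                                           sigma_g^2/2, so r2_PA < 0.5)
    r2_i  = 1 - lambda * (C^-1)_22

The right-hand side is recovered as C @ (g_PA, EBV_i)'; the deregressed proof
is DEBV = y_i / Z'Z_i with reliability r*2 = Z'Z_i / (Z'Z_i + lambda), and the
analysis weight is

    w = (1 - h2) / ((c + (1 - r*2)/r*2) * h2)

with c the fraction of genetic variance not captured by markers.  The closed
forms alpha = 1/(0.5 - r2_PA), delta = (0.5 - r2_PA)/(1 - r2_i) seed a
numerical root-find, which is the normative definition here.

The same solved system yields an adjusted parent average PA_adj = y_PA/Z'Z_PA:
the parental information content with the genotyped offspring's own
contribution excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ebv_from_epd",
    "deregress_animal",
    "deregress_table",
    "adjusted_parent_average",
    "DeregressionResult",
]


class DeregressionError(ValueError):
    pass


@dataclass
class DeregressionResult:
    debv: float
    r2_star: float
    weight: float
    pa_adj: float  # NaN when undefined
    r2_pa_adj: float
    zz_pa: float
    zz_i: float
    flag: str  # "", "no_parent_info", "insufficient_own_info", "pa_adj_undefined"


def ebv_from_epd(epd: float, bif: float) -> tuple[float, float]:
    """EBV = 2*EPD and reliability r2 = 1 - (1 - BIF)^2."""
    if not 0.0 <= bif <= 1.0:
        raise DeregressionError(f"BIF accuracy {bif} outside [0, 1]")
    return 2.0 * epd, 1.0 - (1.0 - bif) ** 2


def _model_reliabilities(zz_pa: float, zz_i: float, lam: float) -> tuple[float, float]:
    a = zz_pa + 4.0 * lam
    d = zz_i + 2.0 * lam
    det = a * d - 4.0 * lam**2
    return 0.5 - lam * d / det, 1.0 - lam * a / det


def _closed_form_start(r2_pa: float, r2_i: float, lam: float) -> tuple[float, float]:
    # Garrick et al. closed forms; exact when r2_pa < 0.5 and delta > 0
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2_i)
    zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
    zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    return zz_pa, zz_i


def solve_information(r2_pa: float, r2_i: float, h2: float, tol: float = 1e-10):
    """Solve (Z'Z_PA, Z'Z_i) so model reliabilities reproduce the inputs.

    Returns (zz_pa, zz_i, C).  Raises if no solution with zz_i > 0 exists
    (i.e. the individual reliability does not exceed the PA reliability).
    Z'Z_PA may be negative when the individual's reliability exceeds four
    times the PA reliability — the exact solution then has no nonnegative
    PA information content; PA_adj is undefined for such records but the
    deregressed proof remains well defined.
    """
    lam = (1.0 - h2) / h2
    if not (0.0 < h2 < 1.0):
        raise DeregressionError(f"heritability {h2} outside (0, 1)")
    if r2_i <= r2_pa:
        raise DeregressionError("insufficient own information: r2_i <= r2_PA")

    def residual(z):
        m_pa, m_i = _model_reliabilities(z[0], z[1], lam)
        return [m_pa - r2_pa, m_i - r2_i]

    x0 = np.asarray(_closed_form_start(r2_pa, r2_i, lam))
    z = x0
    if np.max(np.abs(residual(z))) > tol:
        sol = optimize.root(residual, x0, method="hybr", tol=tol)
        z = sol.x
    if np.max(np.abs(residual(z))) > 1e-8 or z[1] <= 0:
        raise DeregressionError(
            f"deregression solve failed (r2_pa={r2_pa}, r2_i={r2_i}): residual {residual(z)}"
        )
    C = np.array(
        [[z[0] + 4.0 * lam, -2.0 * lam], [-2.0 * lam, z[1] + 2.0 * lam]]
    )
    return float(z[0]), float(z[1]), C


def record_weight(r2_star: float, h2: float, c: float) -> float:
    """Residual-variance weight for a deregressed record."""
    return (1.0 - h2) / ((c + (1.0 - r2_star) / r2_star) * h2)


def _parent_average(ebv_s, r2_s, ebv_d, r2_d) -> tuple[float, float]:
    """(g_PA, r2_PA) with unknown parents contributing zero information."""
    known_s = np.isfinite(ebv_s) and np.isfinite(r2_s)
    known_d = np.isfinite(ebv_d) and np.isfinite(r2_d)
    if known_s and known_d:
        return 0.5 * (ebv_s + ebv_d), 0.25 * (r2_s + r2_d)
    if known_s:
        return 0.5 * ebv_s, 0.25 * r2_s
    if known_d:
        return 0.5 * ebv_d, 0.25 * r2_d
    return 0.0, 0.0


def deregress_animal(
    ebv_i: float,
    r2_i: float,
    ebv_sire: float = np.nan,
    r2_sire: float = np.nan,
    ebv_dam: float = np.nan,
    r2_dam: float = np.nan,
    h2: float = 0.4,
    c: float = 0.5,
) -> DeregressionResult:
    """Deregress one animal's EBV against its parent average.

    Unknown parents (NaN inputs) contribute no information; with both parents
    unknown there is no PA to remove and the EBV passes through unshrunk
    (DEBV = EBV, r*2 = r2_i).  Records whose own reliability does not exceed
    the PA reliability carry no individual information and are flagged
    ``insufficient_own_info`` (weight NaN, excluded from training upstream).
    """
    lam = (1.0 - h2) / h2
    g_pa, r2_pa = _parent_average(ebv_sire, r2_sire, ebv_dam, r2_dam)
    if r2_pa == 0.0:
        r2_star = r2_i
        w = record_weight(r2_star, h2, c) if r2_star > 0 else np.nan
        return DeregressionResult(ebv_i, r2_star, w, np.nan, np.nan, 0.0, np.nan, "no_parent_info")
    if r2_i <= r2_pa:
        return DeregressionResult(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "insufficient_own_info"
        )
    zz_pa, zz_i, C = solve_information(r2_pa, r2_i, h2)
    y = C @ np.array([g_pa, ebv_i])
    debv = y[1] / zz_i
    r2_star = zz_i / (zz_i + lam)
    w = record_weight(r2_star, h2, c)
    if zz_pa <= 0.0:
        pa_adj, r2_pa_adj, flag = np.nan, np.nan, "pa_adj_undefined"
    else:
        pa_adj = y[0] / zz_pa
        r2_pa_adj = min(2.0 * zz_pa / (zz_pa + 4.0 * lam), 1.0 - 1e-12)
        flag = ""
    return DeregressionResult(debv, r2_star, w, pa_adj, r2_pa_adj, zz_pa, zz_i, flag)


def adjusted_parent_average(
    ebv_i, r2_i, ebv_sire, r2_sire, ebv_dam, r2_dam, h2
) -> tuple[float, float]:
    """PA with the genotyped offspring's contribution excluded.

    Returns (PA_adj, r2_PAadj); raises when the parents carry no information.
    """
    res = deregress_animal(ebv_i, r2_i, ebv_sire, r2_sire, ebv_dam, r2_dam, h2=h2)
    if res.flag in ("no_parent_info", "pa_adj_undefined"):
        raise DeregressionError("parents carry no information: PA_adj undefined")
    if res.flag == "insufficient_own_info":
        raise DeregressionError("r2_i <= r2_PA: deregression undefined")
    return res.pa_adj, res.r2_pa_adj


def deregress_table(records: pd.DataFrame, h2: float, c: float = 0.5) -> pd.DataFrame:
    """Deregress a per-animal EPD/BIF table for one trait.

    ``records`` columns: animal, epd, bif_acc, sire_epd, sire_bif, dam_epd,
    dam_bif (parent columns NaN when unknown).  Returns the table augmented
    with ebv, r2, debv, r2_star, weight, pa_adj, r2_pa_adj and a flag column;
    flagged ``insufficient_own_info`` rows have NaN weight and are meant to be
    dropped from training.
    """
    out = []
    for row in records.itertuples(index=False):
        ebv, r2 = ebv_from_epd(row.epd, row.bif_acc)
        ebv_s, r2_s = (
            ebv_from_epd(row.sire_epd, row.sire_bif)
            if np.isfinite(row.sire_epd)
            else (np.nan, np.nan)
        )
        ebv_d, r2_d = (
            ebv_from_epd(row.dam_epd, row.dam_bif)
            if np.isfinite(row.dam_epd)
            else (np.nan, np.nan)
        )
        res = deregress_animal(ebv, r2, ebv_s, r2_s, ebv_d, r2_d, h2=h2, c=c)
        out.append(
            {
                "animal": row.animal,
                "ebv": ebv,
                "r2": r2,
                "debv": res.debv,
                "r2_star": res.r2_star,
                "weight": res.weight,
                "pa_adj": res.pa_adj,
                "r2_pa_adj": res.r2_pa_adj,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(out)
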