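"""Published per-trait reference values from the US Angus genomic-prediction study
this package's methods follow (3 570 genotyped bulls, 16 routinely recorded
traits).  Used for worked examples and arithmetic regression checks: variance
bookkeeping, cross-trait summary means, and report shapes.

Columns: heritability h2, phenotypic variance sigma_p^2 of the deregressed
proofs, genetic variance sigma_g^2 = h2 * sigma_p^2, pooled DGV accuracy and
DEBV-on-DGV regression slope under relatedness-minimizing (kmeans) and random
folds, the PA_adj/DGV blending coefficients b1/b2, and corr(PA_adj, DGV).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["angus_reference_table"]

_ROWS = [
    # trait, h2, sp2, sg2, acc_kmeans, slope_kmeans, acc_random, slope_random, b1, b2, corr_pa_dgv
    ("birth_weight", 0.42, 20.63, 8.67, 0.554, 0.879, 0.700, 0.953, 0.66, 0.54, 0.41),
    ("calving_ease_direct", 0.18, 825.05, 148.51, 0.488, 0.942, 0.617, 1.007, 0.38, 0.80, 0.51),
    ("calving_ease_maternal", 0.12, 1313.37, 157.60, 0.416, 1.181, 0.571, 1.277, 0.13, 1.09, 0.45),
    ("carcass_weight", 0.40, 1535.06, 614.03, 0.471, 1.130, 0.689, 1.208, -0.19, 1.20, 0.51),
    ("docility", 0.37, 1634.60, 604.80, 0.218, 0.614, 0.490, 1.150, 0.82, 0.17, 0.27),
    ("fat_thickness", 0.34, 4.80, 1.63, 0.603, 1.113, 0.793, 1.211, 0.03, 1.10, 0.54),
    ("heifer_pregnancy_rate", 0.13, 1031.74, 134.13, 0.269, 1.337, 0.378, 1.580, 0.23, 1.09, 0.40),
    ("marbling", 0.45, 0.797, 0.359, 0.690, 1.058, 0.817, 1.041, 0.17, 0.97, 0.65),
    ("maternal_weaning_weight", 0.14, 1160.85, 162.52, 0.318, 0.702, 0.492, 0.829, 0.69, 0.42, 0.60),
    ("mature_height", 0.82, 494.03, 405.13, 0.359, 0.977, 0.819, 1.091, 0.21, 0.81, 0.48),
    ("mature_weight", 0.55, 4638.66, 2551.28, 0.312, 0.898, 0.769, 1.125, 0.04, 0.87, 0.37),
    ("rib_eye_muscle_area", 0.51, 430.32, 219.35, 0.601, 0.993, 0.694, 0.958, 0.24, 0.89, 0.61),
    ("scrotal_circumference", 0.43, 839.98, 361.19, 0.487, 0.916, 0.600, 0.983, 0.49, 0.60, 0.54),
    ("weaning_weight", 0.20, 1558.04, 311.61, 0.333, 0.597, 0.534, 0.760, 0.50, 0.42, 0.38),
    ("yearling_height", 0.45, 344.68, 155.19, 0.575, 1.015, 0.850, 1.011, 0.70, 0.56, 0.47),
    ("yearling_weight", 0.49, 2049.19, 1004.12, 0.356, 0.642, 0.573, 0.790, 0.54, 0.46, 0.46),
]

_COLUMNS = [
    "trait",
    "h2",
    "sigma_p2",
    "sigma_g2",
    "accuracy_kmeans",
    "slope_kmeans",
    "accuracy_random",
    "slope_random",
    "b1",
    "b2",
    "corr_pa_dgv",
]


def angus_reference_table() -> pd.DataFrame:
    """The per-trait reference table as a DataFrame (one row per trait)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
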