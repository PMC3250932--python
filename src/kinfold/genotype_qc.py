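"""Marker-matrix I/O, locus/animal quality control, and mean-dosage imputation.

Dosages are counts of the B allele (0/1/2) in a PLINK-RAW-like layout.  Locus
QC applies three filters (any failure removes the locus): call rate below 90%,
minor allele frequency below 1%, and a Hardy-Weinberg Pearson chi-square
(1 df, expectations p^2 : 2pq : q^2 from sample allele frequencies) above 300.
Animals are screened first on their own call rate (default threshold 95%).
Remaining missing genotypes are replaced by the per-locus mean dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "read_dosages",
    "filter_animals",
    "filter_loci",
    "impute_missing",
    "hwe_chi2",
]


class GenotypeError(ValueError):
    pass


@dataclass
class MarkerMatrix:
    """Animals x loci dosage matrix with per-locus QC metadata.

    ``Z`` holds dosages as float with NaN for missing; after imputation values
    may be real-valued (mean dosage).  ``call_rate``, ``maf`` and ``hwe`` are
    recomputed whenever the matrix is filtered.
    """

    animal_ids: np.ndarray
    locus_ids: np.ndarray
    Z: np.ndarray

    @property
    def n_animals(self) -> int:
        return self.Z.shape[0]

    @property
    def n_loci(self) -> int:
        return self.Z.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.Z).mean(axis=0)

    @property
    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.Z).mean(axis=1)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the B allele (NaN where no calls)."""
        n_obs = (~np.isnan(self.Z)).sum(axis=0)
        total = np.nansum(self.Z, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def hwe(self) -> np.ndarray:
        return hwe_chi2(self.Z)

    def qc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_ids,
                "call_rate": self.call_rate,
                "maf": self.maf,
                "hwe_chi2": self.hwe,
            }
        )


def hwe_chi2(Z: np.ndarray) -> np.ndarray:
    """Pearson chi-square (1 df) against Hardy-Weinberg proportions, per locus.

    Expected genotype counts use the sample allele frequency plug-in
    (n*p^2, 2npq, n*q^2).  Monomorphic loci return 0 (observed = expected);
    loci with no calls return NaN.
    """
    Z = np.asarray(Z, dtype=float)
    obs = np.stack([np.nansum(Z == g, axis=0) for g in (0.0, 1.0, 2.0)]).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (obs[1] + 2 * obs[2]) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    chi2 = np.where(n > 0, chi2, np.nan)
    return chi2


def read_dosages(path) -> MarkerMatrix:
    """Read a PLINK-RAW-style dosage table (one row per animal).

    The first column (and an optional ``FID`` column) identifies the animal;
    every remaining column is a locus with entries in {0, 1, 2, NA}.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"IID": str, "FID": str})
    id_col = "IID" if "IID" in df.columns else df.columns[0]
    drop = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    animal_ids = df[id_col].astype(str).to_numpy()
    loci = df.drop(columns=drop if drop else [df.columns[0]])
    Z = loci.to_numpy(dtype=float)
    bad = ~(np.isnan(Z) | np.isin(Z, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeError(
            f"invalid dosage {Z[i, j]!r} for animal {animal_ids[i]!r} at locus {loci.columns[j]!r}"
        )
    return MarkerMatrix(animal_ids, loci.columns.to_numpy(dtype=object), Z)


def filter_animals(M: MarkerMatrix, min_call: float = 0.95) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Remove animals whose genotype call rate falls below ``min_call``."""
    cr = M.animal_call_rate
    keep = cr >= min_call
    if not keep.any():
        raise GenotypeError("animal call-rate filter removed every animal")
    log = pd.DataFrame({"animal": M.animal_ids[~keep], "call_rate": cr[~keep]})
    return MarkerMatrix(M.animal_ids[keep], M.locus_ids.copy(), M.Z[keep]), log


def filter_loci(
    M: MarkerMatrix,
    min_cr: float = 0.90,
    min_maf: float = 0.01,
    max_hwe_chi2: float = 300.0,
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Remove loci failing any of the call-rate / MAF / HWE criteria.

    The returned report counts failures per criterion; the criteria are not
    mutually exclusive, so per-criterion counts can sum to more than the total
    number of loci removed.
    """
    cr, maf, chi2 = M.call_rate, M.maf, M.hwe
    fail_cr = cr < min_cr
    fail_maf = ~(maf >= min_maf)  # NaN MAF (no calls) fails
    fail_hwe = chi2 > max_hwe_chi2
    fail_any = fail_cr | fail_maf | fail_hwe
    keep = ~fail_any
    if not keep.any():
        raise GenotypeError("locus filters removed every locus")
    report = pd.DataFrame(
        {
            "locus": M.locus_ids,
            "call_rate": cr,
            "maf": maf,
            "hwe_chi2": chi2,
            "fail_call_rate": fail_cr,
            "fail_maf": fail_maf,
            "fail_hwe": fail_hwe,
            "removed": fail_any,
        }
    )
    return MarkerMatrix(M.animal_ids.copy(), M.locus_ids[keep], M.Z[:, keep]), report


def impute_missing(M: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages with the per-locus mean (deterministic).

    Downstream models accept real-valued dosages, so the mean is used as-is.
    """
    miss = np.isnan(M.Z)
    if not miss.any():
        return MarkerMatrix(M.animal_ids.copy(), M.locus_ids.copy(), M.Z.copy())
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise GenotypeError(f"locus {M.locus_ids[j]!r} has no observed calls to impute from")
    mean = np.nanmean(M.Z, axis=0)
    Z = np.where(miss, mean[None, :], M.Z)
    return MarkerMatrix(M.animal_ids.copy(), M.locus_ids.copy(), Z)
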