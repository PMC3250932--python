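"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kinfold.pedigree import Pedigree, pedigree_from_records
from kinfold.synthdata import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    """One tiny synthetic dataset shared across the suite (seed 0)."""
    return make_fixture("tiny", seed=0)


@pytest.fixture
def trio_rows():
    return [("S1", "0", "0", 2000), ("D1", "0", "0", 2000), ("X", "S1", "D1", 2004)]


def random_pedigree(n_founders: int, n_offspring: int, seed: int, year0: int = 2000) -> Pedigree:
    """Random mating pedigree with overlapping generations (test helper)."""
    rng = np.random.default_rng(seed)
    rows = [(f"F{i}", "0", "0", year0) for i in range(n_founders)]
    pool = [f"F{i}" for i in range(n_founders)]
    for k in range(n_offspring):
        s, d = rng.choice(pool, 2, replace=False)
        aid = f"A{k}"
        rows.append((aid, s, d, year0 + 4 + k))
        pool.append(aid)
    return pedigree_from_records(rows, validate_years=False)


def gene_drop_A(ped: Pedigree, n_rep: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of the additive relationship matrix by gene dropping.

    Founders receive unique allele labels; each descendant inherits one random
    allele from each parent (unknown parents contribute fresh unique alleles).
    a_ij is estimated as twice the coancestry: the probability that a random
    allele from i and a random allele from j are identical by descent, times 2,
    averaged over replicates (including i = j, which yields 1 + F_i).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    A_sum = np.zeros((n, n))
    chunk = 2000
    done = 0
    while done < n_rep:
        r = min(chunk, n_rep - done)
        alleles = np.zeros((n, 2, r), dtype=np.int64)
        counter = 0
        for i in range(n):
            for slot, p in enumerate((ped.sire[i], ped.dam[i])):
                if p < 0:
                    alleles[i, slot] = counter
                    counter += 1
                else:
                    pick = rng.integers(0, 2, r)
                    alleles[i, slot] = alleles[p, pick, np.arange(r)]
        # coancestry f_ij = mean over 4 allele pairings of IBD indicator
        ibd = np.zeros((n, n))
        for a in range(2):
            for b in range(2):
                ibd += (alleles[:, None, a, :] == alleles[None, :, b, :]).sum(axis=2)
        A_sum += ibd / (2.0 * r) * (r / n_rep)
        done += r
    return A_sum


def hw_objective(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to cluster means (oracle)."""
    obj = 0.0
    for g in np.unique(labels):
        pts = X[labels == g]
        obj += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(obj)
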