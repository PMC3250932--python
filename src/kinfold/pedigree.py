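"""Pedigree ingestion, additive relationships, dissimilarities, and relatedness diagnostics.

The pedigree numerator relationship matrix A is built by the tabular method:
processing animals in topological order (parents before offspring),

    a_ii = 1 + 0.5 * a_sd            (s, d = parents of i)
    a_ij = 0.5 * (a_js + a_jd)       for j processed before i

Unknown parents are treated as unrelated, non-inbred founders.  The inbreeding
coefficient is F_i = a_ii - 1.  The pedigree dissimilarity used for clustering
animals into weakly related groups is

    d_ij = 1 - a_ij / sqrt(a_ii * a_jj)

which removes the effect of inbreeding from the scale and zeroes the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "DissimilarityMatrix",
    "read_pedigree",
    "prune_founders",
    "build_A",
    "dissimilarity",
    "amax_diagnostics",
    "generation_interval",
]

UNKNOWN = -1  # internal index for an unknown parent


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, missing parents)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : np.ndarray of str
        Animal identifiers, parents always preceding offspring.
    sire, dam : np.ndarray of int
        Positional index of each animal's sire/dam in ``ids`` (``-1`` unknown).
    birth_year : np.ndarray of float
        Birth year per animal; ``nan`` when unknown.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        return np.array([self._index[a] for a in animal_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        sire_id = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "0")
        dam_id = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "0")
        return pd.DataFrame(
            {"animal": self.ids, "sire": sire_id, "dam": dam_id, "birth_year": self.birth_year}
        )


@dataclass
class RelationshipMatrix:
    """Additive (numerator) relationships among a set of animals."""

    ids: np.ndarray
    A: np.ndarray

    @property
    def F(self) -> np.ndarray:
        """Inbreeding coefficients, F_i = a_ii - 1."""
        return np.diag(self.A) - 1.0


@dataclass
class DissimilarityMatrix:
    """Pedigree distance d_ij in [0, 1] with zero diagonal."""

    ids: np.ndarray
    D: np.ndarray


def _normalize_parent(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "0", "0.0", "nan", "NA", "."):
        return None
    return s


def _toposort(records: dict[str, tuple[str | None, str | None, float]]) -> list[str]:
    """Kahn's algorithm over the parent->offspring DAG; raises on cycles.

    Ready animals are released in lexicographic id order, so the result does
    not depend on the input row order.
    """
    import heapq

    children: dict[str, list[str]] = {a: [] for a in records}
    n_parents = {}
    for a, (s, d, _) in records.items():
        np_ = 0
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                np_ += 1
        n_parents[a] = np_
    ready = [a for a in records if n_parents[a] == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != len(records):
        cyclic = sorted(a for a in records if n_parents[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cyclic[:10]}")
    return order


def pedigree_from_records(rows, validate_years: bool = True) -> Pedigree:
    """Build a :class:`Pedigree` from ``(animal, sire, dam, birth_year)`` tuples.

    Implicit records (unknown-parent founders) are created for parents that
    appear only as sire/dam.  Rows may be in any order; output is topological.
    """
    records: dict[str, tuple[str | None, str | None, float]] = {}
    for animal, sire, dam, year in rows:
        a = str(animal).strip()
        if a in records:
            raise PedigreeError(f"duplicate animal id {a!r}")
        s, d = _normalize_parent(sire), _normalize_parent(dam)
        if s == a or d == a:
            raise PedigreeError(f"animal {a!r} is its own parent")
        records[a] = (s, d, float(year) if year is not None and not pd.isna(year) else np.nan)
    # implicit founders for named-but-unrecorded parents
    for s, d, _ in list(records.values()):
        for p in (s, d):
            if p is not None and p not in records:
                records[p] = (None, None, np.nan)
    order = _toposort(records)
    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    year = np.full(n, np.nan)
    for a, i in index.items():
        s, d, y = records[a]
        if s is not None:
            sire[i] = index[s]
        if d is not None:
            dam[i] = index[d]
        year[i] = y
    ped = Pedigree(np.array(order, dtype=object), sire, dam, year, index)
    if validate_years:
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p >= 0 and np.isfinite(year[i]) and np.isfinite(year[p]) and year[i] <= year[p]:
                    raise PedigreeError(
                        f"animal {ped.ids[i]!r} (born {year[i]:.0f}) not younger than "
                        f"parent {ped.ids[p]!r} (born {year[p]:.0f})"
                    )
    return ped


def read_pedigree(path, validate_years: bool = True) -> Pedigree:
    """Read a pedigree CSV with columns animal, sire, dam, birth_year.

    Unknown parents are coded 0 or left blank.  Rows may appear in any order;
    the returned pedigree is topologically sorted with implicit founder records
    created for parents lacking their own row.
    """
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    required = {"animal", "sire", "dam", "birth_year"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")
    rows = zip(df["animal"], df["sire"], df["dam"], df["birth_year"])
    return pedigree_from_records(rows, validate_years=validate_years)


def prune_founders(ped: Pedigree, keep=()) -> Pedigree:
    """Drop parentless animals that appear only once as a parent.

    Such founders contribute nothing to relationships among the remaining
    animals (they link a single offspring to nobody).  Pruning repeats to a
    fixed point, since removing a founder can orphan one of its mates' other
    ancestors.  Animals in ``keep`` are never removed.  Relationships among
    kept animals are unchanged.
    """
    keep = set(map(str, keep))
    ids = list(ped.ids)
    sire = {a: (ped.ids[s] if s >= 0 else None) for a, s in zip(ped.ids, ped.sire)}
    dam = {a: (ped.ids[d] if d >= 0 else None) for a, d in zip(ped.ids, ped.dam)}
    year = dict(zip(ped.ids, ped.birth_year))
    while True:
        n_as_parent: dict[str, int] = {}
        for a in ids:
            for p in (sire[a], dam[a]):
                if p is not None:
                    n_as_parent[p] = n_as_parent.get(p, 0) + 1
        drop = {
            a
            for a in ids
            if sire[a] is None
            and dam[a] is None
            and n_as_parent.get(a, 0) == 1
            and a not in keep
        }
        if not drop:
            break
        ids = [a for a in ids if a not in drop]
        for a in ids:
            if sire[a] in drop:
                sire[a] = None
            if dam[a] in drop:
                dam[a] = None
    rows = [(a, sire[a], dam[a], year[a]) for a in ids]
    return pedigree_from_records(rows, validate_years=False)


def build_A(ped: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A is computed over the complete pedigree (so all ancestral pathways are
    accumulated) and then restricted to ``subset`` (default: every animal).
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    if subset is None:
        return RelationshipMatrix(ped.ids.copy(), A)
    idx = ped.index_of(subset)
    return RelationshipMatrix(ped.ids[idx], A[np.ix_(idx, idx)])


def dissimilarity(rel: RelationshipMatrix) -> DissimilarityMatrix:
    """Pedigree distance d_ij = 1 - a_ij / sqrt(a_ii a_jj)."""
    d = np.sqrt(np.diag(rel.A))
    D = 1.0 - rel.A / np.outer(d, d)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(rel.ids.copy(), np.clip(D, 0.0, 1.0))


def amax_diagnostics(rel: RelationshipMatrix, assignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal maximum relationship with each fold, plus fold summaries.

    ``assignment`` maps animal id -> group label.  For every animal the maximum
    additive relationship a_max(g) with members of each group g (self excluded)
    is tabulated; the summary mirrors the usual fold-quality report: group
    size, mean +/- SD of within-group a_ij, mean within-group a_max, mean
    between-group a_max, and mean inbreeding.  Singleton groups yield NaN for
    their own member's within-group a_max.
    """
    ids = rel.ids
    groups = np.array([assignment[a] for a in ids], dtype=object)
    labels = sorted(set(groups))
    A = rel.A
    n = len(ids)
    offdiag = ~np.eye(n, dtype=bool)
    per_rows = []
    for i in range(n):
        row = {"animal": ids[i], "group": groups[i]}
        for g in labels:
            mask = (groups == g) & offdiag[i]
            row[f"amax_{g}"] = float(A[i, mask].max()) if mask.any() else np.nan
        per_rows.append(row)
    per_animal = pd.DataFrame(per_rows)

    summaries = []
    F = rel.F
    for g in labels:
        in_g = groups == g
        k = int(in_g.sum())
        sub = A[np.ix_(in_g, in_g)]
        within_vals = sub[~np.eye(k, dtype=bool)] if k > 1 else np.array([])
        amax_within = per_animal.loc[per_animal["group"] == g, f"amax_{g}"]
        other_cols = [f"amax_{h}" for h in labels if h != g]
        amax_between = (
            per_animal.loc[per_animal["group"] == g, other_cols].mean(axis=1)
            if other_cols
            else pd.Series(dtype=float)
        )
        summaries.append(
            {
                "group": g,
                "n": k,
                "mean_birth_year": np.nan,  # filled by caller when years known
                "mean_F": float(F[in_g].mean()),
                "mean_a_within": float(within_vals.mean()) if within_vals.size else np.nan,
                "sd_a_within": float(within_vals.std(ddof=1)) if within_vals.size > 1 else np.nan,
                "mean_amax_within": float(amax_within.mean()),
                "sd_amax_within": float(amax_within.std(ddof=1)) if k > 1 else np.nan,
                "mean_amax_between": float(amax_between.mean()) if len(other_cols) else np.nan,
            }
        )
    return per_animal, pd.DataFrame(summaries)


def generation_interval(ped: Pedigree, year_window=(None, None)) -> float:
    """Mean parent age at progeny birth over parent-progeny pairs.

    Only pairs whose parent birth year lies inside ``year_window`` (inclusive;
    ``None`` = unbounded) and where both birth years are known contribute.
    """
    lo, hi = year_window
    ages = []
    for i in range(len(ped)):
        for p in (ped.sire[i], ped.dam[i]):
            if p < 0:
                continue
            yp, yi = ped.birth_year[p], ped.birth_year[i]
            if not (np.isfinite(yp) and np.isfinite(yi)):
                continue
            if lo is not None and yp < lo:
                continue
            if hi is not None and yp > hi:
                continue
            ages.append(yi - yp)
    if not ages:
        raise PedigreeError("no parent-progeny pairs with known birth years in window")
    return float(np.mean(ages))
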