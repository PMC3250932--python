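"""Pedigree ingestion, relationship matrices, dissimilarities and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import gene_drop_A, random_pedigree
from kinfold.pedigree import (
    PedigreeError,
    amax_diagnostics,
    build_A,
    dissimilarity,
    generation_interval,
    pedigree_from_records,
    prune_founders,
    read_pedigree,
)


class TestReadPedigree:
    def test_trio_topological_order(self, trio_rows, tmp_path):
        path = tmp_path / "ped.csv"
        pd.DataFrame(trio_rows, columns=["animal", "sire", "dam", "birth_year"]).to_csv(
            path, index=False
        )
        ped = read_pedigree(path)
        assert len(ped) == 3
        assert ped.ids[-1] == "X"  # offspring last

    def test_order_invariance(self, trio_rows):
        fwd = pedigree_from_records(trio_rows)
        rev = pedigree_from_records(trio_rows[::-1])
        assert list(fwd.ids) == list(rev.ids)
        assert np.array_equal(fwd.sire, rev.sire)

    def test_implicit_parent_records_created(self):
        ped = pedigree_from_records([("X", "S1", "D1", 2004)])
        assert set(ped.ids) == {"S1", "D1", "X"}

    def test_cycle_is_fatal(self):
        with pytest.raises(PedigreeError, match="cycle"):
            pedigree_from_records([("A", "B", "0", None), ("B", "A", "0", None)])

    def test_duplicate_id_is_fatal(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            pedigree_from_records([("A", "0", "0", 2000), ("A", "0", "0", 2001)])

    def test_parent_younger_than_offspring_is_fatal(self):
        rows = [("S", "0", "0", 2010), ("X", "S", "0", 2004)]
        with pytest.raises(PedigreeError, match="not younger"):
            pedigree_from_records(rows, validate_years=True)


class TestBuildA:
    def test_unrelated_founders_identity(self):
        ped = pedigree_from_records([(f"F{i}", "0", "0", 2000) for i in range(4)])
        rel = build_A(ped)
        assert np.allclose(rel.A, np.eye(4))

    def test_textbook_relationships(self):
        rows = [
            ("S", "0", "0", 2000),
            ("D", "0", "0", 2000),
            ("A", "S", "D", 2004),
            ("B", "S", "D", 2004),
            ("I", "A", "B", 2008),  # offspring of full-sib mating
        ]
        rel = build_A(pedigree_from_records(rows))
        idx = {a: i for i, a in enumerate(rel.ids)}
        A = rel.A
        assert A[idx["S"], idx["A"]] == pytest.approx(0.5)  # parent-offspring
        assert A[idx["A"], idx["B"]] == pytest.approx(0.5)  # full sibs
        assert A[idx["I"], idx["I"]] == pytest.approx(1.25)
        assert rel.F[idx["I"]] == pytest.approx(0.25)

    def test_matches_gene_dropping_oracle(self):
        """Tabular A equals the IBD probability estimated by gene dropping."""
        ped = random_pedigree(8, 22, seed=5)
        A = build_A(ped).A
        n_rep = 100_000
        A_mc = gene_drop_A(ped, n_rep, seed=11)
        # binomial-ish SE per IBD comparison; a_ij averages 4 indicators / 2
        se = np.sqrt(np.maximum(A_mc * (2 - A_mc), 1e-4) / n_rep)
        assert np.all(np.abs(A - A_mc) <= 3.5 * se + 1e-9)

    def test_subset_restriction(self):
        ped = random_pedigree(5, 10, seed=2)
        keep = list(ped.ids[-4:])
        rel_full = build_A(ped)
        rel_sub = build_A(ped, subset=keep)
        idx = ped.index_of(keep)
        assert np.allclose(rel_sub.A, rel_full.A[np.ix_(idx, idx)])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_psd_and_recursion_consistency(self, seed):
        ped = random_pedigree(10, 60, seed=seed)
        rel = build_A(ped)
        assert np.linalg.eigvalsh(rel.A).min() >= -1e-8
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0:
                assert rel.A[i, i] - 1 == pytest.approx(0.5 * rel.A[s, d])


class TestPruneFounders:
    def test_single_use_founder_removed(self):
        rows = [("S", "0", "0", 2000), ("D", "0", "0", 2000), ("X", "S", "D", 2004)]
        ped = prune_founders(pedigree_from_records(rows), keep={"X"})
        assert set(ped.ids) == {"X"}

    def test_linking_founder_retained(self):
        rows = [
            ("S", "0", "0", 2000),
            ("D", "0", "0", 2000),
            ("A", "S", "D", 2004),
            ("B", "S", "D", 2004),
        ]
        ped = prune_founders(pedigree_from_records(rows), keep={"A", "B"})
        assert {"S", "D"} <= set(ped.ids)  # both founders link the sibs

    def test_relationships_preserved(self):
        ped = random_pedigree(10, 30, seed=7)
        keep = list(ped.ids[-12:])
        before = build_A(ped, subset=keep).A
        pruned = prune_founders(ped, keep=keep)
        after = build_A(pruned, subset=keep).A
        assert np.allclose(before, after, atol=1e-12)


class TestDissimilarity:
    def test_zero_diagonal_and_unrelated_pairs(self):
        ped = pedigree_from_records([("A", "0", "0", 2000), ("B", "0", "0", 2000)])
        D = dissimilarity(build_A(ped)).D
        assert np.allclose(np.diag(D), 0.0)
        assert D[0, 1] == pytest.approx(1.0)

    def test_parent_offspring_distance(self):
        ped = pedigree_from_records([("S", "0", "0", 2000), ("X", "S", "0", 2004)])
        rel = build_A(ped)
        D = dissimilarity(rel).D
        i, j = list(rel.ids).index("S"), list(rel.ids).index("X")
        assert D[i, j] == pytest.approx(0.5)

    def test_bounds(self):
        rel = build_A(random_pedigree(8, 40, seed=3))
        D = dissimilarity(rel).D
        assert D.min() >= 0.0 and D.max() <= 1.0


class TestAmaxDiagnostics:
    def test_disjoint_families_between_amax_zero(self):
        rows = [("S1", "0", "0", 2000), ("A", "S1", "0", 2004), ("S2", "0", "0", 2000), ("B", "S2", "0", 2004)]
        rel = build_A(pedigree_from_records(rows))
        assign = {"S1": 0, "A": 0, "S2": 1, "B": 1}
        per, summ = amax_diagnostics(rel, assign)
        per = per.set_index("animal")
        assert (per.loc[["S1", "A"], "amax_1"] == 0).all()
        assert (per.loc[["S2", "B"], "amax_0"] == 0).all()
        assert summ.set_index("group").loc[0, "mean_amax_between"] == 0.0

    def test_single_group_equals_global_max(self):
        rel = build_A(random_pedigree(6, 20, seed=1))
        assign = {a: 0 for a in rel.ids}
        per, _ = amax_diagnostics(rel, assign)
        offdiag = rel.A - np.diag(np.diag(rel.A))
        assert per["amax_0"].max() == pytest.approx(offdiag.max())

    def test_exhaustive_row_max_oracle(self, tiny_bundle):
        from kinfold.pedigree import build_A as bA

        truth = tiny_bundle["truth"]
        rel = bA(tiny_bundle["pedigree"], subset=truth.genotyped_ids[:80])
        assign = {a: i % 3 for i, a in enumerate(rel.ids)}
        per, _ = amax_diagnostics(rel, assign)
        groups = np.array([assign[a] for a in rel.ids])
        for i in (0, 17, 55):
            for g in range(3):
                mask = (groups == g) & (np.arange(len(rel.ids)) != i)
                expect = rel.A[i, mask].max() if mask.any() else np.nan
                assert per.loc[i, f"amax_{g}"] == pytest.approx(expect, nan_ok=True)

    def test_singleton_group_missing(self):
        rel = build_A(pedigree_from_records([("A", "0", "0", 2000), ("B", "0", "0", 2000)]))
        per, _ = amax_diagnostics(rel, {"A": 0, "B": 1})
        assert np.isnan(per.loc[0, "amax_0"])


class TestGenerationInterval:
    def test_single_pair(self):
        ped = pedigree_from_records([("S", "0", "0", 0), ("X", "S", "0", 5)])
        assert generation_interval(ped) == pytest.approx(5.0)

    def test_window_excluding_all_parents_errors(self):
        ped = pedigree_from_records([("S", "0", "0", 0), ("X", "S", "0", 5)])
        with pytest.raises(PedigreeError):
            generation_interval(ped, year_window=(100, 200))

    def test_fixed_mating_age(self):
        rows = [("F0", "0", "0", 2000)]
        for g in range(1, 5):
            rows.append((f"F{g}", f"F{g - 1}", "0", 2000 + 4 * g))
        ped = pedigree_from_records(rows)
        assert generation_interval(ped) == pytest.approx(4.0)
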