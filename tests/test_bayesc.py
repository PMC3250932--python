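"""BayesC Gibbs sampler: limiting cases, oracles, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from kinfold.bayesc import (
    BayesCConfig,
    BayesCError,
    predict_dgv,
    preliminary_variances,
    train,
)
from kinfold.genotype_qc import MarkerMatrix


def matrix_from(Z):
    Z = np.asarray(Z, dtype=float)
    ids = np.array([f"A{i}" for i in range(Z.shape[0])], dtype=object)
    loci = np.array([f"m{j}" for j in range(Z.shape[1])], dtype=object)
    return MarkerMatrix(ids, loci, Z)


def records_from(M, y, w=None):
    w = np.ones(len(y)) if w is None else w
    return pd.DataFrame({"animal": M.animal_ids, "debv": y, "weight": w})


def sim_training(n, m, n_qtl, seed, reliability=0.8, maf_low=0.1):
    """Unlinked-marker training set with on-panel QTL (sampler calibration rig)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, 1 - maf_low, m)
    Z = rng.binomial(2, p, (n, m)).astype(float)
    qtl = rng.choice(m, n_qtl, replace=False)
    beta = rng.standard_normal(n_qtl)
    tbv = Z[:, qtl] @ beta
    tbv = (tbv - tbv.mean()) / tbv.std(ddof=1)
    noise_sd = np.sqrt((1 - reliability) / reliability)
    y = tbv + rng.standard_normal(n) * noise_sd
    return Z, y, tbv


class TestLimitingCases:
    def test_pi_one_null_model(self):
        rng = np.random.default_rng(0)
        M = matrix_from(rng.integers(0, 3, (40, 10)))
        y = rng.normal(2.0, 1.0, 40)
        w = rng.uniform(0.5, 2.0, 40)
        cfg = BayesCConfig(pi=1.0, n_iter=2000, burn_in=200, seed=1)
        post = train(M, records_from(M, y, w), cfg)
        assert np.all(post.u_mean == 0.0)
        assert post.mu_mean == pytest.approx(np.average(y, weights=w), abs=0.05)

    def test_pi_zero_matches_ridge_oracle(self):
        """pi = 0 with fixed variances is Bayesian ridge: posterior means must
        match the joint (intercept + markers) dense linear solve."""
        rng = np.random.default_rng(3)
        n, m = 50, 30
        Z = rng.binomial(2, rng.uniform(0.2, 0.8, m), (n, m)).astype(float)
        y = rng.normal(size=n) + Z[:, 0] * 0.8
        w = rng.uniform(0.5, 2.0, n)
        su2, se2 = 0.05, 1.0
        M = matrix_from(Z)
        cfg = BayesCConfig(
            pi=0.0, n_iter=12_000, burn_in=2_000, s2_u=su2, s2_e=se2,
            sample_variances=False, seed=7,
        )
        post = train(M, records_from(M, y, w), cfg)

        Zc = Z - Z.mean(axis=0)  # oracle mirrors the training parameterization
        lam = se2 / su2
        X = np.column_stack([np.ones(n), Zc])
        Wm = np.diag(w)
        lhs = X.T @ Wm @ X + np.diag([0.0] + [lam] * m)
        rhs = X.T @ Wm @ y
        sol = np.linalg.solve(lhs, rhs)
        u_ridge = sol[1:]
        # Monte-Carlo tolerance: 3 SE with a conservative autocorrelation factor
        post_sd = np.sqrt(se2 * np.diag(np.linalg.inv(lhs))[1:])
        tol = 3 * post_sd * np.sqrt(20 / 10_000)
        assert np.all(np.abs(post.u_mean - u_ridge) <= tol + 1e-4)

    def test_single_marker_inclusion_matches_quadrature(self):
        """One marker, fixed variances: the posterior inclusion frequency must
        match the two-model marginal-likelihood ratio computed by quadrature."""
        rng = np.random.default_rng(5)
        n = 20
        z = rng.binomial(2, 0.5, n).astype(float)
        y = 0.4 * z + rng.normal(size=n) * 0.8
        w = np.ones(n)
        su2, se2, pi = 0.25, 0.64, 0.5
        M = matrix_from(z[:, None])
        cfg = BayesCConfig(
            pi=pi, n_iter=42_000, burn_in=2_000, s2_u=su2, s2_e=se2,
            sample_variances=False, seed=11,
        )
        post = train(M, records_from(M, y, w), cfg)

        zc = z - z.mean()
        mus = np.linspace(y.mean() - 5, y.mean() + 5, 801)
        us = np.linspace(-5 * np.sqrt(su2), 5 * np.sqrt(su2), 801)

        def loglik(mu, u):
            r = y[:, None, None] - mu[None, :, None] - u[None, None, :] * zc[:, None, None]
            return -0.5 * (r**2).sum(axis=0) / se2

        ll = loglik(mus, us)
        prior_u = np.exp(-0.5 * us**2 / su2) / np.sqrt(2 * np.pi * su2)
        m2 = np.trapezoid(np.trapezoid(np.exp(ll - ll.max()) * prior_u[None, :], us), mus)
        m1 = np.trapezoid(np.exp(ll[:, 400] - ll.max()), mus)  # u = 0 column
        p_incl = (1 - pi) * m2 / ((1 - pi) * m2 + pi * m1)
        # MC error with a conservative effective-sample-size deflation
        se = np.sqrt(p_incl * (1 - p_incl) / (40_000 / 20))
        assert post.incl_freq[0] == pytest.approx(p_incl, abs=4 * se + 0.01)


class TestPrediction:
    def test_zero_effects_zero_dgv(self):
        rng = np.random.default_rng(1)
        M = matrix_from(rng.integers(0, 3, (10, 5)))
        cfg = BayesCConfig(pi=1.0, n_iter=500, burn_in=100, seed=0)
        post = train(M, records_from(M, rng.normal(size=10)), cfg)
        assert np.allclose(predict_dgv(M, post), 0.0)

    def test_duplicate_rows_and_linearity(self):
        rng = np.random.default_rng(2)
        Ztr = rng.integers(0, 3, (30, 8)).astype(float)
        M = matrix_from(Ztr)
        cfg = BayesCConfig(pi=0.5, n_iter=800, burn_in=100, seed=3)
        post = train(M, records_from(M, rng.normal(size=30)), cfg)
        b, c = Ztr[0], Ztr[1]
        a = (b + c) / 2
        Mv = matrix_from(np.stack([a, b, c, b]))
        dgv = predict_dgv(Mv, post)
        assert dgv[1] == pytest.approx(dgv[3])  # duplicates identical
        assert dgv[0] == pytest.approx((dgv[1] + dgv[2]) / 2)  # linear functional

    def test_locus_mismatch_fatal(self):
        rng = np.random.default_rng(2)
        M = matrix_from(rng.integers(0, 3, (10, 5)))
        cfg = BayesCConfig(pi=1.0, n_iter=300, burn_in=100, seed=0)
        post = train(M, records_from(M, rng.normal(size=10)), cfg)
        M2 = MarkerMatrix(M.animal_ids, M.locus_ids[::-1].copy(), M.Z)
        with pytest.raises(BayesCError, match="loci"):
            predict_dgv(M2, post)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        M = matrix_from(rng.integers(0, 3, (25, 12)))
        y = rng.normal(size=25)
        cfg = BayesCConfig(pi=0.9, n_iter=600, burn_in=100, seed=42)
        a = train(M, records_from(M, y), cfg)
        b = train(M, records_from(M, y), cfg)
        assert np.array_equal(a.u_mean, b.u_mean)
        assert np.array_equal(a.chains["se2"], b.chains["se2"])


class TestVariancesAndCalibration:
    def test_preliminary_variance_recovery(self):
        """h2 = 0.5 simulation: the full-data chain splits variance about evenly."""
        Z, y, tbv = sim_training(500, 1000, 50, seed=0, reliability=0.5)
        M = matrix_from(Z)
        cfg = BayesCConfig(pi=0.98, n_iter=1200, burn_in=300, seed=0)
        sg2, se2, sp2 = preliminary_variances(M, records_from(M, y), cfg)
        assert sp2 == pytest.approx(sg2 + se2)
        assert 0.35 <= sg2 / sp2 <= 0.65

    def test_zero_variance_response(self):
        rng = np.random.default_rng(0)
        M = matrix_from(rng.integers(0, 3, (60, 20)))
        y = np.full(60, 3.0)
        cfg = BayesCConfig(pi=0.98, n_iter=800, burn_in=200, seed=0)
        sg2, se2, sp2 = preliminary_variances(M, records_from(M, y), cfg)
        assert sg2 < 1e-4

    def test_heldout_calibration(self):
        """20-QTL trait, n=400 training, reliability 0.8: held-out corr(DGV, TBV)
        exceeds 0.35 in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            Z, y, tbv = sim_training(500, 1000, 20, seed=seed, reliability=0.8)
            M_tr = matrix_from(Z[:400])
            M_va = MarkerMatrix(
                np.array([f"V{i}" for i in range(100)], dtype=object),
                M_tr.locus_ids,
                Z[400:],
            )
            cfg = BayesCConfig(pi=0.98, n_iter=1000, burn_in=200, seed=seed)
            post = train(M_tr, records_from(M_tr, y[:400]), cfg)
            dgv = predict_dgv(M_va, post)
            hits += np.corrcoef(dgv, tbv[400:])[0, 1] > 0.35
        assert hits >= 9

    def test_null_inclusion_rate(self):
        """Pure-noise response: inclusion count stays near the prior rate."""
        rng = np.random.default_rng(6)
        M = matrix_from(rng.integers(0, 3, (100, 200)))
        y = rng.normal(size=100)
        cfg = BayesCConfig(pi=0.9, n_iter=2000, burn_in=500, seed=6)
        post = train(M, records_from(M, y), cfg)
        mean_incl = post.chains["n_incl"].mean()
        assert 0.1 * 20 <= mean_incl <= 3 * 20  # prior expectation (1-pi)*k = 20

    def test_nonpositive_weight_fatal(self):
        rng = np.random.default_rng(0)
        M = matrix_from(rng.integers(0, 3, (10, 4)))
        w = np.ones(10)
        w[3] = 0.0
        with pytest.raises(BayesCError, match="weights"):
            train(M, records_from(M, rng.normal(size=10), w), BayesCConfig(n_iter=200, burn_in=50))
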