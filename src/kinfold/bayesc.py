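"""Weighted BayesC: single-site Gibbs sampler for a mixture marker-effect model.

The training model for deregressed proofs y_i with residual weights w_i is

    y_i = mu + sum_j z_ij u_j + e_i,      Var(e_i) = sigma_e^2 / w_i

where each marker effect u_j is zero with prior probability pi and
N(0, sigma_u^2) with probability 1 - pi; sigma_u^2 and sigma_e^2 carry scaled
inverse-chi-square priors.  Per Gibbs sweep: the intercept is drawn from its
weighted normal full conditional; each marker in fixed map order is included
with probability

    logistic( log((1-pi)/pi) + 0.5*log(sigma_e^2/(sigma_u^2 C_j))
              + r_j^2 / (2 sigma_e^2 C_j) )

with r_j = sum_i w_i z_ij e~_ij (the residual with marker j's own contribution
restored) and C_j = sum_i w_i z_ij^2 + sigma_e^2/sigma_u^2, drawing
u_j ~ N(r_j/C_j, sigma_e^2/C_j) when included; then the two variances are drawn
from their scaled inverse-chi-square full conditionals.  The residual vector is
updated incrementally.  Posterior means over post-burn-in samples give the
marker effects; an animal's direct genomic value is DGV_i = sum_j z_ij u_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .genotype_qc import MarkerMatrix

__all__ = [
    "BayesCConfig",
    "PosteriorSummary",
    "preliminary_variances",
    "train",
    "predict_dgv",
]


class BayesCError(ValueError):
    pass


@dataclass
class BayesCConfig:
    """Sampler settings.  Defaults follow routine 50K-panel practice:
    pi = 0.995 (about 0.5% of markers in the model), 41 000 iterations with the
    first 1 000 discarded as burn-in."""

    pi: float = 0.995
    n_iter: int = 41_000
    burn_in: int = 1_000
    nu_u: float = 4.0
    nu_e: float = 10.0
    s2_u: float | None = None  # prior scale for sigma_u^2; derived if None
    s2_e: float | None = None  # prior scale for sigma_e^2; derived if None
    sample_variances: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise BayesCError(f"pi={self.pi} outside [0, 1]")
        if self.burn_in >= self.n_iter:
            raise BayesCError("burn-in must be shorter than the chain")


@dataclass
class PosteriorSummary:
    """Posterior means and chains from one training run."""

    locus_ids: np.ndarray
    u_mean: np.ndarray  # per-marker posterior mean effect
    incl_freq: np.ndarray  # per-marker posterior inclusion frequency
    mu_mean: float
    var_g_mean: float  # posterior mean variance of genetic values across animals
    su2_mean: float
    se2_mean: float
    z_center: np.ndarray | None = None  # training-set mean dosages (see train())
    chains: dict = field(default_factory=dict)  # mu, su2, se2, n_incl, var_g per kept sample


@njit(cache=True)
def _gibbs(Z, y, w, pi, n_iter, burn_in, nu_u, s2_u, nu_e, s2_e, sample_var, seed):
    np.random.seed(seed)
    n, m = Z.shape
    su2 = s2_u
    se2 = s2_e
    sw = w.sum()
    mu = (w * y).sum() / sw
    u = np.zeros(m)
    e = y - mu  # residual given u = 0
    wZ = np.empty((n, m))
    zz = np.empty(m)  # sum_i w_i z_ij^2
    for j in range(m):
        for i in range(n):
            wZ[i, j] = w[i] * Z[i, j]
        zz[j] = (wZ[:, j] * Z[:, j]).sum()

    n_keep = n_iter - burn_in
    u_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_chain = np.empty(n_keep)
    su2_chain = np.empty(n_keep)
    se2_chain = np.empty(n_keep)
    nincl_chain = np.empty(n_keep, dtype=np.int64)
    varg_chain = np.empty(n_keep)

    log_prior_odds = np.log(1.0 - pi) - np.log(pi) if 0.0 < pi < 1.0 else 0.0

    for it in range(n_iter):
        # intercept: weighted normal full conditional (flat prior)
        r_mu = (w * e).sum() / sw + mu
        mu_new = r_mu + np.random.normal() * np.sqrt(se2 / sw)
        e += mu - mu_new
        mu = mu_new

        n_incl = 0
        ss_u = 0.0
        for j in range(m):
            u_old = u[j]
            r_j = (wZ[:, j] * e).sum() + zz[j] * u_old
            C_j = zz[j] + se2 / su2
            if C_j <= 0.0 or not np.isfinite(C_j):
                raise ValueError("non-positive or non-finite marker precision")
            if pi >= 1.0:
                include = False
            elif pi <= 0.0:
                include = True
            else:
                logodds = (
                    log_prior_odds
                    + 0.5 * np.log(se2 / (su2 * C_j))
                    + r_j * r_j / (2.0 * se2 * C_j)
                )
                if logodds > 35.0:
                    include = True
                elif logodds < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-logodds))
            if include:
                u_new = r_j / C_j + np.random.normal() * np.sqrt(se2 / C_j)
                n_incl += 1
                ss_u += u_new * u_new
            else:
                u_new = 0.0
            if u_new != u_old:
                diff = u_new - u_old
                for i in range(n):
                    e[i] -= Z[i, j] * diff
                u[j] = u_new

        if sample_var:
            df_u = nu_u + n_incl
            su2 = (nu_u * s2_u + ss_u) / np.random.chisquare(df_u)
            df_e = nu_e + n
            sse = (w * e * e).sum()
            se2 = (nu_e * s2_e + sse) / np.random.chisquare(df_e)
            if not (np.isfinite(su2) and np.isfinite(se2)):
                raise ValueError("non-finite variance draw")

        if it >= burn_in:
            k = it - burn_in
            for j in range(m):
                u_sum[j] += u[j]
                if u[j] != 0.0:
                    incl_sum[j] += 1.0
            mu_chain[k] = mu
            su2_chain[k] = su2
            se2_chain[k] = se2
            nincl_chain[k] = n_incl
            # genetic value g = y - mu - e; its variance across animals
            gbar = 0.0
            for i in range(n):
                gbar += y[i] - mu - e[i]
            gbar /= n
            ssg = 0.0
            for i in range(n):
                d = (y[i] - mu - e[i]) - gbar
                ssg += d * d
            varg_chain[k] = ssg / (n - 1)

    return u_sum / n_keep, incl_sum / n_keep, mu_chain, su2_chain, se2_chain, nincl_chain, varg_chain


def _default_scales(Z: np.ndarray, y: np.ndarray, pi: float) -> tuple[float, float]:
    """Moment-based prior scales when none are supplied: split var(y) evenly
    between genetic and residual, spreading the genetic part over the expected
    number of included markers."""
    vy = float(np.var(y, ddof=1))
    if vy == 0.0:
        vy = 1e-8
    sum_var_z = float(np.var(Z, axis=0, ddof=1).sum())
    frac = max(1.0 - pi, 1e-3)
    s2_u = 0.5 * vy / max(frac * sum_var_z, 1e-12)
    return s2_u, 0.5 * vy


def prior_scales_from_variances(
    sg2: float, se2: float, Z: np.ndarray, pi: float
) -> tuple[float, float]:
    """Prior scales so that the marker-effect prior mean matches sigma_g^2
    spread over the expected (1-pi)*k included markers, and the residual prior
    mean matches sigma_e^2."""
    sum_var_z = float(np.var(Z, axis=0, ddof=1).sum())
    frac = max(1.0 - pi, 1e-3)
    return sg2 / max(frac * sum_var_z, 1e-12), se2


def _aligned_arrays(M: MarkerMatrix, records) -> tuple[np.ndarray, np.ndarray]:
    """Extract (debv, weight) aligned to M's animal order from a records frame."""
    rec = records.set_index("animal") if "animal" in getattr(records, "columns", []) else records
    y = np.array([rec.loc[a, "debv"] for a in M.animal_ids], dtype=float)
    w = np.array([rec.loc[a, "weight"] for a in M.animal_ids], dtype=float)
    return y, w


def train(M: MarkerMatrix, records, cfg: BayesCConfig) -> PosteriorSummary:
    """Run the Gibbs sampler on training animals and summarize the posterior.

    ``records`` is a DataFrame indexed (or indexable) by animal with columns
    ``debv`` and ``weight``; rows are aligned to ``M.animal_ids``.  Dosages
    must already be imputed (no NaN).
    """
    Z = np.asarray(M.Z, dtype=np.float64)
    if np.isnan(Z).any():
        raise BayesCError("dosage matrix contains missing values; impute first")
    # Center dosage columns at the training means.  This reparameterizes
    # (mu, u) -> (mu + sum_j zbar_j u_j, u): the model is unchanged, but it
    # removes the nearly flat likelihood direction between the intercept and
    # the marker-mean sum that otherwise random-walks and leaves each fold's
    # DGV with an arbitrary offset.  Predictions apply the same centering.
    z_center = Z.mean(axis=0)
    Z = np.ascontiguousarray(Z - z_center)
    y, w = _aligned_arrays(M, records)
    if not np.all(np.isfinite(y)):
        raise BayesCError("non-finite response values")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise BayesCError("weights must be positive and finite")
    s2_u, s2_e = cfg.s2_u, cfg.s2_e
    if s2_u is None or s2_e is None:
        d_u, d_e = _default_scales(Z, y, cfg.pi)
        s2_u = d_u if s2_u is None else s2_u
        s2_e = d_e if s2_e is None else s2_e
    u_mean, incl, mu_c, su2_c, se2_c, nincl_c, varg_c = _gibbs(
        Z,
        y,
        w,
        cfg.pi,
        cfg.n_iter,
        cfg.burn_in,
        cfg.nu_u,
        s2_u,
        cfg.nu_e,
        s2_e,
        cfg.sample_variances,
        cfg.seed,
    )
    if not np.all(np.isfinite(u_mean)):
        raise BayesCError("non-finite posterior means")
    return PosteriorSummary(
        locus_ids=M.locus_ids.copy(),
        u_mean=u_mean,
        incl_freq=incl,
        z_center=z_center,
        mu_mean=float(mu_c.mean()),
        var_g_mean=float(varg_c.mean()),
        su2_mean=float(su2_c.mean()),
        se2_mean=float(se2_c.mean()),
        chains={"mu": mu_c, "su2": su2_c, "se2": se2_c, "n_incl": nincl_c, "var_g": varg_c},
    )


def preliminary_variances(
    M: MarkerMatrix, records, cfg: BayesCConfig
) -> tuple[float, float, float]:
    """Full-data chain to estimate (sigma_g^2, sigma_e^2, sigma_p^2).

    All animals are used for training; the genetic variance is the posterior
    mean of the across-animal variance of model genetic values, the phenotypic
    variance is the sum of the genetic and residual estimates.  These seed the
    prior scales of the per-fold runs and the sigma_p^2 used for accuracy.
    """
    post = train(M, records, cfg)
    sg2 = post.var_g_mean
    se2 = post.se2_mean
    return sg2, se2, sg2 + se2


def predict_dgv(M: MarkerMatrix, post: PosteriorSummary) -> np.ndarray:
    """DGV_i = sum_j z_ij * u_hat_j for each animal in M (training locus order)."""
    if len(M.locus_ids) != len(post.locus_ids) or not np.array_equal(
        M.locus_ids, post.locus_ids
    ):
        raise BayesCError("validation loci do not match training loci (ids/order)")
    Z = np.asarray(M.Z, dtype=np.float64)
    if np.isnan(Z).any():
        raise BayesCError("dosage matrix contains missing values; impute first")
    if post.z_center is not None:
        Z = Z - post.z_center
    return Z @ post.u_mean


def fold_config(cfg: BayesCConfig, sg2: float, se2: float, Z: np.ndarray) -> BayesCConfig:
    """Derive a per-fold config with prior scales seeded from preliminary variances."""
    s2_u, s2_e = prior_scales_from_variances(sg2, se2, Z, cfg.pi)
    return replace(cfg, s2_u=s2_u, s2_e=s2_e)
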