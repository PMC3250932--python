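"""Weighted bivariate animal model: genetic correlation between a trait and its DGV.

The two "traits" are an animal's deregressed proof (DEBV) and its
cross-validated direct genomic value (DGV).  With additive effects
alpha_1, alpha_2 sharing the pedigree relationship matrix A,

    Var(alpha) = G0 (x) A,   G0 = [[s2_a1, s_a12], [s_a12, s2_a2]]

the DEBV residual is heteroscedastic, Var(e1)_ii = s2_e1 / w_i with the same
reliability-derived weights used in marker-effect training, while the DGV
residual is homoscedastic, Var(e2) = I * s2_e2; the two residuals are
uncorrelated.  Fixed effects: an overall mean for DEBV and fold-group classes
for DGV (each fold's prediction equation has its own scale).  Variance
components are estimated by EM-REML with average-information (AI)
acceleration; AI steps are only accepted when the restricted log-likelihood
does not decrease, otherwise the guaranteed-ascent EM update is used.  The
genetic correlation is r_g = s_a12 / sqrt(s2_a1 * s2_a2) with its standard
error from the inverse AI matrix by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["BivariateModelSpec", "BivariateFit", "fit_bivariate", "dgv_heritability_check"]


class RemlError(RuntimeError):
    pass


@dataclass
class BivariateModelSpec:
    """Data for one trait's bivariate DEBV/DGV analysis (arrays aligned by animal)."""

    debv: np.ndarray
    dgv: np.ndarray
    weights: np.ndarray  # residual weights for DEBV (mean-normalized at fit time)
    groups: np.ndarray  # fold-group labels (fixed-effect classes for DGV)
    A: np.ndarray  # pedigree relationship matrix over the phenotyped animals


@dataclass
class BivariateFit:
    G0: np.ndarray
    se1: float
    se2: float
    rg: float
    rg_se: float
    h2_t: float
    h2_t_se: float
    h2_dgv: float
    h2_dgv_se: float
    logL: float
    trajectory: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    theta_cov: np.ndarray | None = None
    condition_warning: bool = False


def _design(spec: BivariateModelSpec) -> np.ndarray:
    n = len(spec.debv)
    labels = np.unique(spec.groups)
    Xg = np.zeros((n, len(labels)))
    for k, g in enumerate(labels):
        Xg[np.asarray(spec.groups) == g, k] = 1.0
    X = np.zeros((2 * n, 1 + len(labels)))
    X[:n, 0] = 1.0
    X[n:, 1:] = Xg
    return X


def _bend_pd(G: np.ndarray, floor_frac: float = 1e-6) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(G)
    floor = floor_frac * np.trace(G)
    if vals.min() >= floor:
        return G, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


def fit_bivariate(
    spec: BivariateModelSpec,
    max_iter: int = 200,
    tol: float = 1e-6,
    use_ai: bool = True,
    n_em_warmup: int = 3,
    verbose: bool = False,
) -> BivariateFit:
    """Estimate (G0, s2_e1, s2_e2) by REML and derive r_g and heritabilities.

    EM updates guarantee a non-decreasing restricted log-likelihood; AI
    (Newton) steps are attempted after ``n_em_warmup`` EM iterations and kept
    only when they improve the likelihood and stay in the parameter space.
    Raises :class:`RemlError` (with the likelihood trajectory attached) if not
    converged within ``max_iter``.
    """
    y1 = np.asarray(spec.debv, dtype=float)
    y2 = np.asarray(spec.dgv, dtype=float)
    w = np.asarray(spec.weights, dtype=float)
    if np.any(w <= 0):
        raise RemlError("weights must be positive")
    w = w / w.mean()  # mean weight 1 so s2_e1 is on the record scale
    n = len(y1)
    A = np.asarray(spec.A, dtype=float)
    if A.shape != (n, n):
        raise RemlError("A must be square over the phenotyped animals")
    Dw = np.diag(1.0 / w)
    Ainv = linalg.inv(A)
    X = _design(spec)
    y = np.concatenate([y1, y2])

    # moment-based start: half genetic, half residual
    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    c12 = np.cov(y1, y2, ddof=1)[0, 1]
    G0 = 0.5 * np.array([[v1, c12], [c12, v2]])
    G0, _ = _bend_pd(G0)
    se1, se2 = 0.5 * v1, 0.5 * v2

    I_n = np.eye(n)
    traj: list[float] = []

    def assemble(G0, se1, se2):
        V = np.empty((2 * n, 2 * n))
        V[:n, :n] = G0[0, 0] * A + se1 * Dw
        V[:n, n:] = G0[0, 1] * A
        V[n:, :n] = G0[0, 1] * A
        V[n:, n:] = G0[1, 1] * A + se2 * I_n
        return V

    def reml_pieces(G0, se1, se2):
        V = assemble(G0, se1, se2)
        Vi = linalg.inv(V)
        XtVi = X.T @ Vi
        XtViX = XtVi @ X
        M = linalg.inv(XtViX)
        P = Vi - XtVi.T @ M @ XtVi
        Py = P @ y
        s1, ld1 = np.linalg.slogdet(V)
        s2_, ld2 = np.linalg.slogdet(XtViX)
        if s1 <= 0 or s2_ <= 0:
            raise RemlError("indefinite variance matrix during REML")
        logL = -0.5 * (ld1 + ld2 + float(y @ Py))
        return P, Py, logL

    def em_update(G0, se1, se2, P, Py):
        Gmat = np.block([[G0[0, 0] * A, G0[0, 1] * A], [G0[0, 1] * A, G0[1, 1] * A]])
        ahat = Gmat @ Py
        PEV = Gmat - Gmat @ P @ Gmat
        a1, a2 = ahat[:n], ahat[n:]
        g11 = (a1 @ Ainv @ a1 + np.sum(Ainv * PEV[:n, :n].T)) / n
        g12 = (a1 @ Ainv @ a2 + np.sum(Ainv * PEV[:n, n:].T)) / n
        g22 = (a2 @ Ainv @ a2 + np.sum(Ainv * PEV[n:, n:].T)) / n
        e1 = se1 * (Py[:n] / w)
        e2 = se2 * Py[n:]
        P11, P22 = P[:n, :n], P[n:, n:]
        se1_new = float(e1 @ (w * e1)) / n + se1 - se1**2 * np.trace(P11 @ Dw) / n
        se2_new = float(e2 @ e2) / n + se2 - se2**2 * np.trace(P22) / n
        G_new = np.array([[g11, g12], [g12, g22]])
        return G_new, max(se1_new, 1e-12), max(se2_new, 1e-12)

    def theta_of(G0, se1, se2):
        return np.array([G0[0, 0], G0[0, 1], G0[1, 1], se1, se2])

    def unpack(theta):
        return np.array([[theta[0], theta[1]], [theta[1], theta[2]]]), theta[3], theta[4]

    def ai_pieces(P, Py):
        # derivative-of-V times Py, per parameter
        d = np.empty((5, 2 * n))
        APy1, APy2 = A @ Py[:n], A @ Py[n:]
        d[0] = np.concatenate([APy1, np.zeros(n)])
        d[1] = np.concatenate([APy2, APy1])
        d[2] = np.concatenate([np.zeros(n), APy2])
        d[3] = np.concatenate([Py[:n] / w, np.zeros(n)])
        d[4] = np.concatenate([np.zeros(n), Py[n:]])
        Pd = d @ P  # (5, 2n): each row P @ d_i (P symmetric)
        AI = 0.5 * (d @ Pd.T)
        # scores: -0.5 (tr(P V_i) - Py' V_i Py)
        PA11 = np.sum(P[:n, :n] * A.T)
        PA12 = np.sum(P[:n, n:] * A.T)
        PA22 = np.sum(P[n:, n:] * A.T)
        trPV = np.array(
            [
                PA11,
                2.0 * PA12,
                PA22,
                np.trace(P[:n, :n] @ np.diag(1.0 / w)),
                np.trace(P[n:, n:]),
            ]
        )
        score = -0.5 * (trPV - d @ Py)
        return AI, score

    P, Py, logL = reml_pieces(G0, se1, se2)
    traj.append(logL)
    converged = False
    AI = None
    bent_any = False
    for it in range(1, max_iter + 1):
        theta_old = theta_of(G0, se1, se2)
        accepted = False
        if use_ai and it > n_em_warmup:
            AI, score = ai_pieces(P, Py)
            try:
                step = linalg.solve(AI, score, assume_a="pos")
            except linalg.LinAlgError:
                step = None
            if step is not None:
                scale = 1.0
                for _ in range(8):
                    theta_new = theta_old + scale * step
                    G_try, se1_try, se2_try = unpack(theta_new)
                    G_try, _ = _bend_pd(G_try)  # project back onto the PD cone
                    if se1_try <= 0 or se2_try <= 0:
                        scale *= 0.5
                        continue
                    try:
                        P_new, Py_new, logL_new = reml_pieces(G_try, se1_try, se2_try)
                    except RemlError:
                        scale *= 0.5
                        continue
                    if logL_new >= logL - 1e-10:
                        G0, se1, se2 = G_try, se1_try, se2_try
                        P, Py = P_new, Py_new
                        logL_prev, logL = logL, logL_new
                        accepted = True
                        break
                    scale *= 0.5
        if not accepted:
            G_new, se1_new, se2_new = em_update(G0, se1, se2, P, Py)
            G_new, bent = _bend_pd(G_new)
            bent_any = bent_any or bent
            G0, se1, se2 = G_new, se1_new, se2_new
            P, Py, logL_new = reml_pieces(G0, se1, se2)
            logL_prev, logL = logL, logL_new
        traj.append(logL)
        if verbose:
            print(f"iter {it}: logL={logL:.6f}")
        if abs(logL - logL_prev) < tol:
            converged = True
            break
    if not converged:
        err = RemlError(f"REML did not converge in {max_iter} iterations")
        err.trajectory = traj
        raise err

    AI, _ = ai_pieces(P, Py)
    try:
        cov = linalg.inv(AI)
    except linalg.LinAlgError:
        cov = np.full((5, 5), np.nan)
    g11, g12, g22 = G0[0, 0], G0[0, 1], G0[1, 1]
    rg = g12 / np.sqrt(g11 * g22)
    grad_rg = np.array([-0.5 * rg / g11, 1.0 / np.sqrt(g11 * g22), -0.5 * rg / g22, 0, 0])
    rg_se = float(np.sqrt(max(grad_rg @ cov @ grad_rg, 0.0)))
    h2_t = g11 / (g11 + se1)
    grad_h1 = np.array([se1 / (g11 + se1) ** 2, 0, 0, -g11 / (g11 + se1) ** 2, 0])
    h2_t_se = float(np.sqrt(max(grad_h1 @ cov @ grad_h1, 0.0)))
    h2_dgv = g22 / (g22 + se2)
    grad_h2 = np.array([0, 0, se2 / (g22 + se2) ** 2, 0, -g22 / (g22 + se2) ** 2])
    h2_dgv_se = float(np.sqrt(max(grad_h2 @ cov @ grad_h2, 0.0)))
    # DGV are linear functions of other folds' DEBV, so the joint covariance
    # can approach singularity; surface a condition warning rather than fail.
    cond_warn = bool(np.linalg.cond(G0) > 1e8 or bent_any)
    return BivariateFit(
        G0=G0,
        se1=float(se1),
        se2=float(se2),
        rg=float(rg),
        rg_se=rg_se,
        h2_t=float(h2_t),
        h2_t_se=h2_t_se,
        h2_dgv=float(h2_dgv),
        h2_dgv_se=h2_dgv_se,
        logL=float(logL),
        trajectory=traj,
        n_iter=len(traj) - 1,
        converged=True,
        theta_cov=cov,
        condition_warning=cond_warn,
    )


def dgv_heritability_check(fit: BivariateFit, scheme: str = "kmeans") -> dict:
    """Flag DGV heritabilities that fall below the typical range for a scheme.

    Cross-validated DGV behave as a nearly fully heritable trait; values below
    0.8 (relatedness-minimizing folds) or 0.99 (random folds) are noteworthy
    and usually indicate inconsistent prediction equations between folds.
    """
    threshold = 0.99 if scheme == "random" else 0.8
    return {
        "scheme": scheme,
        "h2_dgv": fit.h2_dgv,
        "threshold": threshold,
        "below_typical": bool(fit.h2_dgv < threshold),
    }
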