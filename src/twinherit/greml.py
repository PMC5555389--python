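"""Variance-component estimation by restricted maximum likelihood.

The univariate joint model fits y = Xb + g_snp + g_fam + e where
cov(g_snp) = sigma2_snp * IBS-GRM and cov(g_fam) = sigma2_extra *
IBD-GRM; the IBS matrix identifies the SNP-tagged variance and the IBD
matrix the additional within-family additive variance, so their sum is
narrow-sense heritability.  Binary outcomes are analysed on the
observed 0/1 scale and transformed to the liability scale afterwards.
The bivariate model stacks two disjoint sets of individuals (here men
and women) and estimates the genetic covariance between the traits
through the cross-relatedness block; the genetic covariance is left
unconstrained so the genetic correlation can be negative.

Optimization is average-information REML: one EM step, then AI updates
with step halving, variance components projected to stay non-negative,
convergence when the restricted log-likelihood moves by < 1e-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.stats import chi2, norm

from .grm import GRM

__all__ = [
    "GremlFit",
    "BivarGremlFit",
    "reml_fit",
    "reml_loglik",
    "h2_observed_to_liability",
    "bivariate_reml",
]


class RemlError(RuntimeError):
    pass


def _as_matrix(m):
    return m.matrix if isinstance(m, GRM) else np.asarray(m, float)


# ---------------------------------------------------------------------------
# core engine

def _build_V(mats, theta, n):
    V = np.zeros((n, n))
    for A, t in zip(mats, theta):
        if A.ndim == 1:
            V[np.diag_indices(n)] += t * A
        else:
            V += t * A
    return V


def _reml_pieces(y, X, mats, theta):
    """Restricted log-likelihood and the P-projected quantities."""
    n = len(y)
    V = _build_V(mats, theta, n)
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi, info = lapack.dpotri(cf[0], lower=1)
    if info != 0:
        return None
    Vi = np.tril(Vi) + np.tril(Vi, -1).T
    ViX = Vi @ X
    XtViX = X.T @ ViX
    try:
        cfx = cho_factor(XtViX, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    C = cho_solve(cfx, np.eye(X.shape[1]), check_finite=False)
    Viy = Vi @ y
    Py = Viy - ViX @ (C @ (ViX.T @ y))
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return {"Vi": Vi, "ViX": ViX, "C": C, "Py": Py, "ll": ll}


def reml_loglik(y, X, mats, theta) -> float:
    """Restricted log-likelihood at the given variance components.

    ``mats`` are the covariance structures (full matrices, or 1-D
    arrays read as diagonals); the residual identity must be included
    explicitly as its own structure.
    """
    mats = [_as_matrix(m) if not (isinstance(m, np.ndarray) and m.ndim == 1)
            else m for m in mats]
    pieces = _reml_pieces(np.asarray(y, float), np.asarray(X, float),
                          mats, np.asarray(theta, float))
    if pieces is None:
        return -np.inf
    return pieces["ll"]


def _derivs(y, X, mats, pieces):
    """Scores, AI matrix and u_k = y'P A_k P y for every component."""
    Vi, ViX, C, Py = (pieces[k] for k in ("Vi", "ViX", "C", "Py"))
    K = len(mats)
    APy, trPA, u = [], [], []
    for A in mats:
        if A.ndim == 1:
            apy = A * Py
            tr_via = float(np.diag(Vi) @ A)
            B = A[:, None] * ViX
        else:
            apy = A @ Py
            tr_via = float(np.sum(Vi * A))
            B = A @ ViX
        M = ViX.T @ B
        trPA.append(tr_via - float(np.sum(C * M)))
        APy.append(apy)
        u.append(float(Py @ apy))
    PAPy = [Vi @ a - ViX @ (C @ (ViX.T @ a)) for a in APy]
    AI = 0.5 * np.array([[float(APy[k] @ PAPy[l]) for l in range(K)]
                         for k in range(K)])
    score = -0.5 * (np.array(trPA) - np.array(u))
    return score, AI, np.array(u), np.array(trPA)


def _ai_reml(y, X, mats, theta0, constrained, tol=1e-8, max_iter=100,
             param_map=None):
    """AI-REML in an optional smooth reparameterization phi -> theta.

    ``param_map(phi) -> (theta, J)`` with J = d theta / d phi; identity
    when None.  Returns (phi, theta, ll, AI_phi_inv, iters, converged,
    trajectory).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    vp = float(np.var(y))
    floor = 1e-6 * vp

    identity_map = param_map is None
    if identity_map:
        param_map = lambda ph: (ph, np.eye(len(ph)))

    phi = np.asarray(theta0, float).copy()
    theta, J = param_map(phi)
    pieces = _reml_pieces(y, X, mats, theta)
    if pieces is None:
        raise RemlError("initial V not positive definite")
    ll = pieces["ll"]
    traj = [ll]
    converged = False
    score_phi, AI_phi = None, None
    for it in range(max_iter):
        score, AI, u, trPA = _derivs(y, X, mats, pieces)
        theta, J = param_map(phi)
        score_phi = J.T @ score
        AI_phi = J.T @ AI @ J
        if it == 0 and identity_map:
            # EM-flavoured first step for stability
            step = phi**2 * (u - trPA) / n
        else:
            try:
                step = np.linalg.solve(
                    AI_phi + 1e-12 * np.eye(len(phi)), score_phi)
            except np.linalg.LinAlgError:
                step = phi**2 * ((J.T @ (u - trPA)) / n)
        accepted = False
        for _ in range(8):
            cand = phi + step
            cand[constrained & (cand < floor)] = floor
            theta_c, _ = param_map(cand)
            cand_pieces = _reml_pieces(y, X, mats, theta_c)
            if cand_pieces is not None and cand_pieces["ll"] >= ll - 1e-10:
                accepted = True
                break
            step = 0.5 * step
        if not accepted:
            # no improving step exists (typically a boundary optimum)
            converged = len(traj) < 2 or abs(traj[-1] - traj[-2]) < 1e-6
            break
        delta = cand_pieces["ll"] - ll
        phi, pieces, ll = cand, cand_pieces, cand_pieces["ll"]
        traj.append(ll)
        if abs(delta) < tol:
            converged = True
            break
    if not converged and len(traj) >= max_iter:
        raise RemlError(f"REML did not converge in {max_iter} iterations; "
                        f"trajectory {traj[-5:]}")
    theta, J = param_map(phi)
    try:
        ai_inv = np.linalg.inv(AI_phi)
    except (np.linalg.LinAlgError, TypeError):
        ai_inv = np.full((len(phi), len(phi)), np.nan)
    boundary = [bool(c and t <= floor * 1.01) for c, t in zip(constrained, theta)]
    return {"phi": phi, "theta": theta, "ll": ll, "ai_inv": ai_inv,
            "iters": len(traj) - 1, "converged": converged,
            "boundary": boundary, "trajectory": traj}


# ---------------------------------------------------------------------------
# univariate

@dataclass
class GremlFit:
    """Joint-model variance components on observed and liability scales."""

    sigma2_snp: float
    sigma2_extra: float
    sigma2_e: float
    se: dict
    h2_snp_obs: float
    h2_obs: float
    h2_snp_liab: float
    h2_liab: float
    K: float
    P: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: list
    n: int

    @property
    def total_variance(self) -> float:
        return self.sigma2_snp + self.sigma2_extra + self.sigma2_e


def h2_observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Lee et al. observed-to-liability scale transformation.

    h2_liab = h2_obs * K(1-K)/z^2 * K(1-K)/(P(1-P)) with z the standard
    normal density at the threshold for population prevalence K and P
    the sample case proportion.  Values above 1 are returned uncapped
    with a warning.
    """
    if not (0.0 < K < 1.0 and 0.0 < P < 1.0):
        raise ValueError("K and P must lie in (0, 1)")
    if h2_obs < 0:
        raise ValueError("h2_obs must be >= 0")
    t = norm.ppf(1.0 - K)
    z = norm.pdf(t)
    out = h2_obs * K * (1 - K) / z**2 * K * (1 - K) / (P * (1 - P))
    if out > 1.0:
        warnings.warn(f"liability-scale h2 {out:.3f} exceeds 1", RuntimeWarning)
    return float(out)


def reml_fit(y, X, matrices, K: float | None = None,
             tol: float = 1e-8, max_iter: int = 100) -> GremlFit:
    """Joint REML with one (IBS) or two (IBS + IBD) relatedness matrices.

    ``y`` is the 0/1 outcome, ``X`` the fixed-effect design (intercept,
    birth year, principal components), ``matrices`` the GRMs aligned to
    ``y``.  With prevalence ``K`` supplied, liability-scale versions of
    h2_snp and h2 are filled in (sample proportion P is taken from y).
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")
    mats = [_as_matrix(m) for m in matrices]
    if len(mats) not in (1, 2):
        raise ValueError("one or two relatedness matrices expected")
    for A in mats:
        if A.shape != (len(y), len(y)):
            raise ValueError("relatedness matrix not aligned with y")
    n = len(y)
    if len(mats) == 1 and np.allclose(mats[0], np.eye(n)):
        raise ValueError("single identity-like matrix: genetic and residual "
                         "components are confounded")
    comps = mats + [np.ones(n)]          # residual as diagonal structure
    vp = float(np.var(y))
    theta0 = np.full(len(comps), vp / len(comps))
    res = _ai_reml(y, X, comps, theta0,
                   constrained=np.ones(len(comps), bool),
                   tol=tol, max_iter=max_iter)
    th = res["theta"]
    s_snp = float(th[0])
    s_extra = float(th[1]) if len(mats) == 2 else 0.0
    s_e = float(th[-1])
    total = s_snp + s_extra + s_e
    ses = np.sqrt(np.maximum(np.diag(res["ai_inv"]), 0.0))
    se = {"sigma2_snp": float(ses[0]),
          "sigma2_extra": float(ses[1]) if len(mats) == 2 else 0.0,
          "sigma2_e": float(ses[-1])}
    h2_snp_obs = s_snp / total
    h2_obs = (s_snp + s_extra) / total
    P = float(np.mean(y))
    if K is not None:
        h2_snp_liab = h2_observed_to_liability(h2_snp_obs, K, P)
        h2_liab = h2_observed_to_liability(h2_obs, K, P)
    else:
        h2_snp_liab = h2_liab = np.nan
    return GremlFit(
        sigma2_snp=s_snp, sigma2_extra=s_extra, sigma2_e=s_e, se=se,
        h2_snp_obs=h2_snp_obs, h2_obs=h2_obs,
        h2_snp_liab=h2_snp_liab, h2_liab=h2_liab,
        K=K if K is not None else np.nan, P=P,
        loglik=res["ll"], n_iter=res["iters"], converged=res["converged"],
        boundary=res["boundary"], n=n)


# ---------------------------------------------------------------------------
# bivariate

@dataclass
class BivarGremlFit:
    v_g1: float
    v_g2: float
    cov_g: float
    v_e1: float
    v_e2: float
    rg: float
    rg_se: float
    p_rg0: float
    p_rg1: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: list
    n1: int
    n2: int


def _bivar_components(A, n1, n2):
    """Block-structured covariance components for the stacked system."""
    n = n1 + n2
    Ag1 = np.zeros((n, n)); Ag1[:n1, :n1] = A[:n1, :n1]
    Ag2 = np.zeros((n, n)); Ag2[n1:, n1:] = A[n1:, n1:]
    Ac = np.zeros((n, n))
    Ac[:n1, n1:] = A[:n1, n1:]
    Ac[n1:, :n1] = A[n1:, :n1]
    e1 = np.concatenate([np.ones(n1), np.zeros(n2)])
    e2 = 1.0 - e1
    return [Ag1, Ag2, Ac, e1, e2]


def bivariate_reml(y1, y2, grm, X1, X2, idx1=None, idx2=None,
                   tol: float = 1e-8, max_iter: int = 100,
                   do_tests: bool = True) -> BivarGremlFit:
    """Cross-group genetic correlation by bivariate REML.

    ``y1``/``y2`` are the outcomes of two disjoint individual sets
    (trait 1 = males, trait 2 = females in the childlessness analysis);
    ``grm`` covers all individuals, with ``idx1``/``idx2`` selecting the
    rows of each set (defaults: first len(y1) rows, remaining rows).
    The residual cross-covariance is structurally 0 because nobody
    carries both traits.  rg = cov_g / sqrt(v_g1 v_g2) with a
    delta-method SE; rg = 0 and rg = 1 are tested by likelihood ratio
    against constrained refits.
    """
    A = _as_matrix(grm)
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n1, n2 = len(y1), len(y2)
    if idx1 is None:
        idx1 = np.arange(n1)
    if idx2 is None:
        idx2 = np.arange(n1, n1 + n2)
    if np.intersect1d(idx1, idx2).size:
        raise ValueError("male and female index sets must be disjoint")
    order = np.concatenate([idx1, idx2])
    A = A[np.ix_(order, order)]
    y = np.concatenate([y1, y2])
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    if X1.shape[0] != n1:
        X1 = X1.T
    if X2.shape[0] != n2:
        X2 = X2.T
    X = np.zeros((n1 + n2, X1.shape[1] + X2.shape[1]))
    X[:n1, :X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2

    comps = _bivar_components(A, n1, n2)
    v1, v2 = float(np.var(y1)), float(np.var(y2))
    theta0 = np.array([v1 / 2, v2 / 2, 0.0, v1 / 2, v2 / 2])
    constrained = np.array([True, True, False, True, True])
    res = _ai_reml(y, X, comps, theta0, constrained, tol=tol,
                   max_iter=max_iter)
    vg1, vg2, cg, ve1, ve2 = res["theta"]
    boundary = res["boundary"]
    if boundary[0] or boundary[1]:
        warnings.warn("within-group genetic variance at zero boundary: "
                      "rg undefined", RuntimeWarning)
        rg, rg_se = np.nan, np.nan
    else:
        rg = cg / np.sqrt(vg1 * vg2)
        grad = np.array([-rg / (2 * vg1), -rg / (2 * vg2),
                         1.0 / np.sqrt(vg1 * vg2), 0.0, 0.0])
        var_rg = float(grad @ res["ai_inv"] @ grad)
        rg_se = float(np.sqrt(max(var_rg, 0.0)))

    p_rg0 = p_rg1 = np.nan
    if do_tests and np.isfinite(rg):
        # constrained refits feed likelihood-ratio statistics only, so a
        # looser tolerance (1e-5 on the log-likelihood) is ample there
        tol_t = max(tol, 1e-5)
        # rg = 0: drop the genetic-covariance component
        comps0 = [comps[0], comps[1], comps[3], comps[4]]
        res0 = _ai_reml(y, X, comps0,
                        np.array([vg1, vg2, ve1, ve2]),
                        np.ones(4, bool), tol=tol_t, max_iter=max_iter)
        p_rg0 = float(chi2.sf(2.0 * (res["ll"] - res0["ll"]), 1))

        # rg = 1: genetic covariance tied to sqrt(v_g1 v_g2)
        def rg1_map(ph):
            s1, s2, e1, e2 = ph
            theta = np.array([s1**2, s2**2, s1 * s2, e1, e2])
            J = np.array([
                [2 * s1, 0.0, 0.0, 0.0],
                [0.0, 2 * s2, 0.0, 0.0],
                [s2, s1, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ])
            return theta, J

        phi0 = np.array([np.sqrt(max(vg1, 1e-8)), np.sqrt(max(vg2, 1e-8)),
                         max(ve1, 1e-8), max(ve2, 1e-8)])
        res1 = _ai_reml(y, X, comps, phi0, np.ones(4, bool), tol=tol_t,
                        max_iter=max_iter, param_map=rg1_map)
        p_rg1 = float(chi2.sf(2.0 * (res["ll"] - res1["ll"]), 1))

    return BivarGremlFit(
        v_g1=float(vg1), v_g2=float(vg2), cov_g=float(cg),
        v_e1=float(ve1), v_e2=float(ve2),
        rg=float(rg), rg_se=rg_se, p_rg0=p_rg0, p_rg1=p_rg1,
        loglik=res["ll"], n_iter=res["iters"], converged=res["converged"],
        boundary=boundary, n1=n1, n2=n2)
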