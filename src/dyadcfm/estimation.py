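"""Maximum likelihood estimation of the two-level common fate model.

The data are clustered: dyad j contributes an ``n_j x p_w`` matrix of
observed diary days (day-level full-information ML — a dyad keeps
whatever complete days it has) plus a vector of between-only observed
variables (post-diary outcomes).  Writing ``Sigma_W`` and ``Sigma_B``
for the implied within/between covariances, the covariance of the
stacked cluster vector is

    V_j = I_{n_j} (x) Sigma_W + J_{n_j} (x) Sigma_B   (+ between blocks)

whose eigenstructure in the day dimension splits the likelihood into
``n_j - 1`` deviation components governed by ``Sigma_W`` alone and one
cluster-mean component governed by ``Sigma_B + Sigma_W / n_j`` (jointly
normal with the between-only variables).  The likelihood is evaluated
through that decomposition; the dense ``n_j * p`` covariance is never
materialized outside of test oracles.

Optimization is quasi-Newton (L-BFGS-B) on an unconstrained
reparameterization (log variances, raw paths and means).  Standard
errors come from the inverse of the numerically differentiated observed
information, delta-method-transformed back to the natural scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.optimize import minimize

from .model import CFMSpec, ParameterSet, implied_moments, standardize

__all__ = [
    "ClusterData",
    "FitConfig",
    "FitResult",
    "build_cluster_data",
    "pooled_moments",
    "loglikelihood",
    "dense_loglikelihood",
    "fit",
    "fit_indices",
]

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e15

#: between-only model indicators -> post-diary CSV columns
DISTAL_MAP = {
    "post_qol_plwh": "qol_plwh",
    "post_qol_partner": "qol_partner",
    "post_prep": "prep_attitude",
    "post_rs_plwh": "rs_plwh",
    "post_rs_partner": "rs_partner",
}


@dataclass
class ClusterData:
    """One dyad's observed data: diary-day rows plus between-only values."""

    dyad_id: object
    Y: np.ndarray  # (n_j, p_w), complete rows, spec indicator order
    z: np.ndarray  # (p_z,) between-only observed variables

    @property
    def n_j(self) -> int:
        return self.Y.shape[0]


@dataclass
class FitConfig:
    max_iter: int = 3000
    gtol: float = 1e-7
    ftol: float = 1e-12
    compute_se: bool = True
    compute_fit_indices: bool = True
    track_trace: bool = False
    reltol_hessian: float = 1e-4


@dataclass
class FitResult:
    theta_hat: ParameterSet
    se: dict[str, float]
    beta: dict[str, float]
    loglik: float
    loglik_saturated: float | None
    loglik_baseline: float | None
    chi2: float | None
    df: int
    fit: dict[str, float | None]
    converged: bool
    n_clusters: int
    n_obs: int
    param_names: tuple[str, ...] = ()
    param_cov: np.ndarray | None = None
    trace: list[float] = field(default_factory=list)
    message: str = ""

    def cov_of(self, names: list[str]) -> np.ndarray:
        """Joint asymptotic covariance submatrix for the named parameters."""
        if self.param_cov is None:
            raise ValueError("fit was run without standard errors")
        ix = [self.param_names.index(n) for n in names]
        return self.param_cov[np.ix_(ix, ix)]


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def build_cluster_data(
    panel: pd.DataFrame, post: pd.DataFrame | None, spec: CFMSpec
) -> list[ClusterData]:
    """Assemble per-dyad matrices from tidy diary / post-diary tables.

    A diary day enters a dyad's matrix only if both partners' records
    are present and every required item is non-missing (day-level FIML).
    Dyads left with zero usable days are dropped with a logged count.
    """
    wide = panel.copy()
    wide["role"] = wide["role"].str.lower()
    wide = wide.pivot_table(
        index=["dyad_id", "day"],
        columns="role",
        values=[c for c in panel.columns if c not in ("dyad_id", "day", "role")],
        aggfunc="first",
    )
    wide.columns = [f"{var}_{role}" for var, role in wide.columns]
    wide = wide.reset_index()

    need = list(spec.within.indicators)
    missing_cols = [c for c in need if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"panel lacks required columns: {missing_cols}")
    wide = wide.dropna(subset=need)

    distal = [c for c in spec.between.indicators if c not in spec.within.indicators]
    post_lookup: dict[object, np.ndarray] = {}
    if distal:
        if post is None:
            raise ValueError(f"model requires post-diary variables {distal}")
        pt = post.set_index("dyad_id")
        cols = []
        for name in distal:
            if name == "adherent":
                cols.append((pt["adherence_days"] > 28).astype(float))
            else:
                cols.append(pt[DISTAL_MAP.get(name, name)].astype(float))
        zmat = pd.concat(cols, axis=1)
        post_lookup = {i: zmat.loc[i].to_numpy() for i in zmat.index}

    clusters: list[ClusterData] = []
    dropped = 0
    for dyad_id, grp in wide.groupby("dyad_id"):
        Y = grp[need].to_numpy(dtype=float)
        if Y.shape[0] == 0:
            dropped += 1
            continue
        z = post_lookup.get(dyad_id, np.empty(0)) if distal else np.empty(0)
        if distal and (dyad_id not in post_lookup or np.any(np.isnan(z))):
            dropped += 1
            continue
        clusters.append(ClusterData(dyad_id=dyad_id, Y=Y, z=np.asarray(z, float)))
    if dropped:
        logger.info("dropped %d dyads with no usable observations", dropped)
    return clusters


class _Prepared:
    """Sufficient statistics for the structured likelihood.

    Clusters are grouped by observed day count n_j; within a group the
    quadratic form only needs the group's SSCP of the [cluster mean,
    between-only values] rows, so the per-theta cost is independent of
    the number of clusters.
    """

    def __init__(self, data: list[ClusterData], p_w: int, p_z: int):
        if not data:
            raise ValueError("no clusters")
        self.p_w, self.p_z = p_w, p_z
        self.p_b = p_w + p_z
        self.S_dev_total = np.zeros((p_w, p_w))
        self.N_dev = 0
        groups: dict[int, list[np.ndarray]] = {}
        for cd in data:
            n = cd.n_j
            ybar = cd.Y.mean(axis=0)
            dev = cd.Y - ybar
            self.S_dev_total += dev.T @ dev
            self.N_dev += n - 1
            groups.setdefault(n, []).append(np.concatenate([ybar, cd.z]))
        self.groups = {n: np.vstack(rows) for n, rows in sorted(groups.items())}
        self.n_clusters = len(data)
        self.n_obs = sum(cd.n_j for cd in data)
        # stacked per-group sufficient statistics
        self.n_arr = np.array(sorted(self.groups), dtype=float)
        self.J_arr = np.array([self.groups[int(n)].shape[0] for n in self.n_arr], float)
        self.sum_rows = np.stack([self.groups[int(n)].sum(axis=0) for n in self.n_arr])
        self.sscp = np.stack([M.T @ M for M in (self.groups[int(n)] for n in self.n_arr)])
        # constant: 2pi terms and the mean-component Jacobian p_w*log(n)
        self.const = -0.5 * (
            (self.N_dev * p_w + float(self.J_arr.sum()) * self.p_b) * LOG2PI
            + p_w * float(self.J_arr @ np.log(self.n_arr))
        )


def _loglik_moments(prep: _Prepared, Sw, Sb, mu) -> float:
    """Structured log-likelihood given moment matrices; -inf if non-PD."""
    p_w, p_b = prep.p_w, prep.p_b
    try:
        cw = np.linalg.cholesky(Sw)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_w = 2.0 * np.sum(np.log(np.diag(cw)))
    iw = cho_solve((cw, True), np.eye(p_w))
    ll = prep.const - 0.5 * (
        prep.N_dev * logdet_w + float(np.sum(iw * prep.S_dev_total))
    )
    # mean components, batched over distinct cluster sizes:
    # V_g = Sigma_B + Sigma_W / n_g on the diary block
    G = len(prep.n_arr)
    V = np.broadcast_to(Sb, (G, p_b, p_b)).copy()
    V[:, :p_w, :p_w] += Sw[None, :, :] / prep.n_arr[:, None, None]
    try:
        cv = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diagonal(cv, axis1=1, axis2=2)), axis=1)
    Vinv = np.linalg.inv(V)
    # W_g = sum_j (m_j - mu)(m_j - mu)' from the group's SSCP
    mm = np.outer(mu, mu)
    W = (
        prep.sscp
        - prep.sum_rows[:, :, None] * mu[None, None, :]
        - mu[None, :, None] * prep.sum_rows[:, None, :]
        + prep.J_arr[:, None, None] * mm[None, :, :]
    )
    quad = np.einsum("gij,gij->g", Vinv, W)
    ll -= 0.5 * float(prep.J_arr @ logdet_v + quad.sum())
    return ll


def _loglik_grad_moments(prep: _Prepared, Sw, Sb, mu):
    """Log-likelihood and its gradient w.r.t. (Sigma_W, Sigma_B, mu).

    Same decomposition as :func:`_loglik_moments`; the moment-space
    gradients are the standard Wishart/normal score matrices
    d ll / d Sigma = -(1/2)(m Sigma^{-1} - Sigma^{-1} S Sigma^{-1}).
    Returns (ll, Gw, Gb, gmu) or (-inf, None, None, None) if non-PD.
    """
    p_w, p_b = prep.p_w, prep.p_b
    try:
        cw = np.linalg.cholesky(Sw)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    logdet_w = 2.0 * np.sum(np.log(np.diag(cw)))
    Iw = cho_solve((cw, True), np.eye(p_w))
    ll = prep.const - 0.5 * (
        prep.N_dev * logdet_w + float(np.sum(Iw * prep.S_dev_total))
    )
    Gw = -0.5 * (prep.N_dev * Iw - Iw @ prep.S_dev_total @ Iw)

    G = len(prep.n_arr)
    V = np.broadcast_to(Sb, (G, p_b, p_b)).copy()
    V[:, :p_w, :p_w] += Sw[None, :, :] / prep.n_arr[:, None, None]
    try:
        cv = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, None
    logdet_v = 2.0 * np.sum(np.log(np.diagonal(cv, axis1=1, axis2=2)), axis=1)
    Vinv = np.linalg.inv(V)
    mm = np.outer(mu, mu)
    W = (
        prep.sscp
        - prep.sum_rows[:, :, None] * mu[None, None, :]
        - mu[None, :, None] * prep.sum_rows[:, None, :]
        + prep.J_arr[:, None, None] * mm[None, :, :]
    )
    quad = np.einsum("gij,gij->g", Vinv, W)
    ll -= 0.5 * float(prep.J_arr @ logdet_v + quad.sum())

    dV = -0.5 * (prep.J_arr[:, None, None] * Vinv - Vinv @ W @ Vinv)
    Gb = dV.sum(axis=0)
    Gw += np.einsum("gij,g->ij", dV[:, :p_w, :p_w], 1.0 / prep.n_arr)
    resid = prep.sum_rows - prep.J_arr[:, None] * mu[None, :]
    gmu = np.einsum("gij,gj->i", Vinv, resid)
    return ll, 0.5 * (Gw + Gw.T), 0.5 * (Gb + Gb.T), gmu


def loglikelihood(spec: CFMSpec, theta: ParameterSet, data: list[ClusterData]) -> float:
    """Two-level log-likelihood of ``data`` at ``theta`` (structured path).

    Returns ``-inf`` (optimizer-safe) when an implied component
    covariance is not positive definite.
    """
    prep = _Prepared(data, spec.within.p, spec.between.p - spec.within.p)
    mom = implied_moments(spec, theta)
    return _loglik_moments(prep, mom.sigma_within, mom.sigma_between, mom.mu)


def dense_loglikelihood(spec: CFMSpec, theta: ParameterSet, data: list[ClusterData]) -> float:
    """Brute-force oracle: materialize each cluster's full covariance.

    Stacks the n_j day-vectors and the between-only variables into one
    multivariate normal of dimension ``n_j * p_w + p_z``.  Quadratic in
    memory — test use only.
    """
    from scipy.stats import multivariate_normal

    mom = implied_moments(spec, theta)
    Sw, Sb, mu = mom.sigma_within, mom.sigma_between, mom.mu
    p_w = spec.within.p
    p_z = spec.between.p - p_w
    ll = 0.0
    for cd in data:
        n = cd.n_j
        dim = n * p_w + p_z
        V = np.zeros((dim, dim))
        for t in range(n):
            for s in range(n):
                blk = Sb[:p_w, :p_w].copy()
                if t == s:
                    blk += Sw
                V[t * p_w : (t + 1) * p_w, s * p_w : (s + 1) * p_w] = blk
        if p_z:
            for t in range(n):
                V[t * p_w : (t + 1) * p_w, n * p_w :] = Sb[:p_w, p_w:]
                V[n * p_w :, t * p_w : (t + 1) * p_w] = Sb[p_w:, :p_w]
            V[n * p_w :, n * p_w :] = Sb[p_w:, p_w:]
        m = np.concatenate([np.tile(mu[:p_w], n), mu[p_w:]])
        y = np.concatenate([cd.Y.ravel(), cd.z])
        ll += float(multivariate_normal.logpdf(y, mean=m, cov=V))
    return ll


def pooled_moments(data: list[ClusterData]):
    """Pooled-within and between sample moment matrices (diary indicators).

    ``S_PW = sum_j sum_t (y_jt - ybar_j)(y_jt - ybar_j)' / (N - J)`` and
    ``S_B = sum_j n_j (ybar_j - ybar)(ybar_j - ybar)' / (J - 1)``, the
    conventional between-groups matrix.  Requires >= 2 clusters and more
    total days than clusters.
    """
    J = len(data)
    if J < 2:
        raise ValueError("between moments undefined with a single cluster")
    N = sum(cd.n_j for cd in data)
    if N <= J:
        raise ValueError("need more total observed days than clusters")
    p = data[0].Y.shape[1]
    S_pw = np.zeros((p, p))
    grand = sum(cd.Y.sum(axis=0) for cd in data) / N
    S_b = np.zeros((p, p))
    for cd in data:
        ybar = cd.Y.mean(axis=0)
        dev = cd.Y - ybar
        S_pw += dev.T @ dev
        d = ybar - grand
        S_b += cd.n_j * np.outer(d, d)
    return S_pw / (N - J), S_b / (J - 1), np.array([cd.n_j for cd in data])


# ---------------------------------------------------------------------------
# compiled parameter map and optimizers
# ---------------------------------------------------------------------------


class _Compiled:
    """Precomputed index arrays for fast theta-vector -> moments assembly."""

    def __init__(self, spec: CFMSpec):
        self.spec = spec
        names = spec.param_names
        self.names = names
        self.is_var = np.array(
            [n.startswith("psi(") or n.startswith("theta(") for n in names]
        )
        self.levels = []
        i = 0
        for level in ("within", "between"):
            ls = spec.level(level)
            eta_ix = {e: k for k, e in enumerate(ls.etas)}
            ind_ix = {v: k for k, v in enumerate(ls.indicators)}
            lam = np.zeros((ls.p, ls.q))
            for ind, eta in ls.loadings:
                lam[ind_ix[ind], eta_ix[eta]] = 1.0
            dst = np.array([eta_ix[d] for _, d in ls.paths], dtype=int)
            src = np.array([eta_ix[s] for s, _ in ls.paths], dtype=int)
            th_pos = np.array([ind_ix[v] for v in ls.theta_free], dtype=int)
            sl_paths = slice(i, i + len(ls.paths)); i += len(ls.paths)
            sl_psi = slice(i, i + ls.q); i += ls.q
            sl_th = slice(i, i + len(ls.theta_free)); i += len(ls.theta_free)
            self.levels.append((ls, lam, dst, src, th_pos, sl_paths, sl_psi, sl_th))
        self.sl_mu = slice(i, i + spec.between.p)

    def moments(self, nat: np.ndarray):
        out = []
        for ls, lam, dst, src, th_pos, sl_p, sl_psi, sl_th in self.levels:
            B = np.zeros((ls.q, ls.q))
            B[dst, src] = nat[sl_p]
            A = lam @ np.linalg.solve(np.eye(ls.q) - B, np.eye(ls.q))
            sigma = (A * nat[sl_psi]) @ A.T
            sigma[th_pos, th_pos] += nat[sl_th]
            out.append(0.5 * (sigma + sigma.T))
        return out[0], out[1], nat[self.sl_mu]

    def value_and_grad(self, nat: np.ndarray, prep: _Prepared):
        """Log-likelihood and gradient w.r.t. the natural parameter vector.

        Chains the moment-space score through the structural form:
        with A = Lambda (I-B)^{-1} and score matrix G = d ll / d Sigma,
        d ll/d psi_k = (A' G A)_kk, d ll/d theta_i = G_ii, and
        d ll/d B_{dst,src} = 2 [C_eta (Lambda' G Lambda) (I-B)^{-1}]_{src,dst}.
        """
        cache = []
        sigmas = []
        for ls, lam, dst, src, th_pos, sl_p, sl_psi, sl_th in self.levels:
            B = np.zeros((ls.q, ls.q))
            B[dst, src] = nat[sl_p]
            K = np.linalg.solve(np.eye(ls.q) - B, np.eye(ls.q))
            A = lam @ K
            psi = nat[sl_psi]
            sigma = (A * psi) @ A.T
            sigma[th_pos, th_pos] += nat[sl_th]
            sigmas.append(0.5 * (sigma + sigma.T))
            cache.append((lam, K, A, psi, dst, src, th_pos, sl_p, sl_psi, sl_th))
        mu = nat[self.sl_mu]
        ll, Gw, Gb, gmu = _loglik_grad_moments(prep, sigmas[0], sigmas[1], mu)
        if not np.isfinite(ll):
            return -np.inf, None
        grad = np.empty(len(self.names))
        for (lam, K, A, psi, dst, src, th_pos, sl_p, sl_psi, sl_th), G in zip(
            cache, (Gw, Gb)
        ):
            AGA = A.T @ G @ A
            grad[sl_psi] = np.diag(AGA)
            grad[sl_th] = G[th_pos, th_pos]
            X = ((K * psi) @ K.T) @ (lam.T @ G @ lam) @ K
            grad[sl_p] = 2.0 * X[src, dst]
        grad[self.sl_mu] = gmu
        return ll, grad


def _start_vector(spec: CFMSpec, prep: _Prepared, comp: _Compiled) -> np.ndarray:
    """Method-of-moments start values.

    Grand means for mu.  Per level, the latent covariance matrix is
    approximated from indicator (co)variances — the cross-indicator
    covariance identifies a common-fate latent's variance when both
    loadings are fixed to 1 — then structural paths are solved from the
    normal equations among the approximate latent moments, disturbances
    and residuals by subtraction (floored to stay interior).
    """
    p_w = prep.p_w
    S_pw = prep.S_dev_total / max(prep.N_dev, 1)
    M_all = np.vstack(list(prep.groups.values()))
    C_all = np.atleast_2d(np.cov(M_all, rowvar=False, ddof=1))
    mean_inv_n = float(np.mean(1.0 / np.repeat(prep.n_arr, prep.J_arr.astype(int))))
    Sb_hat = C_all.copy()
    Sb_hat[:p_w, :p_w] -= S_pw * mean_inv_n
    mu0 = M_all.mean(axis=0)

    x = np.zeros(len(comp.names))
    for (ls, lam, dst, src, th_pos, sl_p, sl_psi, sl_th), S in zip(
        comp.levels, (S_pw, Sb_hat)
    ):
        ind_ix = {v: k for k, v in enumerate(ls.indicators)}
        ind_of_eta: dict[str, list[int]] = {}
        for ind, eta in ls.loadings:
            ind_of_eta.setdefault(eta, []).append(ind_ix[ind])
        q = ls.q
        floor = max(1e-4, 0.02 * float(np.mean(np.abs(np.diag(S)))))
        # approximate latent moments from indicator moments
        C = np.zeros((q, q))
        for k, ek in enumerate(ls.etas):
            for l in range(k, q):
                el = ls.etas[l]
                vals = [
                    S[i, j]
                    for i in ind_of_eta[ek]
                    for j in ind_of_eta[el]
                    if not (k == l and i == j and len(ind_of_eta[ek]) > 1)
                ]
                C[k, l] = C[l, k] = float(np.mean(vals))
        w, Q = np.linalg.eigh(C)
        C = Q @ np.diag(np.maximum(w, floor)) @ Q.T

        parents: dict[int, list[int]] = {}
        eta_ix = {e: k for k, e in enumerate(ls.etas)}
        for s_name, d_name in ls.paths:
            parents.setdefault(eta_ix[d_name], []).append(eta_ix[s_name])
        paths0 = np.zeros(len(ls.paths))
        psi0 = np.empty(q)
        for k in range(q):
            if k not in parents:
                psi0[k] = max(C[k, k], floor)
            else:
                P = parents[k]
                coef = np.linalg.solve(C[np.ix_(P, P)] + 1e-8 * np.eye(len(P)), C[P, k])
                psi0[k] = max(C[k, k] - coef @ C[np.ix_(P, P)] @ coef, 0.05 * C[k, k], floor)
                for m, (s_name, d_name) in enumerate(ls.paths):
                    if eta_ix[d_name] == k:
                        paths0[m] = coef[P.index(eta_ix[s_name])]
        th0 = np.array(
            [
                max(S[ind_ix[v], ind_ix[v]] - C[eta_ix[dict(ls.loadings)[v]],
                                                eta_ix[dict(ls.loadings)[v]]],
                    0.05 * S[ind_ix[v], ind_ix[v]], floor)
                for v in ls.theta_free
            ]
        )
        x[sl_p] = paths0
        x[sl_psi] = np.log(psi0)
        x[sl_th] = np.log(th0)
    x[comp.sl_mu] = mu0
    return x


def _maximize(obj, x0, max_iter, gtol, track=False, ftol=1e-12, jac=False):
    trace: list[float] = []

    cb = None
    if track:
        def cb(xk):  # noqa: E306
            v = obj(xk)
            trace.append(-(v[0] if jac else v))

    res = minimize(
        obj,
        x0,
        jac=jac if jac else None,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "maxfun": 10 * max_iter * max(len(x0), 10),
                 "ftol": ftol, "gtol": gtol},
    )
    return res, trace


def _hessian_from_grad(gradf, x, rel=1e-5):
    """Central-difference Hessian from an analytic gradient."""
    k = len(x)
    h = rel * (1.0 + np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[:, i] = (gradf(x + ei) - gradf(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _fit_saturated(prep: _Prepared, max_iter=2000):
    """ML under the unrestricted two-level moment model (chol-parameterized)."""
    p_w, p_b = prep.p_w, prep.p_b
    S_pw = prep.S_dev_total / max(prep.N_dev, 1)
    M_all = np.vstack(list(prep.groups.values()))
    C = np.cov(M_all, rowvar=False, ddof=1).reshape(p_b, p_b)
    mean_inv_n = float(np.mean([1.0 / n for n, M in prep.groups.items() for _ in range(M.shape[0])]))
    Sb0 = C.copy()
    Sb0[:p_w, :p_w] -= S_pw * mean_inv_n
    w, Q = np.linalg.eigh(0.5 * (Sb0 + Sb0.T))
    Sb0 = Q @ np.diag(np.maximum(w, 1e-3 * np.max(np.abs(w)))) @ Q.T

    trilw = np.tril_indices(p_w)
    trilb = np.tril_indices(p_b)

    def pack(Sw, Sb, mu):
        Lw = np.linalg.cholesky(Sw); Lb = np.linalg.cholesky(Sb)
        xw = Lw[trilw].copy(); xb = Lb[trilb].copy()
        dw = np.where(trilw[0] == trilw[1])[0]
        db = np.where(trilb[0] == trilb[1])[0]
        xw[dw] = np.log(xw[dw]); xb[db] = np.log(xb[db])
        return np.concatenate([xw, xb, mu])

    nw, nb = len(trilw[0]), len(trilb[0])
    dw = np.where(trilw[0] == trilw[1])[0]
    db = np.where(trilb[0] == trilb[1])[0]

    def unpack(x):
        xw = x[:nw].copy(); xb = x[nw : nw + nb].copy(); mu = x[nw + nb :]
        xw[dw] = np.exp(xw[dw]); xb[db] = np.exp(xb[db])
        Lw = np.zeros((p_w, p_w)); Lw[trilw] = xw
        Lb = np.zeros((p_b, p_b)); Lb[trilb] = xb
        return Lw @ Lw.T, Lb @ Lb.T, mu

    def obj(x):
        Sw, Sb, mu = unpack(x)
        ll, Gw, Gb, gmu = _loglik_grad_moments(prep, Sw, Sb, mu)
        if not np.isfinite(ll):
            return _BIG, np.zeros_like(x)
        Lw = np.linalg.cholesky(Sw)
        Lb = np.linalg.cholesky(Sb)
        dLw = (2.0 * Gw @ Lw)[trilw]
        dLb = (2.0 * Gb @ Lb)[trilb]
        dLw[dw] *= Lw[trilw][dw]  # log-diagonal chain
        dLb[db] *= Lb[trilb][db]
        return -ll, -np.concatenate([dLw, dLb, gmu])

    x0 = pack(_make_pd(S_pw), Sb0, M_all.mean(axis=0))
    res, _ = _maximize(obj, x0, max_iter, 1e-8, jac=True)
    Sw, Sb, mu = unpack(res.x)
    return -res.fun, Sw, Sb, mu, res.success


def _make_pd(S, floor=1e-8):
    w, Q = np.linalg.eigh(0.5 * (S + S.T))
    return Q @ np.diag(np.maximum(w, floor * max(np.max(w), 1.0))) @ Q.T


def _fit_baseline(prep: _Prepared, max_iter=2000):
    """Independence model: free variances and means, zero covariances."""
    p_w, p_b = prep.p_w, prep.p_b
    S_pw = prep.S_dev_total / max(prep.N_dev, 1)
    M_all = np.vstack(list(prep.groups.values()))
    vb0 = np.maximum(np.var(M_all, axis=0, ddof=1), 1e-3)

    def obj(x):
        vw = np.exp(x[:p_w])
        vb = np.exp(x[p_w : p_w + p_b])
        ll, Gw, Gb, gmu = _loglik_grad_moments(prep, np.diag(vw), np.diag(vb), x[p_w + p_b :])
        if not np.isfinite(ll):
            return _BIG, np.zeros_like(x)
        return -ll, -np.concatenate([np.diag(Gw) * vw, np.diag(Gb) * vb, gmu])

    x0 = np.concatenate(
        [np.log(np.maximum(np.diag(S_pw), 1e-3) * 0.5),
         np.log(vb0 * 0.5), M_all.mean(axis=0)]
    )
    res, _ = _maximize(obj, x0, max_iter, 1e-8, jac=True)
    n_free = p_w + 2 * p_b
    return -res.fun, n_free, res.success


def fit_indices(
    loglik_m: float,
    df_m: int,
    loglik_sat: float,
    loglik_base: float,
    df_base: int,
    n_obs: int,
    S_PW: np.ndarray | None = None,
    S_B: np.ndarray | None = None,
    implied=None,
) -> dict[str, float | None]:
    """Chi-square-based and residual-based fit indices.

    ``chi2 = 2 (l_sat - l_m)``; CFI/TLI against the independence
    baseline; RMSEA with N = total within-level observations; SRMR per
    level from standardized residuals of the supplied sample moments
    against the model-implied ones.  With ``df_m = 0`` RMSEA and TLI are
    undefined and reported as None.
    """
    chi2_m = max(2.0 * (loglik_sat - loglik_m), 0.0)
    chi2_b = max(2.0 * (loglik_sat - loglik_base), 0.0)
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_base, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else min(max(1.0 - num / den, 0.0), 1.0)
    if df_m > 0:
        rmsea = math.sqrt(num / (df_m * n_obs))
        if df_base > 0 and chi2_b / df_base > 1.0:
            tli = ((chi2_b / df_base) - (chi2_m / df_m)) / ((chi2_b / df_base) - 1.0)
            tli = min(max(tli, 0.0), 1.0)
        else:
            tli = 1.0
    else:
        rmsea = None
        tli = None

    def _srmr(S, Sigma):
        d = np.sqrt(np.diag(S))
        resid = (S - Sigma) / np.outer(d, d)
        ix = np.tril_indices(S.shape[0])
        return float(np.sqrt(np.mean(resid[ix] ** 2)))

    srmr_w = _srmr(S_PW, implied.sigma_within) if S_PW is not None and implied else None
    srmr_b = _srmr(S_B, implied.sigma_between) if S_B is not None and implied else None
    return {
        "chi2": chi2_m,
        "cfi": cfi,
        "tli": tli,
        "rmsea": rmsea,
        "srmr_within": srmr_w,
        "srmr_between": srmr_b,
    }


def fit(spec: CFMSpec, data: list[ClusterData], config: FitConfig | None = None) -> FitResult:
    """Fit the model by full-information maximum likelihood.

    Deterministic: same data and config give identical estimates.
    Boundary variance estimates and non-convergence are flagged on the
    result (and logged), never silently discarded.
    """
    if not data:
        raise ValueError("no data")
    if spec.df < 0:
        raise ValueError(f"model not identified: df = {spec.df} < 0")
    config = config or FitConfig()
    prep = _Prepared(data, spec.within.p, spec.between.p - spec.within.p)
    comp = _Compiled(spec)
    is_var = comp.is_var

    def nat_of(x):
        v = x.copy()
        v[is_var] = np.exp(v[is_var])
        return v

    def obj(x):
        nat = nat_of(x)
        ll, g = comp.value_and_grad(nat, prep)
        if not np.isfinite(ll):
            return _BIG, np.zeros_like(x)
        return -ll, -g * np.where(is_var, nat, 1.0)

    x0 = _start_vector(spec, prep, comp)
    res, trace = _maximize(
        obj, x0, config.max_iter, config.gtol, track=config.track_trace,
        ftol=config.ftol, jac=True,
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)
    nat = nat_of(res.x)
    theta_hat = ParameterSet.from_vector(spec, nat)
    loglik = -float(res.fun)

    tiny = nat[is_var] < 1e-8
    if np.any(tiny):
        logger.warning(
            "%d variance estimates at/near the zero boundary", int(np.sum(tiny))
        )

    se: dict[str, float] = {}
    param_cov = None
    if config.compute_se:
        H = _hessian_from_grad(lambda x: obj(x)[1], res.x, rel=config.reltol_hessian)
        cov_x = np.linalg.pinv(0.5 * (H + H.T))
        jac = np.where(is_var, nat, 1.0)
        param_cov = cov_x * np.outer(jac, jac)
        diag = np.diag(param_cov)
        se = {
            n: (math.sqrt(d) if d > 0 else float("nan"))
            for n, d in zip(comp.names, diag)
        }
        if np.any(diag <= 0):
            logger.warning("observed information not positive definite at optimum")

    beta = standardize(spec, theta_hat)

    loglik_sat = loglik_base = chi2 = None
    indices: dict[str, float | None] = {}
    if config.compute_fit_indices and not spec.suppress_fit_indices:
        loglik_sat, Sw_sat, Sb_sat, _, ok_sat = _fit_saturated(prep)
        loglik_base, n_free_base, ok_base = _fit_baseline(prep)
        df_base = spec.n_moments - n_free_base
        mom = implied_moments(spec, theta_hat)
        indices = fit_indices(
            loglik, spec.df, loglik_sat, loglik_base, df_base,
            prep.n_obs, Sw_sat, Sb_sat, mom,
        )
        chi2 = indices.pop("chi2")
        converged = converged and ok_sat and ok_base

    return FitResult(
        theta_hat=theta_hat,
        se=se,
        beta=beta,
        loglik=loglik,
        loglik_saturated=loglik_sat,
        loglik_baseline=loglik_base,
        chi2=chi2,
        df=spec.df,
        fit=indices,
        converged=converged,
        n_clusters=prep.n_clusters,
        n_obs=prep.n_obs,
        param_names=comp.names,
        param_cov=param_cov,
        trace=trace,
        message=str(res.message),
    )
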