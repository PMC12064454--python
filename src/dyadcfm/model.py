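"""Two-level common fate mediation model specifications and covariance algebra.

A common fate model treats a couple-level construct (e.g. we-disease
appraisal, WDA) as a latent variable measured by both partners' reports.
In the diary design the same measurement structure repeats at two levels:

* **within** (level 1): day-to-day fluctuation of the shared construct
  around the couple's own average;
* **between** (level 2): stable differences between couples in their
  diary-period averages, plus any one-off post-diary outcomes, which
  exist only at this level.

At each level the mediation chain is ``WDA_shared -> CDC_shared ->
outcome`` with a direct ``WDA_shared -> outcome`` path (a 1-1-1 mediation
when the outcome is daily, 1-1-2 when it is post-diary).

The implied covariance per level follows the standard structural form

    Sigma = Lambda (I - B)^{-1} Psi (I - B)^{-T} Lambda^T + Theta

with Lambda the (fixed) loading matrix, B the structural coefficients
among latents/outcome blocks, Psi the diagonal latent/disturbance
covariance and Theta the diagonal indicator residual covariance.

Identification: both partners' loadings on each common-fate latent are
fixed to 1 and the latent variance is free.  Unequal standardized
loadings then arise from unequal residual variances, matching the usual
common fate parameterization for distinguishable dyads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LevelSpec",
    "CFMSpec",
    "ParameterSet",
    "ImpliedMoments",
    "OUTCOME_MODELS",
    "build_spec",
    "implied_moments",
    "standardize",
]

#: the six fitted models: which outcome closes the mediation chain
OUTCOME_MODELS = (
    "daily_qol",
    "post_qol",
    "post_adherence",
    "post_prep",
    "daily_rs",
    "post_rs",
)

ROLES = ("plwh", "partner")


@dataclass(frozen=True)
class LevelSpec:
    """Measurement and structural layout of one level of the model.

    ``loadings`` are (indicator, eta) pairs all fixed at 1 (common fate
    identification); ``paths`` are free (source eta, target eta) edges;
    every eta has a free variance/disturbance in Psi; indicators listed
    in ``theta_free`` have a free residual variance, all others have
    their residual fixed to 0 (single-indicator observed outcomes).
    """

    indicators: tuple[str, ...]
    etas: tuple[str, ...]
    loadings: tuple[tuple[str, str], ...]
    paths: tuple[tuple[str, str], ...]
    theta_free: tuple[str, ...]

    def __post_init__(self) -> None:
        loaded = [ind for ind, _ in self.loadings]
        if sorted(loaded) != sorted(self.indicators):
            raise ValueError("each indicator must load on exactly one eta")
        for ind, eta in self.loadings:
            if eta not in self.etas:
                raise ValueError(f"loading on unknown eta {eta!r}")
        # structural graph must be acyclic
        order = {e: i for i, e in enumerate(self.etas)}
        for src, dst in self.paths:
            if order[src] >= order[dst]:
                raise ValueError(f"path {src}->{dst} violates topological order")

    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def q(self) -> int:
        return len(self.etas)


@dataclass(frozen=True)
class CFMSpec:
    """A two-level common fate mediation model specification."""

    outcome_model: str
    within: LevelSpec
    between: LevelSpec
    covariates: tuple[str, ...] = ()
    suppress_fit_indices: bool = False

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free-parameter names in canonical vector order.

        Order: within paths, within Psi, within Theta, between paths,
        between Psi, between Theta, means (between indicators).
        """
        names: list[str] = []
        for level, ls in (("within", self.within), ("between", self.between)):
            names += [f"{s}->{d}@{level}" for s, d in ls.paths]
            names += [f"psi({e})@{level}" for e in ls.etas]
            names += [f"theta({i})@{level}" for i in ls.theta_free]
        names += [f"mu({i})" for i in self.between.indicators]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def n_moments(self) -> int:
        pw, pb = self.within.p, self.between.p
        return pw * (pw + 1) // 2 + pb * (pb + 1) // 2 + pb

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def level(self, which: str) -> LevelSpec:
        if which == "within":
            return self.within
        if which == "between":
            return self.between
        raise ValueError(f"unknown level {which!r}")

    def to_json(self) -> str:
        doc = {
            "outcome_model": self.outcome_model,
            "covariates": list(self.covariates),
            "suppress_fit_indices": self.suppress_fit_indices,
            "levels": {
                lvl: {
                    "indicators": list(ls.indicators),
                    "etas": list(ls.etas),
                    "loadings": [list(t) for t in ls.loadings],
                    "paths": [list(t) for t in ls.paths],
                    "theta_free": list(ls.theta_free),
                }
                for lvl, ls in (("within", self.within), ("between", self.between))
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CFMSpec":
        doc = json.loads(text)

        def _ls(d: dict) -> LevelSpec:
            return LevelSpec(
                indicators=tuple(d["indicators"]),
                etas=tuple(d["etas"]),
                loadings=tuple(tuple(t) for t in d["loadings"]),
                paths=tuple(tuple(t) for t in d["paths"]),
                theta_free=tuple(d["theta_free"]),
            )

        return cls(
            outcome_model=doc["outcome_model"],
            within=_ls(doc["levels"]["within"]),
            between=_ls(doc["levels"]["between"]),
            covariates=tuple(doc.get("covariates", ())),
            suppress_fit_indices=bool(doc.get("suppress_fit_indices", False)),
        )


@dataclass
class ParameterSet:
    """Free-parameter values for a :class:`CFMSpec`, keyed by name.

    Values live on the natural scale (variances positive).  Fixed
    parameters (loadings of 1, residuals of 0) are implied by the spec
    and never appear here.
    """

    spec: CFMSpec
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.spec.param_names) - set(self.values)
        extra = set(self.values) - set(self.spec.param_names)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)[:5]} ...")
        if extra:
            raise ValueError(f"unknown parameters: {sorted(extra)[:5]} ...")

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.spec.param_names])

    @classmethod
    def from_vector(cls, spec: CFMSpec, vec: np.ndarray) -> "ParameterSet":
        names = spec.param_names
        if len(vec) != len(names):
            raise ValueError("vector length mismatch")
        return cls(spec, dict(zip(names, map(float, vec))))

    def matrices(self, level: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (Lambda, B, Psi, Theta) for one level."""
        ls = self.spec.level(level)
        ind_ix = {v: i for i, v in enumerate(ls.indicators)}
        eta_ix = {v: i for i, v in enumerate(ls.etas)}
        lam = np.zeros((ls.p, ls.q))
        for ind, eta in ls.loadings:
            lam[ind_ix[ind], eta_ix[eta]] = 1.0
        B = np.zeros((ls.q, ls.q))
        for src, dst in ls.paths:
            B[eta_ix[dst], eta_ix[src]] = self.values[f"{src}->{dst}@{level}"]
        psi = np.diag([self.values[f"psi({e})@{level}"] for e in ls.etas])
        theta = np.zeros((ls.p, ls.p))
        for ind in ls.theta_free:
            theta[ind_ix[ind], ind_ix[ind]] = self.values[f"theta({ind})@{level}"]
        return lam, B, psi, theta

    def mu(self) -> np.ndarray:
        return np.array(
            [self.values[f"mu({i})"] for i in self.spec.between.indicators]
        )


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied covariance per level and mean vector."""

    sigma_within: np.ndarray
    sigma_between: np.ndarray
    mu: np.ndarray


def _common_fate_block(var: str) -> tuple[list[tuple[str, str]], list[str]]:
    """Loadings and free-residual indicators for one common-fate latent."""
    eta = var.upper()
    inds = [f"{var}_{r}" for r in ROLES]
    return [(i, eta) for i in inds], inds


def _base_level() -> dict:
    """WDA_shared -> CDC_shared measurement core shared by every model."""
    load_w, free_w = _common_fate_block("wda")
    load_c, free_c = _common_fate_block("cdc")
    return {
        "indicators": [f"{v}_{r}" for v in ("wda", "cdc") for r in ROLES],
        "etas": ["WDA", "CDC"],
        "loadings": load_w + load_c,
        "paths": [("WDA", "CDC")],
        "theta_free": free_w + free_c,
    }


def _add_observed_outcome(d: dict, eta: str, indicator: str) -> None:
    """Attach a single-indicator observed outcome (residual fixed to 0)."""
    d["etas"].append(eta)
    d["indicators"].append(indicator)
    d["loadings"].append((indicator, eta))
    d["paths"] += [("WDA", eta), ("CDC", eta)]


def _add_common_fate_outcome(d: dict, var: str) -> None:
    eta = var.upper()
    loads, free = _common_fate_block(var)
    d["etas"].append(eta)
    d["indicators"] += [i for i, _ in loads]
    d["loadings"] += loads
    d["theta_free"] += free
    d["paths"] += [("WDA", eta), ("CDC", eta)]


def build_spec(outcome_model: str, covariates: tuple[str, ...] = ()) -> CFMSpec:
    """Construct the two-level layout for one of the six outcome models.

    Daily outcomes (quality of life, relationship satisfaction) appear at
    both levels; post-diary outcomes attach at the between level only.
    Quality of life is a non-common-fate construct (two partner-specific
    observed outcomes); relationship satisfaction is a common-fate latent
    with one indicator per partner.

    Optional ``covariates`` are dyad-level observed exogenous variables
    regressed on every between-level endogenous variable.
    """
    if outcome_model not in OUTCOME_MODELS:
        raise ValueError(
            f"unknown outcome model {outcome_model!r}; valid: {', '.join(OUTCOME_MODELS)}"
        )
    within = _base_level()
    between = _base_level()
    suppress = False

    if outcome_model == "daily_qol":
        for d in (within, between):
            _add_observed_outcome(d, "QOL_PLWH", "qol_plwh")
            _add_observed_outcome(d, "QOL_PARTNER", "qol_partner")
    elif outcome_model == "daily_rs":
        for d in (within, between):
            _add_common_fate_outcome(d, "rs")
    elif outcome_model == "post_qol":
        _add_observed_outcome(between, "POST_QOL_PLWH", "post_qol_plwh")
        _add_observed_outcome(between, "POST_QOL_PARTNER", "post_qol_partner")
    elif outcome_model == "post_adherence":
        # 0/1 adherent indicator treated as a continuous between-level
        # outcome; chi-square-based fit indices are suppressed.
        _add_observed_outcome(between, "ADH", "adherent")
        suppress = True
    elif outcome_model == "post_prep":
        _add_observed_outcome(between, "ATT", "post_prep")
    elif outcome_model == "post_rs":
        _add_common_fate_outcome(between, "post_rs")

    if covariates:
        # exogenous dyad-level regressors: modeled as single-indicator
        # etas placed first in topological order, with free paths into
        # every endogenous between-level eta.
        endo = list(between["etas"])
        cov_etas = [c.upper() for c in covariates]
        between["etas"] = cov_etas + between["etas"]
        between["indicators"] = list(covariates) + between["indicators"]
        between["loadings"] = [
            (c, c.upper()) for c in covariates
        ] + between["loadings"]
        between["paths"] = [
            (c.upper(), e) for c in covariates for e in endo
        ] + between["paths"]

    def _freeze(d: dict) -> LevelSpec:
        return LevelSpec(
            indicators=tuple(d["indicators"]),
            etas=tuple(d["etas"]),
            loadings=tuple(d["loadings"]),
            paths=tuple(d["paths"]),
            theta_free=tuple(d["theta_free"]),
        )

    return CFMSpec(
        outcome_model=outcome_model,
        within=_freeze(within),
        between=_freeze(between),
        covariates=tuple(covariates),
        suppress_fit_indices=suppress,
    )


def _level_sigma(lam, B, psi, theta) -> np.ndarray:
    q = B.shape[0]
    IB = np.eye(q) - B
    A = lam @ np.linalg.solve(IB, np.eye(q))
    sigma = A @ psi @ A.T + theta
    return 0.5 * (sigma + sigma.T)


def implied_moments(spec: CFMSpec, theta: ParameterSet) -> ImpliedMoments:
    """Model-implied Sigma_W, Sigma_B and mean vector at ``theta``.

    Raises ``np.linalg.LinAlgError`` if (I - B) is singular at either
    level (cannot happen for acyclic B with a consistent ordering, but
    guarded for arbitrary parameter sets).
    """
    out = []
    for level in ("within", "between"):
        lam, B, psi, th = theta.matrices(level)
        if abs(np.linalg.det(np.eye(B.shape[0]) - B)) < 1e-300:
            raise np.linalg.LinAlgError("(I - B) is singular")
        out.append(_level_sigma(lam, B, psi, th))
    return ImpliedMoments(sigma_within=out[0], sigma_between=out[1], mu=theta.mu())


def eta_covariance(spec: CFMSpec, theta: ParameterSet, level: str) -> np.ndarray:
    """Model-implied covariance among the etas at one level."""
    _, B, psi, _ = theta.matrices(level)
    q = B.shape[0]
    IBinv = np.linalg.solve(np.eye(q) - B, np.eye(q))
    C = IBinv @ psi @ IBinv.T
    return 0.5 * (C + C.T)


def standardize(spec: CFMSpec, theta: ParameterSet) -> dict[str, float]:
    """Standardized solution: beta for every path, plus loadings.

    Each path coefficient b becomes ``beta = b * SD(source) / SD(target)``
    using model-implied latent SDs at the path's own level; fixed unit
    loadings become ``SD(eta) / SD(indicator)``, the level-specific
    standardized loading.  Raises ``ValueError`` on a zero implied
    variance.
    """
    mom = implied_moments(spec, theta)
    out: dict[str, float] = {}
    for level, sigma in (("within", mom.sigma_within), ("between", mom.sigma_between)):
        ls = spec.level(level)
        C = eta_covariance(spec, theta, level)
        sd_eta = np.sqrt(np.diag(C))
        sd_ind = np.sqrt(np.diag(sigma))
        if np.any(sd_eta <= 0) or np.any(sd_ind <= 0):
            raise ValueError(f"zero implied variance at {level} level")
        eta_ix = {e: i for i, e in enumerate(ls.etas)}
        ind_ix = {v: i for i, v in enumerate(ls.indicators)}
        for src, dst in ls.paths:
            b = theta.values[f"{src}->{dst}@{level}"]
            out[f"{src}->{dst}@{level}"] = b * sd_eta[eta_ix[src]] / sd_eta[eta_ix[dst]]
        for ind, eta in ls.loadings:
            out[f"lambda({ind}<-{eta})@{level}"] = (
                sd_eta[eta_ix[eta]] / sd_ind[ind_ix[ind]]
            )
    return out
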