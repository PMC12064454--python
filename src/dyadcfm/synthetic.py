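"""Synthetic dyadic daily-diary panels with two-level common-fate structure.

The generator is the common fate mediation model read forward.  For each
dyad j it draws the between-level shared latents (we-disease appraisal
WDA_B, then common dyadic coping CDC_B = a_B * WDA_B + disturbance, then
the outcome latents down the structural chain) and for each day t the
within-level latents analogously.  Each partner's observed daily score is

    y[role, j, t] = mean + (between latent part + between residual)
                         + (within latent part + within residual)

and post-diary outcomes are linear in the between latents plus noise.
ART adherence days are drawn marginally as 30 - Poisson(lambda), with
lambda solved so a configurable fraction exceeds 28 days (the usual 95%
adherence cut-off over 30 days).

Default parameters emulate the study conditions of a 141-dyad, 14-day
diary among HIV-serodiscordant male couples: 7-point daily items, a
0-30 common-dyadic-coping subscale, intraclass correlations near 0.6-0.8
and ~4.4% person-days missing completely at random.  Variance components
are solved from target means/SDs/ICCs and standardized loadings (see
``default_params``), so the generated moments reproduce those targets.

Scores are kept continuous (latent-normal) by default; ``likert=True``
rounds and clips to the instrument grids as a robustness variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

from .model import CFMSpec, LevelSpec, ParameterSet, implied_moments

__all__ = [
    "GenParams",
    "default_params",
    "joint_spec",
    "generate_panel",
    "apply_mcar_mask",
    "PANEL_COLUMNS",
    "POST_COLUMNS",
]

PANEL_COLUMNS = ["dyad_id", "day", "role", "wda", "cdc", "qol", "rs"]
POST_COLUMNS = [
    "dyad_id",
    "qol_plwh",
    "qol_partner",
    "adherence_days",
    "prep_attitude",
    "rs_plwh",
    "rs_partner",
]

ROLES = ("plwh", "partner")
DAILY_VARS = ("wda", "cdc", "qol", "rs")

#: instrument ranges for the optional Likert rounding switch
LIKERT_RANGES = {"wda": (0, 6), "cdc": (0, 30), "qol": (0, 6), "rs": (0, 6)}
POST_RANGES = {
    "qol_plwh": (0, 116),
    "qol_partner": (0, 96),
    "prep_attitude": (0, 20),
    "rs_plwh": (0, 20),
    "rs_partner": (0, 20),
}

# ---------------------------------------------------------------------------
# Calibration targets: the descriptive moments the generator emulates.
# (mean, sd, icc) per daily variable and role; (mean, sd) per post-diary
# outcome; standardized loadings per level used to size the shared-latent
# variances.
# ---------------------------------------------------------------------------

DAILY_TARGETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "wda": {"plwh": (4.04, 1.81, 0.83), "partner": (4.14, 1.66, 0.83)},
    "cdc": {"plwh": (17.32, 8.14, 0.68), "partner": (17.78, 7.42, 0.70)},
    "qol": {"plwh": (4.39, 1.34, 0.58), "partner": (4.41, 1.30, 0.60)},
    "rs": {"plwh": (4.42, 1.43, 0.58), "partner": (4.39, 1.33, 0.64)},
}

POST_TARGETS: dict[str, tuple[float, float]] = {
    "post_qol_plwh": (67.06, 16.33),
    "post_qol_partner": (56.33, 16.50),
    "post_prep": (14.77, 3.98),
    "post_rs_plwh": (14.06, 4.14),
    "post_rs_partner": (14.16, 3.94),
}

STD_LOADINGS: dict[tuple[str, str], tuple[float, float]] = {
    # (var, level): (plwh, partner) standardized loading
    ("wda", "within"): (0.38, 0.41),
    ("cdc", "within"): (0.49, 0.56),
    ("rs", "within"): (0.45, 0.52),
    ("wda", "between"): (0.63, 0.69),
    ("cdc", "between"): (0.61, 0.65),
    ("rs", "between"): (0.61, 0.64),
    ("post_rs", "between"): (0.60, 0.63),
}

DEFAULT_PATHS = {
    "a_within": 4.78,
    "a_between": 2.08,
    "b_within": {"QOL_PLWH": 0.07, "QOL_PARTNER": 0.10, "RS": 0.11},
    "c_within": {"QOL_PLWH": 0.37, "QOL_PARTNER": -0.02, "RS": 0.54},
    "b_between": {
        "QOL_PLWH": 0.01,
        "QOL_PARTNER": 0.02,
        "RS": 0.04,
        "POST_QOL_PLWH": 0.65,
        "POST_QOL_PARTNER": 0.48,
        "ATT": 0.11,
        "POST_RS": 0.15,
    },
    "c_between": {
        "QOL_PLWH": 0.23,
        "QOL_PARTNER": 0.45,
        "RS": 0.37,
        "POST_QOL_PLWH": 3.84,
        "POST_QOL_PARTNER": 6.20,
        "ATT": 1.17,
        "POST_RS": 1.06,
    },
}


@dataclass
class GenParams:
    """All free quantities of the generating model.

    Structural paths are keyed by the target eta name (``QOL_PLWH``,
    ``RS``, ``POST_RS``, ``ATT`` ...); ``disturbance_var`` by level then
    eta; ``residual_var`` by level then indicator (e.g. ``wda_plwh``);
    ``means`` by indicator.  ``latent_var_*`` is the variance of the
    exogenous shared WDA latent per level.
    """

    n_dyads: int = 141
    n_days: int = 14
    a_within: float = 4.78
    a_between: float = 2.08
    b_within: dict[str, float] = field(default_factory=dict)
    b_between: dict[str, float] = field(default_factory=dict)
    c_within: dict[str, float] = field(default_factory=dict)
    c_between: dict[str, float] = field(default_factory=dict)
    latent_var_within: float = 0.08
    latent_var_between: float = 1.08
    disturbance_var: dict[str, dict[str, float]] = field(default_factory=dict)
    residual_var: dict[str, dict[str, float]] = field(default_factory=dict)
    loading: dict[str, dict[str, float]] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.044
    adherent_frac: float = 0.149
    likert: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_dyads < 2:
            raise ValueError("n_dyads must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 < self.adherent_frac < 1.0:
            raise ValueError("adherent_frac must be in (0, 1)")
        for v in (self.latent_var_within, self.latent_var_between):
            if v <= 0:
                raise ValueError("latent variances must be > 0")
        for level in ("within", "between"):
            for d in (self.disturbance_var.get(level, {}), self.residual_var.get(level, {})):
                for k, val in d.items():
                    if val <= 0:
                        raise ValueError(f"non-positive variance for {k} at {level}")
        # implied between-share of total variance per daily indicator in (0,1)
        mom = implied_moments(joint_spec(), _parameter_set(self))
        dd = len(_within_indicators())
        tot = np.diag(mom.sigma_within) + np.diag(mom.sigma_between)[:dd]
        share = np.diag(mom.sigma_between)[:dd] / tot
        if np.any(share <= 0) or np.any(share >= 1):
            raise ValueError("implied between-variance share outside (0, 1)")

    def to_dict(self) -> dict:
        def _plain(x):
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "GenParams":
        return cls(**d)


def _within_indicators() -> list[str]:
    return [f"{v}_{r}" for v in DAILY_VARS for r in ROLES]


def joint_spec() -> CFMSpec:
    """The full generating model: all daily and post-diary outcomes at once.

    Each of the six fitted models is a sub-model of this joint layout
    (the extra outcomes are downstream of the shared latents, so
    marginalizing them preserves the sub-model's structure).  ART
    adherence is excluded: it is generated marginally, not structurally.
    """
    within = dict(
        indicators=_within_indicators(),
        etas=["WDA", "CDC", "QOL_PLWH", "QOL_PARTNER", "RS"],
        loadings=[
            ("wda_plwh", "WDA"),
            ("wda_partner", "WDA"),
            ("cdc_plwh", "CDC"),
            ("cdc_partner", "CDC"),
            ("qol_plwh", "QOL_PLWH"),
            ("qol_partner", "QOL_PARTNER"),
            ("rs_plwh", "RS"),
            ("rs_partner", "RS"),
        ],
        paths=[
            ("WDA", "CDC"),
            ("WDA", "QOL_PLWH"),
            ("CDC", "QOL_PLWH"),
            ("WDA", "QOL_PARTNER"),
            ("CDC", "QOL_PARTNER"),
            ("WDA", "RS"),
            ("CDC", "RS"),
        ],
        theta_free=["wda_plwh", "wda_partner", "cdc_plwh", "cdc_partner", "rs_plwh", "rs_partner"],
    )
    between = dict(
        indicators=within["indicators"]
        + ["post_qol_plwh", "post_qol_partner", "post_prep", "post_rs_plwh", "post_rs_partner"],
        etas=within["etas"] + ["POST_QOL_PLWH", "POST_QOL_PARTNER", "ATT", "POST_RS"],
        loadings=within["loadings"]
        + [
            ("post_qol_plwh", "POST_QOL_PLWH"),
            ("post_qol_partner", "POST_QOL_PARTNER"),
            ("post_prep", "ATT"),
            ("post_rs_plwh", "POST_RS"),
            ("post_rs_partner", "POST_RS"),
        ],
        paths=within["paths"]
        + [
            ("WDA", "POST_QOL_PLWH"),
            ("CDC", "POST_QOL_PLWH"),
            ("WDA", "POST_QOL_PARTNER"),
            ("CDC", "POST_QOL_PARTNER"),
            ("WDA", "ATT"),
            ("CDC", "ATT"),
            ("WDA", "POST_RS"),
            ("CDC", "POST_RS"),
        ],
        theta_free=within["theta_free"] + ["post_rs_plwh", "post_rs_partner"],
    )

    def _freeze(d):
        return LevelSpec(
            indicators=tuple(d["indicators"]),
            etas=tuple(d["etas"]),
            loadings=tuple(d["loadings"]),
            paths=tuple(d["paths"]),
            theta_free=tuple(d["theta_free"]),
        )

    return CFMSpec(outcome_model="joint", within=_freeze(within), between=_freeze(between))


def default_params(seed: int = 0, **overrides) -> GenParams:
    """Generator defaults calibrated to the emulated study's moments.

    The shared-latent variance at each level is sized from the two
    partners' standardized loadings ``l_p, l_a`` and level-specific SDs
    ``s_p, s_a`` as ``phi = l_p * l_a * s_p * s_a`` (the geometric
    convention: reproduces the product of the two loadings exactly and
    each one approximately); endogenous-latent disturbances and
    indicator residuals are then solved by subtraction so implied
    variances hit the target SD^2 split by the target ICC.
    """

    def level_sd(var: str, role: str, level: str) -> float:
        _, sd, icc = DAILY_TARGETS[var][role]
        share = icc if level == "between" else 1.0 - icc
        return sd * np.sqrt(share)

    def shared_var(var: str, level: str) -> float:
        lp, la = STD_LOADINGS[(var, level)]
        return lp * la * level_sd(var, "plwh", level) * level_sd(var, "partner", level)

    p = DEFAULT_PATHS
    dist: dict[str, dict[str, float]] = {"within": {}, "between": {}}
    resid: dict[str, dict[str, float]] = {"within": {}, "between": {}}
    means: dict[str, float] = {}

    phi = {lvl: shared_var("wda", lvl) for lvl in ("within", "between")}
    a = {"within": p["a_within"], "between": p["a_between"]}
    v_cdc = {lvl: shared_var("cdc", lvl) for lvl in ("within", "between")}
    for lvl in ("within", "between"):
        dist[lvl]["CDC"] = v_cdc[lvl] - a[lvl] ** 2 * phi[lvl]
        cov_wc = a[lvl] * phi[lvl]
        for var in ("wda", "cdc"):
            v_lat = phi[lvl] if var == "wda" else v_cdc[lvl]
            for role in ROLES:
                resid[lvl][f"{var}_{role}"] = level_sd(var, role, lvl) ** 2 - v_lat
        # daily observed QoL outcomes (non common fate)
        for role in ROLES:
            eta = f"QOL_{role.upper()}"
            b, c = p[f"b_{lvl}"][eta], p[f"c_{lvl}"][eta]
            explained = b * b * v_cdc[lvl] + c * c * phi[lvl] + 2 * b * c * cov_wc
            dist[lvl][eta] = level_sd("qol", role, lvl) ** 2 - explained
        # daily RS common-fate latent outcome
        v_rs = shared_var("rs", lvl)
        b, c = p[f"b_{lvl}"]["RS"], p[f"c_{lvl}"]["RS"]
        explained = b * b * v_cdc[lvl] + c * c * phi[lvl] + 2 * b * c * cov_wc
        dist[lvl]["RS"] = v_rs - explained
        for role in ROLES:
            resid[lvl][f"rs_{role}"] = level_sd("rs", role, lvl) ** 2 - v_rs

    # post-diary outcomes: between level only
    cov_wc_b = a["between"] * phi["between"]
    for eta, ind in (
        ("POST_QOL_PLWH", "post_qol_plwh"),
        ("POST_QOL_PARTNER", "post_qol_partner"),
        ("ATT", "post_prep"),
    ):
        b, c = p["b_between"][eta], p["c_between"][eta]
        explained = b * b * v_cdc["between"] + c * c * phi["between"] + 2 * b * c * cov_wc_b
        dist["between"][eta] = POST_TARGETS[ind][1] ** 2 - explained
        means[ind] = POST_TARGETS[ind][0]
    lp, la = STD_LOADINGS[("post_rs", "between")]
    sd_p, sd_a = POST_TARGETS["post_rs_plwh"][1], POST_TARGETS["post_rs_partner"][1]
    v_prs = lp * la * sd_p * sd_a
    b, c = p["b_between"]["POST_RS"], p["c_between"]["POST_RS"]
    dist["between"]["POST_RS"] = v_prs - (
        b * b * v_cdc["between"] + c * c * phi["between"] + 2 * b * c * cov_wc_b
    )
    resid["between"]["post_rs_plwh"] = sd_p**2 - v_prs
    resid["between"]["post_rs_partner"] = sd_a**2 - v_prs
    means["post_rs_plwh"] = POST_TARGETS["post_rs_plwh"][0]
    means["post_rs_partner"] = POST_TARGETS["post_rs_partner"][0]

    for var in DAILY_VARS:
        for role in ROLES:
            means[f"{var}_{role}"] = DAILY_TARGETS[var][role][0]

    params = GenParams(
        a_within=p["a_within"],
        a_between=p["a_between"],
        b_within=dict(p["b_within"]),
        b_between=dict(p["b_between"]),
        c_within=dict(p["c_within"]),
        c_between=dict(p["c_between"]),
        latent_var_within=phi["within"],
        latent_var_between=phi["between"],
        disturbance_var=dist,
        residual_var=resid,
        means=means,
        seed=seed,
    )
    params = replace(params, **overrides)
    params.validate()
    return params


def _parameter_set(params: GenParams) -> ParameterSet:
    """Map GenParams onto the joint spec's free-parameter dictionary."""
    spec = joint_spec()
    vals: dict[str, float] = {}
    for lvl in ("within", "between"):
        a = params.a_within if lvl == "within" else params.a_between
        bmap = params.b_within if lvl == "within" else params.b_between
        cmap = params.c_within if lvl == "within" else params.c_between
        ls = spec.level(lvl)
        for src, dst in ls.paths:
            if (src, dst) == ("WDA", "CDC"):
                vals[f"WDA->CDC@{lvl}"] = a
            elif src == "CDC":
                vals[f"CDC->{dst}@{lvl}"] = bmap[dst]
            else:
                vals[f"WDA->{dst}@{lvl}"] = cmap[dst]
        phi = params.latent_var_within if lvl == "within" else params.latent_var_between
        for eta in ls.etas:
            vals[f"psi({eta})@{lvl}"] = (
                phi if eta == "WDA" else params.disturbance_var[lvl][eta]
            )
        for ind in ls.theta_free:
            vals[f"theta({ind})@{lvl}"] = params.residual_var[lvl][ind]
    for ind in spec.between.indicators:
        vals[f"mu({ind})"] = params.means[ind]
    return ParameterSet(spec, vals)


def _draw_level(rng, lam, B, psi_diag, theta_diag, n) -> tuple[np.ndarray, np.ndarray]:
    """Draw n rows of (indicator values, eta values) from one level."""
    q = B.shape[0]
    zeta = rng.standard_normal((n, q)) * np.sqrt(psi_diag)
    eta = np.linalg.solve(np.eye(q) - B, zeta.T).T
    eps = rng.standard_normal((n, lam.shape[0])) * np.sqrt(theta_diag)
    return eta @ lam.T + eps, eta


def _adherence_lambda(target: float) -> float:
    """Rate of 30 - Poisson(lam) such that P(days > 28) = target."""
    return brentq(lambda lam: poisson.cdf(1, lam) - target, 1e-6, 30.0)


def generate_panel(
    params: GenParams, return_latents: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a diary panel and post-diary table from ``params``.

    Returns ``(panel, post)`` as tidy DataFrames; with
    ``return_latents=True`` additionally returns the drawn latent scores
    (``eta_between``: n_dyads x q_B, ``eta_within``: n_dyads*n_days x q_W,
    with column-name lists) for generator diagnostics.

    Deterministic given ``params.seed``.  Raises on parameter sets whose
    implied covariance is not positive definite at either level.
    """
    params.validate()
    ps = _parameter_set(params)
    mom = implied_moments(ps.spec, ps)
    for name, sigma in (("within", mom.sigma_within), ("between", mom.sigma_between)):
        if np.min(np.linalg.eigvalsh(sigma)) <= 0:
            raise ValueError(f"implied {name}-level covariance is not positive definite")

    rng = np.random.default_rng(params.seed)
    J, T = params.n_dyads, params.n_days
    spec = ps.spec

    lam_b, B_b, psi_b, th_b = ps.matrices("between")
    lam_w, B_w, psi_w, th_w = ps.matrices("within")
    y_b, eta_b = _draw_level(rng, lam_b, B_b, np.diag(psi_b), np.diag(th_b), J)
    y_w, eta_w = _draw_level(rng, lam_w, B_w, np.diag(psi_w), np.diag(th_w), J * T)

    mu = ps.mu()
    p_w = spec.within.p
    # daily observed values: mean + between part + within part
    daily = mu[:p_w] + np.repeat(y_b[:, :p_w], T, axis=0) + y_w
    post_vals = mu[p_w:] + y_b[:, p_w:]

    dyads = np.repeat(np.arange(1, J + 1), T)
    days = np.tile(np.arange(1, T + 1), J)
    frames = []
    ind_names = list(spec.within.indicators)
    for role in ROLES:
        cols = {v: daily[:, ind_names.index(f"{v}_{role}")] for v in DAILY_VARS}
        frames.append(
            pd.DataFrame(
                {"dyad_id": dyads, "day": days, "role": role.upper() if role == "plwh" else role, **cols}
            )
        )
    panel = pd.concat(frames, ignore_index=True)
    panel = panel.sort_values(["dyad_id", "day", "role"], kind="stable").reset_index(drop=True)

    lam = _adherence_lambda(params.adherent_frac)
    adherence = np.clip(30 - rng.poisson(lam, size=J), 0, 30)

    post = pd.DataFrame(
        {
            "dyad_id": np.arange(1, J + 1),
            "qol_plwh": post_vals[:, 0],
            "qol_partner": post_vals[:, 1],
            "adherence_days": adherence,
            "prep_attitude": post_vals[:, 2],
            "rs_plwh": post_vals[:, 3],
            "rs_partner": post_vals[:, 4],
        }
    )

    if params.likert:
        for v in DAILY_VARS:
            lo, hi = LIKERT_RANGES[v]
            panel[v] = panel[v].round().clip(lo, hi).astype(int)
        for col, (lo, hi) in POST_RANGES.items():
            post[col] = post[col].round().clip(lo, hi).astype(int)

    if params.missing_rate > 0:
        panel = apply_mcar_mask(panel, params.missing_rate, seed=int(rng.integers(2**31)))

    if return_latents:
        latents = {
            "eta_between": eta_b,
            "eta_between_names": list(spec.between.etas),
            "eta_within": eta_w,
            "eta_within_names": list(spec.within.etas),
            "dyad_of_day": dyads,
        }
        return panel, post, latents
    return panel, post


def apply_mcar_mask(panel: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Remove each person-day record independently with probability ``rate``.

    Missingness is completely at random at the record (row) level — the
    weakest mechanism compatible with full-information ML downstream.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0:
        return panel.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(panel)) >= rate
    out = panel.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("MCAR mask removed every record", stacklevel=2)
    return out
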