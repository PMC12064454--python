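"""Shared fixtures.

The replicate-study fixtures are session-scoped because they drive both
the recovery and the coverage checks; everything is generated
programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyadcfm import build_spec, default_params, generate_panel
from dyadcfm.estimation import FitConfig, build_cluster_data, fit
from dyadcfm.mediation import mediate
from dyadcfm.model import CFMSpec, LevelSpec, ParameterSet


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic study at the emulated design size (141 x 14)."""
    params = default_params(seed=11)
    panel, post = generate_panel(params)
    return params, panel, post


@pytest.fixture(scope="session")
def model1_fit(default_panel):
    params, panel, post = default_panel
    spec = build_spec("daily_qol")
    data = build_cluster_data(panel, post, spec)
    return spec, data, fit(spec, data, FitConfig())


def random_theta(spec: CFMSpec, rng: np.random.Generator) -> ParameterSet:
    """Random admissible parameter set: positive variances, modest paths."""
    vals = {}
    for name in spec.param_names:
        if name.startswith(("psi(", "theta(")):
            vals[name] = float(rng.uniform(0.2, 2.0))
        elif name.startswith("mu("):
            vals[name] = float(rng.normal(0.0, 2.0))
        else:
            vals[name] = float(rng.normal(0.0, 0.5))
    return ParameterSet(spec, vals)


def tiny_spec(n_ind: int = 2) -> CFMSpec:
    """A one-latent common-fate measurement model (df = 0 when n_ind = 2)."""
    inds = tuple(f"y{i}" for i in range(n_ind))
    level = LevelSpec(
        indicators=inds,
        etas=("ETA",),
        loadings=tuple((i, "ETA") for i in inds),
        paths=(),
        theta_free=inds,
    )
    return CFMSpec(outcome_model="daily_qol", within=level, between=level)


@pytest.fixture(scope="session")
def model1_replicates():
    """500 refits of the daily quality-of-life model at the study size.

    Each replicate records the free-parameter estimates and the Monte
    Carlo CI of the within-level indirect effect on the PLWH outcome.
    """
    spec = build_spec("daily_qol")
    out = []
    for s in range(500):
        params = default_params(seed=40_000 + s)
        panel, post = generate_panel(params)
        data = build_cluster_data(panel, post, spec)
        res = fit(spec, data, FitConfig(compute_se=True, compute_fit_indices=False))
        rec = {"converged": res.converged, "theta": dict(res.theta_hat.values)}
        if res.converged:
            m = mediate(res, "within", "QOL_PLWH", reps=5000, seed=s)
            rec["ci"] = (m.ci_lower, m.ci_upper)
        out.append(rec)
    return spec, out


@pytest.fixture(scope="session")
def model5_replicates():
    """200 refits of the daily relationship-satisfaction model."""
    spec = build_spec("daily_rs")
    out = []
    for s in range(200):
        params = default_params(seed=30_000 + s)
        panel, post = generate_panel(params)
        data = build_cluster_data(panel, post, spec)
        res = fit(spec, data, FitConfig(compute_se=False, compute_fit_indices=False))
        out.append({"converged": res.converged, "theta": dict(res.theta_hat.values)})
    return spec, out
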