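"""File formats: tidy CSVs, config round-trips, result serialization.

One fixed CSV dialect throughout: UTF-8, comma-separated, header row,
empty cell = missing, diary days 1-based.  Results files are
machine-parseable (JSON) with a human-readable table alongside; logs
never go into results files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
import yaml
from scipy.stats import norm

from .estimation import FitResult
from .synthetic import GenParams, PANEL_COLUMNS, POST_COLUMNS

__all__ = [
    "write_panel",
    "read_panel",
    "write_post",
    "read_post",
    "save_params",
    "load_params",
    "fit_result_to_dict",
    "fit_result_table",
]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV lacks columns: {sorted(missing)}")
    return df[PANEL_COLUMNS]


def write_post(post: pd.DataFrame, path) -> None:
    post[POST_COLUMNS].to_csv(path, index=False)


def read_post(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(POST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"post-diary CSV lacks columns: {sorted(missing)}")
    return df[POST_COLUMNS]


def save_params(params: GenParams, path) -> None:
    """GenParams -> JSON or YAML (by extension)."""
    path = Path(path)
    doc = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_params(path) -> GenParams:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return GenParams.from_dict(doc)


def _wald(b: float, se: float) -> tuple[float, float]:
    if not se or math.isnan(se) or se <= 0:
        return float("nan"), float("nan")
    z = b / se
    return z, 2.0 * float(norm.sf(abs(z)))


def fit_result_to_dict(res: FitResult) -> dict:
    return {
        "outcome_model": res.theta_hat.spec.outcome_model,
        "converged": res.converged,
        "n_clusters": res.n_clusters,
        "n_obs": res.n_obs,
        "loglik": res.loglik,
        "loglik_saturated": res.loglik_saturated,
        "loglik_baseline": res.loglik_baseline,
        "chi2": res.chi2,
        "df": res.df,
        "fit": res.fit,
        "rmsea_n_convention": "total within-level observations (dyad-days)",
        "estimates": res.theta_hat.values,
        "se": res.se,
        "standardized": res.beta,
        "message": res.message,
    }


def fit_result_table(res: FitResult) -> str:
    """Human-readable parameter table: b, SE, beta, Wald z, p per level."""
    lines = [
        f"Model: {res.theta_hat.spec.outcome_model}   "
        f"clusters={res.n_clusters}  obs={res.n_obs}  "
        f"loglik={res.loglik:.3f}  converged={res.converged}",
        f"{'Parameter':42s} {'b':>9s} {'SE':>8s} {'beta':>7s} {'z':>7s} {'p':>7s}",
    ]
    spec = res.theta_hat.spec
    for level in ("within", "between"):
        lines.append(f"Level: {level}")
        ls = spec.level(level)
        for ind, eta in ls.loadings:
            key = f"lambda({ind}<-{eta})@{level}"
            beta = res.beta.get(key)
            lines.append(
                f"  {ind + ' -> ' + eta:40s} {'1.000':>9s} {'-':>8s} "
                f"{beta:7.3f} {'-':>7s} {'-':>7s}"
            )
        for src, dst in ls.paths:
            key = f"{src}->{dst}@{level}"
            b = res.theta_hat.values[key]
            se = res.se.get(key, float("nan"))
            z, p = _wald(b, se)
            lines.append(
                f"  {src + ' -> ' + dst:40s} {b:9.3f} {se:8.3f} "
                f"{res.beta.get(key, float('nan')):7.3f} {z:7.2f} {p:7.3f}"
            )
    if res.fit:
        fi = ", ".join(
            f"{k.upper()}={v:.3f}" for k, v in res.fit.items() if v is not None
        )
        lines.append(f"Fit: chi2={res.chi2:.3f} df={res.df}  {fi}")
    elif spec.suppress_fit_indices:
        lines.append("Fit indices: not available for binary outcome")
    return "\n".join(lines)
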