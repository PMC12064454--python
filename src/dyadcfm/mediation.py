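"""Indirect effects and Monte Carlo confidence intervals.

The indirect effect at a level is the product a*b of the path into the
mediator (shared we-disease appraisal -> shared common dyadic coping)
and the mediator's path into the outcome.  Its sampling distribution is
non-normal, so the confidence interval is built by the Monte Carlo
(parametric-bootstrap-of-coefficients) method: draw (a*, b*) from a
bivariate normal centered at the estimates with the joint asymptotic
covariance taken from the fitted observed-information inverse — a and b
share an equation system, so they are sampled jointly, not
independently — and take empirical percentiles of a* * b*.  The
delta-method standard error is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .estimation import FitResult

__all__ = ["MediationResult", "indirect_point", "monte_carlo_ci", "mediate"]


@dataclass
class MediationResult:
    level: str
    outcome: str
    a_hat: float
    b_hat: float
    est: float
    se: float
    ci_lower: float
    ci_upper: float
    confidence: float
    reps: int
    seed: int

    @property
    def significant(self) -> bool:
        """Significance convention: the CI excludes zero."""
        return self.ci_lower > 0.0 or self.ci_upper < 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self) | {"significant": self.significant}, indent=2)

    def table_row(self) -> str:
        star = "*" if self.significant else " "
        return (
            f"WDA_shared -> CDC_shared -> {self.outcome} [{self.level}]  "
            f"est={self.est:7.3f}{star} SE={self.se:6.3f} "
            f"{100 * self.confidence:.0f}% CI [{self.ci_lower:7.3f}, {self.ci_upper:7.3f}]"
        )


def indirect_point(a: float, b: float) -> float:
    """Product-of-paths indirect effect: exactly a * b."""
    return a * b


def _psd_factor(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.shape != (2, 2):
        raise ValueError("V_ab must be 2x2")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("V_ab must be symmetric")
    w, Q = np.linalg.eigh(0.5 * (V + V.T))
    if np.min(w) < -1e-10 * max(np.max(np.abs(w)), 1.0):
        raise ValueError("V_ab must be positive semi-definite")
    return Q * np.sqrt(np.maximum(w, 0.0))


def monte_carlo_ci(
    a: float,
    b: float,
    V_ab: np.ndarray,
    reps: int = 20_000,
    seed: int = 0,
    level: float = 0.95,
    outcome: str = "",
    which_level: str = "",
) -> MediationResult:
    """Monte Carlo percentile CI for the indirect effect a*b.

    Draws ``reps`` pairs from N((a, b), V_ab) (PSD factorization, so a
    degenerate V_ab = 0 is legal and collapses the CI to the point) and
    returns the empirical (alpha/2, 1 - alpha/2) percentiles of the
    products.  Deterministic given ``seed``.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    L = _psd_factor(V_ab)
    rng = np.random.default_rng(seed)
    draws = np.array([a, b]) + rng.standard_normal((reps, 2)) @ L.T
    prods = draws[:, 0] * draws[:, 1]
    alpha = 1.0 - level
    lo, hi = np.quantile(prods, [alpha / 2.0, 1.0 - alpha / 2.0])
    V = np.asarray(V_ab, dtype=float)
    se = float(np.sqrt(b * b * V[0, 0] + a * a * V[1, 1] + 2.0 * a * b * V[0, 1]))
    return MediationResult(
        level=which_level,
        outcome=outcome,
        a_hat=float(a),
        b_hat=float(b),
        est=indirect_point(a, b),
        se=se,
        ci_lower=float(lo),
        ci_upper=float(hi),
        confidence=level,
        reps=reps,
        seed=seed,
    )


def mediate(
    fit: FitResult,
    level: str,
    outcome: str,
    reps: int = 20_000,
    seed: int = 0,
    confidence: float = 0.95,
) -> MediationResult:
    """Indirect effect of a fitted model at one level, with Monte Carlo CI.

    ``outcome`` names the outcome block (e.g. ``QOL_PLWH``, ``RS``,
    ``ADH``).  Raises if the mediation chain does not exist at the
    requested level (post-diary outcomes have no within-level path) or
    if the fit did not converge.
    """
    if not fit.converged:
        raise ValueError("cannot mediate on a non-converged fit")
    a_name = f"WDA->CDC@{level}"
    b_name = f"CDC->{outcome}@{level}"
    for name in (a_name, b_name):
        if name not in fit.theta_hat.values:
            raise ValueError(f"path {name} absent from the fitted model")
    a = fit.theta_hat.values[a_name]
    b = fit.theta_hat.values[b_name]
    V_ab = fit.cov_of([a_name, b_name])
    return monte_carlo_ci(
        a, b, V_ab, reps=reps, seed=seed, level=confidence,
        outcome=outcome, which_level=level,
    )
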