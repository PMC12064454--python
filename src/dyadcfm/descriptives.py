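"""Descriptive statistics for dyadic diary panels.

Covers the standard reporting block of an intensive-longitudinal dyad
study: per-variable means/SDs, intraclass correlations (one-way
random-effects ANOVA estimator with the unbalanced n0 correction),
within- and between-cluster correlations via cluster-mean centering,
diary completion rate, the >28-of-30-days ART adherence categorization,
and the screening-flow arithmetic.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "icc_anova",
    "within_between_corr",
    "completion_rate",
    "adherence_category",
    "screening_flow",
    "describe_panel",
]


def _round1(x: float) -> float:
    """Round half-up to one decimal (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def icc_anova(values, clusters) -> float:
    """One-way random-effects ANOVA intraclass correlation.

    icc = (MSB - MSW) / (MSB + (n0 - 1) * MSW), with the conventional
    unbalanced-design correction n0 = (N - sum(n_j^2)/N) / (J - 1).
    Negative estimates are truncated to 0.  Requires at least two
    clusters and at least one cluster with two or more observations.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(clusters)})
    df = df.dropna()
    groups = df.groupby("g")["y"]
    sizes = groups.size().to_numpy(dtype=float)
    J = len(sizes)
    N = sizes.sum()
    if J < 2:
        raise ValueError("need at least two clusters")
    if np.all(sizes < 2):
        raise ValueError("all clusters are singletons; within variance undefined")
    grand = df["y"].mean()
    means = groups.mean().to_numpy()
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(((df["y"] - df["g"].map(groups.mean())) ** 2).sum())
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    n0 = (N - np.sum(sizes**2) / N) / (J - 1)
    if msw == 0:
        return 1.0
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(min(1.0, max(0.0, icc)))


def within_between_corr(x, y, clusters) -> tuple[float, float]:
    """Within- and between-cluster Pearson correlations of x and y.

    r_within correlates the cluster-mean-centered scores; r_between
    correlates the cluster means.  Raises if either level has zero
    variance.
    """
    df = pd.DataFrame(
        {"x": np.asarray(x, float), "y": np.asarray(y, float), "g": np.asarray(clusters)}
    ).dropna()
    if df["g"].nunique() < 2:
        raise ValueError("need at least two clusters")
    means = df.groupby("g")[["x", "y"]].transform("mean")
    cx, cy = df["x"] - means["x"], df["y"] - means["y"]
    gm = df.groupby("g")[["x", "y"]].mean()
    for s in (cx, cy, gm["x"], gm["y"]):
        if float(np.std(s)) == 0.0:
            raise ValueError("zero variance at one level")
    r_within = float(np.corrcoef(cx, cy)[0, 1])
    r_between = float(np.corrcoef(gm["x"], gm["y"])[0, 1])
    return r_within, r_between


def completion_rate(panel: pd.DataFrame, n_dyads: int, n_days: int) -> float:
    """Percent of the expected person-day grid actually observed.

    100 * observed records / (n_dyads * n_days * 2 partners), rounded
    half-up to one decimal.
    """
    if n_dyads < 1 or n_days < 1:
        raise ValueError("empty expected grid")
    expected = n_dyads * n_days * 2
    return _round1(100.0 * len(panel) / expected)


def adherence_category(days: int) -> str:
    """Categorize 30-day ART adherence: adherent iff days > 28.

    The cut-off mirrors the 95%-of-doses standard for viral
    suppression: only 29 or 30 of the last 30 days count as adherent.
    """
    if not 0 <= days <= 30:
        raise ValueError("days must be in [0, 30]")
    return "adherent" if days > 28 else "non_adherent"


def screening_flow(
    reached: int, declined: int, ineligible: int, baseline_only: int
) -> dict[str, float]:
    """Recruitment-flow arithmetic: analytic n and exclusion percentages.

    Returns the analytic sample size and each exclusion as a percent of
    couples reached (one decimal).  Raises if the exclusions exceed the
    number reached.
    """
    counts = dict(
        reached=reached, declined=declined, ineligible=ineligible, baseline_only=baseline_only
    )
    for k, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count for {k}")
    analytic = reached - declined - ineligible - baseline_only
    if analytic < 0:
        raise ValueError("exclusions exceed couples reached")
    return {
        "analytic_n": analytic,
        "declined_percent": _round1(100.0 * declined / reached),
        "ineligible_percent": _round1(100.0 * ineligible / reached),
        "baseline_only_percent": _round1(100.0 * baseline_only / reached),
    }


def describe_panel(
    panel: pd.DataFrame,
    post: pd.DataFrame | None = None,
    n_dyads: int | None = None,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Descriptive report: M, SD, ICC per daily variable and role, plus
    within/between correlations of the PLWH-role variable pairs.

    Returns a tidy DataFrame with one row per (variable, role) and
    attrs carrying the correlation table, completion rate and (when a
    post-diary table is given) the adherent count/percent.
    """
    daily_vars = [c for c in ("wda", "cdc", "qol", "rs") if c in panel.columns]
    rows = []
    for var in daily_vars:
        for role in sorted(panel["role"].unique()):
            sub = panel[panel["role"] == role]
            vals = sub[var].dropna()
            rows.append(
                {
                    "variable": var,
                    "role": role,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "icc": icc_anova(sub[var], sub["dyad_id"]),
                }
            )
    report = pd.DataFrame(rows)

    corr_rows = []
    for i, vx in enumerate(daily_vars):
        for vy in daily_vars[i + 1 :]:
            ok = panel[[vx, vy]].notna().all(axis=1)
            rw, rb = within_between_corr(
                panel.loc[ok, vx], panel.loc[ok, vy], panel.loc[ok, "dyad_id"]
            )
            corr_rows.append({"x": vx, "y": vy, "r_within": rw, "r_between": rb})
    report.attrs["correlations"] = pd.DataFrame(corr_rows)

    if n_dyads and n_days:
        report.attrs["completion_percent"] = completion_rate(panel, n_dyads, n_days)
    if post is not None and "adherence_days" in post.columns:
        adherent = int(
            sum(adherence_category(int(d)) == "adherent" for d in post["adherence_days"])
        )
        report.attrs["adherent_count"] = adherent
        report.attrs["adherent_percent"] = _round1(100.0 * adherent / len(post))
    return report
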