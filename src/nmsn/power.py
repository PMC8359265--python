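"""Trial sample-size estimation for slowing the neuromelanin decline.

A disease-modifying therapy is assumed to reduce the mean 1-year change of
an SN measure by a fraction of the predicted decline. Per-arm sample sizes
for a two-arm comparison of 1-year changes come from the standard normal
approximation

    n = ceil( 2 sigma^2 (z_{1-alpha/2} + z_power)^2 / delta^2 )

with delta the treated-vs-placebo difference in mean annualized change and
sigma the between-subject SD of the 1-year change. A Monte-Carlo
counterpart simulates the two-sample t test directly and binary-searches
the smallest n reaching the target power; the two routes agree within a
few percent and cross-validate each other.

The decline difference can be referenced either to the PD-minus-HV rate
difference (default) or to the PD rate alone (``delta_reference='pd'``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import MEASURES, annual_rate

__all__ = [
    "PowerQuery",
    "PowerEstimate",
    "sample_size_analytic",
    "sample_size_simulated",
    "power_table",
    "queries_from_changes",
    "annualized_changes",
]


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of one sample-size cell."""

    measure: str
    effect_fraction: float
    power: float
    decline_pd: float  # mean annualized change, %/yr
    decline_hv: float = 0.0
    sd_change: float = 1.0  # SD of the 1-year change, %
    alpha: float = 0.05
    delta_reference: str = "difference"  # or "pd"

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in (0, 1]")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sd_change <= 0:
            raise ValueError("sd_change must be positive")
        if self.delta_reference not in ("difference", "pd"):
            raise ValueError("delta_reference must be 'difference' or 'pd'")

    @property
    def delta(self) -> float:
        """Treated-vs-placebo difference in mean 1-year change (%)."""
        base = (
            abs(self.decline_pd - self.decline_hv)
            if self.delta_reference == "difference"
            else abs(self.decline_pd)
        )
        return self.effect_fraction * base


@dataclass(frozen=True)
class PowerEstimate:
    n_per_arm: int
    method: str
    inputs_echo: PowerQuery


def sample_size_analytic(query: PowerQuery) -> PowerEstimate:
    """Per-arm n from the two-arm normal-approximation formula (rounded up)."""
    delta = query.delta
    if delta == 0:
        raise ValueError("zero effect: the declines cancel, no detectable change")
    z_alpha = sps.norm.ppf(1.0 - query.alpha / 2.0)
    z_power = sps.norm.ppf(query.power)
    n = math.ceil(2.0 * query.sd_change**2 * (z_alpha + z_power) ** 2 / delta**2)
    return PowerEstimate(n_per_arm=max(n, 2), method="analytic", inputs_echo=query)


def _rejection_rate(
    n: int, delta: float, sd: float, alpha: float, n_reps: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo rejection rate of the pooled two-sample t test at size n/arm."""
    a = rng.normal(0.0, sd, size=(n_reps, n))
    b = rng.normal(delta, sd, size=(n_reps, n))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = (va + vb) / 2.0
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(pooled * 2.0 / n)
    crit = sps.t.ppf(1.0 - alpha / 2.0, df=2 * n - 2)
    return float(np.mean(np.abs(t) >= crit))


def sample_size_simulated(
    query: PowerQuery, n_reps: int = 1000, seed: int = 0, n_max: int = 20000
) -> PowerEstimate:
    """Smallest per-arm n whose simulated t-test rejection rate reaches the power.

    Doubles n until the target power is reached, then bisects. Raises if the
    target is not attainable below ``n_max``.
    """
    if n_reps < 500:
        raise ValueError("use at least 500 simulation replicates")
    delta = query.delta
    if delta == 0:
        raise ValueError("zero effect: the declines cancel, no detectable change")
    rng = np.random.default_rng(seed)

    def rate(n: int) -> float:
        return _rejection_rate(n, delta, query.sd_change, query.alpha, n_reps, rng)

    lo, hi = 2, 2
    while rate(hi) < query.power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"target power not achievable below n_max={n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if rate(mid) >= query.power:
            hi = mid
        else:
            lo = mid
    return PowerEstimate(n_per_arm=hi, method="simulation", inputs_echo=query)


def annualized_changes(
    table: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    group: str = "PD",
) -> pd.DataFrame:
    """Per-subject annualized changes (%/yr) for one group of a cohort table."""
    df = table[table["group"] == group]
    wide = df.pivot(index="subject_id", columns="visit",
                    values=list(measures) + ["delay_years"])
    needed = [(m, v) for m in measures for v in ("V1", "V2")] + [("delay_years", "V2")]
    wide = (
        wide.dropna(subset=[c for c in needed if c in wide.columns])
        if all(c in wide.columns for c in needed) else wide.iloc[:0]
    )
    if wide.empty:
        raise ValueError(f"no subjects of group {group!r} with both visits")
    out = {}
    delay = wide[("delay_years", "V2")].to_numpy()
    for m in measures:
        out[m] = annual_rate(
            wide[(m, "V1")].to_numpy(), wide[(m, "V2")].to_numpy(), delay, m
        )
    return pd.DataFrame(out, index=wide.index)


def queries_from_changes(
    changes_pd: pd.DataFrame,
    changes_hv: pd.DataFrame | None,
    effect_fractions: Sequence[float] = (0.3, 0.5, 0.7),
    powers: Sequence[float] = (0.9, 0.8),
    alpha: float = 0.05,
    delta_reference: str = "difference",
) -> list[PowerQuery]:
    """Build the measure x effect x power query grid from observed changes.

    ``sigma`` per measure is the SD of the PD annualized changes; the decline
    means come from the PD (and, when given, HV) change tables.
    """
    queries = []
    for m in changes_pd.columns:
        decline_pd = float(changes_pd[m].mean())
        decline_hv = float(changes_hv[m].mean()) if changes_hv is not None else 0.0
        sd = float(changes_pd[m].std(ddof=1))
        for eff in effect_fractions:
            for pw in powers:
                queries.append(
                    PowerQuery(
                        measure=m, effect_fraction=eff, power=pw,
                        decline_pd=decline_pd, decline_hv=decline_hv,
                        sd_change=sd, alpha=alpha, delta_reference=delta_reference,
                    )
                )
    return queries


def power_table(
    queries: Sequence[PowerQuery],
    method: str = "analytic",
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-size grid: rows (effect fraction, power), one column per measure."""
    if not queries:
        raise ValueError("empty query grid")
    estimator = {
        "analytic": sample_size_analytic,
        "simulation": lambda q: sample_size_simulated(q, n_reps=n_reps, seed=seed),
    }[method]
    records = [
        dict(
            measure=q.measure,
            effect_fraction=q.effect_fraction,
            power=q.power,
            n_per_arm=estimator(q).n_per_arm,
        )
        for q in queries
    ]
    long = pd.DataFrame(records)
    return long.pivot_table(
        index=["effect_fraction", "power"], columns="measure", values="n_per_arm"
    ).sort_index(ascending=[True, False])


def render_power_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of the sample-size grid."""
    lines = ["Per-arm sample size to detect a slowed 1-year decline", ""]
    lines.append(table.to_string())
    return "\n".join(lines)
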