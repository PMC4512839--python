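"""Aggregation of cohort runs into population outcomes and scenario
comparisons.

Per-10,000 rates use the *initial* cohort population as denominator (not
person-years): a value of, say, 2,000 for CHD means 2,000 cumulative
incident CHD events over the horizon per 10,000 people alive at entry.
Cohorts aggregate by their size weights. Rounding is half-away-from-zero
and applied only at render time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import RunResult
from .parameters import CohortSpec
from .scenarios import UndefinedValueError, percent_change

MEASURES = ("chd", "stroke", "cvd_death")


def weighted_rate(values, weights) -> float:
    """Size-weighted arithmetic mean of per-cohort rates."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total == 0:
        raise UndefinedValueError("zero total weight")
    return float(np.dot(values, weights) / total)


def per_ten_thousand(count: float, population: float) -> float:
    """Events per 10,000 persons."""
    if population <= 0:
        raise UndefinedValueError("population must be positive")
    return 1e4 * count / population


def scale_to_population(rate_per_10k: float, population: float) -> float:
    """National count implied by a per-10,000 rate (unrounded; display
    rounding to the nearest 1,000 is applied by :func:`format_count`)."""
    return rate_per_10k / 1e4 * population


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the published tables;
    Python's built-in ``round`` is half-to-even)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def format_count(count: float) -> str:
    """Display form of a national count, rounded to the nearest 1,000."""
    return f"{round_half_away(count / 1000.0) * 1000:,.0f}"


@dataclass
class OutcomeSummary:
    """Aggregated per-10,000 outcomes for one scenario.

    ``table`` is indexed by stratum ("total", each sex, each age band, each
    race present) with one column per measure (chd / stroke / cvd_death).
    ``ci_lo``/``ci_hi`` hold Monte Carlo percentile bounds when an
    uncertainty analysis produced them.
    """

    scenario: str
    table: pd.DataFrame
    population: dict[str, float] = field(default_factory=dict)
    ci_lo: pd.DataFrame | None = None
    ci_hi: pd.DataFrame | None = None


def _strata_for(cohorts: list[CohortSpec]) -> dict[str, list[CohortSpec]]:
    strata: dict[str, list[CohortSpec]] = {"total": list(cohorts)}
    for c in cohorts:
        strata.setdefault(c.sex, []).append(c)
        strata.setdefault(c.age_band_label, []).append(c)
        if c.race != "all":
            strata.setdefault(c.race, []).append(c)
    return strata


def summarize_runs(results: dict[str, RunResult],
                   cohorts: list[CohortSpec],
                   scenario_name: str) -> OutcomeSummary:
    """Aggregate per-cohort runs into per-10,000 rates by stratum."""
    strata = _strata_for(cohorts)
    rows = {}
    population = {}
    for stratum, members in strata.items():
        rates = {}
        weights = [c.size for c in members]
        for measure in MEASURES:
            values = [results[c.cohort_id].per_10k(measure)
                      for c in members]
            rates[measure] = weighted_rate(values, weights)
        rows[stratum] = rates
        population[stratum] = float(sum(weights))
    table = pd.DataFrame.from_dict(rows, orient="index")[list(MEASURES)]
    return OutcomeSummary(scenario=scenario_name, table=table,
                          population=population)


def compare_scenarios(reference: OutcomeSummary,
                      comparison: OutcomeSummary) -> pd.DataFrame:
    """Differences (reference - comparison) and percent changes per stratum
    and measure. Raises on stratum mismatch."""
    mismatch = set(reference.table.index) ^ set(comparison.table.index)
    if mismatch:
        raise ValueError(f"stratum mismatch: {sorted(mismatch)}")
    rows = []
    for stratum in reference.table.index:
        for measure in MEASURES:
            ref = float(reference.table.loc[stratum, measure])
            comp = float(comparison.table.loc[stratum, measure])
            rows.append({
                "stratum": stratum, "measure": measure,
                "reference": ref, "comparison": comp,
                "difference": ref - comp,
                "pct_change": percent_change(ref, comp),
            })
    return pd.DataFrame(rows)


def render_outcomes(summary: OutcomeSummary, ndigits: int = 0) -> str:
    """Plain-text table with display rounding (half away from zero)."""
    shown = summary.table.map(lambda x: round_half_away(x, ndigits))
    if summary.ci_lo is not None and summary.ci_hi is not None:
        parts = []
        for stratum in shown.index:
            cells = []
            for measure in MEASURES:
                lo = round_half_away(
                    float(summary.ci_lo.loc[stratum, measure]), ndigits)
                hi = round_half_away(
                    float(summary.ci_hi.loc[stratum, measure]), ndigits)
                cells.append(
                    f"{shown.loc[stratum, measure]:g} ({lo:g}-{hi:g})"
                )
            parts.append((stratum, *cells))
        shown = pd.DataFrame(parts, columns=("stratum", *MEASURES)
                             ).set_index("stratum")
    return f"scenario: {summary.scenario}\n{shown.to_string()}"


def plot_percent_reductions(comparisons: dict[str, pd.DataFrame],
                            strata: list[str], path: str) -> None:
    """Bar chart of percent reductions by stratum for each comparison
    (one panel per measure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(MEASURES),
                             figsize=(4 * len(MEASURES), 3.2), sharey=True)
    width = 0.8 / max(len(comparisons), 1)
    x = np.arange(len(strata))
    for ax, measure in zip(np.atleast_1d(axes), MEASURES):
        for j, (name, comp) in enumerate(comparisons.items()):
            sub = comp[comp["measure"] == measure].set_index("stratum")
            vals = [-float(sub.loc[s, "pct_change"]) if s in sub.index
                    else 0.0 for s in strata]
            ax.bar(x + j * width, vals, width, label=name)
        ax.set_xticks(x + width * (len(comparisons) - 1) / 2)
        ax.set_xticklabels(strata, rotation=45, ha="right")
        ax.set_title(measure)
    np.atleast_1d(axes)[0].set_ylabel("reduction vs baseline, %")
    np.atleast_1d(axes)[-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
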