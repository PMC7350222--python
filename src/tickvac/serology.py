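"""Antibody-response analyses: timecourse comparisons and correlates of protection.

Serology is carried as ELISA OD450 readings at a fixed serum dilution; the
optical density itself is the antibody titer readout.  Two analyses are
implemented:

* per-bleed-day comparison of vaccinated vs control titers (one-way ANOVA,
  flagged at p < 0.05 and p < 0.005), and
* Spearman correlation between each animal's pre-challenge (day-60) titer and
  its per-animal tick stage outcomes, pooling all formulations including the
  control (n = 20 in the reference design), followed by detection of the
  reduction threshold above which titers correlate negatively with outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .stages import StageParameter
from .stats import TestResult, TestUndefinedError, oneway_anova, spearman_rho

__all__ = [
    "AntibodySeries",
    "CorrelationOutcome",
    "titer_timecourse_test",
    "eligible_parameters",
    "correlate_titers_stages",
    "reduction_threshold",
]


@dataclass
class AntibodySeries:
    """One animal's OD450 readings across bleed days for one coated antigen."""

    animal_id: str
    antigen_group: str
    coated_antigen: str
    readings: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for day, od in self.readings.items():
            if od < 0:
                raise ValueError(f"{self.animal_id}: OD450 must be non-negative (day {day})")

    def od(self, day: int) -> float:
        return self.readings[day]


@dataclass
class CorrelationOutcome:
    """Titer-outcome correlation for one stage parameter.

    ``mean_reduction_pct`` is the parameter's mean group-level reduction
    across the vaccine formulations, used for threshold detection.
    ``significant_negative`` iff rho < 0 and p <= alpha.
    """

    parameter: StageParameter
    rho: float
    p_value: float
    mean_reduction_pct: float
    significant_negative: bool
    n: int = 0


def titer_timecourse_test(
    series: Sequence[AntibodySeries],
    control_group: str,
    alpha: float = 0.05,
    strong_alpha: float = 0.005,
) -> pd.DataFrame:
    """Per (coated antigen, day) ANOVA of vaccinated vs control titers.

    For each coated antigen, the vaccinated animals are those whose
    antigen_group is not the control; they are compared against the control
    animals measured on the same coated antigen, day by day.  Returns a table
    with F, p and a significance code ('' / '*' / '**').
    """
    rows = []
    by_antigen: dict[str, list[AntibodySeries]] = {}
    for s in series:
        by_antigen.setdefault(s.coated_antigen, []).append(s)
    for coated in sorted(by_antigen):
        ss = by_antigen[coated]
        controls = [s for s in ss if s.antigen_group == control_group]
        vaccinated = [s for s in ss if s.antigen_group != control_group]
        if not controls:
            raise ValueError(f"no control group series for coated antigen {coated!r}")
        days = sorted({d for s in ss for d in s.readings})
        for group in sorted({s.antigen_group for s in vaccinated}):
            for day in days:
                v = [s.readings[day] for s in vaccinated if s.antigen_group == group and day in s.readings]
                c = [s.readings[day] for s in controls if day in s.readings]
                if len(v) < 2 or len(c) < 2:
                    continue
                res = oneway_anova([v, c])
                code = "**" if res.p_value < strong_alpha else "*" if res.p_value < alpha else ""
                rows.append(
                    {
                        "coated_antigen": coated,
                        "antigen_group": group,
                        "day": day,
                        "F": res.statistic,
                        "p_value": res.p_value,
                        "significance": code,
                    }
                )
    return pd.DataFrame(rows)


def eligible_parameters(
    significance_by_antigen: Mapping[str, Mapping[StageParameter, bool]],
    min_formulations: int = 3,
) -> list[StageParameter]:
    """Parameters significant under at least ``min_formulations`` formulations.

    The correlate-of-protection analysis is restricted to parameters whose
    vaccinated-vs-control difference was significant for at least three of
    the vaccine formulations in the relevant (breed, tick species) cell.
    """
    counts: dict[StageParameter, int] = {}
    for flags in significance_by_antigen.values():
        for param, sig in flags.items():
            if sig:
                counts[param] = counts.get(param, 0) + 1
    return [p for p, n in counts.items() if n >= min_formulations]


def correlate_titers_stages(
    day60_titers: Mapping[str, float],
    stage_values: Mapping[StageParameter, Mapping[str, float]],
    mean_reductions: Mapping[StageParameter, float],
    alpha: float = 0.05,
    expected_n: int | None = 20,
) -> tuple[list[CorrelationOutcome], list[str]]:
    """Spearman rho between day-60 titers and per-animal stage values.

    One titer and one stage value per animal; all formulations (control
    included) are pooled.  Returns the outcomes plus any warnings (e.g. the
    pooled n differing from the design's expected 20).  Raw per-animal
    measurements — not group reductions — enter the correlation, so higher
    titer with fewer/lighter ticks gives rho < 0.
    """
    warnings: list[str] = []
    outcomes: list[CorrelationOutcome] = []
    for param, values in stage_values.items():
        animals = sorted(set(day60_titers) & set(values))
        animals = [a for a in animals if not math.isnan(values[a])]
        if expected_n is not None and len(animals) != expected_n:
            warnings.append(
                f"{param.value}: pooled n={len(animals)} differs from expected {expected_n}"
            )
        titers = [day60_titers[a] for a in animals]
        vals = [values[a] for a in animals]
        res = spearman_rho(titers, vals)  # raises TestUndefinedError on constant titers
        outcomes.append(
            CorrelationOutcome(
                parameter=param,
                rho=res.statistic,
                p_value=res.p_value,
                mean_reduction_pct=float(mean_reductions.get(param, math.nan)),
                significant_negative=(res.statistic < 0 and res.p_value <= alpha),
                n=len(animals),
            )
        )
    return outcomes, warnings


def reduction_threshold(
    outcomes: Sequence[CorrelationOutcome],
) -> tuple[float, bool] | None:
    """Smallest mean reduction showing a significant negative titer correlation.

    Returns ``(threshold_pct, separating)`` where ``separating`` is True when
    every outcome with a smaller mean reduction is non-significant (clean
    threshold behaviour), or ``None`` when no outcome is significant-negative.
    """
    sig = [o for o in outcomes if o.significant_negative]
    if not sig:
        return None
    threshold = min(o.mean_reduction_pct for o in sig)
    nonsig = [o for o in outcomes if not o.significant_negative]
    separating = all(o.mean_reduction_pct < threshold for o in nonsig)
    return threshold, separating
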