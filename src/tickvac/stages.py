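"""Stage-wise reduction estimators and the significance-gated cumulative efficacy index.

The protective effect of an anti-tick vaccine is scored per tick developmental
stage as a percent reduction in vaccinated versus control animals, and the
per-stage reductions are combined into a single cumulative vaccine efficacy E
by multiplying the corresponding *survival fractions*:

    E (%) = 100 * (1 - prod_i (1 - D_i / 100))

where the product runs over the stage parameters whose vaccinated-vs-control
difference passed a significance gate.  A stage that is not gated in
contributes a factor of 1 (no effect), so E is driven only by statistically
supported reductions.

Seven stage parameters are defined for three-host ticks (larval and nymphal
stages feed on separate hosts and are observable): engorgement counts of
larvae/nymphs/adult females (DL, DN, DA), molting success of larvae and nymphs
(DMn, DMa), oviposition measured as egg mass per surviving female (DO) and
egg fertility measured as larval mass per gram of eggs (DF).  One-host ticks
complete the immature stages on the host, so only DA, DO and DF are
observable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "StageClass",
    "StageParameter",
    "THREE_HOST_PARAMETERS",
    "ONE_HOST_PARAMETERS",
    "EARLY_STAGE_PARAMETERS",
    "GroupStageSummary",
    "ReductionEstimate",
    "EfficacyResult",
    "ReductionUndefinedError",
    "round_half_away",
    "stage_reduction",
    "cumulative_efficacy",
    "vaccine_efficacy",
    "count_affected_stages",
    "total_efficacy_by_antigen",
]


class ReductionUndefinedError(ValueError):
    """Raised when a reduction cannot be computed (degenerate control group)."""


class StageClass(enum.Enum):
    COUNT = "count"
    MOLTING = "molting"
    MASS_RATIO = "mass_ratio"


class StageParameter(enum.Enum):
    """One measurable tick life-stage parameter.

    ``stage_class`` decides which measured quantity pair enters the reduction
    formula (engorgement counts, molting proportions, or per-animal mass
    ratios); ``three_host_only`` marks the larval/nymphal parameters that a
    one-host species never exposes.
    """

    DL = "DL"
    DMN = "DMn"
    DN = "DN"
    DMA = "DMa"
    DA = "DA"
    DO = "DO"
    DF = "DF"

    @property
    def stage_class(self) -> StageClass:
        return _STAGE_CLASS[self]

    @property
    def three_host_only(self) -> bool:
        return self in (
            StageParameter.DL,
            StageParameter.DMN,
            StageParameter.DN,
            StageParameter.DMA,
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_STAGE_CLASS = {
    StageParameter.DL: StageClass.COUNT,
    StageParameter.DN: StageClass.COUNT,
    StageParameter.DA: StageClass.COUNT,
    StageParameter.DMN: StageClass.MOLTING,
    StageParameter.DMA: StageClass.MOLTING,
    StageParameter.DO: StageClass.MASS_RATIO,
    StageParameter.DF: StageClass.MASS_RATIO,
}

#: Parameters observable on a three-host tick (all seven, life-cycle order).
THREE_HOST_PARAMETERS: tuple[StageParameter, ...] = (
    StageParameter.DL,
    StageParameter.DMN,
    StageParameter.DN,
    StageParameter.DMA,
    StageParameter.DA,
    StageParameter.DO,
    StageParameter.DF,
)

#: Parameters observable on a one-host tick (adult-derived only).
ONE_HOST_PARAMETERS: tuple[StageParameter, ...] = (
    StageParameter.DA,
    StageParameter.DO,
    StageParameter.DF,
)

#: Early developmental stages of the three-host cycle.
EARLY_STAGE_PARAMETERS: tuple[StageParameter, ...] = (
    StageParameter.DL,
    StageParameter.DMN,
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class GroupStageSummary:
    """Group-level measured values for one stage parameter.

    ``vaccinated_value``/``control_value`` hold the quantity appropriate to the
    stage class: total engorged counts for count parameters, mean molting
    proportion for molting parameters, mean egg mass per female (g) for
    oviposition and mean larval mass per gram of eggs for fertility.
    """

    parameter: StageParameter
    vaccinated_value: float
    control_value: float
    n_vaccinated_animals: int = 4
    n_control_animals: int = 4

    def __post_init__(self) -> None:
        if self.vaccinated_value < 0 or self.control_value < 0:
            raise ValueError(
                f"{self.parameter.value}: measured values must be non-negative "
                f"(got vaccinated={self.vaccinated_value}, control={self.control_value})"
            )
        if self.n_vaccinated_animals < 1 or self.n_control_animals < 1:
            raise ValueError("each arm needs at least one animal")


@dataclass
class ReductionEstimate:
    """Percent reduction for one stage parameter, with its gating state.

    ``included`` may only be true for significant parameters (the gate).  A
    negative reduction (more ticks on vaccinated animals) is representable but
    is never auto-included by the pipeline.
    """

    parameter: StageParameter
    reduction_pct: float
    p_value: float | None = None
    significant: bool = False
    included: bool = False

    def __post_init__(self) -> None:
        if self.included and not self.significant:
            raise ValueError(
                f"{self.parameter.value}: a non-significant parameter cannot be included"
            )
        if self.reduction_pct > 100:
            raise ValueError(
                f"{self.parameter.value}: reduction cannot exceed 100% "
                f"(got {self.reduction_pct})"
            )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def survival_fraction(self) -> float:
        return 1.0 - self.reduction_pct / 100.0


@dataclass
class EfficacyResult:
    """Cumulative vaccine efficacy for one (antigen, breed, tick species) group."""

    antigen: str
    breed: str
    tick_species: str
    reductions: list[ReductionEstimate] = field(default_factory=list)

    @property
    def included_reductions(self) -> list[ReductionEstimate]:
        return [r for r in self.reductions if r.included]

    @property
    def efficacy_pct(self) -> float:
        return cumulative_efficacy(r.reduction_pct for r in self.included_reductions)

    @property
    def efficacy_rounded(self) -> int:
        return round_half_away(self.efficacy_pct)

    def reduction(self, parameter: StageParameter) -> ReductionEstimate | None:
        for r in self.reductions:
            if r.parameter is parameter:
                return r
        return None


def stage_reduction(summary: GroupStageSummary) -> ReductionEstimate:
    """Percent reduction 100*(1 - vaccinated/control) for one stage parameter.

    The same formula serves all stage classes; only the measured quantity pair
    differs.  The p-value and gating flags are filled in by the statistical
    gate afterwards.

    Raises
    ------
    ReductionUndefinedError
        If the control value is zero (the ratio is undefined, signalling a
        degenerate control group).
    """
    if summary.control_value == 0:
        raise ReductionUndefinedError(
            f"{summary.parameter.value}: control value is zero; reduction undefined"
        )
    pct = 100.0 * (1.0 - summary.vaccinated_value / summary.control_value)
    return ReductionEstimate(parameter=summary.parameter, reduction_pct=pct)


def cumulative_efficacy(reduction_pcts: Iterable[float]) -> float:
    """Combine percent reductions into cumulative efficacy via survival fractions.

    ``E = 100*(1 - prod(1 - D/100))``; an empty input gives 0 (empty product).
    """
    survival = 1.0
    for d in reduction_pcts:
        if d > 100:
            raise ValueError(f"included reduction above 100%: {d}")
        survival *= 1.0 - d / 100.0
    return 100.0 * (1.0 - survival)


def vaccine_efficacy(
    reductions: Sequence[ReductionEstimate],
    *,
    antigen: str = "",
    breed: str = "",
    tick_species: str = "",
    printed_integer_mode: bool = False,
) -> EfficacyResult:
    """Build an :class:`EfficacyResult` from gated reduction estimates.

    Excluded parameters contribute a factor of 1.  With
    ``printed_integer_mode`` the product is taken over reductions rounded to
    integer percent first — the convention of published summary tables, kept
    for regression against reported values.
    """
    if printed_integer_mode:
        reductions = [
            ReductionEstimate(
                parameter=r.parameter,
                reduction_pct=float(round_half_away(r.reduction_pct)),
                p_value=r.p_value,
                significant=r.significant,
                included=r.included,
            )
            for r in reductions
        ]
    result = EfficacyResult(
        antigen=antigen,
        breed=breed,
        tick_species=tick_species,
        reductions=list(reductions),
    )
    # surfaces the >100% validation eagerly
    _ = result.efficacy_pct
    return result


def _applicable_parameters(result: EfficacyResult) -> tuple[StageParameter, ...]:
    params = tuple(r.parameter for r in result.reductions)
    if all(not p.three_host_only for p in params):
        return ONE_HOST_PARAMETERS
    return THREE_HOST_PARAMETERS


_GROUP_KEYS = {
    "antigen": lambda r: r.antigen,
    "tick_species": lambda r: r.tick_species,
    "breed": lambda r: r.breed,
}


def count_affected_stages(
    results: Sequence[EfficacyResult],
    by: str = "antigen",
    early_stages: bool = False,
) -> pd.DataFrame:
    """Count gated-in stage parameters per grouping (numerator / denominator).

    The denominator is the number of parameters observable in the grouped
    results (7 per three-host group, 3 per one-host group); with
    ``early_stages`` the count is restricted to DL and DMn over three-host
    groups (2 per group).  Requires a consistent factorial design: every
    grouping level must cover the same (breed, tick species) cells.
    """
    if by not in _GROUP_KEYS:
        raise ValueError(f"unknown grouping {by!r}; choose from {sorted(_GROUP_KEYS)}")
    key = _GROUP_KEYS[by]

    cells: dict[str, set[tuple[str, str]]] = {}
    for r in results:
        cells.setdefault(key(r), set()).add((r.breed, r.tick_species))
    if by == "antigen":
        universe = set.union(*cells.values()) if cells else set()
        missing = {
            level: sorted(universe - seen) for level, seen in cells.items() if seen != universe
        }
        if missing:
            raise ValueError(f"inconsistent factorial design; missing cells: {missing}")

    rows = []
    for level in sorted(cells):
        num = den = 0
        for r in results:
            if key(r) != level:
                continue
            params = _applicable_parameters(r)
            if early_stages:
                if params is ONE_HOST_PARAMETERS:
                    continue
                params = EARLY_STAGE_PARAMETERS
            den += len(params)
            num += sum(
                1
                for est in r.reductions
                if est.included and est.parameter in params
            )
        rows.append({by: level, "affected": num, "possible": den, "fraction": num / den if den else float("nan")})
    return pd.DataFrame(rows).set_index(by)


def total_efficacy_by_antigen(
    results: Sequence[EfficacyResult], *, use_rounded: bool = True
) -> pd.DataFrame:
    """Arithmetic mean efficacy per antigen over its (breed, tick species) groups.

    ``use_rounded`` averages the integer-rounded group efficacies, matching
    the convention of summary tables where group E is reported in whole
    percent; set it False to average unrounded values.
    """
    groups: dict[str, list[float]] = {}
    for r in results:
        e = float(r.efficacy_rounded) if use_rounded else r.efficacy_pct
        groups.setdefault(r.antigen, []).append(e)
    if not groups:
        raise ValueError("no results to aggregate")
    rows = []
    for antigen in sorted(groups):
        vals = groups[antigen]
        mean = sum(vals) / len(vals)
        rows.append(
            {
                "antigen": antigen,
                "n_groups": len(vals),
                "mean_efficacy_pct": mean,
                "mean_efficacy_rounded": round_half_away(mean),
            }
        )
    return pd.DataFrame(rows).set_index("antigen")
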