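"""Per-animal tick life-stage records and the group summaries derived from them.

An :class:`AnimalStageRecord` holds the outcome of one animal's challenge with
one tick species: how many ticks of each stage were applied, how many engorged
and molted, plus the oviposition and fertility masses.  One-host species carry
only the adult-derived fields (the immature stages complete on the host and
are unobservable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .stages import GroupStageSummary, StageClass, StageParameter

__all__ = [
    "AnimalStageRecord",
    "animal_stage_value",
    "success_trial_totals",
    "summarize_group",
]


def _chain_ok(applied, engorged, molted=None) -> bool:
    if applied is None or engorged is None:
        return True
    if engorged > applied:
        return False
    if molted is not None and molted > engorged:
        return False
    return True


@dataclass
class AnimalStageRecord:
    """Observed tick outcomes for one animal and one tick species.

    Larval/nymphal fields are ``None`` for one-host species.  Chain
    consistency (applied >= engorged >= molted) is validated on construction.
    """

    animal_id: str
    breed: str
    antigen_group: str
    tick_species: str
    females_applied: int
    females_engorged: int
    egg_mass_g: float  # total egg mass over engorged females
    larval_mass_per_g_eggs_g: float  # grams of hatched larvae per gram of eggs
    larvae_applied: int | None = None
    larvae_engorged: int | None = None
    larvae_molted: int | None = None
    nymphs_applied: int | None = None
    nymphs_engorged: int | None = None
    nymphs_molted: int | None = None

    def __post_init__(self) -> None:
        if not _chain_ok(self.larvae_applied, self.larvae_engorged, self.larvae_molted):
            raise ValueError(f"{self.animal_id}: larval chain violates applied >= engorged >= molted")
        if not _chain_ok(self.nymphs_applied, self.nymphs_engorged, self.nymphs_molted):
            raise ValueError(f"{self.animal_id}: nymphal chain violates applied >= engorged >= molted")
        if not _chain_ok(self.females_applied, self.females_engorged):
            raise ValueError(f"{self.animal_id}: engorged females exceed applied females")
        if self.egg_mass_g < 0 or self.larval_mass_per_g_eggs_g < 0:
            raise ValueError(f"{self.animal_id}: masses must be non-negative")

    @property
    def is_one_host(self) -> bool:
        return self.larvae_applied is None


_COUNT_FIELDS = {
    StageParameter.DL: ("larvae_engorged", "larvae_applied"),
    StageParameter.DN: ("nymphs_engorged", "nymphs_applied"),
    StageParameter.DA: ("females_engorged", "females_applied"),
}
_MOLT_FIELDS = {
    StageParameter.DMN: ("larvae_molted", "larvae_engorged"),
    StageParameter.DMA: ("nymphs_molted", "nymphs_engorged"),
}


def animal_stage_value(record: AnimalStageRecord, parameter: StageParameter) -> float:
    """One animal's value of a stage parameter, on its natural scale.

    Counts for DL/DN/DA; molting proportion for DMn/DMa; egg mass per
    engorged female (g) for DO; larval mass per gram of eggs for DF.  NaN when
    the denominator of a ratio is zero.
    """
    if parameter in _COUNT_FIELDS:
        value = getattr(record, _COUNT_FIELDS[parameter][0])
        if value is None:
            raise ValueError(f"{parameter.value} not observable for {record.tick_species}")
        return float(value)
    if parameter in _MOLT_FIELDS:
        num_f, den_f = _MOLT_FIELDS[parameter]
        num, den = getattr(record, num_f), getattr(record, den_f)
        if num is None or den is None:
            raise ValueError(f"{parameter.value} not observable for {record.tick_species}")
        return num / den if den else math.nan
    if parameter is StageParameter.DO:
        return record.egg_mass_g / record.females_engorged if record.females_engorged else math.nan
    if parameter is StageParameter.DF:
        return record.larval_mass_per_g_eggs_g
    raise ValueError(f"unknown parameter {parameter}")


def success_trial_totals(
    records: Sequence[AnimalStageRecord],
    parameter: StageParameter,
    mass_unit_scale: float = 1000.0,
) -> tuple[int, int]:
    """Pooled (successes, trials) across an arm, for the 2x2 chi-square gate.

    Count parameters pool engorged over applied; molting pools molted over
    engorged.  Mass parameters are converted to integer pseudo-counts: for DO,
    successes are the total egg mass in ``mass_unit_scale`` units per gram
    (default milligrams) against a 1 g-per-female ceiling; for DF, total
    hatched-larval mass units against total egg mass units.
    """
    cls = parameter.stage_class
    if cls is StageClass.COUNT:
        s_field, t_field = _COUNT_FIELDS[parameter]
    elif cls is StageClass.MOLTING:
        s_field, t_field = _MOLT_FIELDS[parameter]
    else:
        if parameter is StageParameter.DO:
            eggs = sum(r.egg_mass_g for r in records)
            females = sum(r.females_engorged for r in records)
            return round(eggs * mass_unit_scale), round(females * mass_unit_scale)
        larvae = sum(r.larval_mass_per_g_eggs_g * r.egg_mass_g for r in records)
        eggs = sum(r.egg_mass_g for r in records)
        return round(larvae * mass_unit_scale), round(eggs * mass_unit_scale)
    successes = trials = 0
    for r in records:
        s, t = getattr(r, s_field), getattr(r, t_field)
        if s is None or t is None:
            raise ValueError(f"{parameter.value} not observable for {r.tick_species}")
        successes += s
        trials += t
    return successes, trials


def summarize_group(
    vaccinated: Sequence[AnimalStageRecord],
    control: Sequence[AnimalStageRecord],
    parameter: StageParameter,
) -> GroupStageSummary:
    """Group-level measured pair for the reduction formula.

    Count parameters compare total engorged ticks; molting and mass parameters
    compare the arm means of the per-animal values (average molting, average
    egg mass per surviving female, average larval mass per gram of eggs).
    Animals with an undefined ratio (zero denominator) drop out of the mean.
    """
    if parameter.stage_class is StageClass.COUNT:
        v = float(sum(animal_stage_value(r, parameter) for r in vaccinated))
        c = float(sum(animal_stage_value(r, parameter) for r in control))
    else:
        def _mean(recs: Sequence[AnimalStageRecord]) -> float:
            vals = [animal_stage_value(r, parameter) for r in recs]
            vals = [x for x in vals if not math.isnan(x)]
            return sum(vals) / len(vals) if vals else math.nan
        v, c = _mean(vaccinated), _mean(control)
        if math.isnan(v) or math.isnan(c):
            raise ValueError(f"{parameter.value}: no animal with a defined value in one arm")
    return GroupStageSummary(
        parameter=parameter,
        vaccinated_value=v,
        control_value=c,
        n_vaccinated_animals=len(vaccinated),
        n_control_animals=len(control),
    )
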