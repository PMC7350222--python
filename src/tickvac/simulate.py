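"""Synthetic trial generator mirroring the reference study design.

The generator produces complete trials — per-animal tick stage outcomes and
OD450 antibody trajectories — under configurable per-stage vaccine effects,
so every downstream analysis (gating, efficacy, correlates) can be exercised
with known ground truth.

Design defaults follow the reference trial: 2 breeds x 5 vaccine groups
(3 single antigens, the combination, adjuvant control) x 4 animals; a
three-host challenge of ~300 larvae, 200 nymphs per ear and 30 adults at a
1 male : 3 female ratio for *R. appendiculatus* and *A. variegatum*; a
one-host challenge of ~300 larvae for *R. decoloratus* (crossbred cattle
only); vaccination on days 0/30/60 and bleeds on days 0/30/45/60 and at the
end of the experiment.

Counts are drawn as beta-binomial chains (applied -> engorged -> molted) with
the vaccinated success probability scaled by (1 - effect); masses are
log-normal with the vaccinated mean scaled the same way.  A titer->protection
link (off by default) makes an animal's realized effect scale with its
day-60 titer, for exercising the correlate-of-protection analysis under both
null and alternative.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AnimalStageRecord
from .reference import (
    ANTIGENS,
    BREEDS,
    CONTROL_GROUP,
    ONE_HOST_SPECIES,
    THREE_HOST_SPECIES,
    reference_effect_sizes,
)
from .serology import AntibodySeries
from .stages import StageParameter

__all__ = [
    "TickChallenge",
    "BaselineRates",
    "Dispersion",
    "TiterModel",
    "TrialConfig",
    "TrialData",
    "simulate_trial",
    "simulate_antibody_series",
    "simulate_stage_record",
    "simulate_arm_pair",
]

_P = StageParameter


@dataclass(frozen=True)
class TickChallenge:
    """Numbers of ticks applied per animal (three-host protocol)."""

    larvae_applied: int = 300
    nymphs_per_ear: int = 200
    nymphs_both_ears: bool = True  # analysis totals per animal (2 ears) vs per ear
    adults_applied: int = 30
    female_fraction: float = 0.75  # one male per three females

    @property
    def nymphs_applied(self) -> int:
        return self.nymphs_per_ear * (2 if self.nymphs_both_ears else 1)

    @property
    def females_applied(self) -> int:
        return int(self.adults_applied * self.female_fraction)


@dataclass(frozen=True)
class BaselineRates:
    """Control-arm per-stage success probabilities and mass means.

    Field-realistic values for Rhipicephalus/Amblyomma challenge infestations:
    roughly half the applied immatures engorge, most engorged ticks molt,
    engorged females lay ~0.25 g of eggs each, and about half of the egg mass
    converts to hatched larvae.  One-host larvae suffer heavy attrition across
    the full on-host development.
    """

    p_engorge_larva: float = 0.5
    p_molt_larva: float = 0.8
    p_engorge_nymph: float = 0.5
    p_molt_nymph: float = 0.8
    p_engorge_female: float = 0.7
    p_onehost_to_female: float = 0.2  # applied larva -> engorged adult female
    egg_mass_per_female_g: float = 0.25
    larval_mass_per_g_eggs: float = 0.5


@dataclass(frozen=True)
class Dispersion:
    """Extra-binomial variation: intra-animal correlation for counts (shared
    husbandry overdisperses 4-animal arms) and coefficient of variation for
    masses.  Both may be set to 0 for exact binomial/constant sampling."""

    icc: float = 0.02
    mass_cv: float = 0.15


@dataclass(frozen=True)
class TiterModel:
    """OD450 trajectory model: baseline plus per-dose increments with slow
    exponential decay, per-animal response heterogeneity and reading noise.
    ``third_dose_decline`` makes the third dose lower the titer (a documented
    mode of the reference data).  ``link_strength`` in [0, 1] couples an
    animal's realized protection to its day-60 titer (0 = no coupling)."""

    baseline_od: float = 0.2
    dose_increments: tuple[float, ...] = (0.45, 0.45, 0.15)
    decline_increments: tuple[float, ...] = (0.45, 0.45, -0.25)
    decay_per_day: float = 0.002
    response_cv: float = 0.2
    noise_sd: float = 0.05
    cross_reactivity: float = 0.8
    third_dose_decline: bool = False
    link_strength: float = 0.0


@dataclass(frozen=True)
class TrialConfig:
    """Full generator configuration; defaults reproduce the reference design."""

    breeds: tuple[str, ...] = BREEDS
    antigens: tuple[str, ...] = ANTIGENS
    control_group: str = CONTROL_GROUP
    animals_per_group: int = 4
    three_host_species: tuple[str, ...] = THREE_HOST_SPECIES
    one_host_species: tuple[str, ...] = ONE_HOST_SPECIES
    onehost_excluded_breeds: tuple[str, ...] = ("B. indicus",)
    challenge: TickChallenge = TickChallenge()
    baseline: BaselineRates = BaselineRates()
    dispersion: Dispersion = Dispersion()
    titer: TiterModel = TiterModel()
    # (antigen, tick species, parameter) -> effect in [0, 1]; None = reference
    effect_sizes: Mapping[tuple[str, str, StageParameter], float] | None = None
    vaccination_days: tuple[int, ...] = (0, 30, 60)
    bleed_days: tuple[int, ...] = (0, 30, 45, 60)
    end_day: Mapping[str, int] = field(
        default_factory=lambda: {"B. indicus": 180, "crossbred": 195}
    )
    dose_ug: float = 100.0  # metadata only; does not enter the simulation
    seed: int = 0

    def resolved_effects(self) -> dict[tuple[str, str, StageParameter], float]:
        effects = dict(reference_effect_sizes() if self.effect_sizes is None else self.effect_sizes)
        for e in effects.values():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"effect sizes must lie in [0, 1]; got {e}")
        return effects

    def effect(self, antigen: str, species: str, parameter: StageParameter) -> float:
        if antigen == self.control_group:
            return 0.0
        return self._effects.get((antigen, species, parameter), 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_effects", self.resolved_effects())

    def species_for(self, breed: str) -> tuple[str, ...]:
        one_host = () if breed in self.onehost_excluded_breeds else self.one_host_species
        return self.three_host_species + one_host

    def schedule_for(self, breed: str) -> tuple[int, ...]:
        return self.bleed_days + (self.end_day.get(breed, max(self.bleed_days)),)


@dataclass
class TrialData:
    """A complete simulated trial."""

    stage_records: list[AnimalStageRecord]
    serology: list[AntibodySeries]
    config: TrialConfig

    def stage_frame(self) -> pd.DataFrame:
        from .io import stage_records_to_frame

        return stage_records_to_frame(self.stage_records)

    def serology_frame(self) -> pd.DataFrame:
        from .io import serology_to_frame

        return serology_to_frame(self.serology)


def _beta_binomial(rng: np.random.Generator, n: int, p: float, icc: float) -> int:
    if n <= 0 or p <= 0:
        return 0
    if p >= 1:
        return n
    if icc <= 0:
        return int(rng.binomial(n, p))
    s = (1.0 - icc) / icc
    p_i = rng.beta(p * s, (1.0 - p) * s)
    return int(rng.binomial(n, p_i))


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0:
        return 0.0
    if cv <= 0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _deterministic_response(titer: TiterModel, config: TrialConfig, day: int, factor: float) -> float:
    """Noise-free vaccinated titer rise at ``day`` (doses strictly before it)."""
    incs = titer.decline_increments if titer.third_dose_decline else titer.dose_increments
    r = 0.0
    for dose_day, inc in zip(config.vaccination_days, incs):
        if dose_day < day:
            r += inc * math.exp(-titer.decay_per_day * (day - dose_day))
    return factor * r


def simulate_antibody_series(
    config: TrialConfig,
    antigen_group: str,
    coated_antigen: str,
    animal_id: str,
    rng: np.random.Generator,
    breed: str | None = None,
    response_scale: float | None = None,
) -> AntibodySeries:
    """One animal's OD450 trajectory against one coated antigen.

    Control animals fluctuate around the baseline OD; vaccinated animals rise
    after each dose (homologous coatings respond fully, heterologous at the
    cross-reactivity factor).  Readings are clipped at 0.
    """
    tm = config.titer
    schedule = config.schedule_for(breed) if breed is not None else config.bleed_days
    if antigen_group == config.control_group:
        factor = 0.0
    elif antigen_group == coated_antigen or "combined" in antigen_group:
        factor = 1.0
    else:
        factor = tm.cross_reactivity
    if response_scale is None:
        response_scale = _lognormal(rng, 1.0, tm.response_cv)
    readings = {}
    for day in schedule:
        od = (
            tm.baseline_od
            + _deterministic_response(tm, config, day, factor * response_scale)
            + (rng.normal(0.0, tm.noise_sd) if tm.noise_sd > 0 else 0.0)
        )
        readings[day] = max(od, 0.0)
    return AntibodySeries(
        animal_id=animal_id,
        antigen_group=antigen_group,
        coated_antigen=coated_antigen,
        readings=readings,
    )


def simulate_stage_record(
    config: TrialConfig,
    breed: str,
    antigen_group: str,
    species: str,
    animal_id: str,
    rng: np.random.Generator,
    effect_scale: float = 1.0,
) -> AnimalStageRecord:
    """One animal's tick outcomes for one species under the configured effects.

    ``effect_scale`` multiplies every stage effect for this animal (the
    titer->protection link); 1 reproduces the group-level configured effect.
    """
    b, ch, disp = config.baseline, config.challenge, config.dispersion

    def eff(param: StageParameter) -> float:
        return min(max(config.effect(antigen_group, species, param) * effect_scale, 0.0), 1.0)

    one_host = species in config.one_host_species
    if one_host:
        # female share of the applied larvae (1:1 sex ratio in eggs); the
        # immature stages complete unobserved on the host
        females_applied = ch.larvae_applied // 2
        females_engorged = _beta_binomial(
            rng, females_applied, b.p_onehost_to_female * (1.0 - eff(_P.DA)), disp.icc
        )
        larv = dict(
            larvae_applied=None, larvae_engorged=None, larvae_molted=None,
            nymphs_applied=None, nymphs_engorged=None, nymphs_molted=None,
        )
    else:
        larvae_engorged = _beta_binomial(
            rng, ch.larvae_applied, b.p_engorge_larva * (1.0 - eff(_P.DL)), disp.icc
        )
        larvae_molted = _beta_binomial(
            rng, larvae_engorged, b.p_molt_larva * (1.0 - eff(_P.DMN)), disp.icc
        )
        nymphs_engorged = _beta_binomial(
            rng, ch.nymphs_applied, b.p_engorge_nymph * (1.0 - eff(_P.DN)), disp.icc
        )
        nymphs_molted = _beta_binomial(
            rng, nymphs_engorged, b.p_molt_nymph * (1.0 - eff(_P.DMA)), disp.icc
        )
        females_applied = ch.females_applied
        females_engorged = _beta_binomial(
            rng, females_applied, b.p_engorge_female * (1.0 - eff(_P.DA)), disp.icc
        )
        larv = dict(
            larvae_applied=ch.larvae_applied,
            larvae_engorged=larvae_engorged,
            larvae_molted=larvae_molted,
            nymphs_applied=ch.nymphs_applied,
            nymphs_engorged=nymphs_engorged,
            nymphs_molted=nymphs_molted,
        )

    mean_egg = b.egg_mass_per_female_g * (1.0 - eff(_P.DO))
    egg_per_female = _lognormal(rng, mean_egg, disp.mass_cv)
    egg_mass = egg_per_female * females_engorged
    mean_fert = b.larval_mass_per_g_eggs * (1.0 - eff(_P.DF))
    fert = _lognormal(rng, mean_fert, disp.mass_cv) if egg_mass > 0 else 0.0

    return AnimalStageRecord(
        animal_id=animal_id,
        breed=breed,
        antigen_group=antigen_group,
        tick_species=species,
        females_applied=females_applied,
        females_engorged=females_engorged,
        egg_mass_g=egg_mass,
        larval_mass_per_g_eggs_g=fert,
        **larv,
    )


def simulate_trial(config: TrialConfig = TrialConfig()) -> TrialData:
    """Simulate a full trial: stage records and serology for every animal.

    Deterministic for a fixed config+seed.  Serology is generated first so
    that, when the titer link is on, each animal's realized stage effects can
    scale with its day-60 titer.
    """
    rng = np.random.default_rng(config.seed)
    records: list[AnimalStageRecord] = []
    serology: list[AntibodySeries] = []
    tm = config.titer
    peak = tm.baseline_od + _deterministic_response(tm, config, 60, 1.0)

    for breed in config.breeds:
        for group in (*config.antigens, config.control_group):
            for k in range(config.animals_per_group):
                animal_id = f"{breed}|{group}|{k + 1}"
                response_scale = _lognormal(rng, 1.0, tm.response_cv)
                own_od60 = tm.baseline_od + _deterministic_response(
                    tm, config, 60, (0.0 if group == config.control_group else 1.0) * response_scale
                )
                for coated in config.antigens:
                    serology.append(
                        simulate_antibody_series(
                            config, group, coated, animal_id, rng,
                            breed=breed, response_scale=response_scale,
                        )
                    )
                if tm.link_strength > 0:
                    f = own_od60 / peak
                    effect_scale = (1.0 - tm.link_strength) + tm.link_strength * f
                else:
                    effect_scale = 1.0
                for species in config.species_for(breed):
                    records.append(
                        simulate_stage_record(
                            config, breed, group, species, animal_id, rng,
                            effect_scale=effect_scale,
                        )
                    )
    return TrialData(stage_records=records, serology=serology, config=config)


def simulate_arm_pair(
    config: TrialConfig,
    species: str,
    effects: Mapping[StageParameter, float],
    rng: np.random.Generator,
    breed: str = "crossbred",
) -> tuple[list[AnimalStageRecord], list[AnimalStageRecord]]:
    """A single vaccinated/control arm pair with explicit per-parameter effects.

    Convenience for calibration studies: avoids simulating the full factorial
    when only one (species, effect) condition is of interest.
    """
    antigen = "arm"
    cfg = dataclasses.replace(
        config,
        antigens=(antigen,),
        effect_sizes={(antigen, species, p): e for p, e in effects.items()},
    )
    vacc = [
        simulate_stage_record(cfg, breed, antigen, species, f"v{k + 1}", rng)
        for k in range(cfg.animals_per_group)
    ]
    ctrl = [
        simulate_stage_record(cfg, breed, cfg.control_group, species, f"c{k + 1}", rng)
        for k in range(cfg.animals_per_group)
    ]
    return vacc, ctrl
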