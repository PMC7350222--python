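"""End-to-end trial analysis: gated reductions -> efficacy -> correlates -> report.

``run_pipeline`` ties the stages together for a dataset that is either
simulated from a :class:`~tickvac.simulate.TrialConfig` or loaded from the
CSV schemas: per-group significance gating and stage reductions, cumulative
efficacy per (antigen, breed, tick species), stage-coverage accounting,
per-antigen mean efficacy, the between-breed comparison of group efficacies
(Welch), the antibody timecourse ANOVA, the titer-outcome correlation with
threshold detection, and the summary report.  Every gating decision is
recorded in a machine-readable log so the stars in the report are auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import RunManifest
from .records import AnimalStageRecord, animal_stage_value, summarize_group
from .report import write_report
from .serology import (
    AntibodySeries,
    CorrelationOutcome,
    correlate_titers_stages,
    eligible_parameters,
    reduction_threshold,
    titer_timecourse_test,
)
from .simulate import TrialConfig, simulate_trial
from .stages import (
    EfficacyResult,
    ONE_HOST_PARAMETERS,
    StageParameter,
    THREE_HOST_PARAMETERS,
    count_affected_stages,
    stage_reduction,
    total_efficacy_by_antigen,
    vaccine_efficacy,
)
from .stats import GateConfig, TestUndefinedError, chi_square_gate, welch_t

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("tickvac")

#: genus prefix of the species whose per-animal outcomes enter the
#: correlate-of-protection analysis in the reference design
_CORRELATE_GENUS = "R."


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    efficacy_results: list[EfficacyResult]
    gate_log: pd.DataFrame
    coverage_by_antigen: pd.DataFrame
    coverage_early: pd.DataFrame
    antigen_totals: pd.DataFrame
    breed_comparison: pd.DataFrame
    timecourse: pd.DataFrame
    correlation_outcomes: dict[tuple[str, str], list[CorrelationOutcome]]
    threshold: tuple[float, bool] | None
    report_text: str
    manifest: RunManifest | None = None
    warnings: list[str] = field(default_factory=list)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _group_records(
    records: Sequence[AnimalStageRecord], control_group: str
) -> tuple[dict[tuple[str, str, str], list[AnimalStageRecord]], dict[tuple[str, str], list[AnimalStageRecord]]]:
    vaccinated: dict[tuple[str, str, str], list[AnimalStageRecord]] = {}
    controls: dict[tuple[str, str], list[AnimalStageRecord]] = {}
    for r in records:
        if r.antigen_group == control_group:
            controls.setdefault((r.breed, r.tick_species), []).append(r)
        else:
            vaccinated.setdefault((r.antigen_group, r.breed, r.tick_species), []).append(r)
    return vaccinated, controls


def run_pipeline(
    config: TrialConfig | None = None,
    *,
    stage_records: Sequence[AnimalStageRecord] | None = None,
    serology: Sequence[AntibodySeries] | None = None,
    control_group: str = "adjuvant control",
    gate: GateConfig = GateConfig(),
    printed_integer_mode: bool = False,
    correlate_coated_antigen: str = "R. appendiculatus SUB",
    correlate_day: int = 60,
    min_formulations: int = 3,
    input_paths: Sequence[str] = (),
) -> PipelineResult:
    """Run the full analysis; simulate the trial if no records are given."""
    warnings: list[str] = []
    if stage_records is None:
        with _stage("simulate"):
            if config is None:
                config = TrialConfig()
            data = simulate_trial(config)
            stage_records, serology = data.stage_records, data.serology
            control_group = config.control_group
    serology = list(serology or [])

    with _stage("gate"):
        vacc_groups, ctrl_groups = _group_records(stage_records, control_group)
        results: list[EfficacyResult] = []
        log_rows = []
        for (antigen, breed, species), group in sorted(vacc_groups.items()):
            ctrl = ctrl_groups.get((breed, species))
            if not ctrl:
                raise ValueError(f"no control animals for ({breed}, {species})")
            one_host = group[0].is_one_host
            params = ONE_HOST_PARAMETERS if one_host else THREE_HOST_PARAMETERS
            reductions = []
            for param in params:
                est = stage_reduction(summarize_group(group, ctrl, param))
                try:
                    test, significant = chi_square_gate(group, ctrl, param, gate)
                except TestUndefinedError as exc:
                    warnings.append(f"{antigen}/{breed}/{species}/{param.value}: {exc}")
                    test, significant = None, False
                est.p_value = min(max(test.p_value, 0.0), 1.0) if test else None
                est.significant = significant
                est.included = significant and (est.reduction_pct > 0 or gate.include_harmful)
                logger.info(
                    "gate %s/%s/%s %s: reduction=%.1f%% p=%s significant=%s included=%s",
                    antigen, breed, species, param.value, est.reduction_pct,
                    f"{test.p_value:.4g}" if test else "NA", significant, est.included,
                )
                log_rows.append(
                    {
                        "antigen": antigen,
                        "breed": breed,
                        "tick_species": species,
                        "parameter": param.value,
                        "reduction_pct": est.reduction_pct,
                        "statistic": test.statistic if test else math.nan,
                        "p_value": test.p_value if test else math.nan,
                        "significant": significant,
                        "included": est.included,
                        "warning": test.warning if test else "test undefined",
                    }
                )
                reductions.append(est)
            results.append(
                vaccine_efficacy(
                    reductions,
                    antigen=antigen,
                    breed=breed,
                    tick_species=species,
                    printed_integer_mode=printed_integer_mode,
                )
            )
        gate_log = pd.DataFrame(log_rows)

    with _stage("coverage"):
        coverage = count_affected_stages(results, by="antigen")
        coverage_early = count_affected_stages(results, by="antigen", early_stages=True)
        totals = total_efficacy_by_antigen(results)

    with _stage("breed_comparison"):
        rows = []
        antigens = sorted({r.antigen for r in results})
        breeds = sorted({r.breed for r in results})
        if len(breeds) == 2:
            for antigen in antigens:
                samples = {
                    b: [float(r.efficacy_rounded) for r in results if r.antigen == antigen and r.breed == b]
                    for b in breeds
                }
                a, b = (samples[breeds[0]], samples[breeds[1]])
                if len(a) >= 2 and len(b) >= 2:
                    try:
                        t = welch_t(a, b)
                        rows.append(
                            {
                                "antigen": antigen,
                                "breed_a": breeds[0],
                                "breed_b": breeds[1],
                                "mean_a": sum(a) / len(a),
                                "mean_b": sum(b) / len(b),
                                "statistic": t.statistic,
                                "p_value": t.p_value,
                                "df": t.df,
                            }
                        )
                    except TestUndefinedError as exc:
                        warnings.append(f"breed comparison {antigen}: {exc}")
        breed_comparison = pd.DataFrame(rows)

    with _stage("serology"):
        timecourse = (
            titer_timecourse_test(serology, control_group=control_group, alpha=gate.alpha)
            if serology
            else pd.DataFrame()
        )

    with _stage("correlates"):
        correlation_outcomes: dict[tuple[str, str], list[CorrelationOutcome]] = {}
        all_outcomes: list[CorrelationOutcome] = []
        titers = {
            s.animal_id: s.readings[correlate_day]
            for s in serology
            if s.coated_antigen == correlate_coated_antigen and correlate_day in s.readings
        }
        if titers:
            cells = sorted(
                {
                    (r.breed, r.tick_species)
                    for r in stage_records
                    if r.tick_species.startswith(_CORRELATE_GENUS)
                }
            )
            for breed, species in cells:
                cell_results = [r for r in results if r.breed == breed and r.tick_species == species]
                sig_flags = {
                    r.antigen: {e.parameter: e.significant for e in r.reductions}
                    for r in cell_results
                }
                params = eligible_parameters(sig_flags, min_formulations=min_formulations)
                if not params:
                    continue
                cell_records = [
                    r
                    for r in stage_records
                    if r.breed == breed and r.tick_species == species
                ]
                stage_values: dict[StageParameter, dict[str, float]] = {
                    p: {r.animal_id: animal_stage_value(r, p) for r in cell_records}
                    for p in params
                }
                mean_reductions = {
                    p: sum(r.reduction(p).reduction_pct for r in cell_results) / len(cell_results)
                    for p in params
                }
                expected = 20 if len(cell_results) == 4 else None
                try:
                    outcomes, warns = correlate_titers_stages(
                        titers, stage_values, mean_reductions,
                        alpha=gate.alpha, expected_n=expected,
                    )
                except TestUndefinedError as exc:
                    warnings.append(f"correlates {breed}/{species}: {exc}")
                    continue
                warnings.extend(f"{breed}/{species}: {w}" for w in warns)
                correlation_outcomes[(breed, species)] = outcomes
                all_outcomes.extend(outcomes)
        threshold = reduction_threshold(all_outcomes) if all_outcomes else None

    with _stage("report"):
        report_text = write_report(results)

    manifest = RunManifest.create(
        config, seed=getattr(config, "seed", 0), alpha=gate.alpha,
        gate_method=gate.gate_method, input_paths=input_paths,
    )
    return PipelineResult(
        efficacy_results=results,
        gate_log=gate_log,
        coverage_by_antigen=coverage,
        coverage_early=coverage_early,
        antigen_totals=totals,
        breed_comparison=breed_comparison,
        timecourse=timecourse,
        correlation_outcomes=correlation_outcomes,
        threshold=threshold,
        report_text=report_text,
        manifest=manifest,
        warnings=warnings,
    )
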