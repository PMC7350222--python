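"""Synthetic trial generator: determinism, chain consistency, calibration."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import ks_2samp

from tickvac import (
    BaselineRates,
    Dispersion,
    StageParameter,
    TickChallenge,
    TiterModel,
    TrialConfig,
    reference_trial_results,
    simulate_antibody_series,
    simulate_arm_pair,
    simulate_trial,
)
from tickvac.reference import REFERENCE_REDUCTIONS
from tickvac.report import report_frame
from tickvac.stages import stage_reduction
from tickvac.records import summarize_group

P = StageParameter


def _small_config(**kw):
    defaults = dict(
        breeds=("crossbred",),
        antigens=("a1",),
        effect_sizes={},
        animals_per_group=2,
        seed=9,
    )
    defaults.update(kw)
    return TrialConfig(**defaults)


class TestDeterminism:
    def test_same_seed_same_data(self):
        cfg = TrialConfig(seed=123)
        d1, d2 = simulate_trial(cfg), simulate_trial(cfg)
        assert d1.stage_frame().to_csv() == d2.stage_frame().to_csv()
        assert d1.serology_frame().to_csv() == d2.serology_frame().to_csv()

    def test_seed_changes_data(self):
        a = simulate_trial(TrialConfig(seed=1)).stage_frame().to_csv()
        b = simulate_trial(TrialConfig(seed=2)).stage_frame().to_csv()
        assert a != b

    def test_dose_metadata_does_not_change_data(self):
        a = simulate_trial(TrialConfig(seed=1, dose_ug=100.0)).stage_frame().to_csv()
        b = simulate_trial(TrialConfig(seed=1, dose_ug=50.0)).stage_frame().to_csv()
        assert a == b


class TestChainConsistency:
    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_applied_engorged_molted_ordering(self, seed):
        data = simulate_trial(TrialConfig(seed=seed))
        for r in data.stage_records:
            if r.is_one_host:
                assert r.larvae_applied is None and r.nymphs_applied is None
            else:
                assert r.larvae_applied >= r.larvae_engorged >= r.larvae_molted
                assert r.nymphs_applied >= r.nymphs_engorged >= r.nymphs_molted
            assert r.females_applied >= r.females_engorged
            assert r.egg_mass_g >= 0 and r.larval_mass_per_g_eggs_g >= 0

    def test_one_host_excluded_for_b_indicus(self):
        data = simulate_trial(TrialConfig(seed=0))
        assert not any(
            r.breed == "B. indicus" and r.tick_species == "R. decoloratus"
            for r in data.stage_records
        )

    def test_effect_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            TrialConfig(effect_sizes={("a", "s", P.DL): 1.5})


class TestNullCalibration:
    def test_null_reductions_average_zero(self):
        """With all effects 0 the reduction estimators are centred on 0 (+/-2 pp)."""
        cfg = TrialConfig(effect_sizes={})
        rng = np.random.default_rng(77)
        est = {p: [] for p in (P.DL, P.DMN, P.DO)}
        for _ in range(200):
            v, c = simulate_arm_pair(cfg, "R. appendiculatus", {}, rng)
            for p in est:
                est[p].append(stage_reduction(summarize_group(v, c, p)).reduction_pct)
        for p, vals in est.items():
            assert abs(np.mean(vals)) < 2.0, p.value

    def test_large_n_recovers_configured_effect(self):
        cfg = TrialConfig(
            effect_sizes={},
            challenge=TickChallenge(larvae_applied=20000),
            dispersion=Dispersion(icc=0.0, mass_cv=0.0),
        )
        rng = np.random.default_rng(5)
        ests = []
        for _ in range(5):
            v, c = simulate_arm_pair(cfg, "R. appendiculatus", {P.DL: 0.5}, rng)
            ests.append(stage_reduction(summarize_group(v, c, P.DL)).reduction_pct)
        assert abs(np.mean(ests) - 50.0) < 3.0


class TestAntibodySeries:
    def test_flat_series_without_noise_or_response(self):
        cfg = _small_config(
            titer=TiterModel(baseline_od=0.2, noise_sd=0.0, response_cv=0.0)
        )
        rng = np.random.default_rng(0)
        s = simulate_antibody_series(
            cfg, cfg.control_group, "a1", "c1", rng, breed="crossbred"
        )
        assert all(od == pytest.approx(0.2) for od in s.readings.values())
        assert set(s.readings) == {0, 30, 45, 60, 195}

    def test_day60_vaccinated_above_control(self):
        cfg = _small_config()
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(200):
            v = simulate_antibody_series(cfg, "a1", "a1", "v", rng, breed="crossbred")
            c = simulate_antibody_series(cfg, cfg.control_group, "a1", "c", rng, breed="crossbred")
            wins += v.readings[60] > c.readings[60]
        assert wins == 200

    def test_null_titer_model_identical_in_law(self):
        """With zero dose response, vaccinated and control ODs share one law."""
        cfg = _small_config(
            titer=TiterModel(dose_increments=(0.0, 0.0, 0.0))
        )
        rng = np.random.default_rng(2)
        nonsig = 0
        reps = 200
        for _ in range(reps):
            v = [
                simulate_antibody_series(cfg, "a1", "a1", f"v{i}", rng, breed="crossbred").readings[60]
                for i in range(4)
            ]
            c = [
                simulate_antibody_series(cfg, cfg.control_group, "a1", f"c{i}", rng, breed="crossbred").readings[60]
                for i in range(4)
            ]
            nonsig += ks_2samp(v, c).pvalue >= 0.05
        assert nonsig / reps >= 0.90

    def test_third_dose_decline_mode(self):
        base = TiterModel(noise_sd=0.0, response_cv=0.0)
        cfg_up = _small_config(titer=base)
        cfg_down = _small_config(titer=dataclasses.replace(base, third_dose_decline=True))
        rng = np.random.default_rng(0)
        up = simulate_antibody_series(cfg_up, "a1", "a1", "v", rng, breed="crossbred")
        down = simulate_antibody_series(cfg_down, "a1", "a1", "v", rng, breed="crossbred")
        assert up.readings[195] > up.readings[60] - 0.3  # keeps rising/slow decay
        assert down.readings[195] < up.readings[195]  # third dose lowered the titer


class TestReferenceFixture:
    def test_twenty_groups(self, reference_results):
        assert len(reference_results) == 20

    def test_first_row_values(self, reference_results):
        r = next(
            x
            for x in reference_results
            if (x.antigen, x.breed, x.tick_species)
            == ("R. appendiculatus SUB", "B. indicus", "R. appendiculatus")
        )
        got = {e.parameter: (int(e.reduction_pct), e.significant) for e in r.reductions}
        assert got == {
            P.DL: (17, True), P.DMN: (22, True), P.DN: (13, True), P.DMA: (0, False),
            P.DA: (19, False), P.DO: (6, True), P.DF: (0, False),
        }

    def test_report_round_trip_layout(self, reference_results):
        df = report_frame(reference_results)
        assert len(df) == 20
        row = df.iloc[0]
        assert row["DL"] == "17% *" and row["DA"] == "19%" and row["E"] == "47%"
        # one-host rows leave the immature-stage columns blank
        onehost = df[df["tick_species"] == "R. decoloratus"]
        assert (onehost[["DL", "DMn", "DN", "DMa"]] == "").all().all()

    def test_effect_sizes_derived_from_reference(self):
        from tickvac import reference_effect_sizes

        effects = reference_effect_sizes()
        # crossbred-only one-host fertility effect keeps its printed value
        assert effects[("R. decoloratus SUB", "R. decoloratus", P.DF)] == pytest.approx(0.69)
        # averaged across breeds where both were challenged
        expected = (REFERENCE_REDUCTIONS[("combined SUB", "B. indicus", "R. appendiculatus")][P.DL][0] / 100
                    + REFERENCE_REDUCTIONS[("combined SUB", "crossbred", "R. appendiculatus")][P.DL][0] / 100) / 2
        assert effects[("combined SUB", "R. appendiculatus", P.DL)] == pytest.approx(expected)
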