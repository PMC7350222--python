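"""Stage reduction arithmetic and the gated cumulative efficacy index."""

import math

import pytest
from hypothesis import given, strategies as st

from tickvac import (
    EfficacyResult,
    GroupStageSummary,
    ReductionEstimate,
    ReductionUndefinedError,
    StageParameter,
    count_affected_stages,
    cumulative_efficacy,
    round_half_away,
    stage_reduction,
    total_efficacy_by_antigen,
    vaccine_efficacy,
)
from tickvac.reference import DESIGN_CELLS, ANTIGENS

P = StageParameter


def _summary(v, c, param=P.DL):
    return GroupStageSummary(parameter=param, vaccinated_value=v, control_value=c)


class TestStageReduction:
    @pytest.mark.parametrize(
        "vaccinated, control, expected",
        [(50, 50, 0.0), (0, 120, 100.0), (83, 100, 17.0), (130, 100, -30.0)],
    )
    def test_reduction_formula(self, vaccinated, control, expected):
        est = stage_reduction(_summary(vaccinated, control))
        assert est.reduction_pct == pytest.approx(expected)

    def test_same_formula_for_all_stage_classes(self):
        for param in (P.DL, P.DMN, P.DO, P.DF):
            est = stage_reduction(_summary(0.3, 0.6, param))
            assert est.reduction_pct == pytest.approx(50.0)

    def test_zero_control_is_undefined(self):
        with pytest.raises(ReductionUndefinedError):
            stage_reduction(_summary(10, 0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            _summary(-1, 100)


class TestVaccineEfficacy:
    @pytest.mark.parametrize(
        "included, expected_rounded",
        [
            ([17, 22, 13, 6], 47),
            ([], 0),
            ([69, 50, 19, 18, 39], 94),
            ([69], 69),
        ],
    )
    def test_survival_fraction_product(self, included, expected_rounded):
        reductions = [
            ReductionEstimate(P.DL, float(d), significant=True, included=True)
            for d in included
        ]
        res = vaccine_efficacy(reductions, antigen="a", breed="b", tick_species="s")
        assert res.efficacy_rounded == expected_rounded

    def test_excluded_parameters_do_not_change_e(self):
        base = [ReductionEstimate(P.DL, 40.0, significant=True, included=True)]
        with_excluded = base + [
            ReductionEstimate(P.DA, 19.0, significant=False, included=False)
        ]
        assert (
            vaccine_efficacy(base).efficacy_pct
            == vaccine_efficacy(with_excluded).efficacy_pct
        )

    def test_included_above_100_rejected(self):
        with pytest.raises(ValueError):
            ReductionEstimate(P.DL, 101.0, significant=True, included=True)

    def test_included_requires_significant(self):
        with pytest.raises(ValueError):
            ReductionEstimate(P.DL, 50.0, significant=False, included=True)

    @given(
        st.lists(st.floats(min_value=0, max_value=100), max_size=7),
        st.integers(min_value=0, max_value=6),
        st.floats(min_value=0, max_value=10),
    )
    def test_monotone_in_any_included_reduction(self, pcts, idx, bump):
        e0 = cumulative_efficacy(pcts)
        assert 0.0 <= e0 <= 100.0
        if pcts:
            idx = idx % len(pcts)
            bumped = list(pcts)
            bumped[idx] = min(bumped[idx] + bump, 100.0)
            assert cumulative_efficacy(bumped) >= e0 - 1e-9

    def test_printed_integer_mode_rounds_before_product(self):
        reductions = [
            ReductionEstimate(P.DL, 16.6, significant=True, included=True),
            ReductionEstimate(P.DMN, 21.51, significant=True, included=True),
        ]
        exact = vaccine_efficacy(reductions).efficacy_pct
        printed = vaccine_efficacy(reductions, printed_integer_mode=True).efficacy_pct
        assert printed == pytest.approx(cumulative_efficacy([17, 22]))
        assert printed != pytest.approx(exact)


def _blank_results():
    """A full factorial with no included parameters."""
    results = []
    for antigen in ANTIGENS:
        for breed, species in DESIGN_CELLS:
            params = (
                (P.DA, P.DO, P.DF)
                if species == "R. decoloratus"
                else tuple(P)
            )
            results.append(
                EfficacyResult(
                    antigen=antigen,
                    breed=breed,
                    tick_species=species,
                    reductions=[ReductionEstimate(p, 0.0) for p in params],
                )
            )
    return results


class TestCoverageCounts:
    def test_no_included_flags_gives_zero_over_31(self):
        table = count_affected_stages(_blank_results(), by="antigen")
        assert (table["affected"] == 0).all()
        assert (table["possible"] == 31).all()

    def test_early_stage_denominator_is_8(self):
        table = count_affected_stages(_blank_results(), by="antigen", early_stages=True)
        assert (table["possible"] == 8).all()

    def test_missing_cell_raises(self):
        results = _blank_results()[:-1]  # drop one group
        with pytest.raises(ValueError, match="missing cells"):
            count_affected_stages(results, by="antigen")


class TestAntigenTotals:
    def test_reference_means(self, reference_results):
        totals = total_efficacy_by_antigen(reference_results)
        assert totals.loc["R. decoloratus SUB", "mean_efficacy_pct"] == pytest.approx(75.2)
        assert totals.loc["R. appendiculatus SUB", "mean_efficacy_pct"] == pytest.approx(65.4)

    def test_single_group_mean_is_identity(self):
        res = vaccine_efficacy(
            [ReductionEstimate(P.DF, 69.0, significant=True, included=True)],
            antigen="a", breed="b", tick_species="s",
        )
        totals = total_efficacy_by_antigen([res])
        assert totals.loc["a", "mean_efficacy_pct"] == pytest.approx(69.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            total_efficacy_by_antigen([])


@pytest.mark.parametrize(
    "x, expected", [(0.5, 1), (-0.5, -1), (1.4, 1), (2.5, 3), (-2.5, -3), (89.6, 90)]
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
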