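"""Statistical machinery of the gate, checked against hand-computed oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tickvac import (
    GateConfig,
    StageParameter,
    TestUndefinedError,
    chi_square_gate,
    oneway_anova,
    spearman_rho,
    welch_t,
)

P = StageParameter


def pearson_chi2(table):
    """Textbook Pearson chi-square: sum (O - E)^2 / E on a 2x2."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquareGate:
    def test_identical_proportions_not_significant(self, make_record):
        v = [make_record(animal_id="v1", larvae_engorged=150)]
        c = [make_record(animal_id="c1", antigen_group="adjuvant control", larvae_engorged=150)]
        res, sig = chi_square_gate(v, c, P.DL)
        assert res.statistic == pytest.approx(0.0)
        assert not sig

    def test_matches_textbook_formula(self, make_record):
        # pooled table [[10, 290], [100, 200]]
        v = [make_record(larvae_engorged=10, larvae_molted=5)]
        c = [make_record(antigen_group="ctrl", larvae_engorged=100, larvae_molted=50)]
        res, sig = chi_square_gate(v, c, P.DL)
        assert res.statistic == pytest.approx(pearson_chi2([[10, 290], [100, 200]]))
        assert sig and res.p_value < 0.05

    def test_zero_applied_is_undefined(self, make_record):
        v = [make_record(larvae_applied=0, larvae_engorged=0, larvae_molted=0)]
        c = [make_record(antigen_group="ctrl")]
        with pytest.raises(TestUndefinedError):
            chi_square_gate(v, c, P.DL)

    def test_zero_outcome_margin_not_significant(self, make_record):
        v = [make_record(larvae_engorged=0, larvae_molted=0)]
        c = [make_record(antigen_group="ctrl", larvae_engorged=0, larvae_molted=0)]
        res, sig = chi_square_gate(v, c, P.DL)
        assert not sig
        assert res.warning is not None

    def test_mass_parameter_uses_pseudocounts(self, make_record):
        v = [make_record(egg_mass_g=1.5)]
        c = [make_record(antigen_group="ctrl", egg_mass_g=3.75)]
        res, sig = chi_square_gate(v, c, P.DO, GateConfig(mass_unit_scale=1000))
        oracle = pearson_chi2([[1500, 15000 - 1500], [3750, 15000 - 3750]])
        assert res.statistic == pytest.approx(oracle)
        assert sig

    def test_rank_gate_exact_mannwhitney(self, make_record):
        v = [make_record(animal_id=f"v{i}", larvae_engorged=60 + i, larvae_molted=50) for i in range(4)]
        c = [make_record(animal_id=f"c{i}", antigen_group="ctrl", larvae_engorged=200 + i) for i in range(4)]
        res, sig = chi_square_gate(v, c, P.DL, GateConfig(gate_method="rank_per_animal"))
        # complete separation of 4 vs 4: exact two-sided p = 2/C(8,4)
        assert res.p_value == pytest.approx(2 / 70)
        assert sig


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_against_direct_formula(self):
        a, b = [90.0, 89.0, 51.0], [47.0, 50.0]
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        res = welch_t(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(df, abs=1e-9)
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t), df), abs=1e-9)

    def test_zero_variance_both_arms_undefined(self):
        with pytest.raises(TestUndefinedError):
            welch_t([0, 0], [0, 0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    def test_exchange_symmetry(self, a, b):
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va == 0 and vb == 0:
            return
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-9, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9, abs=1e-9)


class TestOneWayAnova:
    def test_hand_ss_decomposition(self):
        # groups {1,2} and {5,6}: SSB=16 (df 1), SSW=1 (df 2) -> F=32
        res = oneway_anova([[1, 2], [5, 6]])
        assert res.statistic == pytest.approx(32.0, abs=1e-9)
        from scipy.stats import f as fdist

        assert res.p_value == pytest.approx(fdist.sf(32.0, 1, 2), abs=1e-9)

    def test_two_groups_equals_pooled_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert oneway_anova([a, b]).statistic == pytest.approx(t**2, rel=1e-10)

    def test_all_equal(self):
        res = oneway_anova([[2, 2], [2, 2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([[1], [1, 2]])

    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=5),
        st.lists(st.floats(-10, 10), min_size=2, max_size=5),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    def test_invariance_shift_and_scale(self, a, b, shift, scale):
        if np.ptp(np.concatenate([a, b])) == 0:
            return
        f0 = oneway_anova([a, b]).statistic
        a2 = [scale * (x + shift) for x in a]
        b2 = [scale * (x + shift) for x in b]
        assert oneway_anova([a2, b2]).statistic == pytest.approx(f0, rel=1e-6, abs=1e-9)


def midranks(v):
    """Average ranks computed from first principles (independent oracle)."""
    v = list(v)
    return [
        1 + sum(1 for u in v if u < x) + (sum(1 for u in v if u == x) - 1) / 2.0
        for x in v
    ]


def pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        res = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value == 0.0

    def test_tied_input_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 2, 0]
        res = spearman_rho(x, y)
        assert res.statistic == pytest.approx(pearson(midranks(x), midranks(y)), abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(TestUndefinedError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])
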