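"""Statistical gate and group comparisons for the trial analysis.

The gate decides which stage parameters enter the cumulative efficacy
product: a vaccinated-vs-control test per parameter at significance level
alpha (default 0.05, strict inequality, no multiple-testing adjustment — one
decision per parameter, as in the source trial design).

Two gate constructions are available:

``chi_square_pooled``
    Pearson chi-square (no continuity correction) on the pooled 2x2 table
    arm x outcome.  Counts and molting pool naturally (engorged/applied,
    molted/engorged).  Continuous masses are scaled to integer pseudo-counts
    first; this mirrors the trial's reported use of chi-square on every
    parameter but is statistically dubious for masses.
``rank_per_animal``
    Exact two-sided Mann-Whitney U on the per-animal values (n=4 vs 4 in the
    reference design) — the defensible alternative for mass parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .records import AnimalStageRecord, animal_stage_value, success_trial_totals
from .stages import StageParameter

__all__ = [
    "GateConfig",
    "TestResult",
    "TestUndefinedError",
    "chi_square_gate",
    "welch_t",
    "oneway_anova",
    "spearman_rho",
]


class TestUndefinedError(ValueError):
    """Raised when a test statistic is undefined for the given data."""

    __test__ = False  # not a pytest collection target


@dataclass(frozen=True)
class GateConfig:
    """Configuration of the significance gate.

    mass_unit_scale converts grams to integer pseudo-count units for the
    chi-square construction on mass parameters (default 1000/g = milligrams).
    include_harmful controls whether significant *negative* reductions may be
    gated into the efficacy product (off by default: a harmful effect would
    push E below the no-effect value).
    """

    alpha: float = 0.05
    gate_method: str = "chi_square_pooled"
    mass_unit_scale: float = 1000.0
    include_harmful: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.gate_method not in ("chi_square_pooled", "rank_per_animal"):
            raise ValueError(f"unknown gate_method {self.gate_method!r}")
        if self.mass_unit_scale <= 0:
            raise ValueError("mass_unit_scale must be positive")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    method: str
    warning: str | None = None

    @property
    def significant_at(self):  # pragma: no cover - convenience
        return lambda alpha: self.p_value < alpha


def chi_square_gate(
    vaccinated: Sequence[AnimalStageRecord],
    control: Sequence[AnimalStageRecord],
    parameter: StageParameter,
    config: GateConfig = GateConfig(),
) -> tuple[TestResult, bool]:
    """Gate one stage parameter; returns (test result, significant flag).

    Significance is strict: p < alpha.  A table with an empty arm margin
    (e.g. zero applied ticks) raises :class:`TestUndefinedError`; a zero
    outcome margin (identical degenerate outcomes in both arms) yields a
    non-significant undefined-statistic result rather than an error.  Any
    expected cell below 1 sets a small-sample warning on the result.
    """
    if not vaccinated or not control:
        raise TestUndefinedError("both arms need at least one animal")

    if config.gate_method == "rank_per_animal":
        x = [animal_stage_value(r, parameter) for r in vaccinated]
        y = [animal_stage_value(r, parameter) for r in control]
        x = [v for v in x if not np.isnan(v)]
        y = [v for v in y if not np.isnan(v)]
        if not x or not y:
            raise TestUndefinedError(f"{parameter.value}: no defined per-animal values in one arm")
        if len(set(x) | set(y)) == 1:
            res = TestResult(np.nan, 1.0, 0.0, "rank_per_animal", warning="all values tied")
            return res, False
        mw = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        res = TestResult(float(mw.statistic), float(mw.pvalue), 0.0, "rank_per_animal")
        return res, res.p_value < config.alpha

    sv, tv = success_trial_totals(vaccinated, parameter, config.mass_unit_scale)
    sc, tc = success_trial_totals(control, parameter, config.mass_unit_scale)
    if tv == 0 or tc == 0:
        raise TestUndefinedError(
            f"{parameter.value}: zero trials in one arm (degenerate margin)"
        )
    table = np.array([[sv, tv - sv], [sc, tc - sc]], dtype=float)
    if np.any(table < 0):
        raise ValueError(f"{parameter.value}: successes exceed trials")
    col_totals = table.sum(axis=0)
    if np.any(col_totals == 0):
        # both arms all-success or all-failure: no information, not significant
        res = TestResult(
            np.nan, 1.0, 1.0, "chi_square_pooled", warning="zero outcome margin; test undefined"
        )
        return res, False
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    warning = "expected cell below 1; chi-square approximation unreliable" if np.any(expected < 1) else None
    res = TestResult(float(chi2), float(p), float(df), "chi_square_pooled", warning=warning)
    return res, res.p_value < config.alpha


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise TestUndefinedError("both samples have zero variance; statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df), "welch_t")


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA; F with (k-1, N-k) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df = (k - 1, n_total - k)
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        return TestResult(0.0, 1.0, df[0], f"oneway_anova{df}")
    with np.errstate(invalid="ignore"):
        f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance, non-zero between
        f, p = np.inf, 0.0
    return TestResult(float(f), float(p), float(df[0]), f"oneway_anova(df={df[0]},{df[1]})")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-rank tie handling.

    rho is the Pearson correlation of mid-ranks; the two-sided p-value uses
    the t approximation with n-2 df (|rho| = 1 gives p = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TestUndefinedError("constant input; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    return TestResult(float(rho), float(p), float(x.size - 2), "spearman_rho")
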