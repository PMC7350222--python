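# Methods

`tickvac` implements the analysis of a stage-structured cattle vaccination
trial against multiple tick species: per-stage reduction estimation, a
significance-gated cumulative efficacy index, serology analyses, and a
synthetic trial generator that makes every step testable in the absence of
the trial's raw per-animal data.

## The efficacy model

For each (vaccine antigen, cattle breed, tick species) group, the effect of
vaccination is measured per tick developmental stage as a percent reduction
relative to the adjuvant-only control group:

* **DL, DN, DA** — reduction in the number of engorged larvae, nymphs and
  adult females: `D = 100 (1 − NT_V / NT_C)` where `NT` is the total count of
  engorged ticks recovered in each arm;
* **DMn, DMa** — reduction in molting success of larvae and nymphs, computed
  on the arm means of the per-animal molting proportions (molted/engorged);
* **DO** — reduction in oviposition, on arm means of egg mass per surviving
  female (g);
* **DF** — reduction in egg fertility, on arm means of larval mass per gram
  of eggs (g/g).

Three-host species (*R. appendiculatus*, *A. variegatum*) expose all seven
parameters; the one-host *R. decoloratus* completes its immature stages on
the host, so only DA, DO and DF are observable (3 parameters per group).

Cumulative vaccine efficacy multiplies the *survival fractions* of the
stages that pass the significance gate:

```
E (%) = 100 · (1 − Π_included (1 − D_i / 100))
```

A multiplicative product of the raw `D` percentages would be dimensionally
meaningless; the survival-fraction reading is the only one that regenerates
the published group efficacies from their printed per-stage reductions, and
it has the right limits (no included stage ⇒ E = 0; any stage at 100% ⇒
E = 100). It also composes: `1 − E_{a∪b}/100 = (1 − E_a/100)(1 − E_b/100)`,
which is property-tested.

Gating rules:

* only parameters with a significant vaccinated-vs-control difference
  (p < α, default α = 0.05, strict inequality, no multiple-testing
  adjustment — one pre-planned decision per parameter) are included;
  excluded parameters contribute a factor of 1;
* negative reductions (more/heavier ticks on vaccinated animals) are
  reported with their sign but never included by default, even when
  significant; `GateConfig(include_harmful=True)` overrides this;
* `E` is computed from unrounded reductions by default; *printed-integer
  mode* first rounds each reduction to whole percent, matching the
  convention of published summary tables and used in the regression tests;
* display rounding is half-away-from-zero to integer percent.

One row of the published summary is internally inconsistent: for the
combined formulation on crossbred cattle challenged with *A. variegatum*,
the flagged reductions {27, 7, 28, 13} give E = 57%, not the printed 69%
(69% arises exactly if the 27% term is multiplied in twice). The fixture in
`tickvac.reference` keeps the published numbers verbatim and the
corresponding regression test documents the discrepancy by failing for that
single row; the published range (47–94%), the per-antigen means (65–75%) and
all coverage counts are unaffected.

## The significance gate

Two constructions are provided (`GateConfig.gate_method`):

* **`chi_square_pooled`** (default, mirroring the trial's reported method):
  Pearson chi-square without continuity correction on the pooled 2×2 table
  arm × outcome. Count parameters pool engorged vs applied; molting pools
  molted vs engorged. Continuous masses are converted to integer
  pseudo-counts with `mass_unit_scale` (default 1000 units/g, i.e.
  milligrams): DO tests egg-mass units against a 1 g-per-female ceiling
  (safely above any realistic *Rhipicephalus* egg mass), DF tests
  hatched-larval-mass units against egg-mass units. Expected cells below 1
  set a small-sample warning; a zero outcome margin yields a non-significant
  undefined result; a zero arm margin (no ticks applied) is an error.
* **`rank_per_animal`**: exact two-sided Mann–Whitney U on the per-animal
  values (4 vs 4 in the reference design).

Caveats, stated rather than hidden: the pooled chi-square is calibrated only
under exchangeable binomial sampling of counts — with between-animal
overdispersion it over-fires, and applied to mg-scale mass pseudo-counts it
is grossly anticonservative whenever masses carry biological noise. The
type-I calibration study therefore targets count parameters with dispersion
set to 0 (where the measured null rate is ~0.05 over 2,000 replicates), and
the whole-pipeline null check uses the rank gate, which is level-correct
(indeed slightly conservative: the smallest achievable exact two-sided
p-value at 4 vs 4 is 2/70 ≈ 0.029) for every stage class. The smallest
achievable p also means α below 0.029 makes the rank gate inert at this
design size.

Supporting comparisons use standard machinery: Welch's t (unequal variances,
Welch–Satterthwaite df) for the between-breed comparison of group
efficacies; one-way ANOVA for per-day titer comparisons (flagged at p < 0.05
and p < 0.005); Spearman's rho as Pearson correlation of mid-ranks with a
two-sided t-approximation p-value (n − 2 df, p = 0 at |rho| = 1). Degenerate
inputs raise explicit errors: both-arms-constant Welch input, groups smaller
than 2, constant correlation input.

## Correlates of protection

Antibody titers are OD450 readings at a fixed serum dilution, used directly
(no endpoint-titer transformation). For each (breed, *Rhipicephalus*
species) cell the analysis pools all five groups — four vaccine formulations
plus control, 4 animals each, n = 20 — and correlates each animal's day-60
titer against its raw per-animal stage values (counts, molting proportions,
masses; group-level reductions would collapse the n). Only parameters
significant under at least three of the four formulations in that cell are
eligible (configurable). An outcome is *significant-negative* when rho < 0
and p ≤ α.

The reduction threshold is the smallest mean group reduction among
significant-negative outcomes; it is flagged *separating* when every
non-significant outcome sits strictly below it. Units differ across
parameters, so cross-parameter averaging of the stage values themselves is
left to reporting; the threshold operates on the reduction percentages,
which are unitless.

## The synthetic trial generator

The generator emulates the reference design: per breed (with the one-host
challenge omitted for *B. indicus*, as in the trial), per group and per
animal it draws

* counts as beta-binomial chains — engorged ~ BB(applied, p·(1 − effect)),
  molted ~ BB(engorged, p·(1 − effect)) — with intra-animal correlation
  `icc` (default 0.02; 0 recovers plain binomial). Challenge numbers follow
  the protocol: 300 larvae, 200 nymphs per ear (totalled per animal by
  default, 400, with a per-ear switch), 30 adults at one male per three
  females ⇒ 22 females. The one-host chain applies 300 larvae and draws
  engorged adult females from the female half (150) with an on-host
  survival of 0.2. Fixed applied numbers per stage (not molted survivors)
  mirror the protocol's re-application of nymphs and adults.
* masses as log-normals with CV 0.15 (positivity guaranteed): egg mass per
  female 0.25 g and larval mass per gram of eggs 0.5 g/g in controls,
  vaccinated means scaled by (1 − effect).
* baseline success rates in controls: larval/nymphal engorgement 0.5,
  molting 0.8, adult female engorgement 0.7 — field-realistic values for
  ear-bag challenge infestations.
* OD450 trajectories: baseline 0.2 plus per-dose increments
  (0.45, 0.45, 0.15) decaying at 0.002/day, per-animal response
  heterogeneity (lognormal, CV 0.2), reading noise (SD 0.05), clipped at 0.
  Heterologous coatings respond at a 0.8 cross-reactivity factor (the
  antigen is highly conserved across the three species); the combined
  formulation responds fully to all coatings. A documented
  `third_dose_decline` mode makes the third dose lower the titer.

Default true effect sizes are taken from the published group reductions
(clamped at 0, averaged over breeds where both were challenged), so the
default simulation represents the study's own observed conditions. The
titer→protection link (`link_strength`, default 0) scales each animal's
realized effects with its day-60 titer relative to the expected vaccinated
peak, producing monotone titer–outcome coupling for power studies.

What the generator does **not** emulate: breed-specific effect sizes (true
effects are per antigen × species), host immunity dynamics over repeated
infestation, between-stage carry-over of damage, tick population dynamics
across generations, or ELISA plate artefacts. Passing tests therefore
validate the estimators and gates against a known stochastic model of the
design — they do not certify the biological conclusions of any real trial.

## Problem sizes and numerical choices

Monte-Carlo studies use 2,000 replicates for the null-calibration of the
gate (binomial 95% band ±0.96 pp around 0.05), 500 replicates per condition
for estimator bias (observed |bias| < 1.5 pp at effects 20/50/80%) and for
correlation power curves, and 200 replicates for the smaller distributional
checks — sizes at which the Monte-Carlo error is well inside the asserted
tolerances while the whole suite runs in seconds. The Spearman
implementation is checked against an exhaustive brute-force mid-rank oracle
for every permutation up to n = 6 and tied vectors. All simulation is
seeded through `numpy.random.default_rng`; a trial is a pure function of
(config, seed), asserted by replay tests, and every pipeline run emits a
manifest (config hash, seed, input digests) plus a gate log with one row per
gating decision so that every star in the report is auditable.

## Known limitations

* The pooled 2×2 chi-square construction for a "4 biological replicates"
  design is an interpretation; the trial report does not state how the test
  was built. Both it and the rank alternative are config-selectable and
  logged.
* With 4 animals per arm the breed comparison (Welch on 2 vs 3 group
  efficacies) has minimal power; it is reported, not emphasised.
* Group-level reductions computed from ratio-of-means are slightly biased
  for small control means; at the reference challenge sizes the bias is
  below half a percentage point.
* The published summary's own arithmetic slip (one row, see above) caps
  exact table-wide reproduction at 19/20 rows.
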