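"""Published group-level results of the Ugandan subolesin (SUB) cattle trial.

The trial vaccinated *Bos indicus* and crossbred calves (4 per group) with
recombinant subolesin from three Ugandan tick species — *R. appendiculatus*,
*A. variegatum* and *R. decoloratus* — singly or combined, against an
adjuvant-only control, then challenged with all three species (one-host
*R. decoloratus* on crossbred cattle only).  What is publicly reported is the
group-level summary: the integer percent reduction of every observable stage
parameter together with a flag marking which reductions were statistically
significant (chi-square, p < 0.05) and therefore entered the cumulative
efficacy product.

This module transcribes that summary verbatim as a fixture, for exact
regression of the efficacy arithmetic.  Raw per-animal data were not
deposited; analyses needing animal-level inputs use the synthetic generator
(:mod:`tickvac.simulate`), whose default effect sizes are derived from these
reductions.

Note: one published row — the combined-antigen formulation on crossbred
cattle infested with *A. variegatum* — reports a cumulative efficacy (69%)
that is not consistent with its own flagged reductions under the survival
product that exactly regenerates every other row (they give 57%; 69% results
only if the 27% larval term is multiplied in twice).  The transcription keeps
the published numbers untouched.
"""

from __future__ import annotations

from .stages import ReductionEstimate, StageParameter, vaccine_efficacy, EfficacyResult

__all__ = [
    "ANTIGENS",
    "BREEDS",
    "THREE_HOST_SPECIES",
    "ONE_HOST_SPECIES",
    "TICK_SPECIES",
    "CONTROL_GROUP",
    "DESIGN_CELLS",
    "REFERENCE_REDUCTIONS",
    "reference_trial_results",
    "reference_effect_sizes",
]

ANTIGENS = (
    "R. appendiculatus SUB",
    "A. variegatum SUB",
    "R. decoloratus SUB",
    "combined SUB",
)
CONTROL_GROUP = "adjuvant control"
BREEDS = ("B. indicus", "crossbred")
THREE_HOST_SPECIES = ("R. appendiculatus", "A. variegatum")
ONE_HOST_SPECIES = ("R. decoloratus",)
TICK_SPECIES = THREE_HOST_SPECIES + ONE_HOST_SPECIES

#: (breed, tick species) cells of the challenge design; B. indicus received no
#: one-host challenge.
DESIGN_CELLS: tuple[tuple[str, str], ...] = (
    ("B. indicus", "R. appendiculatus"),
    ("B. indicus", "A. variegatum"),
    ("crossbred", "R. appendiculatus"),
    ("crossbred", "A. variegatum"),
    ("crossbred", "R. decoloratus"),
)

_P = StageParameter

# (antigen, breed, tick species) -> {parameter: (reduction %, significant)}
# transcribed from the published trial summary table; significance = starred.
REFERENCE_REDUCTIONS: dict[tuple[str, str, str], dict[StageParameter, tuple[int, bool]]] = {
    ("R. appendiculatus SUB", "B. indicus", "R. appendiculatus"): {
        _P.DL: (17, True), _P.DMN: (22, True), _P.DN: (13, True), _P.DMA: (0, False),
        _P.DA: (19, False), _P.DO: (6, True), _P.DF: (0, False),
    },
    ("R. appendiculatus SUB", "B. indicus", "A. variegatum"): {
        _P.DL: (0, False), _P.DMN: (25, True), _P.DN: (0, False), _P.DMA: (3, True),
        _P.DA: (19, False), _P.DO: (31, True), _P.DF: (0, False),
    },
    ("R. appendiculatus SUB", "crossbred", "R. appendiculatus"): {
        _P.DL: (41, True), _P.DMN: (64, True), _P.DN: (0, False), _P.DMA: (0, False),
        _P.DA: (51, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("R. appendiculatus SUB", "crossbred", "A. variegatum"): {
        _P.DL: (34, True), _P.DMN: (44, True), _P.DN: (19, True), _P.DMA: (25, True),
        _P.DA: (0, False), _P.DO: (4, True), _P.DF: (49, True),
    },
    ("R. appendiculatus SUB", "crossbred", "R. decoloratus"): {
        _P.DA: (0, False), _P.DO: (8, True), _P.DF: (47, True),
    },
    ("A. variegatum SUB", "B. indicus", "R. appendiculatus"): {
        _P.DL: (61, True), _P.DMN: (51, True), _P.DN: (0, False), _P.DMA: (0, False),
        _P.DA: (29, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("A. variegatum SUB", "B. indicus", "A. variegatum"): {
        _P.DL: (0, False), _P.DMN: (1, True), _P.DN: (7, True), _P.DMA: (3, True),
        _P.DA: (41, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("A. variegatum SUB", "crossbred", "R. appendiculatus"): {
        _P.DL: (53, True), _P.DMN: (39, True), _P.DN: (0, False), _P.DMA: (39, True),
        _P.DA: (0, False), _P.DO: (4, True), _P.DF: (0, False),
    },
    ("A. variegatum SUB", "crossbred", "A. variegatum"): {
        _P.DL: (54, True), _P.DMN: (28, True), _P.DN: (16, True), _P.DMA: (0, False),
        _P.DA: (0, False), _P.DO: (14, True), _P.DF: (0, False),
    },
    ("A. variegatum SUB", "crossbred", "R. decoloratus"): {
        _P.DA: (0, False), _P.DO: (0, False), _P.DF: (72, True),
    },
    ("R. decoloratus SUB", "B. indicus", "R. appendiculatus"): {
        _P.DL: (0, False), _P.DMN: (0, False), _P.DN: (25, True), _P.DMA: (0, False),
        _P.DA: (55, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("R. decoloratus SUB", "B. indicus", "A. variegatum"): {
        _P.DL: (0, False), _P.DMN: (0, False), _P.DN: (32, True), _P.DMA: (0, False),
        _P.DA: (38, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("R. decoloratus SUB", "crossbred", "R. appendiculatus"): {
        _P.DL: (62, True), _P.DMN: (47, True), _P.DN: (25, True), _P.DMA: (19, True),
        _P.DA: (0, False), _P.DO: (10, True), _P.DF: (0, False),
    },
    ("R. decoloratus SUB", "crossbred", "A. variegatum"): {
        _P.DL: (69, True), _P.DMN: (50, True), _P.DN: (19, True), _P.DMA: (18, True),
        _P.DA: (0, False), _P.DO: (0, False), _P.DF: (39, True),
    },
    ("R. decoloratus SUB", "crossbred", "R. decoloratus"): {
        _P.DA: (0, False), _P.DO: (0, False), _P.DF: (69, True),
    },
    ("combined SUB", "B. indicus", "R. appendiculatus"): {
        _P.DL: (38, True), _P.DMN: (53, True), _P.DN: (0, False), _P.DMA: (0, False),
        _P.DA: (57, True), _P.DO: (0, False), _P.DF: (38, True),
    },
    ("combined SUB", "B. indicus", "A. variegatum"): {
        _P.DL: (0, False), _P.DMN: (0, False), _P.DN: (0, False), _P.DMA: (0, False),
        _P.DA: (51, True), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("combined SUB", "crossbred", "R. appendiculatus"): {
        _P.DL: (29, True), _P.DMN: (53, True), _P.DN: (0, False), _P.DMA: (22, True),
        _P.DA: (0, False), _P.DO: (0, False), _P.DF: (0, False),
    },
    ("combined SUB", "crossbred", "A. variegatum"): {
        _P.DL: (27, True), _P.DMN: (0, False), _P.DN: (7, True), _P.DMA: (28, True),
        _P.DA: (0, False), _P.DO: (13, True), _P.DF: (0, False),
    },
    ("combined SUB", "crossbred", "R. decoloratus"): {
        _P.DA: (0, False), _P.DO: (0, False), _P.DF: (71, True),
    },
}


def reference_trial_results() -> list[EfficacyResult]:
    """The 20 published (antigen, breed, tick species) groups as gated results.

    Significant reductions are included in the efficacy product; everything
    else (including the unstarred non-zero entries) contributes a factor of 1.
    """
    results = []
    for (antigen, breed, species), row in REFERENCE_REDUCTIONS.items():
        reductions = [
            ReductionEstimate(
                parameter=param,
                reduction_pct=float(pct),
                significant=significant,
                included=significant,
            )
            for param, (pct, significant) in row.items()
        ]
        results.append(
            vaccine_efficacy(
                reductions, antigen=antigen, breed=breed, tick_species=species
            )
        )
    return results


def reference_effect_sizes() -> dict[tuple[str, str, StageParameter], float]:
    """Per-(antigen, tick species, parameter) true effects for the simulator.

    Uses the published reductions (significant or not, clamped at 0) divided
    by 100.  Breed differences are folded in by averaging the two breeds'
    printed reductions where both were challenged.
    """
    acc: dict[tuple[str, str, StageParameter], list[float]] = {}
    for (antigen, _breed, species), row in REFERENCE_REDUCTIONS.items():
        for param, (pct, _sig) in row.items():
            acc.setdefault((antigen, species, param), []).append(max(pct, 0) / 100.0)
    return {key: sum(v) / len(v) for key, v in acc.items()}
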