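import hypothesis
import pytest

from tickvac import AnimalStageRecord, reference_trial_results

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_results():
    return reference_trial_results()


@pytest.fixture
def make_record():
    """Factory for three-host stage records with sensible defaults."""

    def _make(
        animal_id="a1",
        breed="crossbred",
        antigen_group="X SUB",
        tick_species="R. appendiculatus",
        larvae_applied=300,
        larvae_engorged=150,
        larvae_molted=120,
        nymphs_applied=400,
        nymphs_engorged=200,
        nymphs_molted=160,
        females_applied=22,
        females_engorged=15,
        egg_mass_g=3.75,
        larval_mass_per_g_eggs_g=0.5,
    ):
        return AnimalStageRecord(
            animal_id=animal_id,
            breed=breed,
            antigen_group=antigen_group,
            tick_species=tick_species,
            larvae_applied=larvae_applied,
            larvae_engorged=larvae_engorged,
            larvae_molted=larvae_molted,
            nymphs_applied=nymphs_applied,
            nymphs_engorged=nymphs_engorged,
            nymphs_molted=nymphs_molted,
            females_applied=females_applied,
            females_engorged=females_engorged,
            egg_mass_g=egg_mass_g,
            larval_mass_per_g_eggs_g=larval_mass_per_g_eggs_g,
        )

    return _make
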