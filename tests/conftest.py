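import pytest

from isomir_transit import HairpinReference, MatureAnnotation, generate_reference
from isomir_transit.simulate import SimulationDesign


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(20, seed=1)


@pytest.fixture()
def toy_hairpin():
    """Hairpin 'GGGGG' + mature 'ACGTACGTACGTACGTACGTAC' + 'TTTTT'."""
    mature = "ACGTACGTACGTACGTACGTAC"
    hp = "GGGGG" + mature + "TTTTT"
    ref = HairpinReference(
        hairpins={"hp1": hp},
        matures=[MatureAnnotation("hp1", "mir1", 5, 5 + len(mature))],
    )
    return ref, mature


@pytest.fixture()
def small_design():
    return SimulationDesign(n_hairpins=10, n_samples_per_group=4, seed=42)
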