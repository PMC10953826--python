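import pytest

from admscreen import (
    analyze_well_image,
    generate_library_fixture,
    render_well_image,
    simulate_well_objects,
)
from admscreen.simgen import CompoundRecord, WellSpec


@pytest.fixture(scope="session")
def library():
    return generate_library_fixture()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {r.name: r for r in library}


@pytest.fixture(scope="session")
def balanced_record():
    """A compound shifting the mix to ~50% clusters (for imaging benchmarks)."""
    return CompoundRecord("BAL-1", "balanced mix", "other",
                          cluster_shift_inh=40.0, cytotox_frac=0.3)


def simulate_and_analyze(record, n_wells, seed0, mode="inhibition"):
    """Render n simulated wells and run the full imaging pass on each."""
    pairs = []
    for i in range(n_wells):
        compound = record.compound_id if record is not None else "VEHICLE"
        dose = 1.0 if record is not None else 0.0
        spec = WellSpec("P1", 0, i, compound, dose, mode, i)
        truth = simulate_well_objects(spec, record, rng_seed=seed0 + i)
        image = render_well_image(truth, rng_seed=seed0 + 1000 + i)
        _, objects = analyze_well_image(image)
        pairs.append((truth, objects))
    return pairs


@pytest.fixture(scope="session")
def analyzed_wells(balanced_record):
    """Six rendered+analyzed wells with a balanced class mix and 30% death."""
    return simulate_and_analyze(balanced_record, n_wells=6, seed0=50)
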