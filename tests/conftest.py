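import pytest

from amplitrace import barcodes as bc
from amplitrace import sim
from amplitrace.plate import PlateLayout, WellAssignment


@pytest.fixture(scope="session")
def small_mid_set():
    """12 + 12 MIDs across lengths 8-10, enough for a 12-well toy plate."""
    return bc.generate_mid_set({8: 4, 9: 4, 10: 4}, seed=101)


@pytest.fixture(scope="session")
def full_mid_set():
    """The production-scale 96 + 96 variable-length set."""
    return bc.generate_mid_set({8: 32, 9: 32, 10: 32}, seed=7)


@pytest.fixture(scope="session")
def coligo_identifiers_96():
    return bc.generate_coligo_identifiers(96, seed=7)


@pytest.fixture(scope="session")
def zero_error_plate():
    """96-well simulated plate, no contamination, no sequencing error."""
    return sim.simulate_plate(sim.SimConfig(seed=11, reads_per_well_mean=60))


def make_toy_layout(n_wells=4, coligo_prefix="coligo"):
    """Minimal 96-format layout using the first ``n_wells`` wells of row A+B."""
    assignments = {}
    for i in range(n_wells):
        r, c = divmod(i, 12)
        label = f"{chr(ord('A') + r)}{c + 1}"
        assignments[label] = WellAssignment(
            sample_id=f"S{i + 1}",
            fwd_mid_id=f"F{i + 1}",
            rev_mid_id=f"R{i + 1}",
            expected_coligo_id=f"{coligo_prefix}{i + 1:03d}",
        )
    return PlateLayout(assignments=assignments)
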