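import numpy as np
import pytest

from hemocharge.io import AlignmentRecord, MultipleAlignment
from hemocharge import simulate as sim


@pytest.fixture
def protein_alignment():
    """4-record toy protein alignment with a gapped reference column."""
    records = [
        AlignmentRecord("Pch_c1", "Pch", "c1", "MKEH-ALDE"),
        AlignmentRecord("Pch_c2", "Pch", "c2", "MKEH-ALDE"),
        AlignmentRecord("Edo_c1", "Edo", "c1", "MKDHQALDK"),
        AlignmentRecord("Ovu_c1", "Ovu", "c1", "MRDHQALEK"),
    ]
    return MultipleAlignment(records=records, alphabet="protein", canonical_start=2306)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    manifest = sim.make_fixture_bundle(out, seed=0)
    return out, manifest


@pytest.fixture(scope="session")
def climate_dataset():
    cfg = sim.ClimateGradientConfig(seed=5)
    return sim.simulate_climate_dataset(cfg)


@pytest.fixture(scope="session")
def small_codon_simulation():
    """8-tip codon alignment with known purifying/positive site mix."""
    cfg = sim.SimulationConfig(
        n_tips=8, branch_length=0.2, site_omegas=(0.2,) * 30 + (5.0,) * 5, seed=3
    )
    codon, tree, omegas = sim.simulate_codon_alignment(cfg)
    return codon, tree, omegas
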