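import numpy as np
import pytest

from mutprot.simulate import SimulationConfig, generate_reference_set
from mutprot.variants import VariantCall


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, n_proteins=6, n_missense=3, n_frameshift=1,
                            max_protein_len=200)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference_set(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_variant(**overrides) -> VariantCall:
    """A passing missense call with defaults overridable per test."""
    base = dict(
        accession="SYN0001",
        gene="GENE1",
        type="missense",
        cds_pos=301,
        protein_pos=101,
        ref_aa="D",
        alt_aa="H",
        ref_base="G",
        alt_base="C",
        tumor_alt_reads=10,
        tumor_total_reads=100,
        normal_alt_reads=0,
        normal_total_reads=100,
        simple_repeat=False,
    )
    base.update(overrides)
    return VariantCall(**base)
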