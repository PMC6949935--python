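import numpy as np
import pytest

from rmtnet import OtuTable, SampleMetadata, SynthSpec, generate_community


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 OTUs x 4 samples with simple, hand-checkable profiles."""
    return OtuTable(
        ["OTU_a", "OTU_b", "OTU_c"],
        ["S1", "S2", "S3", "S4"],
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [2.0, 4.0, 6.0, 8.0],
                  [4.0, 3.0, 2.0, 1.0]]),
        taxonomy={"OTU_a": "k__Bacteria;p__Chloroflexi;c__X",
                  "OTU_b": "k__Bacteria;p__Actinobacteria;c__Y"},
    )


@pytest.fixture
def small_metadata() -> SampleMetadata:
    return SampleMetadata(
        ["S1", "S2", "S3", "S4"],
        {"pH": np.array([7.1, 7.3, 6.9, 7.6]),
         "T": np.array([21.0, 22.5, 20.8, 23.1])},
        group={"S1": "A", "S2": "A", "S3": "B", "S4": "B"},
    )


@pytest.fixture(scope="session")
def planted_community():
    """Default planted-module community (two groups, 4 modules, seed 0)."""
    spec = SynthSpec(seed=0)
    table, meta = generate_community(spec)
    return spec, table, meta


@pytest.fixture(scope="session")
def clean_planted_community():
    """Planted community without structural zeros (correlation-structure
    recovery conditions)."""
    spec = SynthSpec(seed=0, zero_inflation=0.0,
                     env_drivers={1: ("env_m1", 0.9)})
    table, meta = generate_community(spec)
    return spec, table, meta
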