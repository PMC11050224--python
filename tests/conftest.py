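import pytest

from cascadehor.pipeline import run_pipeline_on_sequence
from cascadehor.simulate import (
    PlantSpec,
    doublet_25mer_schemes,
    make_assembly,
    make_family_library,
    make_hor_array,
    make_preset_assembly,
)


@pytest.fixture(scope="session")
def pipe15_zero():
    """Pipeline run on a 50-copy zero-divergence canonical 15mer array."""
    seq, truth = make_preset_assembly(
        "15mer", seed=1, intra_divergence=0.0, flank_length=5000, n_copies=50
    )
    return run_pipeline_on_sequence(seq), truth


@pytest.fixture(scope="session")
def pipe20_zero():
    """Pipeline run on a 50-copy zero-divergence canonical 20mer array."""
    seq, truth = make_preset_assembly(
        "20mer", seed=1, intra_divergence=0.0, flank_length=5000, n_copies=50
    )
    return run_pipeline_on_sequence(seq), truth


@pytest.fixture(scope="session")
def pipe25_doublet():
    """48-copy 25mer array with deletion doublets at copies 8/9, 11/12, 14/15."""
    lib = make_family_library(29, seed=1)
    arr, truth = make_hor_array(
        lib, PlantSpec(doublet_25mer_schemes(48), intra_divergence=0.0, seed=2)
    )
    seq, truth = make_assembly([(arr, truth)], flank_length=5000, seed=3)
    return run_pipeline_on_sequence(seq), truth


@pytest.fixture(scope="session")
def pipe_mix():
    """60-copy 15mer array at 2% divergence with a 65/35 canonical/variant mix."""
    seq, truth = make_preset_assembly(
        "15mer",
        seed=0,
        intra_divergence=2.0,
        flank_length=10000,
        n_copies=60,
        canonical_fraction=0.65,
    )
    return run_pipeline_on_sequence(seq), truth


@pytest.fixture(scope="session")
def pipe_chr15_like():
    """The four-array chromosome-15-like assembly at 1% divergence."""
    seq, truth = make_preset_assembly("chr15-like", seed=3, intra_divergence=1.0)
    return run_pipeline_on_sequence(seq), truth
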