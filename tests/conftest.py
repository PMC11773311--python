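import numpy as np
import pytest

from loopseq.construct import ConstructSpec
from loopseq.synthetic import (
    EfficiencyModel,
    PositionBaseFrequencies,
    SplintModel,
    default_splint_model,
    sample_input_library,
    simulate_reaction,
)


@pytest.fixture(scope="session")
def spec() -> ConstructSpec:
    return ConstructSpec()


@pytest.fixture(scope="session")
def noiseless_efficiencies():
    """Per-sequence efficiencies at the exact group means (no dispersion)."""
    return EfficiencyModel.default(noise_sd=0.0).resolve()


@pytest.fixture(scope="session")
def library_freqs():
    return PositionBaseFrequencies.default().probabilities()


@pytest.fixture(scope="session")
def calibrated_splint(library_freqs, noiseless_efficiencies) -> SplintModel:
    """Splint model calibrated to a 0.44 observed (P2+P3) share at 250 nM."""
    return default_splint_model(library_freqs, noiseless_efficiencies)


@pytest.fixture(scope="session")
def small_batch(noiseless_efficiencies, calibrated_splint):
    """A modest-depth reaction at low concentration with full ground truth."""
    library = sample_input_library(PositionBaseFrequencies.default(), 100_000, seed=11)
    return simulate_reaction(
        library,
        noiseless_efficiencies,
        calibrated_splint,
        concentration_nM=5.0,
        read_depth=5_000,
        seed=13,
        reaction="C:G",
        closing_pair="C:G",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
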