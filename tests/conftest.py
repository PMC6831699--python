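import numpy as np
import pytest

from musevol import (
    BetaParams,
    MomentPair,
    SelectionParams,
    SyntheticCorpusConfig,
    iterate,
    simulate_corpus,
)


@pytest.fixture(scope="session")
def novelty_corpus():
    """A synthetic corpus along a novelty-only orbit from the
    small-feature regime, one generation per 25-year window."""
    traj = iterate(MomentPair(0.02, 0.01), SelectionParams(0.0, 1.0), 16)
    config = SyntheticCorpusConfig(
        trajectory=[s.params for s in traj.states],
        pieces_per_generation=300,
        note_count_range=(100, 1000),
        seed=20260921,
        start_year=1500.0,
        years_per_generation=25.0,
    )
    features, metadata = simulate_corpus(config)
    return traj, config, features, metadata


@pytest.fixture(scope="session")
def beta_sample():
    """10,000 draws from Beta(3, 12), fixed seed."""
    rng = np.random.default_rng(42)
    return rng.beta(3.0, 12.0, size=10_000)
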