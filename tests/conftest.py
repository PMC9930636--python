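"""Shared fixtures: small synthetic inputs with known structure."""

import numpy as np
import pytest

from tempostab import (
    RegimeSpec,
    TemporalStabilityModel,
    generate_regime_bold,
    phase_coherence_dfc,
    hilbert_phase,
    subspace_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_regime_run():
    """Two-regime, fixed-dwell synthetic run with known switch times."""
    spec = RegimeSpec.random(
        20, n_regimes=2, n_communities=3, dwell_mean=50,
        dwell_distribution="fixed", rng=np.random.default_rng(7),
    )
    ts, states = generate_regime_bold(spec, n_timepoints=200, seed=7)
    return ts, states


@pytest.fixture(scope="session")
def two_regime_trajectory(two_regime_run):
    ts, states = two_regime_run
    dfc = phase_coherence_dfc(hilbert_phase(ts))
    return subspace_trajectory(dfc, k=3), states


@pytest.fixture(scope="session")
def small_results():
    """Fitted results on a small seeded regime-switching run."""
    spec = RegimeSpec.random(
        16, n_regimes=2, dwell_mean=20, rng=np.random.default_rng(11)
    )
    ts, _ = generate_regime_bold(spec, n_timepoints=160, seed=11)
    return TemporalStabilityModel(ts).fit(metrics=("angle", "mahalanobis"))


def random_subspace_components(rng, n=8, k=3):
    """Random full-rank N x k component matrix."""
    return rng.normal(size=(n, k))
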