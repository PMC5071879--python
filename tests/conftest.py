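import numpy as np
import pytest

from dysonspec import (
    EnsembleSpec,
    PathwaySpec,
    SpinOrbitalBasis,
    ToySystemSpec,
    make_toy_system,
    simulate_ensemble,
)


@pytest.fixture
def basis3():
    return SpinOrbitalBasis("test", 3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_system():
    """A 3-electron/3-orbital random CI pair in the rotated-orbital regime."""
    spec = ToySystemSpec(
        n_spatial=3, n_electrons=3, seed=7, overlap_regime="rotated-orbitals",
        n_source_terms=5, n_ion_terms=5, n_ion_states=2,
    )
    return make_toy_system(spec)


@pytest.fixture
def small_ensemble():
    """Two-pathway ensemble, 40 trajectories, 400 fs, for structural tests."""
    spec = EnsembleSpec(
        pathways=[PathwaySpec("fast", 80.0, 0.5), PathwaySpec("slow", 400.0, 0.5)],
        n_trajectories=40,
        t_total_fs=400.0,
        seed=3,
    )
    return simulate_ensemble(spec)
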