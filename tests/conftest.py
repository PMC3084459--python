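import numpy as np
import pytest

from fmridecode import SimulationConfig, TimeSeriesMatrix, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tsm(rng, n_scans: int, n_voxels: int, runs: int = 1) -> TimeSeriesMatrix:
    """Random scans x voxels matrix on a 1D voxel line (helper, not a fixture)."""
    X = rng.normal(size=(n_scans, n_voxels))
    idx = np.column_stack(
        [np.arange(n_voxels), np.zeros(n_voxels, int), np.zeros(n_voxels, int)]
    )
    span = n_scans // runs
    boundaries = [(r * span, (r + 1) * span) for r in range(runs)]
    return TimeSeriesMatrix(
        X=X, voxel_index=idx, grid_dims=(n_voxels, 1, 1), run_boundaries=boundaries
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Two-run desk-scale dataset under the default study conditions."""
    return generate_dataset(SimulationConfig(n_runs=2, seed=7))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise- and drift-free dataset: the decoding problem is exactly linear."""
    return generate_dataset(
        SimulationConfig(n_runs=2, noise_sd=0.0, drift_amplitude=0.0, seed=3)
    )
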