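import numpy as np
import pytest

from mupool.decompose import DecompositionConfig, decompose
from mupool.geometry import GridGeometry
from mupool.synth import MotoneuronPool, generate_muap_library, synthesize


def make_pool(rt, a=None, b=None, isi_cov=0.0, size=None, drt_offset=0.0, min_rate=4.0):
    """Hand-built pool with explicit parameters (arrays broadcast from scalars)."""
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    n = rt.size

    def arr(x, default):
        if x is None:
            x = default
        return np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()

    return MotoneuronPool(
        rt=rt,
        a=arr(a, 4.0),
        b=arr(b, 8.0),
        min_rate=arr(min_rate, min_rate),
        isi_cov=arr(isi_cov, isi_cov),
        size=arr(size, 1.0),
        drt_offset=arr(drt_offset, drt_offset),
    )


@pytest.fixture(scope="session")
def grid():
    """Single 13x5 grid, one corner absent, 4 mm spacing (64 electrodes)."""
    return GridGeometry(n_rows=13, n_cols=5, ied_mm=4.0, absent_corner=True, n_grids=1)


@pytest.fixture(scope="session")
def toy_cfg():
    """Decomposition sized for small noise-free toy mixtures."""
    return DecompositionConfig(
        target_extended_channels=320,
        n_source_attempts=15,
        min_discharges=8,
    )


@pytest.fixture(scope="session")
def toy_recording(grid):
    """Five units with non-overlapping, well-spaced discharges, no noise."""
    rng = np.random.default_rng(42)
    n_units, fs, dur_s = 5, 2048.0, 8.0
    n = int(fs * dur_s)
    pool = make_pool(rt=np.linspace(5, 20, n_units), size=np.linspace(1.0, 2.0, n_units))
    library = generate_muap_library(pool, grid, seed=7, fs=fs)
    # interleaved spike slots 60 ms apart so no two action potentials overlap
    slot = int(0.060 * fs)
    trains = []
    for u in range(n_units):
        start = int(0.1 * fs) + u * slot
        spikes = np.arange(start, n - int(0.1 * fs), n_units * slot)
        trains.append(spikes)
    rec = synthesize(trains, library, noise_snr_db=None, fs=fs, seed=0, n_samples=n)
    return rec


@pytest.fixture(scope="session")
def toy_decomposition(toy_recording, toy_cfg):
    return decompose(toy_recording, toy_cfg)
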