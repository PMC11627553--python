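"""Ground-truthed synthetic HD-EMG generation.

Simulates trapezoidal isometric force-matching contractions performed by a
pool of motoneurons that obey the size principle: recruitment thresholds
span the physiological range, and above recruitment each unit's firing
rate follows a logarithmic input-output function

    f(F) = a * ln(F) + b      (pps, F in %MVC)

clipped below at a minimum physiological rate. Each unit imprints a unique
spatial action-potential signature on the electrode grid (surrogate
volume-conductor: Hermite-Rodriguez waveform, amplitude decaying with
distance from the unit territory, timing propagating along the grid
columns). The monopolar recording is the linear superposition of all unit
action-potential trains plus additive white Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridGeometry


def plateau_duration_s(target_pct_mvc: float) -> float:
    """Plateau length by target level: 20 s up to 40 %MVC, 15 s for 50-60, 10 s for 70-80."""
    if target_pct_mvc <= 40:
        return 20.0
    if target_pct_mvc <= 60:
        return 15.0
    return 10.0


@dataclass(frozen=True)
class ForceProtocol:
    """Trapezoidal force-matching protocol."""

    target: float  # %MVC
    ramp_rate: float = 5.0  # %MVC per second
    plateau_s: float | None = None  # None -> level-dependent default
    fs: float = 2048.0

    def resolved_plateau_s(self) -> float:
        return plateau_duration_s(self.target) if self.plateau_s is None else self.plateau_s


def build_force_profile(target: float, protocol: ForceProtocol | None = None) -> np.ndarray:
    """Trapezoidal force trace in %MVC sampled at ``protocol.fs``.

    Ramp-up and ramp-down each last ``target / ramp_rate`` seconds; the
    plateau duration defaults to the level-dependent scheme (20/15/10 s).
    """
    if protocol is None:
        protocol = ForceProtocol(target=target)
    if target < 0 or target > 100:
        raise ValueError("target must be in (0, 100] %MVC")
    if protocol.fs <= 0 or protocol.ramp_rate <= 0:
        raise ValueError("fs and ramp_rate must be positive")
    fs = protocol.fs
    ramp_s = target / protocol.ramp_rate
    plateau_s = protocol.resolved_plateau_s()
    n_ramp = int(round(ramp_s * fs))
    n_plat = int(round(plateau_s * fs))
    up = np.linspace(0.0, target, n_ramp, endpoint=False)
    plat = np.full(n_plat, float(target))
    down = np.linspace(target, 0.0, n_ramp, endpoint=False)
    return np.concatenate([up, plat, down])


def plateau_window(force: np.ndarray, target: float, tol: float = 1e-9) -> tuple[int, int]:
    """[start, stop) sample indices of the force plateau."""
    on = np.flatnonzero(force >= target - tol)
    if on.size == 0:
        raise ValueError("force trace never reaches the target")
    return int(on[0]), int(on[-1]) + 1


@dataclass
class MotoneuronPool:
    """Ground-truth motoneuron pool.

    Per-unit arrays (index = unit), ordered by recruitment threshold:
    ``rt`` recruitment threshold (%MVC); ``a``, ``b`` parameters of the
    logarithmic rate function; ``min_rate`` firing-rate floor (pps);
    ``isi_cov`` coefficient of variation of inter-spike intervals;
    ``size`` relative action-potential amplitude; ``drt_offset``
    derecruitment-minus-recruitment threshold shift (%MVC, negative
    values produce positive hysteresis).
    """

    rt: np.ndarray
    a: np.ndarray
    b: np.ndarray
    min_rate: np.ndarray
    isi_cov: np.ndarray
    size: np.ndarray
    drt_offset: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.rt <= 0):
            raise ValueError("recruitment thresholds must be strictly positive")

    @property
    def n_units(self) -> int:
        return self.rt.size

    def rate_at(self, unit: int, force: float) -> float:
        """Target instantaneous rate of ``unit`` at ``force`` %MVC."""
        return float(max(self.min_rate[unit], self.a[unit] * math.log(force) + self.b[unit]))


def sample_pool(
    n_units: int,
    rt_range: tuple[float, float] = (0.9, 73.4),
    seed: int | None = None,
    *,
    rate_at_rt_range: tuple[float, float] = (6.0, 10.0),
    rate_at_max_range: tuple[float, float] = (25.0, 45.0),
    size_range: tuple[float, float] = (1.0, 30.0),
    isi_cov: float = 0.15,
    min_rate: float = 4.0,
    rt_jitter: float = 0.03,
    drt_offset: float | np.ndarray = 0.0,
) -> MotoneuronPool:
    """Draw a motoneuron pool with an exponential-in-rank threshold ladder.

    rt_i = rt_lo * (rt_hi/rt_lo)^((i-1)/(n-1)) with small multiplicative
    jitter, reproducing the many-low/few-high density of recruitment
    thresholds; unit sizes grow exponentially with rank (size principle).
    Deterministic for a fixed seed.
    """
    rt_lo, rt_hi = rt_range
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if rt_lo <= 0 or rt_hi <= rt_lo:
        raise ValueError("rt_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    rank = np.arange(n_units)
    if n_units == 1:
        rt = np.array([rt_lo])
        size = np.array([size_range[0]])
    else:
        rt = rt_lo * (rt_hi / rt_lo) ** (rank / (n_units - 1))
        rt = rt * np.exp(rng.normal(0.0, rt_jitter, n_units))
        rt = np.clip(np.sort(rt), rt_lo, rt_hi)
        size = size_range[0] * (size_range[1] / size_range[0]) ** (rank / (n_units - 1))
    r_rt = rng.uniform(*rate_at_rt_range, n_units)
    r_max = rng.uniform(*rate_at_max_range, n_units)
    # solve f(rt)=r_rt, f(100)=r_max for the log model
    denom = np.log(100.0) - np.log(rt)
    a = (r_max - r_rt) / np.where(denom > 1e-6, denom, 1e-6)
    b = r_rt - a * np.log(rt)
    mn = np.full(n_units, float(min_rate))
    # keep the rate at recruitment at or above the floor
    bad = r_rt < min_rate
    b[bad] += min_rate - r_rt[bad]
    return MotoneuronPool(
        rt=rt,
        a=a,
        b=b,
        min_rate=mn,
        isi_cov=np.full(n_units, float(isi_cov)),
        size=size,
        drt_offset=np.broadcast_to(np.asarray(drt_offset, dtype=float), (n_units,)).copy(),
        seed=seed,
    )


def generate_spike_trains(
    pool: MotoneuronPool,
    force: np.ndarray,
    fs: float,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Per-unit discharge sample indices for one contraction.

    A unit starts firing at the first sample where force >= rt, and keeps
    firing while force >= rt + drt_offset (a negative offset prolongs
    firing on the ramp-down: positive hysteresis). Inter-spike intervals
    are the reciprocal of max(min_rate, a*ln(F)+b), jittered by a
    multiplicative Gaussian factor of coefficient of variation
    ``isi_cov`` truncated at +/-3 SD.
    """
    rng = np.random.default_rng(seed)
    n = force.size
    trains: list[np.ndarray] = []
    for u in range(pool.n_units):
        rt = pool.rt[u]
        off_thr = rt + pool.drt_offset[u]
        cov = pool.isi_cov[u]
        spikes: list[int] = []
        t = 0
        recruited = False
        while t < n:
            f = force[t]
            thr = off_thr if recruited else rt
            if f < thr:
                if recruited:
                    recruited = False  # derecruited; may re-recruit later
                t += 1
                continue
            recruited = True
            spikes.append(t)
            rate = max(pool.min_rate[u], pool.a[u] * math.log(max(f, 1e-12)) + pool.b[u])
            jitter = 1.0 + cov * float(np.clip(rng.standard_normal(), -3.0, 3.0)) if cov > 0 else 1.0
            t += max(1, int(round(fs / rate * jitter)))
        trains.append(np.asarray(spikes, dtype=np.int64))
    return trains


@dataclass
class MUAPLibrary:
    """Per-unit monopolar action-potential templates.

    ``templates`` has shape (n_units, n_channels, window_samples); the
    waveform of each unit is centred in the window, delayed per channel by
    propagation along the grid columns, and scaled by the spatial decay
    from the unit's territory centre.
    """

    templates: np.ndarray
    geometry: GridGeometry
    fs: float
    centres_mm: np.ndarray  # (n_units, 2)
    iz_mm: np.ndarray  # innervation-zone y position per unit
    velocity_m_s: np.ndarray
    decay_mm: np.ndarray

    @property
    def n_units(self) -> int:
        return self.templates.shape[0]

    @property
    def window_samples(self) -> int:
        return self.templates.shape[2]


def muap_template(
    geometry: GridGeometry,
    centre_mm: tuple[float, float],
    iz_mm: float,
    *,
    amplitude: float = 1.0,
    sigma_ms: float = 1.5,
    velocity_m_s: float = 4.0,
    decay_mm: float = 8.0,
    window_ms: float = 25.0,
    fs: float = 2048.0,
) -> np.ndarray:
    """Single-unit monopolar template (n_channels x window samples).

    First-order Hermite-Rodriguez waveform h(t) = (t/sigma) exp(-(t/sigma)^2),
    amplitude decaying exponentially with electrode distance from the
    territory centre, onset delayed by |y - y_iz| / velocity along the
    column (fibre) direction.
    """
    if geometry.n_channels == 0:
        raise ValueError("geometry has no electrodes")
    pos = geometry.electrode_positions()
    L = int(math.floor(window_ms / 1000.0 * fs))
    t = (np.arange(L) - L // 2) / fs  # seconds, centred
    d = np.hypot(pos[:, 0] - centre_mm[0], pos[:, 1] - centre_mm[1])
    amp = amplitude * np.exp(-d / decay_mm)
    delay = np.abs(pos[:, 1] - iz_mm) / 1000.0 / velocity_m_s  # seconds
    sig = sigma_ms / 1000.0
    arg = (t[None, :] - delay[:, None]) / sig
    return amp[:, None] * arg * np.exp(-(arg**2))


def generate_muap_library(
    pool: MotoneuronPool,
    geometry: GridGeometry,
    window_ms: float = 25.0,
    seed: int | None = None,
    *,
    fs: float = 2048.0,
    sigma_ms_range: tuple[float, float] = (0.8, 2.5),
    velocity_m_s_range: tuple[float, float] = (3.0, 5.0),
    decay_mm_range: tuple[float, float] = (5.0, 10.0),
) -> MUAPLibrary:
    """Draw a unique spatial action-potential signature per unit."""
    if geometry.n_channels == 0:
        raise ValueError("geometry has no electrodes")
    rng = np.random.default_rng(seed)
    pos = geometry.electrode_positions()
    x_lo, y_lo = pos.min(axis=0)
    x_hi, y_hi = pos.max(axis=0)
    n = pool.n_units
    centres = np.column_stack(
        [rng.uniform(x_lo, x_hi, n), rng.uniform(y_lo, y_hi, n)]
    )
    iz = rng.uniform(y_lo + 0.25 * (y_hi - y_lo), y_lo + 0.75 * (y_hi - y_lo), n)
    sigma = rng.uniform(*sigma_ms_range, n)
    vel = rng.uniform(*velocity_m_s_range, n)
    decay = rng.uniform(*decay_mm_range, n)
    L = int(math.floor(window_ms / 1000.0 * fs))
    templates = np.empty((n, geometry.n_channels, L))
    for u in range(n):
        templates[u] = muap_template(
            geometry,
            (centres[u, 0], centres[u, 1]),
            iz[u],
            amplitude=pool.size[u],
            sigma_ms=sigma[u],
            velocity_m_s=vel[u],
            decay_mm=decay[u],
            window_ms=window_ms,
            fs=fs,
        )
    return MUAPLibrary(
        templates=templates,
        geometry=geometry,
        fs=fs,
        centres_mm=centres,
        iz_mm=iz,
        velocity_m_s=vel,
        decay_mm=decay,
    )


@dataclass
class SyntheticRecording:
    """A simulated contraction with ground truth attached."""

    signals: np.ndarray  # (n_channels, n_samples), monopolar
    fs: float
    force: np.ndarray  # %MVC per sample
    truth_spikes: list[np.ndarray]
    pool: MotoneuronPool
    geometry: GridGeometry
    seed: int | None = None
    target: float | None = None
    clean_power: float | None = None
    noise_power: float | None = None

    def __post_init__(self) -> None:
        if self.signals.shape[1] != self.force.size:
            raise ValueError("signals and force must have equal length")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


def _superpose(trains: list[np.ndarray], library: MUAPLibrary, n_samples: int) -> np.ndarray:
    n_ch = library.templates.shape[1]
    L = library.window_samples
    half = L // 2
    out = np.zeros((n_ch, n_samples))
    for u, spikes in enumerate(trains):
        tmpl = library.templates[u]
        for s in spikes:
            lo = s - half
            hi = lo + L
            a = max(0, -lo)
            b = L - max(0, hi - n_samples)
            if b <= a:
                continue
            out[:, lo + a : lo + b] += tmpl[:, a:b]
    return out


def synthesize(
    truth_spikes: list[np.ndarray],
    library: MUAPLibrary,
    noise_snr_db: float | None,
    fs: float,
    seed: int | None = None,
    *,
    force: np.ndarray | None = None,
    pool: MotoneuronPool | None = None,
    noise_std: float | None = None,
    n_samples: int | None = None,
    target: float | None = None,
) -> SyntheticRecording:
    """Superpose action-potential trains and add white Gaussian noise.

    Noise is scaled so that the ratio of clean-signal power to noise
    power (over the whole record, averaged across channels) equals
    ``noise_snr_db``; alternatively an absolute ``noise_std`` may be
    given (required when there are no spikes, where an SNR is undefined).
    """
    if n_samples is None:
        n_samples = force.size if force is not None else (
            int(max((s[-1] for s in truth_spikes if s.size), default=0)) + library.window_samples
        )
    clean = _superpose(truth_spikes, library, n_samples)
    clean_power = float(np.mean(clean**2))
    if noise_std is not None:
        sigma = float(noise_std)
    elif noise_snr_db is not None:
        if clean_power == 0.0:
            raise ValueError("SNR is undefined for an empty spike set; give noise_std")
        sigma = math.sqrt(clean_power / 10.0 ** (noise_snr_db / 10.0))
    else:
        sigma = 0.0
    rng = np.random.default_rng(seed)
    if sigma > 0:
        signals = clean + rng.normal(0.0, sigma, clean.shape)
    else:
        signals = clean
    if force is None:
        force = np.zeros(n_samples)
    if pool is None:
        pool = MotoneuronPool(
            rt=np.ones(len(truth_spikes)),
            a=np.zeros(len(truth_spikes)),
            b=np.zeros(len(truth_spikes)),
            min_rate=np.zeros(len(truth_spikes)),
            isi_cov=np.zeros(len(truth_spikes)),
            size=np.ones(len(truth_spikes)),
            drt_offset=np.zeros(len(truth_spikes)),
        )
    return SyntheticRecording(
        signals=signals,
        fs=fs,
        force=np.asarray(force, dtype=float),
        truth_spikes=[np.asarray(s, dtype=np.int64) for s in truth_spikes],
        pool=pool,
        geometry=library.geometry,
        seed=seed,
        target=target,
        clean_power=clean_power,
        noise_power=sigma**2,
    )


@dataclass(frozen=True)
class Scenario:
    """A named simulation condition: pool, grid, protocol and noise."""

    n_units: int
    rt_range: tuple[float, float]
    levels: tuple[float, ...]
    snr_db: float = 20.0
    size_range: tuple[float, float] = (1.0, 30.0)
    isi_cov: float = 0.15
    drt_offset: float | tuple[float, ...] = 0.0
    geometry: GridGeometry = field(default_factory=GridGeometry)
    fs: float = 2048.0


#: Validation scenario: ten well-separated units over three contraction levels.
TEN_UNIT_VALIDATION = Scenario(
    n_units=10,
    rt_range=(2.0, 25.0),
    levels=(10.0, 20.0, 30.0),
    snr_db=20.0,
    size_range=(1.0, 3.0),
)

#: Full-pool condition mirroring the validation simulation scale: 150 units,
#: thresholds spanning the 1st-99th percentile range, eight target levels.
FULL_POOL = Scenario(
    n_units=150,
    rt_range=(0.9, 73.4),
    levels=(10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0),
    snr_db=20.0,
)


def simulate_scenario(scenario: Scenario, seed: int | None = None) -> list[SyntheticRecording]:
    """One recording per contraction level, sharing pool and MUAP library.

    The pool and spatial signatures are drawn once from ``seed`` so the
    same physical units appear at every level; spike trains and noise use
    per-level child seeds.
    """
    ss = np.random.SeedSequence(seed)
    pool_seed, lib_seed, *level_seeds = [
        int(s) % (2**31) for s in ss.generate_state(2 + 2 * len(scenario.levels))
    ]
    pool = sample_pool(
        scenario.n_units,
        scenario.rt_range,
        seed=pool_seed,
        size_range=scenario.size_range,
        isi_cov=scenario.isi_cov,
        drt_offset=np.broadcast_to(
            np.asarray(scenario.drt_offset, dtype=float), (scenario.n_units,)
        ).copy(),
    )
    library = generate_muap_library(pool, scenario.geometry, seed=lib_seed, fs=scenario.fs)
    recordings = []
    for i, level in enumerate(scenario.levels):
        force = build_force_profile(level, ForceProtocol(target=level, fs=scenario.fs))
        trains = generate_spike_trains(pool, force, scenario.fs, seed=level_seeds[2 * i])
        rec = synthesize(
            trains,
            library,
            scenario.snr_db,
            scenario.fs,
            seed=level_seeds[2 * i + 1],
            force=force,
            pool=pool,
            target=level,
        )
        recordings.append(rec)
    return recordings
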