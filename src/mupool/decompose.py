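"""Convolutive blind-source-separation of multichannel EMG.

The observation model treats the EMG as a convolutive mixture of sparse
motor-unit spike trains. The mixture is made (approximately) instantaneous
by extending each channel with delayed copies, spatially whitened, and
source vectors are estimated one at a time with a fixed-point iteration on
the log-cosh contrast, deflating against previously accepted sources.
Discharge times are the high peaks of the squared source estimate,
separated from baseline activity by two-class centroid clustering; a unit
is accepted when the two peak classes separate with a silhouette value of
at least 0.9. Duplicate estimates of the same unit (recovered at different
delays) are merged, keeping the train with the most regular inter-spike
intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate, find_peaks
from sklearn.cluster import KMeans

from .synth import SyntheticRecording

NOT_COMPUTABLE = float("nan")


@dataclass(frozen=True)
class DecompositionConfig:
    """Thresholds and sizes of the separation algorithm (defaults as printed)."""

    target_extended_channels: int = 1000
    convergence_tol: float = 1e-4
    max_iterations_per_source: int = 100
    n_source_attempts: int = 40
    silhouette_min: float = 0.9
    duplicate_interval_ms: float = 0.5
    duplicate_fraction: float = 0.30
    peak_min_distance_ms: float = 10.0
    min_discharges: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.duplicate_fraction <= 1):
            raise ValueError("duplicate_fraction must be in (0, 1]")
        if self.convergence_tol <= 0 or self.target_extended_channels <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ExtendedWhitenedObservation:
    """Extended, centred and spatially whitened observation.

    ``matrix`` is the whitened data Z = W (X_ext - mean); ``whitening_operator``
    and ``mean_vector`` are stored so that another recording can be carried
    into the same whitened space (cross-contraction reprojection).
    """

    matrix: np.ndarray
    extension_factor: int
    whitening_operator: np.ndarray
    mean_vector: np.ndarray


@dataclass
class MotorUnitEstimate:
    """One decomposed motor unit."""

    separation_vector: np.ndarray  # unit norm, in whitened space
    pulse_train: np.ndarray  # squared source estimate
    discharges: np.ndarray  # sorted sample indices
    silhouette: float
    isi_cov: float
    unit_id: int = -1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.discharges) <= 0):
            raise ValueError("discharges must be strictly increasing")


def extend(signals: np.ndarray, target_extended: int) -> tuple[np.ndarray, int]:
    """Stack delayed copies of each channel.

    The extension factor R is the smallest integer with
    ``n_channels * R >= target_extended``; row ``k*R + d`` holds channel k
    delayed by d samples (leading zeros). A target at or below the channel
    count yields R = 1 (identity).
    """
    signals = np.atleast_2d(np.asarray(signals))
    m, n = signals.shape
    if m < 1 or n < 1:
        raise ValueError("need at least one channel and one sample")
    r = max(1, math.ceil(target_extended / m))
    if r >= n:
        raise ValueError("extension factor exceeds signal length")
    out = np.zeros((m * r, n), dtype=signals.dtype)
    for d in range(r):
        out[d::r, d:] = signals[:, : n - d] if d else signals
    return out, r


def whiten(extended: np.ndarray, rcond: float = 1e-9) -> ExtendedWhitenedObservation:
    """Centre rows and whiten by eigen-decomposition of the covariance.

    Near-zero eigenvalues (below ``rcond`` times the largest) are floored
    to the mean of the smallest half of the spectrum, so rank-deficient
    inputs (e.g. duplicated channels) are handled without failure while
    well-conditioned inputs whiten exactly.
    """
    x = np.asarray(extended, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    n = xc.shape[1]
    cov = (xc @ xc.T) / n
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("degenerate covariance (all-zero input)")
    floor = float(np.mean(evals[: max(1, evals.size // 2)]))
    evals = np.where(evals < rcond * evals[-1], max(floor, rcond * evals[-1]), evals)
    w = (evecs / np.sqrt(evals)) @ evecs.T
    return ExtendedWhitenedObservation(
        matrix=w @ xc,
        extension_factor=1,
        whitening_operator=w,
        mean_vector=mean[:, 0],
    )


def fixed_point_source(
    obs: ExtendedWhitenedObservation,
    w_init: np.ndarray,
    cfg: DecompositionConfig = DecompositionConfig(),
    deflate_against: np.ndarray | None = None,
) -> np.ndarray | None:
    """Fixed-point iteration on the log-cosh contrast.

    Iterates w <- E[z g'(w'z)] - E[g''(w'z)] w with g(x)=log cosh(x)
    (g'=tanh, g''=1-tanh^2), renormalising to unit length each step and
    orthogonalising against accepted separation vectors. Convergence when
    |1 - |w_n . w_{n-1}|| < tol. Returns None if the update becomes
    non-finite (this source attempt is abandoned).
    """
    z = obs.matrix
    n = z.shape[1]
    w = np.asarray(w_init, dtype=float).copy()
    if not np.any(w):
        raise ValueError("w_init must be nonzero")

    def project(v: np.ndarray) -> np.ndarray:
        if deflate_against is not None and deflate_against.size:
            v = v - deflate_against @ (deflate_against.T @ v)
        return v

    w = project(w)
    nw = np.linalg.norm(w)
    if nw == 0:
        return None
    w /= nw
    for _ in range(cfg.max_iterations_per_source):
        u = w @ z
        gu = np.tanh(u)
        w_new = (z @ gu) / n - float(np.mean(1.0 - gu**2)) * w
        w_new = project(w_new)
        norm = np.linalg.norm(w_new)
        if not np.isfinite(norm) or norm == 0:
            return None
        w_new /= norm
        if abs(1.0 - abs(float(w_new @ w))) < cfg.convergence_tol:
            return w_new
        w = w_new
    return w


def detect_discharges(
    pulse_train: np.ndarray,
    fs: float = 2048.0,
    cfg: DecompositionConfig = DecompositionConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discharge times from a source estimate.

    The train is squared (sign disambiguation), local maxima at least
    ``peak_min_distance_ms`` apart are clustered into two amplitude
    classes by centroid (k-means) clustering, and the peaks of the
    higher-centroid class are the discharges.

    Returns (discharge indices, all peak indices, labels) where labels
    are 1 for the spike class. Degenerate cases (fewer than two peaks, or
    indistinguishable amplitude classes) return all peaks labelled 1 with
    a warning.
    """
    if pulse_train.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype=int)
    sq = np.asarray(pulse_train, dtype=float) ** 2
    dist = max(1, int(round(cfg.peak_min_distance_ms / 1000.0 * fs)))
    peaks, _ = find_peaks(sq, distance=dist)
    if peaks.size < 2:
        warnings.warn("fewer than two peaks; no discharge classes", stacklevel=2)
        return np.array([], dtype=np.int64), peaks.astype(np.int64), np.ones(peaks.size, dtype=int)
    amps = sq[peaks]
    if np.ptp(amps) == 0:
        warnings.warn("all peaks identical; degenerate clustering", stacklevel=2)
        return peaks.astype(np.int64), peaks.astype(np.int64), np.ones(peaks.size, dtype=int)
    km = KMeans(
        n_clusters=2,
        n_init=1,
        init=np.array([[amps.min()], [amps.max()]]),
    ).fit(amps.reshape(-1, 1))
    spike_label = int(np.argmax(km.cluster_centers_.ravel()))
    labels = (km.labels_ == spike_label).astype(int)
    return peaks[labels == 1].astype(np.int64), peaks.astype(np.int64), labels


def silhouette_measure(peak_amplitudes: np.ndarray, labels: np.ndarray) -> float:
    """Two-cluster silhouette averaged over the spike class.

    For each spike-class amplitude, a = mean |distance| to the other
    spike-class amplitudes, b = mean |distance| to the noise-class
    amplitudes; the silhouette is mean (b-a)/max(a,b). Returns NaN when
    either class is empty (not computable).
    """
    amps = np.asarray(peak_amplitudes, dtype=float)
    labels = np.asarray(labels)
    spike = amps[labels == 1]
    noise = amps[labels != 1]
    if spike.size == 0 or noise.size == 0:
        return NOT_COMPUTABLE
    vals = np.empty(spike.size)
    for i, x in enumerate(spike):
        if spike.size > 1:
            a = float(np.mean(np.abs(np.delete(spike, i) - x)))
        else:
            a = 0.0
        b = float(np.mean(np.abs(noise - x)))
        m = max(a, b)
        vals[i] = 0.0 if m == 0 else (b - a) / m
    return float(np.mean(vals))


def isi_coefficient_of_variation(discharges: np.ndarray) -> float:
    isi = np.diff(np.asarray(discharges, dtype=float))
    if isi.size < 2 or np.mean(isi) == 0:
        return NOT_COMPUTABLE
    return float(np.std(isi) / np.mean(isi))


def _count_common(a: np.ndarray, b: np.ndarray, tol: int) -> int:
    """Greedy one-to-one count of discharges within tol samples (sorted inputs)."""
    i = j = common = 0
    while i < a.size and j < b.size:
        d = a[i] - b[j]
        if abs(d) <= tol:
            common += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return common


def best_alignment_lag(
    a: np.ndarray, b: np.ndarray, max_lag: int, tol: int = 0
) -> tuple[int, int]:
    """Lag (added to b) maximising common discharges, via cross-correlation
    of binarised trains; ties broken toward the smallest |lag|.

    Symmetric: swapping the trains negates the lag and preserves the
    count (arguments are canonically ordered internally).

    Returns (lag, common count at that lag under ``tol``).
    """
    if a.size == 0 or b.size == 0:
        return 0, 0
    if (b.size, b.tobytes()) < (a.size, a.tobytes()):
        lag, common = best_alignment_lag(b, a, max_lag, tol)
        return -lag, common
    n = int(max(a[-1], b[-1])) + 1
    xa = np.zeros(n)
    xb = np.zeros(n)
    xa[a] = 1.0
    xb[b] = 1.0
    corr = correlate(xa, xb, mode="full", method="fft")  # index n-1 is zero lag
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    order = np.lexsort((np.abs(lags), -corr))
    best = lags[order[0]]
    # refine around the correlation peak with the matching tolerance
    best_common = -1
    best_lag = 0
    for lag in range(best - tol - 1, best + tol + 2):
        c = _count_common(a, b + lag, tol)
        if c > best_common or (c == best_common and abs(lag) < abs(best_lag)):
            best_common = c
            best_lag = lag
    return int(best_lag), int(best_common)


def common_discharge_fraction(
    a: np.ndarray,
    b: np.ndarray,
    fs: float,
    tol_ms: float = 0.5,
    max_lag_ms: float = 50.0,
) -> tuple[float, int]:
    """Fraction of common discharges after optimal lag alignment.

    Trains are aligned at the lag maximising the cross-correlation of the
    binarised trains; discharges within ``tol_ms`` count as common, and
    the fraction is common / min(n_a, n_b).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        return 0.0, 0
    tol = int(round(tol_ms / 1000.0 * fs))
    lag, common = best_alignment_lag(a, b, max_lag=int(round(max_lag_ms / 1000.0 * fs)), tol=tol)
    return common / min(a.size, b.size), lag


def find_duplicates(
    units: list[MotorUnitEstimate],
    fs: float,
    cfg: DecompositionConfig = DecompositionConfig(),
) -> tuple[list[list[int]], list[int]]:
    """Cluster duplicate estimates and pick a representative per cluster.

    Pairs sharing at least ``duplicate_fraction`` of discharges (within
    ``duplicate_interval_ms`` after lag alignment) are linked; connected
    components form clusters; the member with the lowest ISI coefficient
    of variation is retained.
    """
    n = len(units)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            frac, _ = common_discharge_fraction(
                units[i].discharges, units[j].discharges, fs, cfg.duplicate_interval_ms
            )
            if frac >= cfg.duplicate_fraction:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    cluster_lists = list(clusters.values())
    retained = []
    for members in cluster_lists:
        covs = [
            units[m].isi_cov if np.isfinite(units[m].isi_cov) else np.inf for m in members
        ]
        retained.append(members[int(np.argmin(covs))])
    return cluster_lists, retained


@dataclass
class DecompositionResult:
    """Accepted units plus everything needed to reproject another recording."""

    units: list[MotorUnitEstimate]
    extension_factor: int
    whitening_operator: np.ndarray
    mean_vector: np.ndarray
    fs: float
    config: DecompositionConfig = field(default_factory=DecompositionConfig)
    n_attempted: int = 0
    n_accepted_raw: int = 0


def decompose(
    recording: SyntheticRecording,
    cfg: DecompositionConfig = DecompositionConfig(),
) -> DecompositionResult:
    """Full separation of one recording into accepted motor-unit estimates.

    extend -> whiten -> repeatedly {initialise the separation vector at
    the whitened observation column of highest unclaimed activity;
    fixed-point iterate with deflation; detect discharges; accept when
    the silhouette reaches threshold} -> remove duplicates.
    Zero accepted units is a valid outcome (e.g. pure noise).
    """
    fs = recording.fs
    ext, r = extend(recording.signals, cfg.target_extended_channels)
    obs = whiten(ext)
    obs.extension_factor = r
    del ext
    z = obs.matrix
    activity = np.sum(z**2, axis=0)
    claim = max(1, int(round(cfg.peak_min_distance_ms / 1000.0 * fs)))
    accepted: list[MotorUnitEstimate] = []
    basis = np.empty((z.shape[0], 0))
    n_attempted = 0
    for _ in range(cfg.n_source_attempts):
        t0 = int(np.argmax(activity))
        if activity[t0] <= 0:
            break
        n_attempted += 1
        activity[max(0, t0 - claim) : t0 + claim + 1] = 0.0
        w = fixed_point_source(obs, z[:, t0], cfg, deflate_against=basis)
        if w is None:
            continue
        source = w @ z
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            discharges, peaks, labels = detect_discharges(source, fs, cfg)
        if discharges.size < cfg.min_discharges:
            continue
        sil = silhouette_measure(source[peaks] ** 2, labels)
        if not np.isfinite(sil) or sil < cfg.silhouette_min:
            continue
        est = MotorUnitEstimate(
            separation_vector=w,
            pulse_train=source**2,
            discharges=discharges,
            silhouette=float(sil),
            isi_cov=isi_coefficient_of_variation(discharges),
        )
        accepted.append(est)
        basis = np.column_stack([basis, w])
        for s in discharges:
            activity[max(0, s - claim) : s + claim + 1] = 0.0
    n_raw = len(accepted)
    if accepted:
        _, retained = find_duplicates(accepted, fs, cfg)
        accepted = [accepted[i] for i in sorted(retained)]
    for uid, est in enumerate(accepted):
        est.unit_id = uid
    return DecompositionResult(
        units=accepted,
        extension_factor=r,
        whitening_operator=obs.whitening_operator,
        mean_vector=obs.mean_vector,
        fs=fs,
        config=cfg,
        n_attempted=n_attempted,
        n_accepted_raw=n_raw,
    )
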