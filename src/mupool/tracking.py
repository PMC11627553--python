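"""Cross-contraction motor-unit tracking and spike-train agreement.

Units are tracked between consecutive contraction levels by carrying the
separation vectors estimated at one level into the other level's
recording: the second recording is extended with the first level's
extension factor, centred and whitened with its stored whitening
operator, and projected onto its separation vectors. Discharges detected
from these reprojected pulse trains (when the spike class separates
cleanly from the noise) are matched against the units identified natively
at the second level; pairs sharing more than 30% of discharge times are
the same unit. Chains of pairwise matches are merged transitively into a
registry of unique units across all levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decompose import (
    DecompositionConfig,
    DecompositionResult,
    MotorUnitEstimate,
    NOT_COMPUTABLE,
    _count_common,
    best_alignment_lag,
    common_discharge_fraction,
    detect_discharges,
    silhouette_measure,
)
from .synth import SyntheticRecording


@dataclass(frozen=True)
class MatchResult:
    common_fraction: float
    lag: int
    is_match: bool


@dataclass
class TrackedMotorUnit:
    """One physical unit with its estimate at every level where it was found."""

    unit_id: int
    by_level: dict[float, MotorUnitEstimate] = field(default_factory=dict)
    provenance: float | None = None  # level of first identification

    @property
    def levels(self) -> list[float]:
        return sorted(self.by_level)


def reproject(
    result_a: DecompositionResult,
    recording_b: SyntheticRecording,
    cfg: DecompositionConfig | None = None,
) -> list[np.ndarray | None]:
    """Project recording B through A's separation vectors.

    Returns one discharge train per unit of A, or None where the
    reprojected pulse train's spike class does not separate cleanly from
    the noise (silhouette below threshold).
    """
    cfg = cfg or result_a.config
    from .decompose import extend  # local import to avoid cycle confusion

    if recording_b.signals.shape[0] * result_a.extension_factor != result_a.mean_vector.size:
        raise ValueError("channel layout of B does not match A's decomposition")
    ext, _ = extend(
        recording_b.signals, recording_b.signals.shape[0] * result_a.extension_factor
    )
    z = result_a.whitening_operator @ (ext - result_a.mean_vector[:, None])
    out: list[np.ndarray | None] = []
    for unit in result_a.units:
        source = unit.separation_vector @ z
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            discharges, peaks, labels = detect_discharges(source, result_a.fs, cfg)
        if discharges.size < cfg.min_discharges:
            out.append(None)
            continue
        sil = silhouette_measure(source[peaks] ** 2, labels)
        out.append(discharges if np.isfinite(sil) and sil >= cfg.silhouette_min else None)
    return out


def match_trains(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    fs: float,
    tol_ms: float = 0.5,
    threshold: float = 0.30,
) -> MatchResult:
    """Common-discharge matching of one pair of trains (duplicate logic)."""
    frac, lag = common_discharge_fraction(spikes_a, spikes_b, fs, tol_ms)
    return MatchResult(common_fraction=frac, lag=lag, is_match=frac >= threshold)


def rate_of_agreement(
    est_spikes: np.ndarray,
    ref_spikes: np.ndarray,
    fs: float,
    tol_ms: float = 0.5,
    align: bool = True,
) -> float:
    """RoA = TP / (TP + FN + FP) between two discharge series.

    Greedy one-to-one nearest matching within ``tol_ms`` after optimal
    lag alignment of the binarised trains. Symmetric in its arguments.
    Returns NaN when both trains are empty.
    """
    a = np.asarray(est_spikes, dtype=np.int64)
    b = np.asarray(ref_spikes, dtype=np.int64)
    if a.size == 0 and b.size == 0:
        return NOT_COMPUTABLE
    if a.size == 0 or b.size == 0:
        return 0.0
    tol = int(round(tol_ms / 1000.0 * fs))
    if align:
        max_lag = int(round(0.05 * fs))
        _, tp = best_alignment_lag(a, b, max_lag=max_lag, tol=tol)
    else:
        tp = _count_common(a, b, tol)
    fn = b.size - tp
    fp = a.size - tp
    return tp / (tp + fn + fp)


@dataclass
class TrackingReport:
    """Per consecutive-level-pair match bookkeeping."""

    pair: tuple[float, float]
    matches: list[tuple[int, int, float]]  # (unit index at lo, unit index at hi, fraction)
    n_lo: int
    n_hi: int

    @property
    def yield_fraction(self) -> float:
        """Fraction of units identified at the lower level tracked into the higher."""
        return len(self.matches) / self.n_lo if self.n_lo else NOT_COMPUTABLE


def match_levels(
    result_lo: DecompositionResult,
    recording_lo: SyntheticRecording,
    result_hi: DecompositionResult,
    cfg: DecompositionConfig | None = None,
) -> list[tuple[int, int, float]]:
    """Match units between two consecutive levels via reprojection.

    The higher level's separation vectors are carried onto the lower
    level's recording and the resulting pulse trains are matched (>30%
    common discharges) against the units identified natively at the
    lower level. This direction is the robust one: units recruited only
    at the higher level simply fall silent in the lower recording,
    whereas the opposite projection is corrupted by the activity of
    units the lower-level vectors have never seen. Each side is matched
    at most once, resolving conflicts by highest common fraction.

    Returns (lower unit index, upper unit index, common fraction) triples.
    """
    cfg = cfg or result_lo.config
    reproj = reproject(result_hi, recording_lo, cfg)
    candidates: list[tuple[float, int, int]] = []
    for j, train in enumerate(reproj):
        if train is None:
            continue
        for i, unit_lo in enumerate(result_lo.units):
            m = match_trains(
                train, unit_lo.discharges, result_lo.fs, cfg.duplicate_interval_ms,
                cfg.duplicate_fraction,
            )
            if m.is_match:
                candidates.append((m.common_fraction, i, j))
    candidates.sort(reverse=True)
    used_lo: set[int] = set()
    used_hi: set[int] = set()
    matches = []
    for frac, i, j in candidates:
        if i in used_lo or j in used_hi:
            continue
        used_lo.add(i)
        used_hi.add(j)
        matches.append((i, j, frac))
    return matches


def build_registry(
    results: dict[float, DecompositionResult],
    recordings: dict[float, SyntheticRecording],
    cfg: DecompositionConfig | None = None,
) -> tuple[list[TrackedMotorUnit], list[TrackingReport]]:
    """Merge per-level estimates into unique tracked units.

    Tracking runs between consecutive levels (ascending); identities are
    merged transitively, so a unit matched 10<->20 and 20<->30 spans
    10-30. Every per-level estimate lands in exactly one registry entry.
    """
    levels = sorted(results)
    # registry id per (level, unit index)
    ids: dict[tuple[float, int], int] = {}
    next_id = 0
    reports: list[TrackingReport] = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        matches = match_levels(results[lo], recordings[lo], results[hi], cfg)
        reports.append(
            TrackingReport(
                pair=(lo, hi),
                matches=matches,
                n_lo=len(results[lo].units),
                n_hi=len(results[hi].units),
            )
        )
    for level in levels:
        for i in range(len(results[level].units)):
            ids[(level, i)] = -1
    for report in reports:
        lo, hi = report.pair
        for i, j, _ in report.matches:
            if ids[(lo, i)] == -1:
                ids[(lo, i)] = next_id
                next_id += 1
            ids[(hi, j)] = ids[(lo, i)]
    for level in levels:
        for i in range(len(results[level].units)):
            if ids[(level, i)] == -1:
                ids[(level, i)] = next_id
                next_id += 1
    registry: dict[int, TrackedMotorUnit] = {}
    for (level, i), uid in sorted(ids.items()):
        tmu = registry.setdefault(uid, TrackedMotorUnit(unit_id=uid, provenance=level))
        tmu.by_level[level] = results[level].units[i]
        if tmu.provenance is None or level < tmu.provenance:
            tmu.provenance = level
    return [registry[k] for k in sorted(registry)], reports
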