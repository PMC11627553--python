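"""Stage orchestration: simulate -> decompose -> track -> validate -> ratecode.

Each stage reads and writes artifacts in a working directory, so the
pipeline can be resumed stage by stage; ``run_pipeline("all", ...)`` runs
the five stages in sequence. Heavy intermediates (whitening operators,
separation vectors) are stored as .npz next to the HDF5 recordings;
summary outputs are CSV/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ratecoding as rc
from .decompose import DecompositionResult, MotorUnitEstimate, decompose
from .io import (
    ContainerFormatError,
    PipelineConfig,
    export_spikes_csv,
    read_recording,
    write_recording,
    write_report,
    write_templates,
)
from .synth import (
    Scenario,
    SyntheticRecording,
    build_force_profile,
    plateau_window,
    simulate_scenario,
)
from .tracking import TrackedMotorUnit, build_registry, rate_of_agreement
from .waveforms import (
    estimate_templates,
    explained_power_ratio,
    reconstruct_synthetic,
    single_differential,
    uniqueness_test,
)

#: matching tolerance (ms) for agreement with simulation ground truth;
#: wider than the 0.5 ms duplicate window to absorb +/- one sample of
#: peak-detection jitter after lag alignment.
TRUTH_ROA_TOL_MS = 2.0


def _level_name(level: float) -> str:
    return f"level_{level:05.1f}".replace(".", "p")


def scenario_from_config(cfg: PipelineConfig) -> Scenario:
    return Scenario(
        n_units=cfg.n_units,
        rt_range=(cfg.rt_lo, cfg.rt_hi),
        levels=cfg.levels,
        snr_db=cfg.snr_db,
        size_range=(cfg.size_lo, cfg.size_hi),
        isi_cov=cfg.isi_cov,
        drt_offset=cfg.drt_offset,
        geometry=cfg.geometry(),
        fs=cfg.fs,
    )


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict[float, SyntheticRecording]:
    workdir.mkdir(parents=True, exist_ok=True)
    recs = simulate_scenario(scenario_from_config(cfg), seed=cfg.seed)
    out = {}
    for rec in recs:
        name = _level_name(rec.target)
        write_recording(workdir / f"{name}.h5", rec)
        export_spikes_csv(
            workdir / f"{name}_truth_spikes.csv",
            {u: s for u, s in enumerate(rec.truth_spikes)},
            rec.fs,
        )
        out[rec.target] = rec
    return out


def _save_result(path: Path, res: DecompositionResult) -> None:
    np.savez_compressed(
        path,
        extension_factor=res.extension_factor,
        whitening_operator=res.whitening_operator,
        mean_vector=res.mean_vector,
        fs=res.fs,
        n_attempted=res.n_attempted,
        n_accepted_raw=res.n_accepted_raw,
        vectors=np.array([u.separation_vector for u in res.units])
        if res.units
        else np.empty((0, res.mean_vector.size)),
        silhouettes=np.array([u.silhouette for u in res.units]),
        isi_covs=np.array([u.isi_cov for u in res.units]),
        **{
            f"discharges_{u.unit_id:03d}": u.discharges for u in res.units
        },
    )


def _load_result(path: Path, cfg: PipelineConfig) -> DecompositionResult:
    with np.load(path) as z:
        units = []
        for uid in range(z["vectors"].shape[0]):
            units.append(
                MotorUnitEstimate(
                    separation_vector=z["vectors"][uid],
                    pulse_train=np.array([]),
                    discharges=z[f"discharges_{uid:03d}"],
                    silhouette=float(z["silhouettes"][uid]),
                    isi_cov=float(z["isi_covs"][uid]),
                    unit_id=uid,
                )
            )
        return DecompositionResult(
            units=units,
            extension_factor=int(z["extension_factor"]),
            whitening_operator=z["whitening_operator"],
            mean_vector=z["mean_vector"],
            fs=float(z["fs"]),
            config=cfg.decomposition(),
            n_attempted=int(z["n_attempted"]),
            n_accepted_raw=int(z["n_accepted_raw"]),
        )


def stage_decompose(cfg: PipelineConfig, workdir: Path) -> dict[float, DecompositionResult]:
    results = {}
    for level in cfg.levels:
        name = _level_name(level)
        h5 = workdir / f"{name}.h5"
        if not h5.exists():
            raise ContainerFormatError(f"missing recording {h5}; run simulate first")
        rec = read_recording(h5)
        res = decompose(rec, cfg.decomposition())
        _save_result(workdir / f"{name}_decomposition.npz", res)
        export_spikes_csv(
            workdir / f"{name}_spikes.csv",
            {u.unit_id: u.discharges for u in res.units},
            rec.fs,
            silhouettes={u.unit_id: u.silhouette for u in res.units},
        )
        write_report(
            workdir / f"{name}_decomposition.json",
            {
                "config": cfg.echo(),
                "level": level,
                "n_attempted": res.n_attempted,
                "n_accepted_before_dedup": res.n_accepted_raw,
                "n_units": len(res.units),
                "silhouettes": [u.silhouette for u in res.units],
            },
        )
        results[level] = res
    return results


def _load_all(cfg: PipelineConfig, workdir: Path):
    recordings = {}
    results = {}
    for level in cfg.levels:
        name = _level_name(level)
        recordings[level] = read_recording(workdir / f"{name}.h5")
        results[level] = _load_result(workdir / f"{name}_decomposition.npz", cfg)
    return recordings, results


def stage_track(cfg: PipelineConfig, workdir: Path):
    recordings, results = _load_all(cfg, workdir)
    registry, reports = build_registry(results, recordings, cfg.decomposition())
    payload = {
        "config": cfg.echo(),
        "pairs": [
            {
                "levels": list(r.pair),
                "n_lower": r.n_lo,
                "n_upper": r.n_hi,
                "n_matched": len(r.matches),
                "yield_fraction": r.yield_fraction,
                "match_fractions": [m[2] for m in r.matches],
            }
            for r in reports
        ],
        "registry": [
            {
                "unit_id": t.unit_id,
                "levels": t.levels,
                "first_identified_at": t.provenance,
                "spike_csv": {
                    str(lv): f"{_level_name(lv)}_spikes.csv" for lv in t.levels
                },
            }
            for t in registry
        ],
    }
    write_report(workdir / "tracking.json", payload)
    return registry, reports


def _align_to_reference(ref: np.ndarray, other: np.ndarray, max_shift: int) -> np.ndarray:
    """Time-shift ``other`` (all channels jointly) to best match ``ref``.

    Separate decompositions of the same unit recover its discharge train
    with different constant delays (any delayed source is an equally
    valid solution of the convolutive model), so templates estimated at
    different levels are time-shifted copies; they are aligned on the
    shift minimising the residual before any cross-level comparison.
    """
    best_shift, best_score = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        score = float(np.sum(ref * np.roll(other, s, axis=1)))
        if score > best_score:
            best_score, best_shift = score, s
    return np.roll(other, best_shift, axis=1)


def unit_templates(
    registry: list[TrackedMotorUnit],
    recordings: dict[float, SyntheticRecording],
    window_ms: float,
) -> dict[int, dict[float, np.ndarray]]:
    """Per tracked unit, per level: SD template matrix from its discharges.

    Within a unit, templates from the second level on are aligned to the
    first level's template.
    """
    sds = {
        lv: single_differential(rec.signals, rec.geometry, rec.fs)
        for lv, rec in recordings.items()
    }
    out: dict[int, dict[float, np.ndarray]] = {}
    for tmu in registry:
        out[tmu.unit_id] = {}
        ref = None
        for lv, est in sorted(tmu.by_level.items()):
            tset = estimate_templates(sds[lv], {0: est.discharges}, window_ms)
            tmpl = tset.templates[0]
            if ref is None:
                ref = tmpl
            else:
                tmpl = _align_to_reference(ref, tmpl, max_shift=tmpl.shape[1] // 3)
            out[tmu.unit_id][lv] = tmpl
    return out


def stage_validate(cfg: PipelineConfig, workdir: Path) -> dict:
    recordings, results = _load_all(cfg, workdir)
    registry, _ = build_registry(results, recordings, cfg.decomposition())
    # explained power per level from the decomposed trains
    per_level_power = {}
    for lv, rec in recordings.items():
        sd = single_differential(rec.signals, rec.geometry, rec.fs)
        trains = {u.unit_id: u.discharges for u in results[lv].units}
        if not trains:
            per_level_power[lv] = float("nan")
            continue
        tset = estimate_templates(sd, trains, cfg.sta_window_ms)
        write_templates(workdir / f"{_level_name(lv)}.h5", tset.templates, cfg.sta_window_ms)
        synth = reconstruct_synthetic(tset.templates, trains, rec.n_samples)
        window = plateau_window(rec.force, rec.target) if rec.target else None
        per_level_power[lv] = explained_power_ratio(synth, sd.sd_signals, window)
    templates = unit_templates(registry, recordings, cfg.uniqueness_window_ms)
    report = uniqueness_test(templates)
    rows = [
        {
            "unit_id": e.unit_id,
            "reference_rmse_pct": e.reference_rmse,
            "fifth_percentile_pct": e.fifth_percentile,
            "unique": e.unique,
            "outlier": e.outlier,
            "assessable": e.assessable,
        }
        for e in report.entries
    ]
    pd.DataFrame(rows).to_csv(workdir / "uniqueness.csv", index=False)
    payload = {
        "config": cfg.echo(),
        "explained_power_ratio_by_level": {str(k): v for k, v in per_level_power.items()},
        "fraction_unique": report.fraction_unique,
        "outlier_unit_ids": report.outlier_ids(),
    }
    write_report(workdir / "validation.json", payload)
    return payload


def build_profiles(
    registry: list[TrackedMotorUnit],
    recordings: dict[float, SyntheticRecording],
    cfg: PipelineConfig,
    exclude: set[int] | None = None,
) -> list[rc.RateCodingProfile]:
    """Rate-coding profile of every tracked (non-outlier) unit."""
    exclude = exclude or set()
    profiles = []
    for tmu in registry:
        if tmu.unit_id in exclude:
            continue
        per_thr = []
        obs_up = []
        obs_down = []
        plateau_rates: dict[float, float] = {}
        for lv, est in sorted(tmu.by_level.items()):
            rec = recordings[lv]
            p_lo, p_hi = plateau_window(rec.force, rec.target)
            per_thr.append(rc.thresholds(est.discharges, rec.force, rec.target))
            obs_up.append(
                rc.ramp_observation(est.discharges, rec.force, rec.fs, (0, p_lo), "up")
            )
            obs_down.append(
                rc.ramp_observation(
                    est.discharges, rec.force, rec.fs, (p_hi, rec.n_samples), "down"
                )
            )
            plateau_rates[lv] = rc.plateau_mean_rate(est.discharges, rec.fs, (p_lo, p_hi))
        rt, drt, hysteresis = rc.pooled_thresholds(per_thr)
        pooled_up = rc.pool_ramp_observations(obs_up)
        pooled_down = rc.pool_ramp_observations(obs_down)
        fits_up: dict[str, rc.ModelFit] = {}
        best_up = best_down = None
        accel_f = accel_t = float("nan")
        try:
            fits_up = rc.fit_candidates(pooled_up)
            best_up = rc.select_best(fits_up)
            if np.isfinite(rt) and rt > 0:
                accel_f, accel_t = rc.initial_acceleration(
                    fits_up["natural_log"], rt, cfg.ramp_rate
                )
        except ValueError:
            pass
        try:
            best_down = rc.select_best(rc.fit_candidates(pooled_down))
        except ValueError:
            pass
        increments, mean_inc = rc.rate_increments(plateau_rates)
        profiles.append(
            rc.RateCodingProfile(
                unit_id=tmu.unit_id,
                rt=rt,
                drt=drt,
                hysteresis=hysteresis,
                group=rc.threshold_group(rt) if np.isfinite(rt) else "unknown",
                best_model_up=best_up,
                best_model_down=best_down,
                fits_up=fits_up,
                init_accel_force=accel_f,
                init_accel_time=accel_t,
                plateau_rates=plateau_rates,
                increments=increments,
                mean_increment=mean_inc,
            )
        )
    return profiles


def stage_ratecode(cfg: PipelineConfig, workdir: Path):
    recordings, results = _load_all(cfg, workdir)
    registry, _ = build_registry(results, recordings, cfg.decomposition())
    templates = unit_templates(registry, recordings, cfg.uniqueness_window_ms)
    outliers = set(uniqueness_test(templates).outlier_ids())
    profiles = build_profiles(registry, recordings, cfg, exclude=outliers)
    rows = []
    for p in profiles:
        row = {
            "unit_id": p.unit_id,
            "rt": p.rt,
            "drt": p.drt,
            "hysteresis": p.hysteresis,
            "group": p.group,
            "model_up": p.best_model_up,
            "model_down": p.best_model_down,
            "init_accel_force": p.init_accel_force,
            "init_accel_time": p.init_accel_time,
            "mean_increment": p.mean_increment,
        }
        for m in rc.MODELS:
            if m in p.fits_up:
                row[f"bic_{m}"] = p.fits_up[m].bic
        if "natural_log" in p.fits_up:
            row["a_log"], row["b_log"] = p.fits_up["natural_log"].params
        for lv, rate in p.plateau_rates.items():
            row[f"plateau_rate_{lv:g}"] = rate
        rows.append(row)
    pd.DataFrame(rows).to_csv(workdir / "profiles.csv", index=False)
    pools = rc.pool_regressions(profiles)
    write_report(
        workdir / "pool_regressions.json",
        {
            "config": cfg.echo(),
            "n_units": pools.n_units,
            "skipped": pools.skipped,
            "accel_vs_rt": pools.accel_vs_rt,
            "increment_vs_rt": pools.increment_vs_rt,
            "rt_vs_drt": pools.rt_vs_drt,
        },
    )
    return profiles, pools


STAGES = ("simulate", "decompose", "track", "validate", "ratecode")


def run_pipeline(command: str, cfg: PipelineConfig, workdir: str | Path) -> dict:
    """Run one stage (or ``"all"``) in ``workdir``; returns a summary dict.

    Exit semantics for callers: zero accepted units is a valid outcome,
    not an error; malformed containers and missing prerequisites raise.
    """
    workdir = Path(workdir)
    if command not in STAGES + ("all",):
        raise ValueError(f"unknown command {command!r}")
    summary: dict = {"command": command, "config": cfg.echo(), "workdir": str(workdir)}
    commands = STAGES if command == "all" else (command,)
    for cmd in commands:
        if cmd == "simulate":
            recs = stage_simulate(cfg, workdir)
            summary["simulate"] = {
                str(lv): {"n_samples": r.n_samples, "n_truth_units": len(r.truth_spikes)}
                for lv, r in recs.items()
            }
        elif cmd == "decompose":
            res = stage_decompose(cfg, workdir)
            summary["decompose"] = {str(lv): len(r.units) for lv, r in res.items()}
        elif cmd == "track":
            registry, reports = stage_track(cfg, workdir)
            summary["track"] = {
                "n_tracked_units": len(registry),
                "yield_fractions": [r.yield_fraction for r in reports],
            }
        elif cmd == "validate":
            v = stage_validate(cfg, workdir)
            summary["validate"] = {
                "explained_power_ratio_by_level": v["explained_power_ratio_by_level"],
                "fraction_unique": v["fraction_unique"],
            }
        elif cmd == "ratecode":
            profiles, pools = stage_ratecode(cfg, workdir)
            summary["ratecode"] = {
                "n_profiles": len(profiles),
                "models_up": {
                    m: sum(p.best_model_up == m for p in profiles) for m in rc.MODELS
                },
            }
    write_report(workdir / "pipeline_summary.json", summary)
    return summary


@dataclass
class TruthMatch:
    """Best ground-truth assignment of one decomposed unit."""

    truth_unit: int
    roa: float


def match_to_truth(
    result: DecompositionResult, recording: SyntheticRecording, tol_ms: float = TRUTH_ROA_TOL_MS
) -> list[TruthMatch]:
    """Greedy best-RoA assignment of decomposed units to ground-truth units."""
    out = []
    for est in result.units:
        best_u, best_roa = -1, -1.0
        for u, truth in enumerate(recording.truth_spikes):
            if truth.size == 0:
                continue
            roa = rate_of_agreement(est.discharges, truth, recording.fs, tol_ms)
            if np.isfinite(roa) and roa > best_roa:
                best_u, best_roa = u, roa
        out.append(TruthMatch(truth_unit=best_u, roa=max(best_roa, 0.0)))
    return out
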