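"""HDF5 recording container, CSV sidecars and pipeline configuration.

Layout of the container (one file per contraction):

    /signals          (channels x samples) monopolar EMG
    /force            (%MVC per sample)
    /meta             attrs: fs, target, grid geometry fields, seed
    /truth/unit_NNN   ground-truth discharge indices (synthetic only)
    /truth/pool/*     pool parameter arrays
    /derived/...      decomposition and template outputs

Spike trains are exported 0-based in samples with fs recorded alongside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .decompose import DecompositionConfig
from .geometry import GridGeometry
from .synth import MotoneuronPool, SyntheticRecording

_POOL_FIELDS = ("rt", "a", "b", "min_rate", "isi_cov", "size", "drt_offset")
_GEOM_FIELDS = ("n_rows", "n_cols", "ied_mm", "absent_corner", "n_grids", "grid_gap_mm")


class ContainerFormatError(RuntimeError):
    """The HDF5 file does not follow the recording-container layout."""


def write_recording(path: str | Path, rec: SyntheticRecording) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signals", data=rec.signals, compression="gzip", compression_opts=1)
        h5.create_dataset("force", data=rec.force)
        meta = h5.create_group("meta")
        meta.attrs["fs"] = rec.fs
        if rec.target is not None:
            meta.attrs["target"] = rec.target
        if rec.seed is not None:
            meta.attrs["seed"] = rec.seed
        if rec.clean_power is not None:
            meta.attrs["clean_power"] = rec.clean_power
        if rec.noise_power is not None:
            meta.attrs["noise_power"] = rec.noise_power
        for f in _GEOM_FIELDS:
            meta.attrs[f"geometry_{f}"] = getattr(rec.geometry, f)
        truth = h5.create_group("truth")
        for u, spikes in enumerate(rec.truth_spikes):
            truth.create_dataset(f"unit_{u:03d}", data=np.asarray(spikes, dtype=np.int64))
        pool = truth.create_group("pool")
        for f in _POOL_FIELDS:
            pool.create_dataset(f, data=getattr(rec.pool, f))


def read_recording(path: str | Path) -> SyntheticRecording:
    with h5py.File(path, "r") as h5:
        if "signals" not in h5:
            raise ContainerFormatError(f"{path}: missing /signals dataset")
        if "force" not in h5 or "meta" not in h5:
            raise ContainerFormatError(f"{path}: missing /force or /meta")
        meta = h5["meta"].attrs
        fs = float(meta["fs"])
        if fs <= 0:
            raise ContainerFormatError("fs must be positive")
        geometry = GridGeometry(
            n_rows=int(meta["geometry_n_rows"]),
            n_cols=int(meta["geometry_n_cols"]),
            ied_mm=float(meta["geometry_ied_mm"]),
            absent_corner=bool(meta["geometry_absent_corner"]),
            n_grids=int(meta["geometry_n_grids"]),
            grid_gap_mm=float(meta["geometry_grid_gap_mm"]),
        )
        truth_spikes: list[np.ndarray] = []
        pool = None
        if "truth" in h5:
            keys = sorted(k for k in h5["truth"] if k.startswith("unit_"))
            truth_spikes = [h5["truth"][k][...] for k in keys]
            if "pool" in h5["truth"]:
                pg = h5["truth"]["pool"]
                pool = MotoneuronPool(**{f: pg[f][...] for f in _POOL_FIELDS})
        if pool is None:
            pool = MotoneuronPool(
                rt=np.ones(len(truth_spikes)) if truth_spikes else np.ones(1),
                a=np.zeros(max(len(truth_spikes), 1)),
                b=np.zeros(max(len(truth_spikes), 1)),
                min_rate=np.zeros(max(len(truth_spikes), 1)),
                isi_cov=np.zeros(max(len(truth_spikes), 1)),
                size=np.ones(max(len(truth_spikes), 1)),
                drt_offset=np.zeros(max(len(truth_spikes), 1)),
            )
        return SyntheticRecording(
            signals=h5["signals"][...],
            fs=fs,
            force=h5["force"][...],
            truth_spikes=truth_spikes,
            pool=pool,
            geometry=geometry,
            seed=int(meta["seed"]) if "seed" in meta else None,
            target=float(meta["target"]) if "target" in meta else None,
            clean_power=float(meta["clean_power"]) if "clean_power" in meta else None,
            noise_power=float(meta["noise_power"]) if "noise_power" in meta else None,
        )


def export_spikes_csv(
    path: str | Path,
    trains: dict[int, np.ndarray],
    fs: float,
    silhouettes: dict[int, float] | None = None,
) -> None:
    """Spike CSV: unit_id, sample_index (0-based), optional silhouette; fs in a header comment."""
    rows = []
    for uid in sorted(trains):
        for s in np.asarray(trains[uid], dtype=np.int64):
            row = {"unit_id": uid, "sample_index": int(s)}
            if silhouettes is not None:
                row["silhouette"] = silhouettes.get(uid, float("nan"))
            rows.append(row)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_templates(path: str | Path, templates: dict[int, np.ndarray], window_ms: float) -> None:
    """Store per-unit SD templates under /derived/templates of a recording file."""
    with h5py.File(path, "a") as h5:
        grp = h5.require_group("derived")
        if "templates" in grp:
            del grp["templates"]
        tgrp = grp.create_group("templates")
        tgrp.attrs["window_ms"] = window_ms
        for uid, tmpl in templates.items():
            tgrp.create_dataset(f"unit_{uid:03d}", data=tmpl)


def read_templates(path: str | Path) -> dict[int, np.ndarray]:
    with h5py.File(path, "r") as h5:
        if "derived" not in h5 or "templates" not in h5["derived"]:
            return {}
        tgrp = h5["derived"]["templates"]
        return {int(k.split("_")[1]): tgrp[k][...] for k in tgrp}


@dataclass
class PipelineConfig:
    """Flat, human-readable configuration covering every stage.

    Defaults are the printed analysis constants: 1000 extended channels,
    1e-4 convergence tolerance, silhouette 0.9, 0.5 ms common-discharge
    window, 30% duplicate threshold, 25 ms reconstruction and 50 ms
    uniqueness windows, 5 %MVC/s ramps, threshold groups at 25/50/75.
    The simulator's firing-variability default (ISI CoV 0.15) is a
    conventional renewal-process value.
    """

    target_extended_channels: int = 1000
    convergence_tol: float = 1e-4
    max_iterations_per_source: int = 100
    n_source_attempts: int = 40
    silhouette_min: float = 0.9
    duplicate_interval_ms: float = 0.5
    duplicate_fraction: float = 0.30
    peak_min_distance_ms: float = 10.0
    min_discharges: int = 10
    sta_window_ms: float = 25.0
    uniqueness_window_ms: float = 50.0
    ramp_rate: float = 5.0
    group_bounds: tuple[float, float, float] = (25.0, 50.0, 75.0)
    # simulator scenario
    n_units: int = 10
    rt_lo: float = 2.0
    rt_hi: float = 25.0
    levels: tuple[float, ...] = (10.0, 20.0, 30.0)
    snr_db: float = 20.0
    isi_cov: float = 0.15
    size_lo: float = 1.0
    size_hi: float = 3.0
    drt_offset: float = 0.0
    fs: float = 2048.0
    n_rows: int = 13
    n_cols: int = 5
    ied_mm: float = 4.0
    absent_corner: bool = True
    n_grids: int = 1
    seed: int = 1

    def decomposition(self) -> DecompositionConfig:
        return DecompositionConfig(
            target_extended_channels=self.target_extended_channels,
            convergence_tol=self.convergence_tol,
            max_iterations_per_source=self.max_iterations_per_source,
            n_source_attempts=self.n_source_attempts,
            silhouette_min=self.silhouette_min,
            duplicate_interval_ms=self.duplicate_interval_ms,
            duplicate_fraction=self.duplicate_fraction,
            peak_min_distance_ms=self.peak_min_distance_ms,
            min_discharges=self.min_discharges,
        )

    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            ied_mm=self.ied_mm,
            absent_corner=self.absent_corner,
            n_grids=self.n_grids,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["group_bounds"] = list(self.group_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["levels"] = tuple(d.get("levels", cls.levels))
        d["group_bounds"] = tuple(d.get("group_bounds", cls.group_bounds))
        return cls(**d)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["group_bounds"] = list(self.group_bounds)
        return d


def write_report(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
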