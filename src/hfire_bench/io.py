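"""Trace and table I/O, presets, run configuration, and run manifests.

Trace files are oscilloscope-export style delimited text: comma-separated,
dot decimal, LF line endings, one header row, columns ``time_s``,
``voltage_V``, ``current_A``.  Metadata travels in a JSON sidecar next to
each trace file (same stem, ``.json`` suffix).  Presets (tissue models and
electrode geometries) ship as YAML inside the package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometrySpec, NeedlePairGeometry, PlateGeometry
from .synth import TissueParams, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "load_tissue_preset",
    "load_geometry_preset",
    "list_presets",
    "RunConfig",
    "write_manifest",
]

_TRACE_COLUMNS = ["time_s", "voltage_V", "current_A"]
#: maximum allowed timestamp jitter, as a fraction of the sampling period
_MAX_JITTER_FRAC = 0.01


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": trace.times_s,
            "voltage_V": trace.voltage_v,
            "current_A": trace.current_a,
        }
    )
    # %.17g guarantees float64 round-trips bit-exactly through the text file
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    sidecar = path.with_suffix(".json")
    meta = dict(trace.metadata)
    meta["sampling_period_ns"] = trace.sampling_period_ns
    sidecar.write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace file, validating columns and sampling uniformity.

    Rejects files whose timestamp increments deviate from the median period
    by more than 1%, naming the first offending sample index.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing column(s) {missing}; expected {_TRACE_COLUMNS}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    period = float(np.median(dt))
    if period <= 0:
        raise ValueError(f"{path.name}: non-increasing timestamps")
    bad = np.flatnonzero(np.abs(dt - period) > _MAX_JITTER_FRAC * period)
    if bad.size:
        raise ValueError(
            f"{path.name}: non-uniform sampling at sample index {int(bad[0]) + 1} "
            f"(interval {dt[bad[0]]:.3e} s vs period {period:.3e} s)"
        )
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    sampling_ns = float(meta.pop("sampling_period_ns", period * 1e9))
    return Trace(
        sampling_period_ns=sampling_ns,
        voltage_v=df["voltage_V"].to_numpy(dtype=float),
        current_a=df["current_A"].to_numpy(dtype=float),
        metadata=meta,
    )


# -- presets ------------------------------------------------------------------


def _load_yaml(name: str) -> dict:
    with resources.files("hfire_bench.presets").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def list_presets() -> dict[str, list[str]]:
    return {
        "tissue": sorted(_load_yaml("tissues.yaml")),
        "geometry": sorted(_load_yaml("geometries.yaml")),
    }


def load_tissue_preset(name: str) -> TissueParams:
    """Load a named tissue model preset (e.g. ``potato``, ``cardiac``)."""
    presets = _load_yaml("tissues.yaml")
    if name not in presets:
        raise ValueError(f"unknown tissue preset {name!r}; known: {sorted(presets)}")
    p = dict(presets[name])
    p.pop("comment", None)
    return TissueParams(**p)


def load_geometry_preset(name: str) -> GeometrySpec:
    """Load a named electrode geometry preset (e.g. ``potato_plate``)."""
    presets = _load_yaml("geometries.yaml")
    if name not in presets:
        raise ValueError(f"unknown geometry preset {name!r}; known: {sorted(presets)}")
    p = dict(presets[name])
    p.pop("comment", None)
    kind = p.pop("kind")
    if kind == "plate":
        return PlateGeometry(**p)
    if kind == "needle_pair":
        return NeedlePairGeometry(**p)
    raise ValueError(f"unknown geometry kind {kind!r}")


# -- run configuration --------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a design run (YAML-loadable).

    Schema version 1: keys ``pulse_widths_us``, ``delays_us``, ``geometry``
    (preset name), ``tissue`` (preset name), ``levels`` (list of V/cm or a
    ramp-setting name), ``n_replicates``, ``seed``.
    """

    pulse_widths_us: tuple[float, ...]
    delays_us: tuple[float, ...]
    geometry_preset: str
    tissue_preset: str
    levels: tuple[float, ...]
    n_replicates: int = 8
    seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        levels = raw["levels"]
        if isinstance(levels, str):
            from .geometry import ramp_levels

            levels = ramp_levels(levels)
        return cls(
            pulse_widths_us=tuple(float(p) for p in raw["pulse_widths_us"]),
            delays_us=tuple(float(d) for d in raw["delays_us"]),
            geometry_preset=str(raw["geometry"]),
            tissue_preset=str(raw["tissue"]),
            levels=tuple(float(lv) for lv in levels),
            n_replicates=int(raw.get("n_replicates", 8)),
            seed=int(raw.get("seed", 0)),
            schema_version=int(raw.get("schema_version", 1)),
        )

    def content_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig | dict, seed: int) -> Path:
    """Record the config hash and seed so a run can be reproduced exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, RunConfig):
        payload = {"config": config.__dict__, "config_hash": config.content_hash()}
    else:
        blob = json.dumps(config, sort_keys=True, default=str)
        payload = {"config": config, "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}
    payload["seed"] = int(seed)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
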