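"""Configuration loading, validation and result serialization.

A run is fully described by a :class:`RunConfig`: model parameters,
protocol spec, optional sweep / eFAST / virtual-population blocks, a
seed and an output directory.  Every run writes a ``manifest.json``
with the fully-resolved configuration (defaults included), so any
output directory can be regenerated from its manifest alone.

Tabular results go to CSV (long format — one row per cell per
protocol for sweeps, so grids of any shape share one schema); scalars
and manifests go to JSON at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import ModelParams
from .gsa_efast import EfastResult
from .protocols import ProtocolSpec
from .simulator import SimulationResult
from .sweeps import SweepResult
from .vpop import KMCurve

__all__ = ["RunConfig", "load_config", "save_config", "write_results"]


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved run configuration."""

    params: ModelParams = field(default_factory=ModelParams)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    sweep: dict = field(default_factory=dict)
    efast: dict = field(default_factory=dict)
    vpop: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "protocol": self.protocol.to_dict(),
            "sweep": dict(self.sweep),
            "efast": dict(self.efast),
            "vpop": dict(self.vpop),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, mapping: dict | None) -> "RunConfig":
        mapping = dict(mapping or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs: dict = {}
        if "params" in mapping:
            kwargs["params"] = ModelParams.from_dict(mapping.pop("params") or {})
        if "protocol" in mapping:
            kwargs["protocol"] = ProtocolSpec.from_dict(mapping.pop("protocol") or {})
        kwargs.update(mapping)
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML config; unspecified fields fall back to baseline defaults.

    Validation happens eagerly at load time (constraint violations such
    as ``rx_on <= rx_off`` raise with the offending field named before
    any simulation runs).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (frozenset, set)):
            return sorted(x.value if hasattr(x, "value") else x for x in o)
        if hasattr(o, "value"):  # enums
            return o.value
        return super().default(o)


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def write_results(result, out_dir, stem: str | None = None) -> list[Path]:
    """Serialize a result object; returns the list of files written.

    * ``SimulationResult`` -> ``<stem>.csv`` (t, S, R, C, T, treating)
      plus a ``<stem>.json`` sidecar with TTP, dose times and
      composition at progression.
    * ``SweepResult`` -> long-format ``<stem>.csv`` plus a JSON
      manifest of grids and baseline parameters.
    * ``EfastResult`` -> ``<stem>.csv`` of indices and p-values.
    * ``KMCurve`` -> ``<stem>.csv`` with (time, survival, n_at_risk).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []

    if isinstance(result, SimulationResult):
        stem = stem or "run"
        df = pd.DataFrame(
            {
                "t": result.times,
                "S": result.S,
                "R": result.R,
                "C": result.C,
                "T": result.T,
                "treating": result.treating.astype(int),
            }
        )
        csv = out_dir / f"{stem}.csv"
        df.to_csv(csv, index=False)
        _dump_json(
            {
                "protocol": result.spec.protocol.value,
                "ttp": result.ttp,
                "progressed": result.progressed,
                "dose_times": result.dose_times,
                "on_intervals": result.on_intervals,
                "S_at_ttp": result.S_at_ttp,
                "R_at_ttp": result.R_at_ttp,
                "fraction_resistant_at_ttp": result.fraction_resistant_at_ttp,
                "params": result.params.to_dict(),
                "spec": result.spec.to_dict(),
            },
            out_dir / f"{stem}.json",
        )
        written += [csv, out_dir / f"{stem}.json"]

    elif isinstance(result, SweepResult):
        stem = stem or "sweep"
        csv = out_dir / f"{stem}.csv"
        result.to_dataframe().to_csv(csv, index=False)
        manifest = {
            "axis_names": list(result.axis_names),
            "axis_values": [list(map(float, a)) for a in result.axis_values],
            "protocols": [p.value for p in result.protocols],
            "base_params": result.base_params.to_dict(),
            "base_spec": result.base_spec.to_dict() if result.base_spec else None,
        }
        _dump_json(manifest, out_dir / f"{stem}.json")
        written += [csv, out_dir / f"{stem}.json"]

    elif isinstance(result, EfastResult):
        stem = stem or "efast"
        csv = out_dir / f"{stem}.csv"
        result.to_dataframe().to_csv(csv, index=False)
        written.append(csv)

    elif isinstance(result, KMCurve):
        stem = stem or "km"
        csv = out_dir / f"{stem}.csv"
        times = np.concatenate([[0.0], result.event_times, [result.horizon]])
        surv = np.concatenate([[1.0], result.survival, [result.survival[-1] if result.survival.size else 1.0]])
        risk = np.concatenate([[result.n], result.n_at_risk, [int(result.n * (result.survival[-1] if result.survival.size else 1.0))]])
        pd.DataFrame({"time": times, "survival": surv, "n_at_risk": risk}).to_csv(
            csv, index=False
        )
        written.append(csv)

    else:
        raise TypeError(f"no writer for result type {type(result).__name__}")
    return written
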