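"""Run configuration, result serialization and reproducibility metadata.

A run is described by a :class:`RunConfig` (model parameters + study
selector + study options), parsed from CLI flags and/or a YAML file.
Results are written as one directory per run: ``metadata.json`` with the
fully resolved config and seeds (sufficient to reproduce the run
bit-exactly), plus one CSV per table and per trajectory.
"""

from __future__ import annotations

import dataclasses
import json
import secrets
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .model import ModelParams, Trajectory, TOPOLOGIES, WELL_MIXED

STUDIES = ("simulate", "theory", "tstar", "sweep", "scaling", "compare",
           "apoptosis")

_CONFIG_KEYS = {
    "n_cells", "r0", "delta", "apoptosis_prob", "topology", "lattice_shape",
    "seed", "study", "replicates", "max_sweeps", "sample_every", "burn_in",
    "window", "vary", "values", "a_values", "n_values", "topologies",
    "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one study run, with all defaults explicit."""

    params: ModelParams
    study: str
    replicates: int = 20
    max_sweeps: float = 1000.0
    sample_every: float = 1.0
    burn_in: float = 500.0
    window: float = 1500.0
    vary: Optional[str] = None
    values: Optional[Tuple[float, ...]] = None
    a_values: Optional[Tuple[float, ...]] = None
    n_values: Optional[Tuple[int, ...]] = None
    topologies: Tuple[str, ...] = (WELL_MIXED,)
    out_dir: str = "results"

    def __post_init__(self):
        if self.study not in STUDIES:
            raise ValueError(f"study must be one of {STUDIES}, got {self.study!r}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        for name in ("max_sweeps", "sample_every", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in!r}")
        if self.study == "sweep":
            if self.vary is None or not self.values:
                raise ValueError("sweep requires 'vary' and a non-empty 'values'")
        for t in self.topologies:
            if t not in TOPOLOGIES:
                raise ValueError(f"unknown topology {t!r} in topologies")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update({k: v for k, v in dataclasses.asdict(self).items()
                  if k != "params"})
        return d


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig; unknown keys are an error."""
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "study" not in data:
        raise ValueError("config must select a 'study'")
    for req in ("n_cells", "r0", "delta", "apoptosis_prob"):
        if req not in data:
            raise ValueError(f"config is missing required field {req!r}")
    shape = data.get("lattice_shape")
    params = ModelParams(
        n_cells=int(data["n_cells"]),
        r0=float(data["r0"]),
        delta=float(data["delta"]),
        apoptosis_prob=float(data["apoptosis_prob"]),
        topology=data.get("topology", WELL_MIXED),
        lattice_shape=tuple(int(s) for s in shape) if shape else None,
        seed=int(data.get("seed", secrets.randbelow(2**31))),
    )
    kwargs = {}
    for name, cast in [("replicates", int), ("max_sweeps", float),
                       ("sample_every", float), ("burn_in", float),
                       ("window", float), ("out_dir", str)]:
        if data.get(name) is not None:
            kwargs[name] = cast(data[name])
    if data.get("vary") is not None:
        kwargs["vary"] = str(data["vary"])
    for name, cast in [("values", float), ("a_values", float),
                       ("n_values", int)]:
        if data.get(name) is not None:
            kwargs[name] = tuple(cast(v) for v in data[name])
    if data.get("topologies") is not None:
        kwargs["topologies"] = tuple(str(t) for t in data["topologies"])
    return RunConfig(params=params, study=str(data["study"]), **kwargs)


def parse_config(path) -> RunConfig:
    """Parse a YAML config file into a validated RunConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


@dataclass
class ResultBundle:
    """Everything a run produced, plus metadata sufficient to reproduce it."""

    config: RunConfig
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    trajectories: Dict[str, Trajectory] = field(default_factory=dict)
    scalars: Dict[str, float] = field(default_factory=dict)

    def metadata(self) -> dict:
        from . import __version__

        return {
            "tool": "tissueratchet",
            "version": __version__,
            "config": self.config.to_dict(),
            "scalars": self.scalars,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }


def write_results(bundle: ResultBundle, out_dir) -> List[Path]:
    """Write metadata JSON plus one CSV per table/trajectory; stable columns."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        written = []
        meta_path = out / "metadata.json"
        meta_path.write_text(
            json.dumps(bundle.metadata(), indent=2, sort_keys=True) + "\n")
        written.append(meta_path)
        for name, table in bundle.tables.items():
            p = out / f"{name}.csv"
            table.to_csv(p, index=False, lineterminator="\n")
            written.append(p)
        for name, traj in bundle.trajectories.items():
            p = out / f"{name}.csv"
            traj.to_frame().to_csv(p, index=False, lineterminator="\n")
            written.append(p)
        return written
    except OSError as exc:
        raise OSError(f"failed writing results under {out}: {exc}") from exc
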