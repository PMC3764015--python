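"""Configuration loading/validation and report output.

Run configurations are structured text (YAML) with explicit sections;
unknown keys fail loudly so typos cannot silently fall back to defaults.
Experiment reports are written as a metrics JSON plus CSV tables with a
checksummed manifest, so a results directory is self-describing and
reproducible from its recorded provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .integrate import IntegratorConfig, SimulationResult
from .experiments import ExperimentReport
from .params import ModelParams
from .protocols import load_preset

__all__ = ["RunConfig", "load_config", "save_config", "write_report",
           "read_activity_csv"]

_ANALYSIS_KEYS = {"wake_threshold", "window_mode", "window_width_s",
                  "spectral_band_h"}


@dataclass
class RunConfig:
    """Validated run configuration: preset + overrides + plumbing."""

    preset: str = "human_nominal"
    overrides: dict = field(default_factory=dict)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    analysis: dict = field(default_factory=lambda: {
        "wake_threshold": 1.0, "window_mode": "sliding",
        "window_width_s": 600.0, "spectral_band_h": [2.0, 30.0]})
    output_dir: str = "results"

    def build_params(self) -> ModelParams:
        """Materialize the preset with overrides applied and validated."""
        base = load_preset(self.preset).params.to_dict()
        for dotted, value in self.overrides.items():
            section, _, name = dotted.partition(".")
            if not name or section not in base or name not in base[section] \
                    or isinstance(base[section][name], dict):
                raise ValueError(f"unknown parameter override {dotted!r}")
            base[section][name] = value
        return ModelParams.from_dict(base)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"preset", "overrides", "integrator", "analysis", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    integ = raw.get("integrator", {})
    bad = set(integ) - {f.name for f in dataclasses.fields(IntegratorConfig)}
    if bad:
        raise ValueError(f"unknown integrator keys: {sorted(bad)}")
    ana = dict(RunConfig().analysis)
    extra = set(raw.get("analysis", {})) - _ANALYSIS_KEYS
    if extra:
        raise ValueError(f"unknown analysis keys: {sorted(extra)}")
    ana.update(raw.get("analysis", {}))
    if ana["wake_threshold"] <= 0:
        raise ValueError("wake_threshold must be positive")
    cfg = RunConfig(preset=raw.get("preset", "human_nominal"),
                    overrides=raw.get("overrides", {}),
                    integrator=IntegratorConfig(**integ).validate(),
                    analysis=ana,
                    output_dir=raw.get("output_dir", "results"))
    cfg.build_params()  # validates preset name, overrides, and ranges
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    doc = {"preset": cfg.preset, "overrides": cfg.overrides,
           "integrator": dataclasses.asdict(cfg.integrator),
           "analysis": cfg.analysis, "output_dir": cfg.output_dir}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: ExperimentReport, out_dir) -> dict:
    """Write an experiment report; returns the checksum manifest.

    Layout: ``metrics.json``, one ``<table>.csv`` per table, and
    ``manifest.json`` listing every artifact with its sha256.  Writing the
    same report twice yields identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    mpath = out / "metrics.json"
    with open(mpath, "w") as fh:
        json.dump({"experiment": report.experiment,
                   "metrics": _to_jsonable(report.metrics),
                   "provenance": _to_jsonable(report.provenance)},
                  fh, indent=2, sort_keys=True)
    paths.append(mpath)
    for name, table in sorted(report.tables.items()):
        tpath = out / f"{name}.csv"
        table.to_csv(tpath, index=False)
        paths.append(tpath)
    manifest = {"experiment": report.experiment,
                "artifacts": {p.name: _sha256(p) for p in paths}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_activity_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a SimulationResult CSV or a generic two-column (time, activity)
    CSV; returns (time_s, activity)."""
    import pandas as pd
    df = pd.read_csv(path)
    if {"time_s", "Q_m"} <= set(df.columns):
        return df["time_s"].to_numpy(float), df["Q_m"].to_numpy(float)
    if df.shape[1] < 2:
        raise ValueError("need at least two columns (time, activity)")
    return (df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
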