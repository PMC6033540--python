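"""Run configuration, result serialization and manifests.

Configs are flat key-value YAML files with a single documented schema
(`CONFIG_SCHEMA`); units are fixed to kb and min throughout so a config
can never silently change unit conventions.  Unknown keys are rejected
by name, as are missing required keys.

`write_results` emits tab-separated tables plus a YAML manifest carrying
every parameter, the master seed and the package version — enough to
regenerate the outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeSpec, periodic_genome, read_origin_file, uniform_genome
from .observables import EnsembleKinetics, kinetics_table
from .simulate import SimParams

__all__ = ["RunConfig", "load_config", "write_results", "read_kinetics_table",
           "CONFIG_SCHEMA"]

#: key -> (required, default, description).  All lengths kb, times min.
CONFIG_SCHEMA: dict[str, tuple[bool, Any, str]] = {
    "v": (True, None, "replication fork speed, kb/min"),
    "kon": (True, None, "productive-interaction rate, 1/min"),
    "ndt": (True, None, "total firing factors NDT (Poisson mean in poisson mode)"),
    "genome_source": (True, None, "origin layout: uniform | periodic | file"),
    "length_kb": (False, None, "chromosome length, kb (uniform/periodic)"),
    "rho0": (False, None, "potential-origin density, 1/kb (uniform/periodic)"),
    "origin_file": (False, None, "origin-map path (genome_source: file)"),
    "categories": (False, ["Confirmed", "Likely", "Dubious"],
                   "status categories kept from the origin file"),
    "interval_to_point": (False, "midpoint",
                          "collapse origin intervals to midpoint | start"),
    "tau_load": (False, 0.0, "factor loading timescale, min"),
    "dt": (False, 0.01, "time step, min"),
    "ndt_mode": (False, "constant", "constant | poisson"),
    "recycle_at_ends": (False, False,
                        "re-pair half factors discarded at chromosome ends"),
    "loading_mode": (False, "stochastic", "stochastic | deterministic"),
    "max_time": (False, 1.0e4, "non-termination guard, min"),
    "n_runs": (False, 100, "independent S-phases per ensemble"),
    "bin_width": (False, 0.5, "observable binning, min"),
    "seed": (False, 0, "master seed for all randomness"),
    "out_dir": (False, ".", "output directory"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration; see `CONFIG_SCHEMA` for fields."""

    values: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def build_genome(self, rng: np.random.Generator) -> GenomeSpec:
        src = self.values["genome_source"]
        if src == "file":
            return read_origin_file(self.values["origin_file"],
                                    self.values["categories"],
                                    self.values["interval_to_point"])
        length, rho0 = self.values["length_kb"], self.values["rho0"]
        builder = uniform_genome if src == "uniform" else periodic_genome
        return builder(float(length), float(rho0), rng)

    def build_params(self, rng: np.random.Generator) -> SimParams:
        v = self.values
        return SimParams(
            genome=self.build_genome(rng),
            v=float(v["v"]), kon=float(v["kon"]), ndt=int(v["ndt"]),
            tau_load=float(v["tau_load"]), dt=float(v["dt"]),
            ndt_mode=v["ndt_mode"], recycle_at_ends=bool(v["recycle_at_ends"]),
            loading_mode=v["loading_mode"], max_time=float(v["max_time"]),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML config.

    Raises ``ValueError`` naming every unknown key, every missing
    required key, and any inconsistent genome-source combination.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    missing = sorted(k for k, (req, _, _) in CONFIG_SCHEMA.items()
                     if req and k not in raw)
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    values = {k: raw.get(k, default) for k, (_, default, _) in CONFIG_SCHEMA.items()}

    src = values["genome_source"]
    if src in ("uniform", "periodic"):
        need = [k for k in ("length_kb", "rho0") if values[k] is None]
        if need:
            raise ValueError(f"genome_source={src!r} requires keys: {need}")
    elif src == "file":
        if values["origin_file"] is None:
            raise ValueError("genome_source='file' requires key: ['origin_file']")
    else:
        raise ValueError(f"genome_source must be uniform|periodic|file, got {src!r}")
    return RunConfig(values)


def _param_echo(ensemble: EnsembleKinetics, config: RunConfig | None) -> list[str]:
    lines = [
        f"# oridyn {__version__}",
        f"# n_runs={ensemble.n_runs} bin_width_min={ensemble.bin_width}",
        f"# rho0_per_kb={ensemble.rho0:.6g} nfd_star={ensemble.nfd_star:.6g}"
        f" total_length_kb={ensemble.total_length:.3f}",
        f"# master_seed={ensemble.master_seed}",
    ]
    if config is not None:
        kv = " ".join(f"{k}={config.values[k]}" for k in
                      ("v", "kon", "ndt", "genome_source", "tau_load", "dt",
                       "ndt_mode") if config.values.get(k) is not None)
        lines.append(f"# {kv}")
    return lines


def write_results(ensemble: EnsembleKinetics, out_dir: str | Path,
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write ensemble outputs and a reproducibility manifest.

    Emits ``kinetics.tsv`` (pooled curves with a parameter-echo comment
    header), ``replication_times.txt`` (one value per line, min),
    ``per_run.tsv``, ``events.tsv`` (if any run kept its per-origin event
    log) and ``manifest.yaml``.  Returns the paths keyed by name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tab = kinetics_table(ensemble)
    kpath = out / "kinetics.tsv"
    with open(kpath, "w", encoding="utf-8") as fh:
        fh.write("\n".join(_param_echo(ensemble, config)) + "\n")
        tab.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    paths["kinetics"] = kpath

    rpath = out / "replication_times.txt"
    np.savetxt(rpath, ensemble.replication_times, fmt="%.6f")
    paths["replication_times"] = rpath

    ppath = out / "per_run.tsv"
    ensemble.per_run.to_csv(ppath, sep="\t", index=False, float_format="%.8g")
    paths["per_run"] = ppath

    events = [rec.events for rec in ensemble.records if len(rec.events)]
    if events:
        epath = out / "events.tsv"
        ev = pd.concat(events, keys=range(len(events)), names=["run"])
        ev.reset_index(level=0).to_csv(epath, sep="\t", index=False,
                                       float_format="%.6f")
        paths["events"] = epath

    manifest: dict[str, Any] = {
        "package": "oridyn",
        "version": __version__,
        "master_seed": ensemble.master_seed,
        "n_runs": ensemble.n_runs,
        "bin_width_min": ensemble.bin_width,
        "rho0_per_kb": float(ensemble.rho0),
        "n_origins_mean": float(ensemble.per_run["n_origins"].mean()),
        "total_length_kb": float(ensemble.total_length),
    }
    if config is not None:
        manifest["config"] = {
            k: v for k, v in config.values.items() if v is not None
        }
    mpath = out / "manifest.yaml"
    with open(mpath, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = mpath
    return paths


def read_kinetics_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a ``kinetics.tsv`` written by `write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
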