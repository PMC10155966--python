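"""Text file formats: isotherm CSV, YAML run configuration and the
reproducibility manifest.

Isotherm CSV dialect: a header row then one row per injection with columns
``injection_volume_uL, heat_ucal``.  Experiment metadata (cell volume in mL,
temperature in °C, stated concentrations in μM, discard_first) travels in the
YAML config / function arguments, not in the CSV.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import (CELSIUS_OFFSET, AnalyteConcentrations, Isotherm,
                      TitrationProtocol)

__all__ = ["read_isotherm", "write_isotherm", "IsothermMeta", "RunConfig",
           "write_manifest"]

CSV_COLUMNS = ("injection_volume_uL", "heat_ucal")
MAX_SANE_HEAT_UCAL = 1e4


@dataclass(frozen=True)
class IsothermMeta:
    """Sidecar metadata for one isotherm CSV (user-facing units)."""

    cell_volume_ml: float = 1.42
    temperature_C: float = 25.0
    cell_uM: float = 17.0
    syringe_uM: float = 500.0
    discard_first: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "IsothermMeta":
        known = {k: d[k] for k in
                 ("cell_volume_ml", "temperature_C", "cell_uM", "syringe_uM",
                  "discard_first") if k in d}
        return cls(**known)


def read_isotherm(path, meta: IsothermMeta, label: str = "") -> Isotherm:
    """Parse an isotherm CSV plus its metadata into an :class:`Isotherm`."""
    df = pd.read_csv(path)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in CSV_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} at row {bad[0]}")
    heats = df["heat_ucal"].astype(float).to_numpy()
    too_big = np.flatnonzero(np.abs(heats) > MAX_SANE_HEAT_UCAL)
    if len(too_big):
        raise ValueError(f"{path}: |heat| > {MAX_SANE_HEAT_UCAL:g} ucal at "
                         f"row {too_big[0]} (unit mismatch?)")
    protocol = TitrationProtocol(
        meta.cell_volume_ml, meta.temperature_C + CELSIUS_OFFSET,
        tuple(df["injection_volume_uL"].astype(float)),
        discard_first=meta.discard_first)
    conc = AnalyteConcentrations(meta.cell_uM, meta.syringe_uM)
    return Isotherm(protocol, conc, heats, label=label or str(path))


def write_isotherm(iso: Isotherm, path) -> None:
    """Write an isotherm in the same CSV dialect the reader accepts."""
    df = pd.DataFrame({
        "injection_volume_uL": iso.protocol.injection_volumes_ul,
        "heat_ucal": iso.heats_ucal,
    })
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """A fitting run described in one YAML file.

    ``isotherms`` is a list of {path, cell_volume_ml, temperature_C,
    cell_uM, syringe_uM, discard_first} entries; concentration priors are
    fractional half-widths; prior overrides map parameter names to
    {kind, bounds} or {kind, mean, sd}.
    """

    isotherms: list
    model: str = "two_site"
    cell_fraction: float = 0.10
    syringe_fraction: float = 0.10
    conc_prior_kind: str = "uniform"
    prior_overrides: dict = field(default_factory=dict)
    n_walkers: int = 50
    n_steps: int = 20000
    n_replicas: int = 1
    seed: int | None = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for entry in cfg.isotherms:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(entry["path"])
        return cfg

    def load_isotherms(self) -> list:
        return [read_isotherm(e["path"], IsothermMeta.from_dict(e))
                for e in self.isotherms]

    def build_prior_overrides(self):
        from .model import PriorSpec
        out = {}
        for name, spec in self.prior_overrides.items():
            if spec.get("kind", "uniform") == "uniform":
                lo, hi = spec["bounds"]
                out[name] = PriorSpec.uniform(lo, hi)
            else:
                out[name] = PriorSpec.normal(spec["mean"], spec["sd"])
        return out


def write_manifest(path, config: dict, convergence: dict | None = None,
                   extra: dict | None = None) -> None:
    """Emit the reproducibility manifest: config echo, package versions,
    seed and the convergence report."""
    import itcbayes

    manifest = {
        "itcbayes_version": itcbayes.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": config,
    }
    if convergence is not None:
        manifest["convergence"] = _plain(convergence)
    if extra:
        manifest.update(_plain(extra))
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _plain(obj):
    """Recursively coerce numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
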