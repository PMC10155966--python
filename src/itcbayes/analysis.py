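"""Simulation campaigns built on the fitting pipeline: credibility-region
coverage calibration and the practical-identifiability heat map."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import AnalyteConcentrations, ThermoTwoSite
from .model import ITCModel
from .results import credible_region
from .simulate import Fixture, NoiseModel, replicate_set, simulate_isotherm

logger = logging.getLogger(__name__)

__all__ = ["CoverageCurve", "coverage_validation", "identifiability_heatmap",
           "DEFAULT_COVERAGE_LEVELS"]

DEFAULT_COVERAGE_LEVELS = (0.10, 0.30, 0.50, 0.70, 0.90, 0.95)


@dataclass
class CoverageCurve:
    """Predicted-versus-observed credibility, pooled over parameters.

    ``observed[level]`` is the fraction of (replicate, parameter) pairs whose
    credible interval at that nominal level contained the generating value;
    ``bootstrap_sd`` holds the sd over 1000 bootstrap resamples of the
    replicates.  A calibrated model tracks the diagonal.
    """

    levels: tuple
    observed: pd.DataFrame          # rows: parameter, cols: level
    bootstrap_sd: pd.DataFrame
    n_replicates: int
    n_excluded: int = 0

    def pooled(self) -> pd.Series:
        return self.observed.mean(axis=0)


def _bootstrap_sd(cover: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """sd of the coverage fraction over bootstrap resamples of replicates.
    ``cover`` is (n_replicates, n_levels) boolean."""
    n = cover.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    frac = cover[idx].mean(axis=1)        # (n_boot, n_levels)
    return frac.std(axis=0)


def coverage_validation(fx: Fixture, n_replicates: int = 20,
                        conc_prior_width: float = 0.10,
                        levels=DEFAULT_COVERAGE_LEVELS,
                        n_steps: int = 8000, n_walkers: int = 50,
                        seed: int | None = None, n_boot: int = 1000,
                        fit_fn=None,
                        exclude_unconverged: bool = True) -> CoverageCurve:
    """Check calibration of the credible regions by simulation.

    For each replicate a fresh isotherm is generated at the fixture's true
    parameters, with "measured" concentrations drawn from the +/-w uniform
    window around truth; the model is fitted with that same fractional prior
    and coverage of the generating thermodynamic values is recorded at each
    nominal level.  Unconverged replicates are excluded and counted.

    ``fit_fn(isotherm, replicate_seed) -> DataFrame-or-None`` may replace the
    MCMC fit (e.g. with an analytically calibrated oracle) for fast checks of
    the coverage machinery itself.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    reps = replicate_set(fx, n_replicates, conc_prior_width,
                         seed=int(rng.integers(2**31)))
    thermo_names = ("dG", "ddG", "dH", "ddH")
    truths = {n: getattr(fx.thermo, n) for n in thermo_names}
    cover = {n: [] for n in thermo_names}
    n_excluded = 0
    for i, (iso, stated, truth) in enumerate(reps):
        rep_seed = int(rng.integers(2**31))
        if fit_fn is not None:
            flat = fit_fn(iso, rep_seed)
        else:
            model = ITCModel(iso, kind="two_site",
                             cell_fraction=conc_prior_width,
                             syringe_fraction=conc_prior_width)
            res = model.fit(n_steps=n_steps, n_walkers=n_walkers,
                            seed=rep_seed, n_replicas=1)
            flat = res.samples
            if exclude_unconverged and not res.converged:
                flat = None
        if flat is None:
            n_excluded += 1
            logger.warning("replicate %d excluded (unconverged)", i)
            continue
        for name in thermo_names:
            cis = [credible_region(flat[name], lv) for lv in levels]
            cover[name].append([ci.contains(truths[name]) for ci in cis])

    if n_excluded == n_replicates:
        raise RuntimeError("every replicate was excluded as unconverged; "
                           "increase n_steps or pass "
                           "exclude_unconverged=False")
    obs_rows, sd_rows = {}, {}
    boot_rng = np.random.default_rng(int(rng.integers(2**31)))
    for name in thermo_names:
        arr = np.asarray(cover[name], dtype=bool)
        obs_rows[name] = arr.mean(axis=0)
        sd_rows[name] = _bootstrap_sd(arr, n_boot, boot_rng)
    observed = pd.DataFrame(obs_rows, index=list(levels)).T
    boot = pd.DataFrame(sd_rows, index=list(levels)).T
    return CoverageCurve(tuple(levels), observed, boot,
                         n_replicates - n_excluded, n_excluded)


def identifiability_heatmap(dG_values, ddG_values, dH: float = -10.0,
                            ddH: float = -1.5, protocol=None,
                            concentrations=None, noise_sd: float = 0.2,
                            n_steps: int = 6000, n_walkers: int = 50,
                            cell_fraction: float = 0.10,
                            syringe_fraction: float = 0.10,
                            seed: int | None = None) -> pd.DataFrame:
    """Map practical identifiability over a (dG, ddG) grid.

    At each grid point one synthetic isotherm is simulated (fixed dH, ddH;
    per-point seed derived from ``seed``), fitted, and the 95% credible-region
    width of each thermodynamic parameter recorded, along with the per-step
    Wiseman c values of the generating parameters.  Per-point failures are
    recorded (``failed`` column) and the map is still returned.
    """
    from .results import c_values
    from .simulate import standard_protocol

    protocol = protocol or standard_protocol(6.0)
    concentrations = concentrations or AnalyteConcentrations(17.0, 500.0)
    rng = np.random.default_rng(seed)
    rows = []
    for dg in dG_values:
        for ddg in ddG_values:
            thermo = ThermoTwoSite(dg, ddg, dH, ddH)
            point_seed = int(rng.integers(2**31))
            (c1, c2), _ = c_values(concentrations.cell_uM, thermo,
                                   protocol.temperature_K)
            row = {"dG": dg, "ddG": ddg, "c1": c1, "c2": c2, "failed": False}
            try:
                iso = simulate_isotherm(thermo, protocol, concentrations,
                                        NoiseModel(noise_sd, point_seed))
                model = ITCModel(iso, kind="two_site",
                                 cell_fraction=cell_fraction,
                                 syringe_fraction=syringe_fraction)
                res = model.fit(n_steps=n_steps, n_walkers=n_walkers,
                                seed=point_seed, n_replicas=1)
                for name in ("dG", "ddG", "dH", "ddH"):
                    row[f"width_{name}"] = res.credible_interval(name).width
            except Exception as exc:       # keep the rest of the grid
                logger.warning("grid point (%g, %g) failed: %s", dg, ddg, exc)
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)
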