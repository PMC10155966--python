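"""Posterior summaries: credible intervals, derived thermodynamic
quantities, Wiseman c values and the fitted-results container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import ThermoTwoSite, kd_from_dg

__all__ = ["CredibleInterval", "credible_region", "derived_quantities",
           "c_values", "ITCResults"]

#: Informative band for the Wiseman parameter c = n[cell]/Kd.
C_INFORMATIVE = (5.0, 500.0)


@dataclass(frozen=True)
class CredibleInterval:
    """Central posterior interval (e.g. 2.5-97.5 percentile for 95%)."""

    level: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value) -> bool:
        return self.lower <= value <= self.upper


def credible_region(samples, level: float = 0.95,
                    min_samples: int = 100) -> CredibleInterval:
    """Central credible interval from 1-D posterior draws."""
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < min_samples:
        raise ValueError(f"only {len(x)} samples; need >= {min_samples}")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    if level == 1.0:
        return CredibleInterval(level, float(np.min(x)), float(np.max(x)))
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
    return CredibleInterval(level, float(lo), float(hi))


def derived_quantities(samples: pd.DataFrame, T: float,
                       isotherm_index: int = 0) -> pd.DataFrame:
    """Sample-wise derived quantities for a two-site posterior.

    ``total_dG = 2dG + ddG`` and ``total_dH = 2dH + ddH`` are the free energy
    and enthalpy of filling both sites; ``minusTdS = dG - dH`` (from
    dG = dH - T dS) and ``minusTddS = ddG - ddH`` are the entropic terms;
    ``kd1``/``kd2`` the microscopic dissociation constants (M); ``conc_ratio``
    the syringe/cell concentration ratio (the identifiable combination under
    the degeneracy); ``c1``/``c2`` the per-step Wiseman parameters.
    """
    j = isotherm_index
    out = pd.DataFrame(index=samples.index)
    out["total_dG"] = 2 * samples["dG"] + samples["ddG"]
    out["total_dH"] = 2 * samples["dH"] + samples["ddH"]
    out["minusTdS"] = samples["dG"] - samples["dH"]
    out["minusTddS"] = samples["ddG"] - samples["ddH"]
    out["kd1"] = kd_from_dg(samples["dG"].to_numpy(), T)
    out["kd2"] = kd_from_dg((samples["dG"] + samples["ddG"]).to_numpy(), T)
    if f"cell_uM_{j}" in samples:
        cell = samples[f"cell_uM_{j}"]
        out["conc_ratio"] = samples[f"syringe_uM_{j}"] / cell
        out["c1"] = cell * 1e-6 / out["kd1"]
        out["c2"] = cell * 1e-6 / out["kd2"]
    return out


def c_values(cell_uM: float, thermo: ThermoTwoSite, T: float,
             n_sites: int = 1):
    """Wiseman parameters ``c_k = n [cell] / Kd_k`` for both binding steps.

    Returns ``((c1, c2), (flag1, flag2))`` where a flag marks a step whose c
    falls outside the informative 5-500 band (the isotherm carries little
    information about that step's affinity).
    """
    if cell_uM <= 0:
        raise ValueError("cell concentration must be positive")
    cell_M = cell_uM * 1e-6
    cs = (n_sites * cell_M / thermo.kd1(T), n_sites * cell_M / thermo.kd2(T))
    flags = tuple(not (C_INFORMATIVE[0] <= c <= C_INFORMATIVE[1]) for c in cs)
    return cs, flags


class ITCResults:
    """Posterior sampling results for an :class:`~itcbayes.model.ITCModel`.

    Wraps one or more replica runs; summaries pool the post-burn-in, thinned
    samples of all replicas.
    """

    def __init__(self, model, runs):
        from .sampling import check_convergence
        self.model = model
        self.runs = list(runs)
        self.convergence = check_convergence(self.runs)
        self._flat = pd.concat([r.flat() for r in self.runs],
                               ignore_index=True)

    # ------------------------------------------------------------ accessors
    @property
    def samples(self) -> pd.DataFrame:
        """Pooled post-burn-in, thinned posterior draws."""
        return self._flat

    @property
    def param_names(self) -> list:
        return self.model.param_names

    @property
    def converged(self) -> bool:
        return bool(self.convergence["passed"])

    @property
    def tau(self) -> pd.Series:
        taus = np.max([r.tau for r in self.runs], axis=0)
        return pd.Series(taus, index=self.param_names)

    @property
    def acceptance_fraction(self) -> float:
        return float(np.mean([r.acceptance_fraction for r in self.runs]))

    def credible_interval(self, name: str, level: float = 0.95) -> CredibleInterval:
        if name in self._flat:
            return credible_region(self._flat[name], level)
        return credible_region(self.derived()[name], level)

    def derived(self, isotherm_index: int = 0) -> pd.DataFrame:
        if self.model.kind != "two_site":
            raise ValueError("derived quantities are defined for the "
                             "two-site model")
        return derived_quantities(self._flat, self.model.temperature_K,
                                  isotherm_index)

    def posterior_mean_thermo(self):
        m = self._flat.mean()
        if self.model.kind == "two_site":
            return ThermoTwoSite(m["dG"], m["ddG"], m["dH"], m["ddH"])
        from .binding import ThermoOneSite
        return ThermoOneSite(m["dG"], m["dH"])

    # ------------------------------------------------------------- summary
    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-parameter posterior mean, median, credible interval, width,
        autocorrelation time and convergence flag."""
        rows = []
        rep = self.convergence["parameters"]
        for name in self.param_names:
            ci = self.credible_interval(name, level)
            rows.append({
                "parameter": name,
                "mean": self._flat[name].mean(),
                "median": self._flat[name].median(),
                f"cr{int(level * 100)}_low": ci.lower,
                f"cr{int(level * 100)}_high": ci.upper,
                "cr_width": ci.width,
                "tau": rep[name]["tau"],
                "converged": rep[name]["long_enough"]
                and rep[name].get("replicas_agree", True),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def summary_text(self, level: float = 0.95) -> str:
        df = self.summary(level)
        head = (f"ITC Bayesian fit: {self.model.kind}, "
                f"{len(self.model.isotherms)} isotherm(s), "
                f"{self.model.n_params} parameters\n"
                f"pooled samples: {len(self._flat)}  "
                f"replicas: {len(self.runs)}  "
                f"acceptance: {self.acceptance_fraction:.3f}  "
                f"converged: {self.converged}\n")
        return head + df.to_string(float_format=lambda v: f"{v:.4g}")

    def predicted_isotherm(self, theta=None, isotherm_index: int = 0):
        """Model injection heats (μcal) at a parameter vector (default: the
        posterior mean)."""
        if theta is None:
            theta = self._flat.mean().to_numpy()
        return self.model._predicted_heats(np.atleast_2d(theta),
                                           isotherm_index)[0]

    def to_csv(self, path):
        """Persist pooled samples as a columnar text file."""
        self._flat.to_csv(path, index=False)
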