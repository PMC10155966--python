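"""Synthetic isotherm generation.

Simulated titrations mirror the conditions used to validate the inference
pipeline: a 1.42 mL cell at 25 °C, one 2 μL priming injection followed by 34
equal injections, and i.i.d. Gaussian noise of 0.2 μcal on each integrated
injection heat.  The flat per-injection offset dH0 is zero in generation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binding import (AnalyteConcentrations, Isotherm, ThermoOneSite,
                      ThermoTwoSite, TitrationProtocol, model_injection_heats)

__all__ = ["NoiseModel", "Fixture", "FIXTURES", "fixture",
           "standard_protocol", "simulate_isotherm", "replicate_set"]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian per-injection heat noise: standard deviation in μcal."""

    sd_ucal: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.sd_ucal < 0:
            raise ValueError("noise sd must be non-negative")


def standard_protocol(injection_ul: float = 6.0, n_injections: int = 34,
                      first_ul: float = 2.0, cell_volume_ml: float = 1.42,
                      temperature_K: float = 298.15,
                      discard_first: bool = True) -> TitrationProtocol:
    """The simulation protocol: one small priming injection then
    ``n_injections`` equal injections."""
    vols = (first_ul,) + (injection_ul,) * n_injections
    return TitrationProtocol(cell_volume_ml, temperature_K, vols,
                             discard_first=discard_first)


@dataclass(frozen=True)
class Fixture:
    """A named simulation scenario: thermodynamics + protocol +
    concentrations + noise level."""

    name: str
    thermo: object
    protocol: TitrationProtocol
    concentrations: AnalyteConcentrations
    noise_sd_ucal: float = 0.2


FIXTURES = {
    # two-site scenario used throughout pipeline validation
    "validation2site": Fixture(
        "validation2site",
        ThermoTwoSite(dG=-7.0, ddG=-1.0, dH=-10.0, ddH=-1.5),
        standard_protocol(6.0),
        AnalyteConcentrations(17.0, 500.0)),
    # 1:1 reference scenario
    "one2one": Fixture(
        "one2one",
        ThermoOneSite(dG=-8.0, dH=-12.0),
        standard_protocol(6.0),
        AnalyteConcentrations(34.0, 500.0)),
    # weak-binding scenarios mimicking the BSN motif-I isotherm, at two cell
    # concentrations (larger c at 70 uM)
    "bsn_mimic_17": Fixture(
        "bsn_mimic_17",
        ThermoTwoSite(dG=-5.1, ddG=-1.7, dH=-11.0, ddH=-2.0),
        standard_protocol(10.0),
        AnalyteConcentrations(17.0, 900.0)),
    "bsn_mimic_70": Fixture(
        "bsn_mimic_70",
        ThermoTwoSite(dG=-5.1, ddG=-1.7, dH=-11.0, ddH=-2.0),
        standard_protocol(10.0),
        AnalyteConcentrations(70.0, 2000.0)),
}


def coop_panel(ddG_values=(-4.0, -3.0, -2.0, -1.0, 0.0, 1.0)) -> list:
    """Cooperativity sweep: ΔΔG varied with ΔΔH = 0, showing how positive
    cooperativity (ΔΔG < 0) deepens the early-injection "U" dip.
    Generated noiseless."""
    return [Fixture(f"coop_ddG{g:+g}",
                    ThermoTwoSite(dG=-7.0, ddG=g, dH=-10.0, ddH=0.0),
                    standard_protocol(6.0),
                    AnalyteConcentrations(17.0, 500.0),
                    noise_sd_ucal=0.0)
            for g in ddG_values]


# the cooperativity sweep is itself a registered (composite) scenario
FIXTURES["coop_panel"] = tuple(coop_panel())


def fixture(name: str):
    """Look up a registered simulation scenario by name.

    Returns a :class:`Fixture`, or a tuple of fixtures for the composite
    ``coop_panel`` sweep."""
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; registered: "
                       f"{sorted(FIXTURES)}") from None


def simulate_isotherm(thermo, protocol: TitrationProtocol,
                      conc: AnalyteConcentrations,
                      noise: NoiseModel = NoiseModel(),
                      label: str = "") -> Isotherm:
    """Simulate one isotherm: noiseless per-injection heats from the forward
    model (dH0 = 0) plus i.i.d. Gaussian noise.  Deterministic given
    ``noise.seed``."""
    dq = model_injection_heats(thermo, protocol, conc, dH0_ucal=0.0)
    rng = np.random.default_rng(noise.seed)
    if noise.sd_ucal > 0:
        dq = dq + rng.normal(0.0, noise.sd_ucal, size=len(dq))
    tag = label or f"sim(seed={noise.seed})"
    return Isotherm(protocol, conc, dq, label=tag)


def simulate_fixture(name: str, seed: int | None = None) -> Isotherm:
    """Simulate a registered fixture with its own noise level."""
    fx = fixture(name)
    return simulate_isotherm(fx.thermo, fx.protocol, fx.concentrations,
                             NoiseModel(fx.noise_sd_ucal, seed),
                             label=f"{name}(seed={seed})")


def replicate_set(fx: Fixture, n_replicates: int,
                  conc_prior_width: float = 0.10, seed: int | None = None):
    """Replicate isotherms for credibility-region calibration.

    Each replicate is generated at the fixture's *true* concentrations with
    fresh noise; its "measured" (stated) concentrations are drawn
    independently from the uniform window ``true * U(1-w, 1+w)`` to emulate
    concentration-measurement error.  Returns a list of
    ``(Isotherm, stated AnalyteConcentrations, true thermo)`` triples, where
    the isotherm carries the *stated* concentrations (what an experimenter
    would record).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    out = []
    w = conc_prior_width
    for i in range(n_replicates):
        iso = simulate_isotherm(
            fx.thermo, fx.protocol, fx.concentrations,
            NoiseModel(fx.noise_sd_ucal, int(rng.integers(2**31))),
            label=f"{fx.name}-rep{i}")
        stated = AnalyteConcentrations(
            fx.concentrations.cell_uM * rng.uniform(1 - w, 1 + w),
            fx.concentrations.syringe_uM * rng.uniform(1 - w, 1 + w))
        out.append((replace(iso, stated_concentrations=stated), stated,
                    fx.thermo))
    return out
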