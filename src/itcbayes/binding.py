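"""Deterministic forward models for titration calorimetry of 1:1 and
symmetric two-site binding.

The titrand M (a symmetric dimer with two equivalent ligand grooves in the
two-site case) sits in the calorimeter cell at total concentration [M_t]; the
titrant X is injected from the syringe.  Binding is parameterised by
*microscopic*, site-resolved free energies and enthalpies:

* 1:1 —  ``dG``, ``dH`` with ``Kd = exp(dG/RT)``.
* two-site —  ``dG``, ``ddG``, ``dH``, ``ddH`` where the first binding step
  has ``Kd1 = exp(dG/RT)`` and enthalpy ``dH``, and the second step has
  ``Kd2 = exp((dG+ddG)/RT)`` and enthalpy ``dH + ddH``.  ``ddG < 0`` means
  positive cooperativity.  Statistical factors (2, 1/2) for the two
  indistinguishable sites are carried inside the mass-balance equations, so
  the macroscopic first stepwise constant is ``Kd1/2``.

All thermodynamic quantities are in kcal/mol, concentrations in molar,
volumes in litres, and total heats ``Q`` in calories; per-injection heats
``dQ`` are reported in microcalories to match instrument output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

__all__ = [
    "R_KCAL",
    "CELSIUS_OFFSET",
    "ThermoOneSite",
    "ThermoTwoSite",
    "TitrationProtocol",
    "AnalyteConcentrations",
    "StateConcentrations",
    "Isotherm",
    "kd_from_dg",
    "dg_from_kd",
    "dilution_series",
    "heat_one_site",
    "solve_free_two_site",
    "solve_free_two_site_lm",
    "heat_two_site",
    "injection_heats",
    "degeneracy_transform",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3
CELSIUS_OFFSET = 273.15

# unit conversions, centralized here
UL_TO_L = 1e-6
ML_TO_L = 1e-3
UM_TO_M = 1e-6
CAL_TO_UCAL = 1e6
KCAL_TO_CAL = 1e3


def _check_finite(x, name):
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite, got {x!r}")


@dataclass(frozen=True)
class ThermoOneSite:
    """Microscopic thermodynamics of a 1:1 binding step (kcal/mol)."""

    dG: float
    dH: float

    def __post_init__(self):
        _check_finite([self.dG, self.dH], "ThermoOneSite parameters")

    def kd(self, T: float) -> float:
        return kd_from_dg(self.dG, T)


@dataclass(frozen=True)
class ThermoTwoSite:
    """Microscopic thermodynamics of symmetric two-site binding (kcal/mol).

    ``dG``/``dH`` describe the first site-resolved step; ``ddG``/``ddH`` are
    the differences of the second step relative to the first, so step two has
    free energy ``dG + ddG`` and enthalpy ``dH + ddH``.
    """

    dG: float
    ddG: float
    dH: float
    ddH: float

    def __post_init__(self):
        _check_finite([self.dG, self.ddG, self.dH, self.ddH],
                      "ThermoTwoSite parameters")

    def kd1(self, T: float) -> float:
        return kd_from_dg(self.dG, T)

    def kd2(self, T: float) -> float:
        return kd_from_dg(self.dG + self.ddG, T)

    @property
    def dH2(self) -> float:
        return self.dH + self.ddH


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and cell geometry.

    Parameters
    ----------
    cell_volume_ml : active cell volume V0 in mL.
    temperature_K : absolute temperature.
    injection_volumes_ul : ordered injection volumes in μL.
    discard_first : drop injection 1 when fitting (it is still simulated);
        standard practice because the first, small injection is corrupted by
        diffusion across the syringe tip.
    """

    cell_volume_ml: float
    temperature_K: float
    injection_volumes_ul: tuple
    discard_first: bool = True

    def __post_init__(self):
        object.__setattr__(self, "injection_volumes_ul",
                           tuple(float(v) for v in self.injection_volumes_ul))
        if self.cell_volume_ml <= 0:
            raise ValueError("cell volume must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if len(self.injection_volumes_ul) == 0:
            raise ValueError("need at least one injection")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ValueError("all injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    @property
    def cell_volume_l(self) -> float:
        return self.cell_volume_ml * ML_TO_L

    @property
    def volumes_l(self) -> np.ndarray:
        return np.asarray(self.injection_volumes_ul) * UL_TO_L


@dataclass(frozen=True)
class AnalyteConcentrations:
    """Stated initial analyte concentrations in μM (cell titrand, syringe
    titrant)."""

    cell_uM: float
    syringe_uM: float

    def __post_init__(self):
        if self.cell_uM <= 0 or self.syringe_uM <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def cell_M(self) -> float:
        return self.cell_uM * UM_TO_M

    @property
    def syringe_M(self) -> float:
        return self.syringe_uM * UM_TO_M


@dataclass(frozen=True)
class StateConcentrations:
    """Equilibrium species concentrations (molar) for the two-site scheme."""

    free_M: float
    free_X: float
    bound_MX: float
    bound_MX2: float

    def total_M(self) -> float:
        return self.free_M + self.bound_MX + self.bound_MX2

    def total_X(self) -> float:
        return self.free_X + self.bound_MX + 2.0 * self.bound_MX2


@dataclass(frozen=True)
class Isotherm:
    """A measured or simulated titration: protocol, stated concentrations and
    per-injection integrated heats (μcal)."""

    protocol: TitrationProtocol
    stated_concentrations: AnalyteConcentrations
    heats_ucal: np.ndarray
    label: str = ""

    def __post_init__(self):
        heats = np.asarray(self.heats_ucal, dtype=float)
        object.__setattr__(self, "heats_ucal", heats)
        if len(heats) != self.protocol.n_injections:
            raise ValueError(
                f"{len(heats)} heats for {self.protocol.n_injections} injections")

    def retained_heats(self) -> np.ndarray:
        """Heats used for fitting, honouring ``discard_first``."""
        if self.protocol.discard_first:
            return self.heats_ucal[1:]
        return self.heats_ucal


def kd_from_dg(dG, T):
    """Dissociation constant (M) from a binding free energy (kcal/mol),
    ``Kd = exp(dG / RT)``."""
    dG = np.asarray(dG, dtype=float)
    if not np.all(np.isfinite(dG)):
        raise ValueError("dG must be finite")
    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive")
    out = np.exp(dG / (R_KCAL * T))
    return float(out) if out.ndim == 0 else out


def dg_from_kd(kd, T):
    """Inverse of :func:`kd_from_dg`."""
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be positive")
    out = R_KCAL * T * np.log(kd)
    return float(out) if out.ndim == 0 else out


def dilution_series(protocol: TitrationProtocol, conc: AnalyteConcentrations,
                    scheme: str = "exponential"):
    """Total cell concentrations (M) of titrand and titrant after each
    injection.

    The cell is perfused: each injection displaces an equal volume of mixed
    cell content.  Two bookkeeping conventions are provided:

    * ``"exponential"`` (default, the continuous-displacement limit used by
      MicroCal/Origin): after cumulative injected volume ΔV,
      ``[M_t] = M0 exp(-ΔV/V0)`` and ``[X_t] = X0 (1 - exp(-ΔV/V0))``.
    * ``"stepwise"``: per-injection perfect mixing with the displaced volume
      carrying the average of pre- and post-injection concentrations (the
      same convention as the displaced-volume heat correction):
      ``c -> (c (V0 - V_i/2) + c_syr V_i) / (V0 + V_i/2)``.

    Returns ``(Mt, Xt)`` arrays of length ``n_injections``.
    """
    v = protocol.volumes_l
    v0 = protocol.cell_volume_l
    cum = np.cumsum(v)
    if cum[-1] >= 10.0 * v0:
        warnings.warn("cumulative injected volume exceeds 10x the cell "
                      "volume; dilution model is unphysical here")
    m0 = conc.cell_M
    x0 = conc.syringe_M
    if scheme == "exponential":
        f = np.exp(-cum / v0)
        return m0 * f, x0 * (1.0 - f)
    if scheme == "stepwise":
        mt = np.empty_like(cum)
        xt = np.empty_like(cum)
        m, x = m0, 0.0
        for i, vi in enumerate(v):
            m = m * (v0 - vi / 2) / (v0 + vi / 2)
            x = (x * (v0 - vi / 2) + x0 * vi) / (v0 + vi / 2)
            mt[i], xt[i] = m, x
        return mt, xt
    raise ValueError(f"unknown dilution scheme {scheme!r}")


def heat_one_site(Mt, Xt, thermo: ThermoOneSite, V0_l, T):
    """Total heat Q (cal) of a 1:1 binding system at total concentrations
    ``Mt``, ``Xt`` (M), from the standard quadratic (identical-sites, n=1)
    binding expression.
    """
    Mt = np.asarray(Mt, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    if np.any(Mt <= 0) or np.any(Xt < 0):
        raise ValueError("require Mt > 0 and Xt >= 0")
    kd = thermo.kd(T)
    r = Xt / Mt
    s = 1.0 + r + kd / Mt
    disc = s * s - 4.0 * r
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in quadratic model")
    q = V0_l * Mt * (thermo.dH * KCAL_TO_CAL) / 2.0 * (s - np.sqrt(disc))
    return float(q) if q.ndim == 0 else q


def _two_site_free_x(Mt, Xt, Kd1, Kd2, n_iter=62):
    """Vectorized solve of the two-site mass balance for free ligand X.

    Free macromolecule is eliminated analytically:
    ``M = Mt / (1 + 2X/Kd1 + X^2/(Kd1 Kd2))``, leaving a single strictly
    increasing residual in X bracketed by [0, Xt]; bisection to machine
    precision.  All inputs broadcast.
    """
    Mt, Xt, Kd1, Kd2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (Mt, Xt, Kd1, Kd2)))

    def resid(x):
        p1 = 2.0 * x / Kd1
        p2 = x * x / (Kd1 * Kd2)
        m = Mt / (1.0 + p1 + p2)
        return x + m * (p1 + 2.0 * p2) - Xt

    lo = np.zeros_like(Xt)
    hi = np.array(Xt, copy=True)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        high = resid(mid) > 0.0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def solve_free_two_site(Mt, Xt, Kd1, Kd2) -> tuple:
    """Free concentrations ``([M], [X])`` (M) satisfying the two-site mass
    balance

    ``Mt = [M] (1 + 2[X]/Kd1 + [X]^2/(Kd1 Kd2))``,
    ``Xt = [X] + [M] (2[X]/Kd1 + 2[X]^2/(Kd1 Kd2))``.

    Inputs broadcast; scalars in, scalars out.  Deterministic bracketed
    bisection on the exact one-dimensional reduction in [X].
    """
    Mt_a = np.asarray(Mt, dtype=float)
    Xt_a = np.asarray(Xt, dtype=float)
    if np.any(Mt_a <= 0) or np.any(Xt_a < 0):
        raise ValueError("require Mt > 0 and Xt >= 0")
    if np.any(np.asarray(Kd1) <= 0) or np.any(np.asarray(Kd2) <= 0):
        raise ValueError("dissociation constants must be positive")
    x = _two_site_free_x(Mt_a, Xt_a, Kd1, Kd2)
    m = Mt_a / (1.0 + 2.0 * x / Kd1 + x * x / (np.asarray(Kd1) * np.asarray(Kd2)))
    if np.ndim(m) == 0:
        return float(m), float(x)
    return m, x


def solve_free_two_site_lm(Mt, Xt, Kd1, Kd2) -> tuple:
    """Scalar Levenberg–Marquardt solve of the same mass balance in
    log-transformed variables (positivity enforced by construction).

    Slower than :func:`solve_free_two_site`; kept as an independent route for
    cross-checking.  Falls back to the bisection solver on non-convergence.
    """
    Mt, Xt = float(Mt), float(Xt)
    if Xt == 0.0:
        return Mt, 0.0
    x0 = min(Xt, Kd1)
    guess = np.log([Mt, x0])

    def fun(logmx):
        # LM trial points can overflow in intermediate products; harmless,
        # the residual just stays large there
        with np.errstate(over="ignore", invalid="ignore"):
            m, x = np.exp(logmx)
            p1 = 2.0 * x / Kd1
            p2 = x * x / (Kd1 * Kd2)
            return [m * (1.0 + p1 + p2) - Mt,
                    x + m * (p1 + 2.0 * p2) - Xt]

    sol = root(fun, guess, method="lm", options={"xtol": 1e-14})
    if sol.success:
        m, x = np.exp(sol.x)
        scale = max(Mt, Xt)
        if max(abs(sol.fun[0]), abs(sol.fun[1])) < 1e-8 * scale:
            return float(m), float(x)
    return solve_free_two_site(Mt, Xt, Kd1, Kd2)


def two_site_species(Mt, Xt, thermo: ThermoTwoSite, T) -> StateConcentrations:
    """Full species breakdown at equilibrium (scalar convenience)."""
    kd1, kd2 = thermo.kd1(T), thermo.kd2(T)
    m, x = solve_free_two_site(Mt, Xt, kd1, kd2)
    mx = 2.0 * x * m / kd1
    mx2 = x * x * m / (kd1 * kd2)
    return StateConcentrations(m, x, mx, mx2)


def heat_two_site(Mt, Xt, thermo: ThermoTwoSite, V0_l, T):
    """Total heat Q (cal) of the two-site system:
    ``Q = V0 (ΔH1 [MX] + (ΔH1 + ΔH2) [MX2])``
    with ΔH1 = dH and ΔH2 = dH + ddH.
    """
    kd1, kd2 = thermo.kd1(T), thermo.kd2(T)
    m, x = solve_free_two_site(Mt, Xt, kd1, kd2)
    mx = 2.0 * np.asarray(x) * m / kd1
    mx2 = np.asarray(x) ** 2 * m / (kd1 * kd2)
    dh1 = thermo.dH * KCAL_TO_CAL
    dh2 = thermo.dH2 * KCAL_TO_CAL
    q = V0_l * (dh1 * mx + (dh1 + dh2) * mx2)
    return float(q) if np.ndim(q) == 0 else q


def injection_heats(Q_series_cal, protocol: TitrationProtocol,
                    dH0_ucal: float = 0.0) -> np.ndarray:
    """Per-injection heats dQ_i (μcal) from the cumulative total-heat series.

    ``Q_series_cal`` holds the total heat after each injection (one entry per
    injection, evaluated at the post-injection concentrations; the
    pre-titration state contributes Q0 = 0).  The displaced-volume correction
    adds back the heat carried out of the active volume by the perfused
    liquid::

        dQ_i = Q_i + (V_i/V0) (Q_i + Q_{i-1})/2 - Q_{i-1} + dH0

    where dH0 (μcal) is a flat per-injection offset absorbing dilution heat
    and buffer mismatch.
    """
    q = np.asarray(Q_series_cal, dtype=float)
    if q.ndim != 1 or len(q) != protocol.n_injections:
        raise ValueError(
            f"Q series of length {len(q)} does not match "
            f"{protocol.n_injections} injections")
    qprev = np.concatenate([[0.0], q[:-1]])
    v = protocol.volumes_l
    v0 = protocol.cell_volume_l
    dq_cal = q + (v / v0) * 0.5 * (q + qprev) - qprev
    return dq_cal * CAL_TO_UCAL + dH0_ucal


def model_injection_heats(thermo, protocol: TitrationProtocol,
                          conc: AnalyteConcentrations, dH0_ucal: float = 0.0,
                          scheme: str = "exponential") -> np.ndarray:
    """Noiseless per-injection heat series (μcal) for either binding model."""
    mt, xt = dilution_series(protocol, conc, scheme=scheme)
    v0 = protocol.cell_volume_l
    T = protocol.temperature_K
    if isinstance(thermo, ThermoTwoSite):
        q = heat_two_site(mt, xt, thermo, v0, T)
    elif isinstance(thermo, ThermoOneSite):
        q = heat_one_site(mt, xt, thermo, v0, T)
    else:
        raise TypeError(f"unsupported thermo type {type(thermo).__name__}")
    return injection_heats(q, protocol, dH0_ucal)


def degeneracy_transform(thermo, conc: AnalyteConcentrations, alpha: float,
                         T: float):
    """Apply the exact concentration-degeneracy scaling.

    For any α > 0, multiplying both analyte concentrations and every Kd by α
    while dividing every enthalpy by α leaves all model heats unchanged.  In
    the energy parameterisation: ``dG -> dG + RT ln α`` (ddG unchanged),
    ``dH -> dH/α``, ``ddH -> ddH/α``.

    Returns the transformed ``(thermo, concentrations)`` pair.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    shift = R_KCAL * T * np.log(alpha)
    new_conc = AnalyteConcentrations(conc.cell_uM * alpha,
                                     conc.syringe_uM * alpha)
    if isinstance(thermo, ThermoTwoSite):
        new_thermo = ThermoTwoSite(thermo.dG + shift, thermo.ddG,
                                   thermo.dH / alpha, thermo.ddH / alpha)
    elif isinstance(thermo, ThermoOneSite):
        new_thermo = ThermoOneSite(thermo.dG + shift, thermo.dH / alpha)
    else:
        raise TypeError(f"unsupported thermo type {type(thermo).__name__}")
    return new_thermo, new_conc
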