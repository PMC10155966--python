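"""Priors, likelihood and posterior for Bayesian ITC inference.

The model follows the statsmodels idiom: build an :class:`ITCModel` from one
or more isotherms, then call :meth:`ITCModel.fit` to obtain an
:class:`~itcbayes.results.ITCResults` carrying posterior samples, credible
intervals and diagnostics.

Parameter vector layout (fixed, documented order)
-------------------------------------------------
Thermodynamic block first, then one block of four nuisance/concentration
parameters per isotherm, in isotherm order::

    two-site: [dG, ddG, dH, ddH,
               cell_uM_0, syringe_uM_0, dH0_ucal_0, sigma_ucal_0,
               cell_uM_1, ...]
    1:1:      [dG, dH, cell_uM_0, ...]

so a two-site model has ``4 + 4k`` parameters for ``k`` isotherms (12 for a
two-isotherm global model) and a 1:1 model ``2 + 4k``.  Energies are in
kcal/mol, concentrations in μM, the per-injection offset dH0 and the noise
standard deviation σ in μcal.

The likelihood is Gaussian and independent across retained injections: each
measured heat x_i is normal with mean μ_i(θ), the forward-model injection
heat, and standard deviation σ (one σ per isotherm).  Since only the ratio of
analyte concentrations is identifiable (the exact α-scaling degeneracy), the
likelihood is constant along degenerate directions and the concentration
priors shape those posterior marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .binding import (CAL_TO_UCAL, KCAL_TO_CAL, R_KCAL, Isotherm,
                      _two_site_free_x)

logger = logging.getLogger(__name__)

__all__ = ["PriorSpec", "PriorSet", "default_priors", "ITCModel"]

THERMO_NAMES = {"two_site": ("dG", "ddG", "dH", "ddH"),
                "one_site": ("dG", "dH")}
NUISANCE_NAMES = ("cell_uM", "syringe_uM", "dH0_ucal", "sigma_ucal")

#: Wide default uniform prior ranges for the thermodynamic parameters
#: (kcal/mol); nuisance priors fixed to dH0 in [-10, 10] μcal and
#: σ in [0.001, 1] μcal.
DEFAULT_THERMO_BOUNDS = {
    "dG": (-15.0, -2.0),
    "ddG": (-7.5, 7.5),
    "dH": (-60.0, 20.0),
    "ddH": (-45.0, 45.0),
}
DEFAULT_DH0_BOUNDS = (-10.0, 10.0)
DEFAULT_SIGMA_BOUNDS = (0.001, 1.0)


@dataclass(frozen=True)
class PriorSpec:
    """One-dimensional prior: ``uniform`` on [lower, upper] or ``normal``
    with given mean/sd, in the parameter's native units."""

    kind: str
    lower: float = np.nan
    upper: float = np.nan
    mean: float = np.nan
    sd: float = np.nan

    def __post_init__(self):
        if self.kind == "uniform":
            if not self.lower < self.upper:
                raise ValueError("uniform prior needs lower < upper")
        elif self.kind == "normal":
            if not (np.isfinite(self.mean) and self.sd > 0):
                raise ValueError("normal prior needs finite mean and sd > 0")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def uniform(cls, lower, upper):
        return cls("uniform", lower=float(lower), upper=float(upper))

    @classmethod
    def normal(cls, mean, sd):
        return cls("normal", mean=float(mean), sd=float(sd))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "uniform":
            out = np.where((x >= self.lower) & (x <= self.upper),
                           -np.log(self.upper - self.lower), -np.inf)
        else:
            out = (-0.5 * ((x - self.mean) / self.sd) ** 2
                   - 0.5 * np.log(2 * np.pi * self.sd ** 2))
        return float(out) if out.ndim == 0 else out

    def sample(self, rng, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.lower, self.upper, size=size)
        return rng.normal(self.mean, self.sd, size=size)


class PriorSet:
    """Ordered mapping of parameter name -> :class:`PriorSpec`, covering the
    model's full parameter list."""

    def __init__(self, specs: dict):
        self.specs = dict(specs)

    def __getitem__(self, name):
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(f"no prior for parameter {name!r}") from None

    def __contains__(self, name):
        return name in self.specs

    def names(self):
        return list(self.specs)

    def log_prior(self, theta, names):
        """Sum of per-parameter log densities for a (..., ndim) array."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        total = np.zeros(theta.shape[0])
        for j, name in enumerate(names):
            total = total + self[name].logpdf(theta[:, j])
        return total

    def sample(self, names, rng, n):
        return np.column_stack([self[name].sample(rng, n) for name in names])


def concentration_prior(stated_uM: float, fraction: float = 0.10,
                        kind: str = "uniform") -> PriorSpec:
    """Prior for an analyte concentration as a fractional window around its
    stated value: uniform on ±fraction (default), or normal with
    sd = fraction * stated for sensitivity studies."""
    if kind == "uniform":
        return PriorSpec.uniform(stated_uM * (1 - fraction),
                                 stated_uM * (1 + fraction))
    if kind == "normal":
        return PriorSpec.normal(stated_uM, stated_uM * fraction)
    raise ValueError(f"unknown concentration prior kind {kind!r}")


def default_priors(kind, isotherms, cell_fraction=0.10, syringe_fraction=0.10,
                   conc_kind="uniform", overrides=None) -> PriorSet:
    """Default :class:`PriorSet` for a model over the given isotherms."""
    specs = {name: PriorSpec.uniform(*DEFAULT_THERMO_BOUNDS[name])
             for name in THERMO_NAMES[kind]}
    for j, iso in enumerate(isotherms):
        conc = iso.stated_concentrations
        specs[f"cell_uM_{j}"] = concentration_prior(
            conc.cell_uM, cell_fraction, conc_kind)
        specs[f"syringe_uM_{j}"] = concentration_prior(
            conc.syringe_uM, syringe_fraction, conc_kind)
        specs[f"dH0_ucal_{j}"] = PriorSpec.uniform(*DEFAULT_DH0_BOUNDS)
        specs[f"sigma_ucal_{j}"] = PriorSpec.uniform(*DEFAULT_SIGMA_BOUNDS)
    if overrides:
        for name, spec in overrides.items():
            if name not in specs:
                raise KeyError(f"override for unknown parameter {name!r}")
            specs[name] = spec
    return PriorSet(specs)


class ITCModel:
    """Bayesian binding model over one or more isotherms.

    Parameters
    ----------
    isotherms : Isotherm or sequence of Isotherm
        Thermodynamic parameters are shared (global model); each isotherm
        contributes its own concentration and nuisance block.
    kind : "two_site" or "one_site"
    priors : PriorSet, optional
        Full prior set; by default built by :func:`default_priors` with the
        given concentration fractions.
    cell_fraction, syringe_fraction : float
        Half-width of the fractional concentration windows.
    prior_overrides : dict name -> PriorSpec
    dilution : "exponential" or "stepwise"
    """

    def __init__(self, isotherms, kind="two_site", priors=None,
                 cell_fraction=0.10, syringe_fraction=0.10,
                 conc_prior_kind="uniform", prior_overrides=None,
                 dilution="exponential"):
        if isinstance(isotherms, Isotherm):
            isotherms = [isotherms]
        self.isotherms = list(isotherms)
        if not self.isotherms:
            raise ValueError("need at least one isotherm")
        if kind not in THERMO_NAMES:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.dilution = dilution
        self.temperature_K = self.isotherms[0].protocol.temperature_K
        self.priors = priors or default_priors(
            kind, self.isotherms, cell_fraction, syringe_fraction,
            conc_prior_kind, prior_overrides)
        missing = [n for n in self.param_names if n not in self.priors]
        if missing:
            raise KeyError(f"priors missing for parameters {missing}")
        self.n_solver_failures = 0
        self._precompute()

    # ---------------------------------------------------------------- layout
    @property
    def param_names(self) -> list:
        names = list(THERMO_NAMES[self.kind])
        for j in range(len(self.isotherms)):
            names += [f"{n}_{j}" for n in NUISANCE_NAMES]
        return names

    @property
    def n_params(self) -> int:
        return len(THERMO_NAMES[self.kind]) + 4 * len(self.isotherms)

    def _precompute(self):
        self._per_iso = []
        for iso in self.isotherms:
            p = iso.protocol
            v = p.volumes_l
            cum = np.cumsum(v)
            v0 = p.cell_volume_l
            keep = slice(1, None) if p.discard_first else slice(None)
            self._per_iso.append({
                "dil": np.exp(-cum / v0),        # exponential displacement
                "vratio": v / v0,
                "v0": v0,
                "T": p.temperature_K,
                "keep": keep,
                "data": iso.heats_ucal[keep],
            })
        if self.dilution == "stepwise":
            from .binding import dilution_series
            for iso, d in zip(self.isotherms, self._per_iso):
                mt, xt = dilution_series(iso.protocol,
                                         iso.stated_concentrations,
                                         scheme="stepwise")
                # store normalized profiles; rescaled by sampled concs
                d["mt_unit"] = mt / iso.stated_concentrations.cell_M
                d["xt_unit"] = xt / iso.stated_concentrations.syringe_M

    # -------------------------------------------------------- forward models
    def _predicted_heats(self, theta, j):
        """Noiseless μcal injection-heat series for isotherm ``j`` at each
        parameter row of ``theta`` (n, ndim).  Returns (n, n_injections)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        d = self._per_iso[j]
        nther = len(THERMO_NAMES[self.kind])
        blk = nther + 4 * j
        cell_M = theta[:, blk] * 1e-6
        syr_M = theta[:, blk + 1] * 1e-6
        dH0 = theta[:, blk + 2]
        RT = R_KCAL * d["T"]
        if self.dilution == "stepwise":
            mt = cell_M[:, None] * d["mt_unit"][None, :]
            xt = syr_M[:, None] * d["xt_unit"][None, :]
        else:
            f = d["dil"]
            mt = cell_M[:, None] * f[None, :]
            xt = syr_M[:, None] * (1.0 - f[None, :])
        if self.kind == "two_site":
            dG, ddG, dH, ddH = (theta[:, i] for i in range(4))
            kd1 = np.exp(dG / RT)[:, None]
            kd2 = np.exp((dG + ddG) / RT)[:, None]
            x = _two_site_free_x(mt, xt, kd1, kd2)
            p1 = 2.0 * x / kd1
            p2 = x * x / (kd1 * kd2)
            m = mt / (1.0 + p1 + p2)
            dh1 = (dH * KCAL_TO_CAL)[:, None]
            dh2 = ((dH + ddH) * KCAL_TO_CAL)[:, None]
            q = d["v0"] * (dh1 * (p1 * m) + (dh1 + dh2) * (p2 * m))
        else:
            dG, dH = theta[:, 0], theta[:, 1]
            kd = np.exp(dG / RT)[:, None]
            r = xt / mt
            s = 1.0 + r + kd / mt
            disc = np.maximum(s * s - 4.0 * r, 0.0)
            q = (d["v0"] * mt * (dH * KCAL_TO_CAL)[:, None] / 2.0
                 * (s - np.sqrt(disc)))
        qprev = np.concatenate([np.zeros((q.shape[0], 1)), q[:, :-1]], axis=1)
        dq = q + d["vratio"][None, :] * 0.5 * (q + qprev) - qprev
        return dq * CAL_TO_UCAL + dH0[:, None]

    # ------------------------------------------------------------- densities
    def log_prior(self, theta):
        """Sum of per-parameter prior log densities; -inf outside support."""
        out = self.priors.log_prior(theta, self.param_names)
        return float(out[0]) if np.ndim(theta) == 1 else out

    def log_likelihood(self, theta):
        """Gaussian log likelihood over all retained injections of all
        isotherms.  Forward-solver failures yield -inf (zero-likelihood)."""
        theta2 = np.atleast_2d(np.asarray(theta, dtype=float))
        ll = np.zeros(theta2.shape[0])
        nther = len(THERMO_NAMES[self.kind])
        with np.errstate(over="ignore", invalid="ignore"):
            for j, d in enumerate(self._per_iso):
                sigma = theta2[:, nther + 4 * j + 3]
                mu = self._predicted_heats(theta2, j)[:, d["keep"]]
                resid = mu - d["data"][None, :]
                n = resid.shape[1]
                ll = ll + (-0.5 * n * np.log(2 * np.pi * sigma ** 2)
                           - np.sum(resid ** 2, axis=1) / (2 * sigma ** 2))
        bad = ~np.isfinite(ll)
        if np.any(bad):
            self.n_solver_failures += int(np.sum(bad))
            logger.warning("forward model non-finite for %d parameter sets",
                           int(np.sum(bad)))
            ll[bad] = -np.inf
        return float(ll[0]) if np.ndim(theta) == 1 else ll

    def log_posterior(self, theta):
        """log prior + log likelihood; -inf propagates."""
        theta2 = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self.priors.log_prior(theta2, self.param_names)
        out = np.full(theta2.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            out[ok] = lp[ok] + self.log_likelihood(theta2[ok])
        return float(out[0]) if np.ndim(theta) == 1 else out

    # ------------------------------------------------------------ convenience
    def theta_from_values(self, thermo, per_isotherm=None):
        """Assemble a parameter vector from a thermo object plus per-isotherm
        ``(cell_uM, syringe_uM, dH0, sigma)`` tuples (default: stated
        concentrations, dH0=0, sigma=0.2)."""
        if self.kind == "two_site":
            vals = [thermo.dG, thermo.ddG, thermo.dH, thermo.ddH]
        else:
            vals = [thermo.dG, thermo.dH]
        for j, iso in enumerate(self.isotherms):
            if per_isotherm is not None:
                vals += list(per_isotherm[j])
            else:
                c = iso.stated_concentrations
                vals += [c.cell_uM, c.syringe_uM, 0.0, 0.2]
        return np.asarray(vals, dtype=float)

    def fit(self, n_steps=20000, n_walkers=50, seed=None, n_replicas=1,
            move_mix=0.2, progress=False):
        """Sample the posterior with the affine-invariant ensemble sampler
        and return an :class:`~itcbayes.results.ITCResults`.

        ``n_replicas`` independent replicas (fresh walker initialisation and
        RNG stream) are pooled after per-replica burn-in; convergence is
        assessed from autocorrelation times and cross-replica agreement.
        """
        from .results import ITCResults
        from .sampling import SamplerConfig, run_ensemble

        cfg = SamplerConfig(n_walkers=n_walkers, n_steps=n_steps,
                            de_fraction=move_mix, seed=seed,
                            n_replicas=n_replicas, progress=progress)
        runs = [run_ensemble(self, cfg, replica=i) for i in range(n_replicas)]
        return ITCResults(self, runs)
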