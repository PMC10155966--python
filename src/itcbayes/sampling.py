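"""Affine-invariant ensemble MCMC driver, autocorrelation analysis and
convergence checks.

Sampling uses emcee's ensemble sampler with a 20%:80% mix of
differential-evolution and stretch moves.  Walkers are initialised by i.i.d.
draws from the priors (redrawn where the posterior is -inf).  Convergence
requires the chain length to exceed 50x the integrated autocorrelation time
for every parameter and, across replicas, near-identical marginal credible
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import emcee
import numpy as np
import pandas as pd
from emcee.autocorr import integrated_time

logger = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "PosteriorSamples", "run_ensemble",
           "autocorrelation_time", "check_convergence"]


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``n_walkers`` defaults to 50 (25-50 is the typical band); the move mix is
    ``de_fraction`` differential-evolution and the rest stretch moves.
    """

    n_walkers: int = 50
    n_steps: int = 20000
    de_fraction: float = 0.2
    seed: int | None = None
    n_replicas: int = 3
    progress: bool = False
    #: "collapse" (default): after a short exploration phase started from
    #: i.i.d. prior draws, restart all walkers in a tight ball around the
    #: best point found, then run the production chain.  "prior": production
    #: chain starts directly from the prior draws.  Ensemble moves contract
    #: slowly, so walkers started in far-off corners of a wide prior box can
    #: take tens of thousands of steps to join the posterior bulk; the
    #: restart removes that transient without touching the invariant
    #: distribution (burn-in is discarded either way).
    init: str = "collapse"
    n_explore: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_steps < 1 or self.n_walkers < 2:
            raise ValueError("need n_steps >= 1 and n_walkers >= 2")


@dataclass
class PosteriorSamples:
    """Raw walker chains plus diagnostics for one sampling run.

    ``chain`` has shape (n_steps, n_walkers, n_params).  ``burn`` (5x the
    largest autocorrelation time) and ``thin`` (tau/2) are defaults applied
    by :meth:`flat`; the raw chain is always retained.
    """

    chain: np.ndarray
    log_prob: np.ndarray
    param_names: list
    acceptance_fraction: float
    tau: np.ndarray
    burn: int
    thin: int
    config: SamplerConfig
    replica: int = 0

    @property
    def n_steps(self):
        return self.chain.shape[0]

    def flat(self, burn=None, thin=None) -> pd.DataFrame:
        """Post-burn-in, thinned samples flattened across walkers."""
        burn = self.burn if burn is None else burn
        thin = self.thin if thin is None else thin
        sub = self.chain[burn::max(thin, 1)]
        flat = sub.reshape(-1, sub.shape[-1])
        return pd.DataFrame(flat, columns=self.param_names)

    @property
    def n_effective(self) -> int:
        return len(self.flat())


def sample_initial_walkers(model, n_walkers, rng, max_redraws=100):
    """i.i.d. prior draws, redrawing any walker whose posterior is -inf."""
    names = model.param_names
    p0 = model.priors.sample(names, rng, n_walkers)
    lp = model.log_posterior(p0)
    if not np.any(np.isfinite(lp)):
        # quick sanity probe before looping
        for _ in range(max_redraws):
            p0 = model.priors.sample(names, rng, n_walkers)
            lp = model.log_posterior(p0)
            if np.any(np.isfinite(lp)):
                break
        else:
            raise RuntimeError(
                "all walker initialisations have zero posterior "
                "(priors inconsistent with data scale)")
    for _ in range(max_redraws):
        bad = ~np.isfinite(lp)
        if not np.any(bad):
            break
        p0[bad] = model.priors.sample(names, rng, int(np.sum(bad)))
        lp = model.log_posterior(p0)
    # any remaining bad walkers are copied from a finite one
    bad = ~np.isfinite(lp)
    if np.any(bad):
        good = np.flatnonzero(np.isfinite(lp))
        p0[bad] = p0[rng.choice(good, size=int(np.sum(bad)))]
    return p0


def _collapse_walkers(model, explorer, rng, rel_scale=1e-3):
    """Restart positions: a tight Gaussian ball around the best point seen
    during exploration, scattered by ``rel_scale`` of each prior's scale and
    clipped inside uniform supports."""
    flat = explorer.get_chain(flat=True)
    flp = explorer.get_log_prob(flat=True)
    best = flat[np.argmax(flp)]
    names = model.param_names
    scale = np.empty(len(names))
    lo = np.full(len(names), -np.inf)
    hi = np.full(len(names), np.inf)
    for i, name in enumerate(names):
        spec = model.priors[name]
        if spec.kind == "uniform":
            scale[i] = spec.upper - spec.lower
            lo[i], hi[i] = spec.lower, spec.upper
        else:
            scale[i] = spec.sd
    n = explorer.nwalkers
    p0 = best[None, :] + rel_scale * scale[None, :] * rng.standard_normal(
        (n, len(names)))
    eps = 1e-9 * scale
    return np.clip(p0, lo + eps, hi - eps)


def run_ensemble(model, cfg: SamplerConfig, replica: int = 0) -> PosteriorSamples:
    """Run one ensemble-sampler replica and return its chains plus
    diagnostics.  Deterministic given ``cfg.seed`` and ``replica``."""
    ndim = model.n_params
    if cfg.n_walkers < 2 * ndim:
        raise ValueError(f"{cfg.n_walkers} walkers < 2 x {ndim} parameters")
    seed = None if cfg.seed is None else (int(cfg.seed) + 7919 * replica) % (2**31)
    rng = np.random.default_rng(seed)
    p0 = sample_initial_walkers(model, cfg.n_walkers, rng)

    moves = [(emcee.moves.DEMove(), cfg.de_fraction),
             (emcee.moves.StretchMove(), 1.0 - cfg.de_fraction)]
    moves = [(m, w) for m, w in moves if w > 0]

    if cfg.init == "collapse" and cfg.n_explore > 0:
        explorer = emcee.EnsembleSampler(cfg.n_walkers, ndim,
                                         model.log_posterior, moves=moves,
                                         vectorize=True)
        explorer.random_state = np.random.RandomState(
            rng.integers(2**31)).get_state()
        explorer.run_mcmc(p0, cfg.n_explore, progress=False)
        p0 = _collapse_walkers(model, explorer, rng)
    elif cfg.init != "prior" and cfg.init != "collapse":
        raise ValueError(f"unknown init strategy {cfg.init!r}")

    sampler = emcee.EnsembleSampler(cfg.n_walkers, ndim, model.log_posterior,
                                    moves=moves, vectorize=True)
    sampler.random_state = np.random.RandomState(
        rng.integers(2**31)).get_state()
    sampler.run_mcmc(p0, cfg.n_steps, progress=cfg.progress)

    chain = sampler.get_chain()
    tau = autocorrelation_time(chain)
    max_tau = float(np.nanmax(tau))
    burn = min(int(5 * max_tau), cfg.n_steps // 2)
    thin = max(1, int(max_tau / 2))
    acc = float(np.mean(sampler.acceptance_fraction))
    logger.info("replica %d: acceptance %.3f, max tau %.1f over %d steps",
                replica, acc, max_tau, cfg.n_steps)
    return PosteriorSamples(chain=chain, log_prob=sampler.get_log_prob(),
                            param_names=model.param_names,
                            acceptance_fraction=acc, tau=tau, burn=burn,
                            thin=thin, config=cfg, replica=replica)


def autocorrelation_time(chain) -> np.ndarray:
    """Integrated autocorrelation time per parameter via the standard
    windowed estimator on walker-averaged chains.

    ``chain`` is (n_steps, n_walkers, n_params) or (n_steps, n_walkers) for
    a single parameter.  Never raises on short chains (tol=0); callers judge
    convergence via :func:`check_convergence`.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim == 2:
        chain = chain[:, :, None]
    return np.atleast_1d(integrated_time(chain, tol=0, quiet=True))


def check_convergence(samples, steps_per_tau: float = 50.0,
                      cr_level: float = 0.95,
                      endpoint_tolerance: float = 0.10) -> dict:
    """Convergence report for one run or a list of replicas.

    Passes iff every parameter satisfies ``n_steps > steps_per_tau * tau``
    in every replica and, when several replicas exist, each replica's
    credible-interval endpoints lie within ``endpoint_tolerance`` of the
    pooled interval width.
    """
    runs = samples if isinstance(samples, (list, tuple)) else [samples]
    names = runs[0].param_names
    report = {"parameters": {}, "replicas": len(runs), "passed": True}
    for i, name in enumerate(names):
        taus = [float(r.tau[i]) for r in runs]
        ratios = [r.n_steps / max(t, 1e-12) for r, t in zip(runs, taus)]
        ok = all(rt > steps_per_tau for rt in ratios)
        report["parameters"][name] = {
            "tau": max(taus), "steps_per_tau": min(ratios), "long_enough": ok}
        report["passed"] &= ok
    if len(runs) > 1:
        lo_q, hi_q = (1 - cr_level) / 2, 1 - (1 - cr_level) / 2
        pooled = pd.concat([r.flat() for r in runs], ignore_index=True)
        for i, name in enumerate(names):
            plo, phi = np.quantile(pooled[name], [lo_q, hi_q])
            width = max(phi - plo, 1e-12)
            agree = True
            for r in runs:
                rlo, rhi = np.quantile(r.flat()[name], [lo_q, hi_q])
                agree &= (abs(rlo - plo) <= endpoint_tolerance * width
                          and abs(rhi - phi) <= endpoint_tolerance * width)
            report["parameters"][name]["replicas_agree"] = agree
            report["passed"] &= agree
    return report
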