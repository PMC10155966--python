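"""Basic plotting helpers (presentation only; never used in the
likelihood).  Isotherms are conventionally displayed as kcal per mole of
injectant versus molar ratio."""

from __future__ import annotations

import numpy as np

from .binding import Isotherm, dilution_series

__all__ = ["per_mole_of_injectant", "plot_isotherm", "plot_marginals"]


def per_mole_of_injectant(iso: Isotherm) -> tuple:
    """(molar ratio, kcal/mol-of-injectant) display normalisation."""
    p = iso.protocol
    moles = p.volumes_l * iso.stated_concentrations.syringe_M
    mt, xt = dilution_series(p, iso.stated_concentrations)
    ratio = xt / mt
    kcal_per_mol = iso.heats_ucal * 1e-6 / 1e3 / moles  # ucal -> kcal
    return ratio, kcal_per_mol


def plot_isotherm(iso: Isotherm, model_heats=None, ax=None):
    """Scatter the measured per-injection heats (and optionally a model
    curve) in display normalisation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = per_mole_of_injectant(iso)
    ax.plot(x, y, "o", label=iso.label or "data")
    if model_heats is not None:
        ym = (np.asarray(model_heats) * 1e-6 / 1e3
              / (iso.protocol.volumes_l * iso.stated_concentrations.syringe_M))
        ax.plot(x, ym, "-", label="model")
    ax.set_xlabel("molar ratio [X]t/[M]t")
    ax.set_ylabel("kcal/mol of injectant")
    ax.legend()
    return ax


def plot_marginals(samples, names=None, truths=None, bins=60):
    """Histogram the 1-D posterior marginals on a grid of axes."""
    import matplotlib.pyplot as plt

    names = list(names or samples.columns)
    n = len(names)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), names):
        ax.hist(samples[name], bins=bins, density=True)
        if truths and name in truths:
            ax.axvline(truths[name], color="r")
        ax.set_xlabel(name)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig
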