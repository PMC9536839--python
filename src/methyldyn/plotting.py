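"""Small plotting helpers (matplotlib); cosmetic, not used by the fits."""

from __future__ import annotations

import numpy as np


def plot_dispersion(ax, dataset, result=None, model=None, color=None):
    """CPMG R2,eff profile with optional fitted curve."""
    ax.errorbar(dataset.nu_cpmg, dataset.r2eff, yerr=dataset.r2eff_err,
                fmt="o", ms=4, color=color, label=dataset.tag)
    if result is not None and model is not None:
        sim = model._simulate_dataset(result.params, dataset)
        order = np.argsort(dataset.nu_cpmg)
        ax.plot(dataset.nu_cpmg[order], sim[order], "-", color=color)
    ax.set_xlabel(r"$\nu_\mathrm{CPMG}$ (Hz)")
    ax.set_ylabel(r"$R_{2,\mathrm{eff}}$ (s$^{-1}$)")


def plot_cest(ax, dataset, result=None, model=None, color=None):
    """CEST profile (normalized intensity vs offset) with optional fit."""
    ax.plot(dataset.offsets_hz, dataset.intensity, "o", ms=3, color=color,
            label=f"{dataset.spinlock_hz:g} Hz lock")
    if result is not None and model is not None:
        sim = model._simulate_dataset(result.params, dataset)
        order = np.argsort(dataset.offsets_hz)
        ax.plot(dataset.offsets_hz[order], sim[order], "-", color=color)
    ax.set_xlabel("offset (Hz)")
    ax.set_ylabel(r"$I/I_0$")


def plot_ds2_kde(ax, ds2_values, label=None, bandwidth=None, color=None):
    """Kernel-density overlay of order-parameter changes."""
    from scipy.stats import gaussian_kde

    vals = np.asarray(ds2_values, dtype=float)
    kde = gaussian_kde(vals, bw_method=bandwidth)
    x = np.linspace(vals.min() - 0.1, vals.max() + 0.1, 256)
    ax.plot(x, kde(x), label=label, color=color)
    ax.set_xlabel(r"$\Delta S^2_\mathrm{axis}$")
    ax.set_ylabel("density")
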