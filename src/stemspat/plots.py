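"""Matplotlib views of envelope tests, correlograms and ordinations."""

from __future__ import annotations

import numpy as np


def plot_pcf(result, ax=None):
    """Observed g(r) with the CSR envelope band; the dashed line is g = 1."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.fill_between(result.r_grid, result.g_lo, result.g_hi, alpha=0.3, label="CSR envelope")
    ax.plot(result.r_grid, result.g_obs, "k-", label="observed g(r)")
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("r (m)")
    ax.set_ylabel("g(r)")
    ax.set_title(f"{result.classification} (extent {result.extent_m:.0f} m)")
    ax.legend()
    return ax


def plot_correlogram(estimator, ax=None):
    """I(c) per distance class; filled markers fall outside the envelope."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    mid = estimator.bins_.midpoints
    i_vals = getattr(estimator, "i_", getattr(estimator, "i12_", None))
    ax.fill_between(mid, estimator.env_lo_, estimator.env_hi_, alpha=0.3)
    ax.plot(mid, i_vals, "-", c="k", lw=0.8)
    sig = estimator.significant_
    ax.plot(mid[~sig], np.asarray(i_vals)[~sig], "o", mfc="white", mec="k")
    ax.plot(mid[sig], np.asarray(i_vals)[sig], "o", c="k")
    ax.axhline(0.0, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("distance class midpoint (m)")
    ax.set_ylabel("Moran's I")
    return ax


def plot_cca_biplot(model, ax=None, n_species_labels: int = 10):
    """Scaling-2 biplot: sites as dots, species as labels, predictors as arrows."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if model.n_constrained_ < 2:
        raise ValueError("biplot needs at least two constrained axes")
    ax.plot(model.wa_site_scores_[:, 0], model.wa_site_scores_[:, 1], ".", c="grey", ms=3)
    order = np.argsort(-np.abs(model.species_scores_[:, :2]).sum(axis=1))
    for j in order[:n_species_labels]:
        ax.annotate(
            model.species_ids_[j],
            model.species_scores_[j, :2],
            fontsize=8,
            ha="center",
        )
    scale = np.abs(model.wa_site_scores_[:, :2]).max()
    for name, vec in zip(model.design_.columns, model.biplot_scores_[:, :2]):
        ax.annotate(
            "",
            xy=vec * scale,
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="tab:blue"),
        )
        ax.annotate(name, vec * scale * 1.05, color="tab:blue", fontsize=8)
    ev = model.eigenvalues_
    tot = model.total_inertia_
    ax.set_xlabel(f"CCA1 ({ev[0] / tot * 100:.1f}%)")
    ax.set_ylabel(f"CCA2 ({ev[1] / tot * 100:.1f}%)")
    return ax
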