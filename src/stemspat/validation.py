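"""Calibration and recovery checks of the estimators against known truth.

These runners exercise the package end to end under controlled conditions -
closed-form oracles for the homogeneous Poisson and Thomas processes,
pointwise envelope calibration on CSR data, and hypothesis-scenario
recovery on synthetic communities - and return the measured quantities.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from ._utils import derive_seed
from .autocorr import MoranCorrelogram
from .datamodel import DistanceBins, TransectWindow
from .io import standardize_dbh_by_species
from .ordination import fit_cca, variance_decomposition
from .pointpattern import CSREnvelope, pcf, ripley_k, simulate_csr_count
from .simulate import gen_community, scenario_template, sim_poisson, sim_thomas

__all__ = [
    "published_densities",
    "csr_k_calibration",
    "thomas_pcf_calibration",
    "envelope_calibration",
    "scenario_recovery",
    "h3_cca_recovery",
]


def published_densities() -> dict:
    """Recompute the survey's density arithmetic from its printed counts.

    2005 subplots x 0.125 ha = 250.625 ha; guild counts over that area give
    trees/ha, and the four guilds' total over all 84678 registered stems
    gives the target share in percent.
    """
    import pandas as pd

    from .pipeline import summarize_guilds

    window = TransectWindow.study_design(8, 6265.625)  # 8 x 31.328 ha
    counts = {"SLP": 834, "LLP": 800, "NPLD": 4694, "STS": 1195}
    stems = pd.DataFrame({"guild": np.repeat(list(counts), list(counts.values()))})
    table = summarize_guilds(stems, window, total_registered=84678)
    dens = dict(zip(table["guild"], table["density_per_ha"]))
    return {
        "area_ha": window.total_area_ha,
        "density_per_ha": dens,
        "target_share_pct": table.attrs["target_share_pct"],
    }


def csr_k_calibration(
    n_sim: int = 200,
    intensity: float = 4.0,
    r_values=(10.0, 25.0, 50.0),
    seed: int = 0,
) -> dict:
    """Mean Ripley K over CSR simulations vs the pi r^2 closed form.

    One 2000 m x 50 m transect; returns the per-r means, Monte-Carlo
    standard errors and z-scores of the deviation from pi r^2.
    """
    window = TransectWindow.study_design(1, 2000.0)
    r = np.asarray(r_values, dtype=float)
    rng = np.random.default_rng(derive_seed(seed, "csr_k"))
    ks = []
    while len(ks) < n_sim:
        pts = sim_poisson(window, intensity, rng)
        if len(pts) >= 2:
            ks.append(ripley_k(pts, window, r))
    ks = np.asarray(ks)
    mean = ks.mean(axis=0)
    se = ks.std(axis=0, ddof=1) / np.sqrt(n_sim)
    return {
        "r": r,
        "k_mean": mean,
        "k_expected": np.pi * r**2,
        "se": se,
        "z": (mean - np.pi * r**2) / se,
        "n_sim": n_sim,
    }


def thomas_pcf_calibration(
    n_sim: int = 200,
    parent_intensity: float = 0.5,
    cluster_sd: float = 20.0,
    mean_offspring: float = 10.0,
    r_values=(10.0, 20.0, 40.0),
    seed: int = 0,
) -> dict:
    """Mean pair-correlation estimate over Thomas simulations vs the process'
    closed form g(r) = 1 + exp(-r^2 / 4 sigma^2) / (4 pi kappa sigma^2)."""
    window = TransectWindow.study_design(1, 2000.0)
    r = np.asarray(r_values, dtype=float)
    rng = np.random.default_rng(derive_seed(seed, "thomas_g"))
    gs = []
    while len(gs) < n_sim:
        pts = sim_thomas(window, parent_intensity, mean_offspring, cluster_sd, rng)
        if len(pts) >= 10:
            gs.append(pcf(pts, window, r))
    gs = np.asarray(gs)
    kappa_m2 = parent_intensity / 1e4
    g_true = 1 + np.exp(-(r**2) / (4 * cluster_sd**2)) / (
        4 * np.pi * kappa_m2 * cluster_sd**2
    )
    mean = gs.mean(axis=0)
    return {
        "r": r,
        "g_mean": mean,
        "g_expected": g_true,
        "rel_err": mean / g_true - 1.0,
        "n_sim": n_sim,
    }


def envelope_calibration(
    n_rep: int = 200,
    n_points: int = 100,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Pointwise exceedance rate of the CSR envelope on CSR data.

    A well calibrated 95% pointwise envelope is left by the observed g(r) at
    ~5% of the scanned distances."""
    window = TransectWindow.study_design(1, 1000.0)
    r_grid = np.arange(10.0, 210.0, 10.0)
    rng = np.random.default_rng(derive_seed(seed, "env_cal"))
    outside = total = 0
    for _ in range(n_rep):
        pts = simulate_csr_count(window, n_points, rng)
        est = CSREnvelope(
            window,
            r_grid=r_grid,
            n_sim=n_sim,
            alpha=alpha,
            random_state=int(rng.integers(2**31)),
        ).fit(pts)
        outside += int(((est.g_obs_ > est.g_hi_) | (est.g_obs_ < est.g_lo_)).sum())
        total += len(r_grid)
    return {"exceedance_pct": 100.0 * outside / total, "n_rep": n_rep}


def scenario_recovery(
    name: str,
    n_seeds: int = 50,
    n_sim: int = 100,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Classify the pooled pioneer guild of h1/h2 communities and test its
    short-range diameter autocorrelation, over independent seeds.

    Success for "h1": pattern aggregated AND first-class Moran I above the
    permutation envelope (the disturbance-cohort signature).  Success for
    "h2": pattern random AND first-class I inside the envelope.
    """
    cfg = scenario_template(name)
    window = cfg.window
    r_grid = np.arange(10.0, 260.0, 10.0)
    bins = DistanceBins(np.arange(0.0, 1100.0, 100.0))
    hits = 0
    labels = []
    for s in range(n_seeds):
        stems, _, _ = gen_community(cfg, derive_seed(seed, name, "sim", s))
        std = standardize_dbh_by_species(stems)
        slp = std[std["guild"] == "SLP"]
        pts = window.to_global(slp)
        env = CSREnvelope(
            window,
            r_grid=r_grid,
            n_sim=n_sim,
            random_state=derive_seed(seed, name, "pcf", s),
        ).fit(pts)
        cor = MoranCorrelogram(
            bins=bins,
            n_perm=n_perm,
            mantel=False,
            random_state=derive_seed(seed, name, "moran", s),
        ).fit(pts, slp["mark"].to_numpy())
        sig_short = bool(cor.i_[0] > cor.env_hi_[0])
        labels.append((env.classification_, sig_short))
        if name == "h1":
            hits += env.classification_ == "aggregated" and sig_short
        else:
            hits += env.classification_ == "random" and not sig_short
    return {
        "success_rate_pct": 100.0 * hits / n_seeds,
        "n_seeds": n_seeds,
        "labels": labels,
    }


def h3_cca_recovery(n_seeds: int = 50, seed: int = 0) -> dict:
    """Fraction of h3 communities whose species-level CCA attributes the
    largest single-variable share to distance-to-water (the generating
    gradient of the reference species)."""
    from .io import filter_species, tabulate_abundance

    cfg = scenario_template("h3")
    hits = 0
    for s in range(n_seeds):
        stems, subplots, _ = gen_community(cfg, derive_seed(seed, "h3", "sim", s))
        filtered, _ = filter_species(stems, 50)
        Y = tabulate_abundance(filtered, subplots, by="species")
        X = subplots.set_index("subplot_id")[
            ["slope_pct", "dist_water_m", "altitude_m", "topography"]
        ].loc[Y.index]
        model = fit_cca(Y, X)
        shares = variance_decomposition(model)
        top = shares.loc[shares["chi_square"].idxmax(), "term"]
        hits += top == "dist_water_m"
    return {"water_top_share_pct": 100.0 * hits / n_seeds, "n_seeds": n_seeds}
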