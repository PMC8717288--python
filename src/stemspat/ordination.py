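"""Canonical correspondence analysis (CCA) with permutation inference.

CCA relates a site x species abundance table Y to site-level environmental
predictors X.  The chi-square standardized abundance matrix

    Qbar = D_r^{-1/2} (P - r c^T) D_c^{-1/2},   P = Y / y_tot

(r, c the row/column mass vectors) carries the total inertia of a
correspondence analysis; CCA decomposes it into the part lying in the span
of the row-weighted, weighted-centred predictors (constrained inertia,
eigen-decomposed into canonical axes) and a residual (unconstrained) part.
Constrained + unconstrained inertia equals the CA total by construction.

Significance of the model, of individual axes and of the marginal effect of
each predictor uses permutation pseudo-F tests; model search uses backward
elimination under a deviance-style AIC analog

    AIC = n ln(residual inertia / n) + 2 (1 + rank of constraints),

exposed with its full elimination trace so the search can be audited (there
is no canonical AIC for CCA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import check_random_state

logger = logging.getLogger("stemspat")

__all__ = [
    "EnvDesign",
    "CanonicalCorrespondenceAnalysis",
    "fit_cca",
    "anova_cca",
    "backward_select",
    "variance_decomposition",
    "compare_with_without",
]

_RANK_TOL = 1e-9


@dataclass
class EnvDesign:
    """Environmental predictors expanded to a numeric design matrix.

    Numeric columns map to one term each; string/categorical columns to
    indicator contrasts with a reference level ("flat" when present, else
    the first sorted level), so a 4-level topography factor carries df = 3.
    """

    env: pd.DataFrame
    terms: list = field(init=False)
    matrix: np.ndarray = field(init=False)
    columns: list = field(init=False)
    term_columns: dict = field(init=False)

    def __post_init__(self):
        env = self.env
        if not isinstance(env, pd.DataFrame):
            env = pd.DataFrame(
                np.atleast_2d(np.asarray(env, dtype=float)),
            )
            env.columns = [f"x{j}" for j in range(env.shape[1])]
        self.env = env.reset_index(drop=True)
        cols, names, term_cols, terms = [], [], {}, []
        for name in self.env.columns:
            col = self.env[name]
            terms.append(str(name))
            if pd.api.types.is_numeric_dtype(col):
                term_cols[str(name)] = [len(names)]
                names.append(str(name))
                cols.append(col.to_numpy(dtype=float))
            else:
                levels = sorted(col.astype(str).unique())
                ref = "flat" if "flat" in levels else levels[0]
                idxs = []
                for lev in levels:
                    if lev == ref:
                        continue
                    idxs.append(len(names))
                    names.append(f"{name}[{lev}]")
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                term_cols[str(name)] = idxs
        self.terms = terms
        self.columns = names
        self.term_columns = term_cols
        self.matrix = (
            np.column_stack(cols) if cols else np.empty((len(self.env), 0))
        )

    def drop(self, term: str) -> "EnvDesign":
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        return EnvDesign(self.env.drop(columns=[term]))

    def subset_rows(self, keep: np.ndarray) -> "EnvDesign":
        return EnvDesign(self.env.loc[keep].reset_index(drop=True))


def _chi_square_decomposition(Y: np.ndarray):
    """Row/column masses and the standardized matrix Qbar of a count table."""
    tot = Y.sum()
    if tot <= 0:
        raise ValueError("abundance table has zero grand total")
    P = Y / tot
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return r, c, Qbar


def _weighted_design(X: np.ndarray, r: np.ndarray):
    """Row-weighted, weighted-centred design and its orthonormal column basis."""
    wmean = r @ X
    Xw = np.sqrt(r)[:, None] * (X - wmean)
    if Xw.shape[1] == 0:
        return Xw, np.empty((len(r), 0)), wmean
    U, s, _ = np.linalg.svd(Xw, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(s[0], 1.0))) if len(s) else 0
    return Xw, U[:, :rank], wmean


def _constrained_inertia(Qbar: np.ndarray, U: np.ndarray) -> float:
    return float(np.sum((U.T @ Qbar) ** 2))


class CanonicalCorrespondenceAnalysis(BaseEstimator):
    """CCA of an abundance table on environmental predictors.

    ``fit(X, Y)`` takes X as a DataFrame of predictors (categoricals are
    expanded automatically), an array, or a prebuilt :class:`EnvDesign`, and
    Y as the site x species abundance table (DataFrame or array).  Sites
    with zero total abundance are dropped (count logged in
    ``n_dropped_sites_``), as are all-zero species columns.

    Attributes
    ----------
    eigenvalues_ : constrained then unconstrained eigenvalues (descending
        within each block); ``n_constrained_`` marks the split
    total_inertia_, constrained_inertia_, unconstrained_inertia_ : floats
    proportion_constrained_ : constrained / total, in [0, 1]
    site_scores_ : linear-combination site scores (scaling 1)
    wa_site_scores_ : weighted-average site scores
    species_scores_ : species scores scaled by the axis eigenvalue (scaling 2)
    biplot_scores_ : correlations of the predictors with the axes
    """

    def __init__(self, scaling: int = 2):
        self.scaling = scaling

    def fit(self, X, Y):
        design = X if isinstance(X, EnvDesign) else EnvDesign(
            X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.atleast_2d(np.asarray(X, float)))
        )
        Yf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, dtype=float))
        Yv = Yf.to_numpy(dtype=float)
        if np.any(Yv < 0):
            raise ValueError("abundances must be non-negative")
        if len(Yv) != len(design.env):
            raise ValueError("X and Y must describe the same sites")

        keep_rows = Yv.sum(axis=1) > 0
        self.n_dropped_sites_ = int((~keep_rows).sum())
        if self.n_dropped_sites_:
            logger.info("dropped %d all-zero sites from CCA", self.n_dropped_sites_)
        keep_cols = Yv[keep_rows].sum(axis=0) > 0
        self.dropped_species_ = [
            str(s) for s in np.asarray(Yf.columns)[~keep_cols]
        ]
        if self.dropped_species_:
            logger.info("dropped all-zero species: %s", self.dropped_species_)
        Yv = Yv[np.ix_(keep_rows, keep_cols)]
        design = design.subset_rows(keep_rows)

        r, c, Qbar = _chi_square_decomposition(Yv)
        Xmat = design.matrix
        Xw, U, wmean = _weighted_design(Xmat, r)
        rank = U.shape[1]
        if 0 < rank < Xmat.shape[1]:
            warnings.warn(
                "collinear predictors: projecting onto the span (least-norm fit)",
                stacklevel=2,
            )

        Qhat = U @ (U.T @ Qbar)
        resid = Qbar - Qhat
        Uc, sc, Vct = np.linalg.svd(Qhat, full_matrices=False)
        n_axes = int(np.sum(sc**2 > 1e-12 * max(sc[0] ** 2, 1.0))) if len(sc) else 0
        Ur, sr, Vrt = np.linalg.svd(resid, full_matrices=False)
        n_res = int(np.sum(sr**2 > 1e-12 * max(sr[0] ** 2 if len(sr) else 1.0, 1.0)))

        ev_c = sc[:n_axes] ** 2
        ev_r = sr[:n_res] ** 2
        self.total_inertia_ = float(np.sum(Qbar**2))
        self.constrained_inertia_ = float(np.sum(Qhat**2))
        self.unconstrained_inertia_ = float(np.sum(resid**2))
        self.proportion_constrained_ = (
            self.constrained_inertia_ / self.total_inertia_ if self.total_inertia_ else 0.0
        )
        self.eigenvalues_ = np.concatenate([ev_c, ev_r])
        self.n_constrained_ = n_axes
        self.rank_ = rank

        # scores (constrained axes only)
        Uk, sk, Vk = Uc[:, :n_axes], sc[:n_axes], Vct[:n_axes].T
        with np.errstate(divide="ignore", invalid="ignore"):
            self.site_scores_ = Uk / np.sqrt(r)[:, None]
            self.species_scores_ = (Vk * sk) / np.sqrt(c)[:, None]
            self.wa_site_scores_ = (Qbar @ Vk) / np.sqrt(r)[:, None]
        # correlation of weighted predictors with the axes
        denom = np.linalg.norm(Xw, axis=0)
        denom[denom == 0] = 1.0
        self.biplot_scores_ = (Xw / denom).T @ Uk

        self.site_ids_ = list(np.asarray(Yf.index)[keep_rows])
        self.species_ids_ = [str(s) for s in np.asarray(Yf.columns)[keep_cols]]
        self.Y_ = pd.DataFrame(Yv, index=self.site_ids_, columns=self.species_ids_)
        self.design_ = design
        self.row_weights_ = r
        self.col_weights_ = c
        self._Qbar = Qbar
        self._U_basis = U
        self._wmean = wmean
        self.n_sites_ = len(Yv)
        return self

    # ---- derived quantities -------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Linear-combination site scores for (new) predictor rows."""
        design = X if isinstance(X, EnvDesign) else EnvDesign(
            X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.atleast_2d(np.asarray(X, float)))
        )
        if design.columns != self.design_.columns:
            raise ValueError("predictor columns do not match the fitted design")
        Xc = design.matrix - self._wmean
        Xw_fit = np.sqrt(self.row_weights_)[:, None] * (
            self.design_.matrix - self._wmean
        )
        B, *_ = np.linalg.lstsq(Xw_fit, self._Qbar, rcond=None)
        Qhat = Xw_fit @ B
        _, sc, Vct = np.linalg.svd(Qhat, full_matrices=False)
        k = self.n_constrained_
        with np.errstate(divide="ignore", invalid="ignore"):
            axes = B @ Vct[:k].T / sc[:k]
        return Xc @ axes

    def summary(self) -> dict:
        return {
            "total_inertia": self.total_inertia_,
            "constrained_inertia": self.constrained_inertia_,
            "unconstrained_inertia": self.unconstrained_inertia_,
            "proportion_constrained": self.proportion_constrained_,
            "eigenvalues_constrained": self.eigenvalues_[: self.n_constrained_].tolist(),
            "rank": self.rank_,
            "n_sites": self.n_sites_,
            "n_species": len(self.species_ids_),
            "dropped_sites": self.n_dropped_sites_,
            "dropped_species": self.dropped_species_,
        }


def fit_cca(Y, X, scaling: int = 2) -> CanonicalCorrespondenceAnalysis:
    """Fit a CCA of abundance table Y on predictors X (response first,
    mirroring the formula notation abundance ~ environment)."""
    return CanonicalCorrespondenceAnalysis(scaling=scaling).fit(X, Y)


def _refit_inertia(model: CanonicalCorrespondenceAnalysis, design: EnvDesign):
    """Constrained inertia and rank of an alternative design on the fitted Y."""
    _, U, _ = _weighted_design(design.matrix, model.row_weights_)
    return _constrained_inertia(model._Qbar, U), U.shape[1]


def anova_cca(
    model: CanonicalCorrespondenceAnalysis,
    n_perm: int = 999,
    seed=None,
    scope: str = "model",
) -> pd.DataFrame:
    """Permutation pseudo-F tests for a fitted CCA.

    scope="model"  : overall test; rows of the predictor table are permuted.
    scope="axes"   : each constrained axis, against eigenvalues of models
                     refitted on row-permuted predictors (simultaneous, not
                     conditional on earlier axes).
    scope="margin" : marginal effect of each term; the term is removed, the
                     reduced-model residuals are permuted across sites and
                     the full model refitted (residual-permutation scheme).

    p = (1 + exceedances) / (1 + n_perm).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value", stacklevel=2)
    rng = check_random_state(seed)
    Qbar = model._Qbar
    r = model.row_weights_
    design = model.design_
    n = model.n_sites_
    ci_full, q = _refit_inertia(model, design)
    ti = model.total_inertia_
    df_res = n - 1 - q
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    ri_full = ti - ci_full

    rows = []
    if scope == "model":
        f_obs = (ci_full / q) / (ri_full / df_res)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dperm = EnvDesign(design.env.iloc[perm].reset_index(drop=True))
            ci_p, q_p = _refit_inertia(model, dperm)
            f_p = (ci_p / max(q_p, 1)) / ((ti - ci_p) / df_res)
            exceed += f_p >= f_obs
        rows.append(
            ("Model", q, ci_full, f_obs, (1 + exceed) / (1 + n_perm))
        )
    elif scope == "axes":
        ev = model.eigenvalues_[: model.n_constrained_]
        f_obs = ev / (ri_full / df_res)
        exceed = np.zeros(len(ev))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dperm = EnvDesign(design.env.iloc[perm].reset_index(drop=True))
            _, U = _weighted_design(dperm.matrix, r)[:2]
            sv = np.linalg.svd(U @ (U.T @ Qbar), compute_uv=False)
            ev_p = np.zeros(len(ev))
            take = min(len(ev), len(sv))
            ev_p[:take] = sv[:take] ** 2
            ci_p = float(np.sum(sv**2))
            f_p = ev_p / ((ti - ci_p) / df_res)
            exceed += f_p >= f_obs
        for k, (e, f, x) in enumerate(zip(ev, f_obs, exceed), start=1):
            rows.append((f"CCA{k}", 1, float(e), float(f), (1 + x) / (1 + n_perm)))
    elif scope == "margin":
        for term in design.terms:
            reduced = design.drop(term)
            _, U_red, _ = _weighted_design(reduced.matrix, r)
            ci_red = _constrained_inertia(Qbar, U_red)
            df_t = q - U_red.shape[1]
            if df_t == 0:
                rows.append((term, 0, 0.0, np.nan, np.nan))
                continue
            chi_t = ci_full - ci_red
            f_obs = (chi_t / df_t) / (ri_full / df_res)
            Qhat_red = U_red @ (U_red.T @ Qbar)
            resid_red = Qbar - Qhat_red
            _, U_full, _ = _weighted_design(design.matrix, r)
            exceed = 0
            for _ in range(n_perm):
                Qp = Qhat_red + resid_red[rng.permutation(n)]
                ci_f = _constrained_inertia(Qp, U_full)
                ci_r = _constrained_inertia(Qp, U_red)
                ti_p = float(np.sum(Qp**2))
                f_p = ((ci_f - ci_r) / df_t) / ((ti_p - ci_f) / df_res)
                exceed += f_p >= f_obs
            rows.append((term, df_t, chi_t, f_obs, (1 + exceed) / (1 + n_perm)))
    else:
        raise ValueError("scope must be 'model', 'axes' or 'margin'")

    return pd.DataFrame(rows, columns=["term", "df", "chi_square", "pseudo_F", "p_perm"])


def backward_select(
    Y, X, criterion: str = "aic"
) -> tuple[CanonicalCorrespondenceAnalysis, pd.DataFrame]:
    """Backward elimination of predictor terms by the AIC analog.

    At each step the term whose removal lowers the criterion most is
    dropped; stops when no removal improves it.  May return the
    intercept-only (unconstrained) model.  Returns the fitted final model
    and the elimination trace.
    """
    if criterion != "aic":
        raise ValueError("only the 'aic' criterion is implemented")
    model = fit_cca(Y, X)
    design = model.design_
    n = model.n_sites_

    def aic_of(d: EnvDesign) -> float:
        ci, rank = _refit_inertia(model, d)
        ri = model.total_inertia_ - ci
        return n * np.log(max(ri, 1e-300) / n) + 2.0 * (1 + rank)

    trace = [("<full>", aic_of(design), list(design.terms))]
    while design.terms:
        current = trace[-1][1]
        candidates = [(aic_of(design.drop(t)), t) for t in design.terms]
        best_aic, best_term = min(candidates)
        if best_aic < current:
            design = design.drop(best_term)
            trace.append((f"- {best_term}", best_aic, list(design.terms)))
        else:
            break
    # refit on the zero-row-filtered table the criterion was evaluated on
    final = fit_cca(model.Y_, design)
    trace_df = pd.DataFrame(trace, columns=["step", "aic", "terms"])
    return final, trace_df


def variance_decomposition(model: CanonicalCorrespondenceAnalysis) -> pd.DataFrame:
    """Marginal chi-square of each term and its share of constrained inertia.

    Shares are reported raw (they need not sum to 100% when predictors are
    correlated) and normalized to sum to 100%.
    """
    design = model.design_
    ci_full, _ = _refit_inertia(model, design)
    rows = []
    for term in design.terms:
        ci_red, _ = _refit_inertia(model, design.drop(term))
        rows.append((term, ci_full - ci_red))
    out = pd.DataFrame(rows, columns=["term", "chi_square"])
    if ci_full > 0:
        out["share_pct"] = out["chi_square"] / ci_full * 100.0
    else:
        out["share_pct"] = 0.0
    total = out["chi_square"].sum()
    out["share_normalized_pct"] = (
        out["chi_square"] / total * 100.0 if total > 0 else 0.0
    )
    return out


def compare_with_without(Y, X, focal: str) -> dict:
    """Fit the CCA with and without a focal species column.

    Mirrors the reference-species comparison: removing a species that drives
    the environment-abundance association deflates the constrained
    proportion.
    """
    Yf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, dtype=float))
    if focal not in map(str, Yf.columns):
        raise KeyError(f"focal species {focal!r} not in the abundance table")
    with_f = fit_cca(Yf, X)
    without = fit_cca(Yf.drop(columns=[focal]), X)
    return {
        "with": with_f,
        "without": without,
        "proportion_with": with_f.proportion_constrained_,
        "proportion_without": without.proportion_constrained_,
        "delta_proportion": with_f.proportion_constrained_
        - without.proportion_constrained_,
    }
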