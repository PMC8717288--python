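"""Distance-class Moran correlograms of stem diameter and Mantel tests.

Moran's I in distance class c measures whether trees separated by a
distance in (c_lo, c_hi] have more similar dbh than randomly paired trees:

    I(c) = [N / sum w_ij] * sum_{i != j} w_ij (m_i - mbar)(m_j - mbar)
                                       / sum_i (m_i - mbar)^2

with w_ij = 1 iff d_ij falls in class c.  Its randomization expectation is
-1/(N-1).  The intertype variant correlates the diameters of two different
species, each standardized by its own mean and (maximum-likelihood)
standard deviation:

    I12(c) = sum_i sum_j w_ij (m1_i - mbar1)(m2_j - mbar2)
             / (sigma1 sigma2 sum w_ij)

With the ML divisor the intertype statistic of a species against an exact
copy of itself collapses to the within-species I(c) on every class.
Significance comes from random mark permutations over fixed locations, and
from a Mantel test between the pairwise mark-product and log-distance
matrices.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from ._utils import check_random_state, envelope_quantiles
from .datamodel import DistanceBins

logger = logging.getLogger("stemspat")

__all__ = [
    "MoranCorrelogram",
    "IntertypeMoran",
    "moran_correlogram",
    "intertype_moran",
    "mark_permutation_envelope",
    "mantel_test",
    "dbh_mantel",
    "LOW_SUPPORT_PAIRS",
]

#: classes with fewer ordered pairs than this are flagged low-support
LOW_SUPPORT_PAIRS = 30


def _pair_class_index(
    points1: np.ndarray, points2: np.ndarray, bins: DistanceBins
) -> np.ndarray:
    """Distance-class index matrix (n1, n2); -1 = no class (incl. d = 0)."""
    p1 = np.atleast_2d(np.asarray(points1, dtype=float))
    p2 = np.atleast_2d(np.asarray(points2, dtype=float))
    d = np.hypot(
        p1[:, 0][:, None] - p2[None, :, 0], p1[:, 1][:, None] - p2[None, :, 1]
    )
    return bins.assign(d)


def _class_sums(cls_flat: np.ndarray, weights: np.ndarray, n_classes: int):
    """Per-class sums of pair weights; class -1 collected into a spill slot."""
    return np.bincount(cls_flat + 1, weights=weights, minlength=n_classes + 1)[1:]


def moran_correlogram(
    points: np.ndarray, marks: np.ndarray, bins: DistanceBins
) -> tuple[np.ndarray, np.ndarray]:
    """Moran's I per distance class and ordered pair counts.

    Classes without pairs return NaN (missing, not zero).  Raises on fewer
    than 3 points or zero mark variance.
    """
    marks = np.asarray(marks, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("Moran's I needs at least 2 points")
    z = marks - marks.mean()
    denom = float(np.sum(z**2))
    if denom == 0.0:
        raise ValueError("marks have zero variance; Moran's I is undefined")
    cls = _pair_class_index(pts, pts, bins)
    np.fill_diagonal(cls, -1)
    flat = cls.ravel()
    n_pairs = _class_sums(flat, np.ones_like(flat, dtype=float), bins.n_classes)
    cross = _class_sums(flat, np.outer(z, z).ravel(), bins.n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        i_vals = len(pts) / n_pairs * cross / denom
    i_vals[n_pairs == 0] = np.nan
    if np.any(n_pairs == 0):
        warnings.warn("distance classes without pairs reported as missing", stacklevel=2)
    return i_vals, n_pairs.astype(int)


def intertype_moran(
    points1: np.ndarray,
    marks1: np.ndarray,
    points2: np.ndarray,
    marks2: np.ndarray,
    bins: DistanceBins,
) -> tuple[np.ndarray, np.ndarray]:
    """Intertype Moran's I12 per distance class and cross-pair counts.

    Sums run over ordered cross pairs (i from species 1, j from species 2);
    sigma uses the divisor-N form.  Symmetric in the two species.
    """
    m1 = np.asarray(marks1, dtype=float)
    m2 = np.asarray(marks2, dtype=float)
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("each species needs at least 2 stems")
    z1 = m1 - m1.mean()
    z2 = m2 - m2.mean()
    s1 = float(np.sqrt(np.mean(z1**2)))
    s2 = float(np.sqrt(np.mean(z2**2)))
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("a species has zero dbh variance; I12 is undefined")
    cls = _pair_class_index(points1, points2, bins)
    flat = cls.ravel()
    n_pairs = _class_sums(flat, np.ones_like(flat, dtype=float), bins.n_classes)
    cross = _class_sums(flat, np.outer(z1, z2).ravel(), bins.n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        i12 = cross / (s1 * s2 * n_pairs)
    i12[n_pairs == 0] = np.nan
    return i12, n_pairs.astype(int)


def mark_permutation_envelope(
    points: np.ndarray,
    marks: np.ndarray,
    bins: DistanceBins,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise null envelope of I(c) from random mark permutations."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = check_random_state(seed)
    marks = np.asarray(marks, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    z = marks - marks.mean()
    denom = float(np.sum(z**2))
    cls = _pair_class_index(pts, pts, bins)
    np.fill_diagonal(cls, -1)
    flat = cls.ravel()
    n_pairs = _class_sums(flat, np.ones_like(flat, dtype=float), bins.n_classes)
    sims = np.empty((n_perm, bins.n_classes))
    for s in range(n_perm):
        zp = z[rng.permutation(n)]
        cross = _class_sums(flat, np.outer(zp, zp).ravel(), bins.n_classes)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims[s] = n / n_pairs * cross / denom
    sims[:, n_pairs == 0] = np.nan
    lo, hi = envelope_quantiles(sims, alpha)
    return lo, hi


class MoranCorrelogram(BaseEstimator):
    """Moran's I correlogram of a stem mark with permutation envelopes.

    Parameters
    ----------
    bins : DistanceBins or None
        Distance classes; the study default is (0,100], ..., (3900,4000] m.
    n_perm : int
        Mark permutations for the envelope and the Mantel test.
    alpha : float
        Two-sided pointwise envelope level.
    mantel : bool
        Also run the Mantel test between the pairwise standardized
        mark-product matrix and ln(distance).
    random_state : int, Generator or None

    Attributes
    ----------
    i_ : array of I(c) per class (NaN where the class has no pairs)
    n_pairs_ : ordered pair counts per class
    env_lo_, env_hi_ : permutation envelope
    significant_ : boolean array, I outside the envelope
    low_support_ : boolean array, fewer than 30 pairs in the class
    mantel_r_, mantel_p_ : Mantel statistics (if ``mantel``)
    """

    def __init__(
        self,
        bins: DistanceBins | None = None,
        n_perm: int = 999,
        alpha: float = 0.05,
        mantel: bool = True,
        random_state=None,
    ):
        self.bins = bins
        self.n_perm = n_perm
        self.alpha = alpha
        self.mantel = mantel
        self.random_state = random_state

    def fit(self, X, y):
        bins = self.bins if self.bins is not None else DistanceBins.study_default()
        pts = np.atleast_2d(np.asarray(X, dtype=float))
        marks = np.asarray(y, dtype=float)
        rng = check_random_state(self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.i_, self.n_pairs_ = moran_correlogram(pts, marks, bins)
        seed_env = int(rng.integers(2**31))
        seed_man = int(rng.integers(2**31))
        self.env_lo_, self.env_hi_ = mark_permutation_envelope(
            pts, marks, bins, n_perm=self.n_perm, alpha=self.alpha, seed=seed_env
        )
        with np.errstate(invalid="ignore"):
            self.significant_ = (self.i_ > self.env_hi_) | (self.i_ < self.env_lo_)
        self.significant_ &= ~np.isnan(self.i_)
        self.low_support_ = self.n_pairs_ < LOW_SUPPORT_PAIRS
        self.bins_ = bins
        if self.mantel:
            self.mantel_r_, self.mantel_p_ = dbh_mantel(
                pts, marks, n_perm=self.n_perm, seed=seed_man
            )
        return self


class IntertypeMoran(BaseEstimator):
    """Intertype Moran correlogram between two species' dbh values.

    ``fit(X, y, X2, y2)`` takes each species' coordinates and marks; the
    permutation envelope permutes each species' marks independently.
    """

    def __init__(
        self,
        bins: DistanceBins | None = None,
        n_perm: int = 999,
        alpha: float = 0.05,
        random_state=None,
    ):
        self.bins = bins
        self.n_perm = n_perm
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y, X2=None, y2=None):
        if X2 is None or y2 is None:
            raise ValueError("intertype analysis needs both species: fit(X, y, X2, y2)")
        bins = self.bins if self.bins is not None else DistanceBins.study_default()
        p1 = np.atleast_2d(np.asarray(X, dtype=float))
        p2 = np.atleast_2d(np.asarray(X2, dtype=float))
        m1 = np.asarray(y, dtype=float)
        m2 = np.asarray(y2, dtype=float)
        rng = check_random_state(self.random_state)
        self.i12_, self.n_pairs_ = intertype_moran(p1, m1, p2, m2, bins)

        z1 = m1 - m1.mean()
        z2 = m2 - m2.mean()
        s1 = np.sqrt(np.mean(z1**2))
        s2 = np.sqrt(np.mean(z2**2))
        cls = _pair_class_index(p1, p2, bins)
        flat = cls.ravel()
        ones = np.ones_like(flat, dtype=float)
        n_pairs = _class_sums(flat, ones, bins.n_classes)
        sims = np.empty((self.n_perm, bins.n_classes))
        for s in range(self.n_perm):
            zp1 = z1[rng.permutation(len(z1))]
            zp2 = z2[rng.permutation(len(z2))]
            cross = _class_sums(flat, np.outer(zp1, zp2).ravel(), bins.n_classes)
            with np.errstate(invalid="ignore", divide="ignore"):
                sims[s] = cross / (s1 * s2 * n_pairs)
        sims[:, n_pairs == 0] = np.nan
        self.env_lo_, self.env_hi_ = envelope_quantiles(sims, self.alpha)
        with np.errstate(invalid="ignore"):
            self.significant_ = (self.i12_ > self.env_hi_) | (self.i12_ < self.env_lo_)
        self.significant_ &= ~np.isnan(self.i12_)
        self.low_support_ = self.n_pairs_ < LOW_SUPPORT_PAIRS
        self.bins_ = bins
        return self


def mantel_test(
    A: np.ndarray, B: np.ndarray, n_perm: int = 999, seed=None
) -> tuple[float, float]:
    """Mantel permutation test between two square symmetric matrices.

    r is the Pearson correlation of the strictly-upper-triangle entries;
    the p-value permutes rows and columns of B jointly and is two-sided on
    |r|: p = (1 + #{|r*| >= |r|}) / (1 + n_perm).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    a = a - a.mean()
    sa = np.sqrt(np.sum(a**2))
    b = B[iu]
    sb = np.sqrt(np.sum((b - b.mean()) ** 2))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("constant matrix: Mantel correlation undefined")

    def corr_with(Bp: np.ndarray) -> float:
        bv = Bp[iu]
        bv = bv - bv.mean()
        return float(np.dot(a, bv) / (sa * np.sqrt(np.sum(bv**2))))

    r_obs = corr_with(B)
    rng = check_random_state(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if abs(corr_with(B[np.ix_(idx, idx)])) >= abs(r_obs) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return r_obs, p


def dbh_mantel(
    points: np.ndarray, marks: np.ndarray, n_perm: int = 999, seed=None
) -> tuple[float, float]:
    """Mantel test between pairwise mark products and log distances.

    Builds A_ij = z_i z_j with z the standardized marks and B_ij = ln(d_ij);
    a negative r means mark similarity decays with distance (the cohort
    signature).  Coincident points get d = 0.5 m before the log, with a
    warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    marks = np.asarray(marks, dtype=float)
    if len(pts) < 4:
        raise ValueError("the Mantel test needs at least 4 points")
    z = marks - marks.mean()
    s = np.sqrt(np.mean(z**2))
    if s == 0.0:
        raise ValueError("marks have zero variance")
    z = z / s
    d = np.hypot(
        pts[:, 0][:, None] - pts[None, :, 0], pts[:, 1][:, None] - pts[None, :, 1]
    )
    off_diag_zero = (d == 0).sum() - len(pts)
    if off_diag_zero > 0:
        warnings.warn(
            f"{off_diag_zero // 2} coincident pairs; using d = 0.5 m before the log",
            stacklevel=2,
        )
        d = np.where(d == 0, 0.5, d)
    np.fill_diagonal(d, 1.0)  # diagonal is ignored by the upper-triangle test
    return mantel_test(np.outer(z, z), np.log(d), n_perm=n_perm, seed=seed)
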