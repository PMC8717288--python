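"""Shared helpers: seed derivation and envelope quantiles."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "envelope_quantiles", "check_random_state"]


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stable sub-seed < 2**31 from a master seed and context tokens.

    Hashing (seed, stage, unit) keeps each analysis unit's random stream
    independent of how many other units a run contains.
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def check_random_state(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def envelope_quantiles(sims: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise (alpha/2, 1-alpha/2) bounds from Monte-Carlo simulations.

    Uses the Weibull plotting position so a new draw from the null falls
    outside the envelope with probability ~alpha even at modest n_sim;
    sims has shape (n_sim, n_grid).
    """
    lo = np.quantile(sims, alpha / 2.0, axis=0, method="weibull")
    hi = np.quantile(sims, 1.0 - alpha / 2.0, axis=0, method="weibull")
    return lo, hi
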