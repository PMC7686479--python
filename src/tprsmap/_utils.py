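"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def rng_for(seed, *stream: int) -> np.random.Generator:
    """Deterministic generator for a (seed, stream...) pair.

    A fixed integer stream id per operation keeps sub-streams independent
    while remaining reproducible from a single master seed.
    """
    if seed is None:
        return np.random.default_rng()
    if isinstance(seed, (list, tuple)):
        key = [int(s) & 0x7FFFFFFF for s in seed]
    else:
        key = [int(seed) & 0x7FFFFFFF]
    return np.random.default_rng([*key, *stream])


def zscore_columns(x: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-scores; constant columns become all-zero.

    Returns (z, constant_mask).
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (x - mu) / sd_safe
    z[:, constant] = 0.0
    return z, constant


def zscore_vector(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace NaN entries with the per-column mean (column of all NaN -> 0)."""
    d = np.array(dosages, dtype=float)
    if not np.isnan(d).any():
        return d
    col_mean = np.nanmean(np.where(np.isnan(d).all(axis=0), 0.0, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


def batch_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve many small OLS problems at once.

    X: (B, n, p) stacked design matrices; y: (B, n). Returns (B, p)
    coefficients via the normal equations (designs here are tiny and
    well conditioned after standardization).
    """
    G = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(G, Xty[..., None])[..., 0]
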