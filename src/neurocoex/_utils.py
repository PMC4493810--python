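"""Shared helpers: seeding, validation, small numerics."""

from __future__ import annotations

import numpy as np


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Split a root seed into *n* independent generators.

    All randomness in a pipeline run flows from one root seed through
    ``numpy.random.SeedSequence.spawn``, so stages are independent and the
    whole run is reproducible from the root seed alone.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def check_proportion(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)


def offdiag(mat: np.ndarray) -> np.ndarray:
    """Flattened strictly-upper-triangular entries of a square matrix."""
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with guards for zero-variance rows.

    Constant rows get correlation 0 with everything (and 1 on the
    diagonal) instead of NaN, so downstream adjacency stays in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1)
    good = sd > 0
    denom = np.where(good, sd, 1.0)
    xs = xc / denom[:, None]
    r = xs @ xs.T / x.shape[1]
    r[~good, :] = 0.0
    r[:, ~good] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
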