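"""Modular Single-set Enrichment Test (MSET).

Permutation over-representation of a query gene set in each reference
module: the observed overlap O = |query & module| is compared with the
overlaps of random gene sets of the same effective size (|query &
background|) drawn uniformly without replacement from the array background.
The p-value counts the simulated sets with an overlap at least as large:

    p = (1 + #{draws with overlap >= O}) / (n_sim + 1)

The plus-one numerator/denominator keeps p strictly positive; genes of the
query absent from the background cannot be drawn and are dropped before
sizing, so the null draws match what the array could have produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MSETResult:
    module_id: str
    module_size: int
    overlap: int
    n_sim: int
    p_perm: float
    enriched: bool


def _prepare(query: set, background) -> tuple[list[str], set]:
    background = list(dict.fromkeys(background))
    bg_set = set(background)
    query = set(query)
    outside = query - bg_set
    if outside:
        warnings.warn(
            f"{len(outside)} query genes absent from the background were dropped"
        )
    return background, query & bg_set


def mset_scan(
    query: set,
    modules: dict[str, list[str]],
    background,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[MSETResult]:
    """MSET over a module collection, sharing the simulated draws.

    One set of ``n_sim`` random query-sized draws is scored against every
    module (statistically equivalent to independent draws per module, since
    each module's p depends only on the marginal overlap distribution).
    Modules are restricted to the background before sizing; a module with
    no background member raises.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    background, query = _prepare(query, background)
    n_bg = len(background)
    q = len(query)
    index = {g: i for i, g in enumerate(background)}

    module_masks = {}
    for module_id, members in modules.items():
        idx = [index[g] for g in set(members) if g in index]
        if not idx:
            raise ValueError(f"module {module_id!r} has no genes in the background")
        mask = np.zeros(n_bg, dtype=bool)
        mask[idx] = True
        module_masks[module_id] = mask

    query_mask = np.zeros(n_bg, dtype=bool)
    query_mask[[index[g] for g in query]] = True

    module_ids = list(module_masks)
    mask_matrix = np.stack([module_masks[m] for m in module_ids]).astype(np.int64)
    observed = (mask_matrix @ query_mask.astype(np.int64)).astype(int)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(module_ids), dtype=np.int64)
    if q > 0:
        for _ in range(n_sim):
            draw = rng.choice(n_bg, size=q, replace=False)
            exceed += mask_matrix[:, draw].sum(axis=1) >= observed
    else:
        exceed[:] = n_sim

    results = []
    for i, module_id in enumerate(module_ids):
        mask = module_masks[module_id]
        obs = int(observed[i])
        p = (1.0 + int(exceed[i])) / (n_sim + 1.0)
        results.append(
            MSETResult(
                module_id=module_id,
                module_size=int(mask.sum()),
                overlap=obs,
                n_sim=n_sim,
                p_perm=p,
                enriched=p <= alpha,
            )
        )
    return results


def mset_test(
    query: set,
    module: list[str],
    background,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MSETResult:
    """MSET p-value for a single module (see :func:`mset_scan`)."""
    (result,) = mset_scan(
        query, {"module": list(module)}, background, n_sim=n_sim, alpha=alpha, seed=seed
    )
    return result


def mset_table(results: list[MSETResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
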