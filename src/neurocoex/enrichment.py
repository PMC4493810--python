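"""Hypergeometric over-representation analysis with BH adjustment.

For a query gene set of size n drawn from a background of N genes, each
annotation category with C background members is scored by

    O = |query & category|          observed count
    E = C * n / N                   expected count
    R = O / E                       enrichment ratio
    p = P(X >= O),  X ~ Hypergeom(N, C, n)

with Benjamini-Hochberg adjustment across categories.  Reporting follows
the usual over-representation table: categories with at least 10 observed
genes and adjP <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENRICHMENT_COLUMNS = ["category_id", "C", "O", "E", "R", "p", "adjP", "genes"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: set, categories: dict[str, list[str]], background: set
) -> pd.DataFrame:
    """Score every category for over-representation of the query set.

    Categories are intersected with the background before sizing; rows are
    returned unfiltered (apply :func:`filter_enrichment` for reporting).
    A category entirely outside the background gets E = 0 and an undefined
    ratio (NaN), flagged by ``valid = False``.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    query = set(query) & background
    n = len(query)
    nn = len(background)
    rows = []
    for cat_id, members in categories.items():
        in_bg = set(members) & background
        c = len(in_bg)
        observed = sorted(query & in_bg)
        o = len(observed)
        e = c * n / nn
        r = o / e if e > 0 else np.nan
        p = float(stats.hypergeom.sf(o - 1, nn, c, n)) if c > 0 else 1.0
        rows.append((cat_id, c, o, e, r, p, np.nan, ";".join(observed)))
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    out["valid"] = out["C"] > 0
    if len(out):
        out["adjP"] = bh_adjust(out["p"].to_numpy())
    return out


def filter_enrichment(
    rows: pd.DataFrame, min_genes: int = 10, max_adjp: float = 0.05
) -> pd.DataFrame:
    """Reporting filter: O >= min_genes and adjP <= max_adjp, sorted by p."""
    keep = rows[(rows["O"] >= min_genes) & (rows["adjP"] <= max_adjp)]
    return keep.sort_values("p", kind="stable").reset_index(drop=True)


def format_enrichment(rows: pd.DataFrame) -> pd.DataFrame:
    """Round E and R to 2 decimals for table display (full precision kept
    in the unformatted frame)."""
    out = rows.copy()
    out["E"] = out["E"].round(2)
    out["R"] = out["R"].round(2)
    return out
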