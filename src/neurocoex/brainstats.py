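"""Case/control brain-expression statistics.

Covers the bulk-tissue side of the pipeline: per-gene Wilcoxon rank-sum
scans between diagnoses, a permutation scan for genes whose expression
tracks brain pH (the one covariate differing between groups), and the
developmental-stage filters applied to RPKM panels (expression prevalence /
IQR gating and fold-change between foetal and non-foetal samples).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

EXACT_MAX_N = 25


def wilcoxon_scan(
    expr: pd.DataFrame, groups: pd.Series, alpha: float = 0.01
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two groups.

    Uses the exact null distribution when the combined sample size is at
    most 25 and the gene has no ties, and the tie-corrected normal
    approximation otherwise.  Rows with p < *alpha* are flagged
    (``significant``); BH-adjusted p-values are reported alongside without
    being used for the flag, matching an uncorrected p < 0.01 screen.
    """
    groups = groups.loc[expr.columns]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    ga = expr.loc[:, (groups == levels[0]).to_numpy()]
    gb = expr.loc[:, (groups == levels[1]).to_numpy()]
    if ga.shape[1] == 0 or gb.shape[1] == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    n_constant = 0
    for gene in expr.index:
        x = ga.loc[gene].dropna().to_numpy()
        y = gb.loc[gene].dropna().to_numpy()
        combined = np.concatenate([x, y])
        if np.ptp(combined) == 0:
            n_constant += 1
            rows.append((gene, np.nan, 1.0, "none"))
            continue
        has_ties = len(np.unique(combined)) < len(combined)
        method = "exact" if (len(combined) <= EXACT_MAX_N and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        direction = "up" if np.median(x) > np.median(y) else "down"
        rows.append((gene, float(res.statistic), float(res.pvalue), direction))
    if n_constant:
        warnings.warn(f"{n_constant} genes constant across all samples; p set to 1")
    out = pd.DataFrame(rows, columns=["gene_id", "W", "p", "direction"]).set_index(
        "gene_id", drop=False
    )
    out["adjP"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the rows of y on design [1, x] (ordinary least squares)."""
    design = np.column_stack([np.ones_like(x, dtype=float), x])
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ coef).T


def ph_permutation_scan(
    expr: pd.DataFrame,
    ph: pd.Series,
    diagnosis: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test for a pH effect on each gene, adjusted for diagnosis.

    Per gene the model is ``expression ~ diagnosis + pH``; the statistic is
    the partial F for the pH term.  pH values are permuted across samples
    *n_perm* times (diagnosis intact) and
    ``p_perm = (1 + #{perm F >= observed F}) / (n_perm + 1)``.

    The partial F is computed via double residualization: with r_y the gene
    residuals on diagnosis and r_ph the pH residuals on diagnosis,
    ``F = (n - 3) r^2 / (1 - r^2)`` where ``r = cor(r_y, r_ph)`` — so the
    permutation comparison can equivalently (and monotonically) be done on
    r^2, which is what the vectorized implementation uses.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ph = ph.loc[expr.columns].to_numpy(dtype=float)
    if np.ptp(ph) == 0:
        raise ValueError("pH is constant across samples; F undefined")
    dx = (diagnosis.loc[expr.columns] == pd.unique(diagnosis)[0]).to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float)
    n = y.shape[1]

    r_y = _residualize(y, dx)
    r_y_sd = r_y.std(axis=1)
    r_y_sd[r_y_sd == 0] = np.nan

    def partial_r2(ph_vec: np.ndarray) -> np.ndarray:
        r_ph = _residualize(ph_vec[None, :], dx)[0]
        sd_ph = r_ph.std()
        r = (r_y @ r_ph) / (n * r_y_sd * sd_ph)
        return np.clip(r * r, 0.0, 1.0 - 1e-12)

    obs_r2 = partial_r2(ph)
    f_obs = (n - 3) * obs_r2 / (1.0 - obs_r2)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[0])
    for _ in range(n_perm):
        perm_r2 = partial_r2(rng.permutation(ph))
        exceed += perm_r2 >= obs_r2
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    out = pd.DataFrame(
        {
            "gene_id": expr.index,
            "F": f_obs,
            "p_perm": p_perm,
            "flagged": p_perm < alpha,
        }
    ).set_index("gene_id", drop=False)
    return out


def brainspan_filter(
    rpkm: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_fraction: float = 0.75,
    min_iqr: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Expression-prevalence / IQR gate for developmental RPKM panels.

    A gene is retained iff the fraction of samples with RPKM >= *min_rpkm*
    exceeds *min_fraction* OR its interquartile range exceeds *min_iqr*
    (a disjunction: broadly expressed or dynamically expressed).
    """
    if (rpkm.to_numpy() < 0).any():
        raise ValueError("RPKM values must be nonnegative")
    frac = (rpkm >= min_rpkm).mean(axis=1)
    iqr = pd.Series(stats.iqr(rpkm.to_numpy(), axis=1), index=rpkm.index)
    keep = (frac > min_fraction) | (iqr > min_iqr)
    table = pd.DataFrame(
        {
            "gene_id": rpkm.index,
            "fraction_expressed": frac,
            "iqr": iqr,
            "retained": keep,
        }
    ).set_index("gene_id", drop=False)
    return list(rpkm.index[keep]), table


def stage_fold_change(
    rpkm: pd.DataFrame,
    stage: pd.Series,
    min_fc: float = 2.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Direction-symmetric fold change between foetal and non-foetal means.

    ``fold_change = max(m1/m2, m2/m1)`` of the group means with a small
    pseudocount guarding zero means; a gene is stage-differential iff the
    fold change exceeds *min_fc* (default 2).
    """
    stage = stage.loc[rpkm.columns]
    levels = pd.unique(stage)
    if len(levels) != 2:
        raise ValueError(f"need exactly two stages, got {list(levels)}")
    m1 = rpkm.loc[:, (stage == levels[0]).to_numpy()].mean(axis=1) + pseudocount
    m2 = rpkm.loc[:, (stage == levels[1]).to_numpy()].mean(axis=1) + pseudocount
    fc = np.maximum(m1 / m2, m2 / m1)
    return pd.DataFrame(
        {
            "gene_id": rpkm.index,
            "fold_change": fc,
            "stage_de": fc > min_fc,
        }
    ).set_index("gene_id", drop=False)


def compare_gene_sets(a: set, b: set, universe: set) -> dict:
    """Overlap record of two gene sets within a universe.

    Reports the intersection/difference counts, the Jaccard index and the
    hypergeometric upper-tail probability of an overlap at least as large.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    a, b, universe = set(a), set(b), set(universe)
    if not (a <= universe and b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    o = len(a & b)
    union = len(a | b)
    p = float(stats.hypergeom.sf(o - 1, len(universe), len(a), len(b)))
    return {
        "overlap": o,
        "a_only": len(a - b),
        "b_only": len(b - a),
        "jaccard": (o / union) if union else 1.0,
        "p_hypergeom": p,
        "universe": len(universe),
    }
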