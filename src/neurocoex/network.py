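"""Unsigned weighted gene co-expression networks.

The construction follows the standard weighted-network recipe: an unsigned
adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the soft power beta chosen
as the smallest candidate whose connectivity distribution fits a scale-free
(log-log linear) law with R^2 above a target (0.8 by default); a
topological overlap measure (TOM) that augments direct adjacency with
shared-neighbour agreement; average-linkage clustering of the TOM
dissimilarity; adaptive branch cutting into modules of at least 20 genes;
module eigengenes (first principal component of the standardized module
profiles); module membership kME (correlation of each gene with each
eigengene); and hub genes at kME > 0.75 to their own module.

The model object follows the fit/results idiom::

    model = CoexpressionNetwork(expr, power=7, min_module_size=20)
    res = model.fit()
    res.modules          # gene -> module label (Series)
    res.eigengenes       # samples x modules
    res.kme              # genes x modules
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from . import treecut
from ._utils import pearson_matrix

#: module label palette, assigned in order of decreasing module size
MODULE_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
UNASSIGNED = "unassigned"


@dataclass
class NetworkConfig:
    """Construction parameters (defaults are the pipeline's reference values)."""

    soft_power: int | None = 7
    candidate_powers: tuple = tuple(range(1, 21))
    scale_free_target_r2: float = 0.8
    min_module_size: int = 20
    deep_split: int = 2
    hub_kme: float = 0.75
    tree_cut: str = "hybrid"  # or "height"
    cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.soft_power is not None and self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.deep_split not in range(5):
            raise ValueError("deep_split must be in 0..4")


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes removed before correlation")
        expr = expr.loc[~constant]
    return expr


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index of a connectivity vector.

    Bins log10(k) into *n_bins* equal-occupancy bins, regresses
    log10(bin frequency) on log10(mean bin connectivity) and returns
    ``(r2, slope)`` with r2 zeroed when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.quantile(logk, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0, 0.0
    which = np.clip(np.digitize(logk, edges[1:-1]), 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        members = logk[which == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(np.mean(10.0 ** members)))
        ys.append(np.log10(len(members) / len(logk)))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.array(xs) + intercept
    ss_res = float(np.sum((np.array(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope > 0:
        r2 = 0.0
    return max(0.0, min(1.0, r2)), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power reaching the scale-free topology target R^2.

    Returns the chosen power and the per-power fit table (power, r2, slope,
    mean_connectivity).  If no candidate reaches the target the power with
    the best r2 is returned with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expr.shape[0] < 30:
        raise ValueError("need at least 30 genes for a meaningful fit")
    expr = _drop_constant(expr)
    abs_cor = np.abs(pearson_matrix(expr.to_numpy()))
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    for power in candidate_powers:
        k = (abs_cor ** power).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append((int(power), r2, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_connectivity"])
    hit = table[table["r2"] >= target_r2]
    if len(hit):
        chosen = int(hit["power"].iloc[0])
    else:
        chosen = int(table.loc[table["r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached R^2 >= {target_r2}; "
            f"using the best fit (power {chosen})"
        )
    return chosen, table


def adjacency_matrix(expr: pd.DataFrame, power: int = 7) -> pd.DataFrame:
    """Unsigned adjacency |cor|^power with unit diagonal."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    expr = _drop_constant(expr)
    adj = np.abs(pearson_matrix(expr.to_numpy())) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def tom_matrix(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with ``k_i = sum_{u != i} a_iu`` and unit diagonal.
    """
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # (A^2)_ij = sum_u a_iu a_uj over u != i,j since diag(a)=0
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 20,
    deep_split: int = 2,
    tree_cut: str = "hybrid",
    cut_height: float | None = None,
) -> pd.Series:
    """Modules from a TOM dissimilarity via average linkage + branch cutting.

    Returns a gene -> label Series; labels come from the module palette in
    order of decreasing size, with 'unassigned' for unclustered genes.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    link = average(squareform(d, checks=False))
    if tree_cut == "hybrid":
        labels = treecut.cutree_hybrid(
            link, d, min_cluster_size=min_module_size, deep_split=deep_split,
            cut_height=cut_height,
        )
    elif tree_cut == "height":
        heights = link[:, 2]
        if cut_height is None:
            # same adaptive placement as the hybrid cut
            ref = float(np.quantile(heights, 0.05))
            cut_height = ref + 0.99 * (float(heights.max()) - ref)
        labels = treecut.cutree_height(link, cut_height, min_cluster_size=min_module_size)
    else:
        raise ValueError("tree_cut must be 'hybrid' or 'height'")
    names = np.array([UNASSIGNED] + MODULE_PALETTE[: labels.max()], dtype=object)
    index = dissimilarity.index if isinstance(dissimilarity, pd.DataFrame) else None
    return pd.Series(names[labels], index=index, name="module")


def module_eigengenes(
    expr: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component summary of each module.

    Genes are standardized across samples; the eigengene is the first right
    singular vector over samples (unit norm), sign-oriented so its mean
    correlation with the member genes is nonnegative.  Returns
    ``(eigengenes: samples x modules, var_explained: per module)``.
    """
    assignment = assignment.loc[expr.index]
    eig = {}
    varexp = {}
    for module in [m for m in assignment.unique() if m != UNASSIGNED]:
        sub = expr.loc[assignment == module]
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            warnings.warn(
                f"module {module!r}: {int((sd == 0).sum())} constant genes dropped "
                "from the eigengene"
            )
            sub = sub.loc[sd > 0]
        if len(sub) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 usable genes")
        z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=0)).T.to_numpy()
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        if np.mean([np.corrcoef(row, v)[0, 1] for row in z]) < 0:
            v = -v
        eig[module] = v
        varexp[module] = float(s[0] ** 2 / np.sum(s ** 2))
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    return eigengenes, pd.Series(varexp, name="var_explained")


def compute_kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME table: Pearson correlation of every gene with every eigengene."""
    if not expr.columns.equals(eigengenes.index):
        raise ValueError("expression and eigengene sample sets differ")
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc / np.where(xc.std(axis=1) > 0, xc.std(axis=1), 1.0)[:, None]
    e = eigengenes.to_numpy(dtype=float)
    ec = e - e.mean(axis=0, keepdims=True)
    es = ec / np.where(ec.std(axis=0) > 0, ec.std(axis=0), 1.0)[None, :]
    kme = xs @ es / x.shape[1]
    return pd.DataFrame(kme, index=expr.index, columns=eigengenes.columns)


def identify_hubs(
    kme: pd.DataFrame, assignment: pd.Series, threshold: float = 0.75
) -> dict[str, list[str]]:
    """Hub genes: kME to the gene's own module strictly above *threshold*."""
    hubs: dict[str, list[str]] = {}
    for module in kme.columns:
        members = assignment.index[assignment == module]
        vals = kme.loc[members, module]
        hubs[module] = sorted(vals.index[vals > threshold])
    return hubs


def export_edge_list(
    adj: pd.DataFrame,
    assignment: pd.Series,
    module: str,
    min_weight: float = 0.0,
    corr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cytoscape-importable intra-module edge table.

    One row per unordered gene pair with adjacency weight >= *min_weight*;
    the ``sign`` column carries the signed correlation when *corr* is given.
    """
    members = list(assignment.index[assignment == module])
    if not members:
        raise ValueError(f"module {module!r} has no members")
    rows = []
    for i, g1 in enumerate(members):
        for g2 in members[i + 1 :]:
            w = float(adj.loc[g1, g2])
            if w >= min_weight:
                sign = float(corr.loc[g1, g2]) if corr is not None else np.nan
                rows.append((g1, g2, w, sign))
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])


class CoexpressionNetwork:
    """Weighted co-expression network model for a genes x samples matrix.

    Parameters
    ----------
    expr : DataFrame, genes x samples (log2 expression or log2 ratios).
    power : soft-threshold exponent; ``None`` selects it by the scale-free
        criterion over ``candidate_powers``.
    Remaining keyword arguments override :class:`NetworkConfig` defaults.
    """

    def __init__(self, expr: pd.DataFrame, power: int | None = 7, **config):
        self.expr = _drop_constant(expr)
        self.config = NetworkConfig(soft_power=power, **config)

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, **kwargs) -> "CoexpressionNetwork":
        return cls(expr, **kwargs)

    def fit(self) -> "CoexpressionResults":
        cfg = self.config
        if cfg.soft_power is None:
            power, sft = pick_soft_threshold(
                self.expr, cfg.candidate_powers, cfg.scale_free_target_r2
            )
        else:
            power, sft = cfg.soft_power, None
        adj = adjacency_matrix(self.expr, power)
        tom = tom_matrix(adj)
        modules = detect_modules(
            1.0 - tom,
            min_module_size=cfg.min_module_size,
            deep_split=cfg.deep_split,
            tree_cut=cfg.tree_cut,
            cut_height=cfg.cut_height,
        )
        eigengenes, varexp = module_eigengenes(self.expr, modules)
        kme = compute_kme(self.expr, eigengenes)
        hubs = identify_hubs(kme, modules, cfg.hub_kme)
        corr = pd.DataFrame(
            pearson_matrix(self.expr.to_numpy()), index=self.expr.index,
            columns=self.expr.index,
        )
        return CoexpressionResults(
            model=self, power=power, scale_free_table=sft, adjacency=adj,
            tom=tom, modules=modules, eigengenes=eigengenes,
            var_explained=varexp, kme=kme, hubs=hubs, correlation=corr,
        )


@dataclass
class CoexpressionResults:
    """Fitted network: modules, eigengenes, membership and hubs."""

    model: CoexpressionNetwork
    power: int
    scale_free_table: pd.DataFrame | None
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    var_explained: pd.Series
    kme: pd.DataFrame
    hubs: dict[str, list[str]] = field(default_factory=dict)
    correlation: pd.DataFrame | None = None

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()

    def edge_list(self, module: str, min_weight: float = 0.0) -> pd.DataFrame:
        return export_edge_list(
            self.adjacency, self.modules, module, min_weight, corr=self.correlation
        )

    def summary(self) -> str:
        lines = [
            "Co-expression network summary",
            f"  genes: {self.adjacency.shape[0]}  samples: {self.model.expr.shape[1]}",
            f"  soft power: {self.power}  (unsigned, |cor|^beta)",
            "",
            f"  {'module':<14}{'size':>6}{'varExpl':>9}{'hubs':>6}",
        ]
        sizes = self.module_sizes
        for module in sizes.index:
            ve = self.var_explained.get(module, float("nan"))
            nh = len(self.hubs.get(module, []))
            lines.append(
                f"  {module:<14}{sizes[module]:>6}{ve:>9.3f}{nh:>6}"
                if module != UNASSIGNED
                else f"  {module:<14}{sizes[module]:>6}{'':>9}{'':>6}"
            )
        return "\n".join(lines)
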