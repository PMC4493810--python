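"""Permutation-based module preservation between two expression datasets.

Given modules defined on a reference dataset (e.g. controls), the question
is whether each module's density and connectivity survive in a test dataset
(e.g. cases).  Observed statistics per module:

density (computed in the test data)
    * mean intra-module |correlation|
    * mean intra-module unsigned adjacency |cor|^beta
    * proportion of variance explained by the module eigengene

connectivity (agreement between reference and test)
    * cor(kIM_ref, kIM_test)  — intramodular connectivity per member gene
    * cor(kME_ref, kME_test)  — membership to the module eigengene
    * cor of the vectorized intra-module correlation matrices

The null recomputes every statistic on random gene sets of the same size
drawn from the assigned universe; ``Z_s = (obs - mean_null) / sd_null``.
``Z_density`` and ``Z_connectivity`` are the medians of their groups and
``Z_summary`` their mean.  A module is strongly preserved at Z_summary > 10,
moderately for 2 < Z_summary <= 10, and not preserved at Z_summary <= 2
(boundaries resolved conservatively downward).  The medianRank orders
modules by the observed statistics alone (rank 1 = most preserved), which
is far less sensitive to module size than the Z statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import offdiag, pearson_matrix
from .network import UNASSIGNED

DENSITY_STATS = ("mean_abs_cor", "mean_adjacency", "prop_var_explained")
CONNECTIVITY_STATS = ("cor_kim", "cor_kme", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS

STRONG_Z = 10.0
MODERATE_Z = 2.0


def classify_preservation(z_summary: float) -> str:
    """Preservation class from Z_summary (thresholds 2 and 10)."""
    if not np.isfinite(z_summary):
        raise ValueError("Z_summary must be finite")
    if z_summary > STRONG_Z:
        return "strong"
    if z_summary > MODERATE_Z:
        return "moderate"
    return "not_preserved"


def _eigengene_stats(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of row-standardized data: (eigengene over samples, varexp)."""
    sd = x.std(axis=1)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    if np.mean(z @ v) < 0:
        v = -v
    return v, float(s[0] ** 2 / np.sum(s**2))


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def module_stats(ref: np.ndarray, test: np.ndarray, power: int) -> dict[str, float]:
    """Observed preservation statistics for one gene set (rows = genes)."""
    cor_ref = pearson_matrix(ref)
    cor_test = pearson_matrix(test)
    adj_ref = np.abs(cor_ref) ** power
    adj_test = np.abs(cor_test) ** power
    np.fill_diagonal(adj_ref, 0.0)
    np.fill_diagonal(adj_test, 0.0)

    eig_test, varexp_test = _eigengene_stats(test)
    eig_ref, _ = _eigengene_stats(ref)

    def kme(x: np.ndarray, eig: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1)
        sd[sd == 0] = 1.0
        ec = eig - eig.mean()
        return (xc / sd[:, None]) @ (ec / ec.std()) / x.shape[1]

    return {
        "mean_abs_cor": float(np.mean(np.abs(offdiag(cor_test)))),
        "mean_adjacency": float(np.mean(offdiag(adj_test))),
        "prop_var_explained": varexp_test,
        "cor_kim": _safe_cor(adj_ref.sum(axis=1), adj_test.sum(axis=1)),
        "cor_kme": _safe_cor(kme(ref, eig_ref), kme(test, eig_test)),
        "cor_cor": _safe_cor(offdiag(cor_ref), offdiag(cor_test)),
    }


def median_rank(observed: pd.DataFrame) -> pd.Series:
    """Per-module median of the per-statistic preservation ranks.

    For every statistic, modules are ranked by observed value (highest =
    rank 1 = most preserved, average ranks on ties); each module's
    medianRank is the median over statistics.
    """
    if len(observed) < 2:
        raise ValueError("median_rank needs at least 2 modules")
    ranks = observed.rank(ascending=False, method="average", axis=0)
    return ranks.median(axis=1).rename("medianRank")


class ModulePreservation:
    """Permutation preservation model for reference-defined modules.

    Parameters
    ----------
    ref_expr, test_expr : genes x samples DataFrames; gene universes must
        overlap, and statistics are computed on the intersection.
    assignment : gene -> module label Series (from the reference network).
    power : unsigned soft-threshold used for adjacency-based statistics.
    n_permutations : random gene sets per module size (>= 100).
    null_universe : 'all' (default) draws null gene sets from every gene in
        the intersection — the label-permutation null; 'assigned' restricts
        draws to genes inside real modules, which makes the null harsher
        when most assigned genes belong to strong modules.
    """

    def __init__(
        self,
        ref_expr: pd.DataFrame,
        test_expr: pd.DataFrame,
        assignment: pd.Series,
        power: int = 7,
        n_permutations: int = 1000,
        seed: int | None = None,
        null_universe: str = "all",
        min_module_size: int = 3,
    ):
        if n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        common = ref_expr.index.intersection(test_expr.index)
        if len(common) == 0:
            raise ValueError("gene universes do not overlap")
        self.ref = ref_expr.loc[common]
        self.test = test_expr.loc[common]
        self.assignment = assignment.reindex(common).fillna(UNASSIGNED)
        self.power = power
        self.n_permutations = n_permutations
        self.seed = seed
        if null_universe not in ("assigned", "all"):
            raise ValueError("null_universe must be 'assigned' or 'all'")
        self.null_universe = null_universe
        self.min_module_size = min_module_size

    def fit(self) -> "PreservationResults":
        ref_x = self.ref.to_numpy(dtype=float)
        test_x = self.test.to_numpy(dtype=float)
        genes = self.ref.index

        modules = [
            m
            for m in pd.unique(self.assignment)
            if m != UNASSIGNED
        ]
        member_idx: dict[str, np.ndarray] = {}
        for m in modules:
            idx = np.flatnonzero((self.assignment == m).to_numpy())
            if len(idx) < self.min_module_size:
                warnings.warn(
                    f"module {m!r} has {len(idx)} genes in the intersection; skipped"
                )
                continue
            member_idx[m] = idx

        if self.null_universe == "assigned":
            universe = np.flatnonzero((self.assignment != UNASSIGNED).to_numpy())
        else:
            universe = np.arange(len(genes))

        observed = pd.DataFrame(
            {
                m: module_stats(ref_x[idx], test_x[idx], self.power)
                for m, idx in member_idx.items()
            }
        ).T
        observed = observed[list(ALL_STATS)]

        rng = np.random.default_rng(self.seed)
        # permutations shared across modules of equal size
        sizes = sorted({len(idx) for idx in member_idx.values()})
        null_by_size: dict[int, pd.DataFrame] = {}
        for size in sizes:
            draws = []
            for _ in range(self.n_permutations):
                pick = rng.choice(universe, size=size, replace=False)
                draws.append(module_stats(ref_x[pick], test_x[pick], self.power))
            null_by_size[size] = pd.DataFrame(draws)

        z_rows = {}
        for m, idx in member_idx.items():
            null = null_by_size[len(idx)]
            mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
            zs = {}
            for stat in ALL_STATS:
                if sd[stat] <= 1e-8 * max(1.0, abs(mean[stat])):
                    warnings.warn(
                        f"module {m!r}: null sd of {stat} is 0; statistic dropped"
                    )
                    zs[stat] = np.nan
                else:
                    zs[stat] = (observed.loc[m, stat] - mean[stat]) / sd[stat]
            z_rows[m] = zs
        z_table = pd.DataFrame(z_rows).T[list(ALL_STATS)]

        report = pd.DataFrame(index=z_table.index)
        report["size"] = [len(member_idx[m]) for m in z_table.index]
        report["Z_density"] = z_table[list(DENSITY_STATS)].median(axis=1, skipna=True)
        report["Z_connectivity"] = z_table[list(CONNECTIVITY_STATS)].median(
            axis=1, skipna=True
        )
        # a composite whose statistics were all dropped (e.g. connectivity
        # with test == ref, where every null draw scores exactly 1) does not
        # contribute to the summary
        report["Z_summary"] = report[["Z_density", "Z_connectivity"]].mean(
            axis=1, skipna=True
        )
        if len(report) >= 2:
            report["medianRank"] = median_rank(observed)
        else:
            report["medianRank"] = 1.0
        report["class"] = [classify_preservation(z) for z in report["Z_summary"]]
        report["n_permutations"] = self.n_permutations

        return PreservationResults(
            model=self, report=report, observed=observed, z_table=z_table
        )


@dataclass
class PreservationResults:
    """Per-module preservation report with the underlying statistics."""

    model: ModulePreservation
    report: pd.DataFrame
    observed: pd.DataFrame
    z_table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Module preservation (permutation Z statistics)",
            f"  permutations: {self.model.n_permutations}"
            f"  power: {self.model.power}",
            "",
            f"  {'module':<14}{'size':>6}{'Zdens':>8}{'Zconn':>8}"
            f"{'Zsum':>8}{'medRank':>9}  class",
        ]
        for m, row in self.report.iterrows():
            lines.append(
                f"  {m:<14}{int(row['size']):>6}{row['Z_density']:>8.2f}"
                f"{row['Z_connectivity']:>8.2f}{row['Z_summary']:>8.2f}"
                f"{row['medianRank']:>9.1f}  {row['class']}"
            )
        return "\n".join(lines)

    def plot(self, path=None):
        """Z_summary and medianRank versus module size, with the 2/10
        preservation thresholds dashed."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        rep = self.report
        ax1.scatter(rep["size"], rep["medianRank"])
        for m, row in rep.iterrows():
            ax1.annotate(m, (row["size"], row["medianRank"]))
        ax1.invert_yaxis()
        ax1.set_xlabel("module size")
        ax1.set_ylabel("median preservation rank")
        ax2.scatter(rep["size"], rep["Z_summary"])
        for m, row in rep.iterrows():
            ax2.annotate(m, (row["size"], row["Z_summary"]))
        ax2.axhline(MODERATE_Z, ls="--", c="grey")
        ax2.axhline(STRONG_Z, ls="--", c="grey")
        ax2.set_xlabel("module size")
        ax2.set_ylabel("Z summary")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
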