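"""Workflow orchestration: the three runnable analysis chains.

* :func:`run_cellmodel` — two-channel arrays: LOWESS normalization,
  self-self cutoffs, probe classification, gene-level DEG calls per
  condition, condition-exclusive DEG set.
* :func:`run_brain` — bulk cohort: Wilcoxon scan, pH permutation scan,
  overlap of the flagged sets, optional MSET against reference modules.
* :func:`run_preservation` — network chain: modules detected on the
  reference group, preservation tested in the other group (both directions),
  hubs, edge lists and optional module enrichment.

Every run draws all randomness from one root seed (split per stage), echoes
its configuration as JSON next to the outputs, and writes plain
tab-separated tables, so a run is reproducible byte-for-byte from its
emitted config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import brainstats, enrichment, io, mset, twochannel
from .network import CoexpressionNetwork
from .preservation import ModulePreservation

log = logging.getLogger("neurocoex")


@dataclass
class PipelineConfig:
    """All tunable parameters with the pipeline's reference defaults."""

    # two-channel stage
    lowess_span: float = 0.2
    cutoff_bins: int = 20
    credibility: float = 0.99
    min_probes: int = 2
    min_reliable_fraction: float = 0.5
    min_agreement: float = 0.8
    # brain stage
    wilcoxon_alpha: float = 0.01
    ph_n_perm: int = 1000
    ph_alpha: float = 0.05
    # methylation
    beta_hypo: float = 0.2
    beta_hyper: float = 0.8
    # network stage
    soft_power: int | None = 7
    min_module_size: int = 20
    deep_split: int = 2
    hub_kme: float = 0.75
    # preservation
    preservation_n_perm: int = 1000
    # MSET
    mset_n_sim: int = 10_000
    mset_alpha: float = 0.05
    # enrichment reporting
    enrich_min_genes: int = 10
    enrich_max_adjp: float = 0.05
    # randomness
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _emit(outdir: Path | None, name: str, obj) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, str):
        path.write_text(obj)
    else:
        io.write_json(obj, path)


def run_cellmodel(
    config: PipelineConfig,
    selfself_probes: pd.DataFrame,
    case_probes: pd.DataFrame,
    control_probes: pd.DataFrame,
    outdir: str | Path | None = None,
) -> dict:
    """Two-channel DEG workflow: normalize, calibrate, call, intersect."""
    if len(selfself_probes) == 0:
        raise ValueError("self-self arrays are required to calibrate cutoffs")
    outdir = Path(outdir) if outdir is not None else None

    norm_self = twochannel.lowess_normalize(selfself_probes, config.lowess_span)
    cutoffs = twochannel.fit_selfself_cutoffs(
        norm_self, n_bins=config.cutoff_bins, credibility=config.credibility
    )
    results = {}
    for label, probes in (("case", case_probes), ("control", control_probes)):
        norm = twochannel.lowess_normalize(probes, config.lowess_span)
        calls = twochannel.classify_probes(norm, cutoffs)
        deg = twochannel.call_gene_deg(
            calls,
            min_probes=config.min_probes,
            min_reliable_fraction=config.min_reliable_fraction,
            min_agreement=config.min_agreement,
        )
        results[label] = deg
        log.info("cellmodel %s: %s", label, twochannel.deg_counts(deg))
        _emit(outdir, f"deg_{label}.tsv", deg)
    exclusive = twochannel.exclusive_deg(results["case"], results["control"])
    counts = {
        "case": twochannel.deg_counts(results["case"]),
        "control": twochannel.deg_counts(results["control"]),
        "exclusive": twochannel.deg_counts(exclusive),
    }
    _emit(outdir, "deg_exclusive.tsv", exclusive)
    _emit(outdir, "cellmodel_counts.json", counts)
    _emit(outdir, "config.json", config.to_json())
    return {
        "cutoffs": cutoffs,
        "deg_case": results["case"],
        "deg_control": results["control"],
        "exclusive": exclusive,
        "counts": counts,
    }


def run_brain(
    config: PipelineConfig,
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    query: set | None = None,
    reference_modules: dict[str, list[str]] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Bulk-cohort workflow: rank-sum scan, pH scan, overlaps, MSET."""
    outdir = Path(outdir) if outdir is not None else None
    seeds = _stage_seeds(config.seed)

    deg = brainstats.wilcoxon_scan(
        expr, metadata["diagnosis"], alpha=config.wilcoxon_alpha
    )
    ph = brainstats.ph_permutation_scan(
        expr,
        metadata["pH"],
        metadata["diagnosis"],
        n_perm=config.ph_n_perm,
        alpha=config.ph_alpha,
        seed=seeds[0],
    )
    deg_set = set(deg.index[deg["significant"]])
    ph_set = set(ph.index[ph["flagged"]])
    overlap = brainstats.compare_gene_sets(deg_set, ph_set, set(expr.index))
    log.info(
        "brain: %d DEG (p<%.3g), %d pH-affected, overlap %d",
        len(deg_set), config.wilcoxon_alpha, len(ph_set), overlap["overlap"],
    )

    out = {"deg": deg, "ph": ph, "overlap": overlap}
    _emit(outdir, "brain_deg.tsv", deg.reset_index(drop=True))
    _emit(outdir, "brain_ph.tsv", ph.reset_index(drop=True))
    _emit(outdir, "brain_overlap.json", overlap)

    if reference_modules is not None:
        mset_query = query if query is not None else deg_set
        results = mset.mset_scan(
            mset_query,
            reference_modules,
            list(expr.index),
            n_sim=config.mset_n_sim,
            alpha=config.mset_alpha,
            seed=seeds[1],
        )
        out["mset"] = mset.mset_table(results)
        _emit(outdir, "brain_mset.tsv", out["mset"])
    _emit(outdir, "config.json", config.to_json())
    return out


def run_preservation(
    config: PipelineConfig,
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_subset: list[str] | None = None,
    categories: dict[str, list[str]] | None = None,
    reference_group: str = "control",
    outdir: str | Path | None = None,
) -> dict:
    """Network workflow: modules on the reference group, preservation in the
    other, both directions, hubs and optional module enrichment."""
    outdir = Path(outdir) if outdir is not None else None
    seeds = _stage_seeds(config.seed)

    if gene_subset is not None:
        present = [g for g in gene_subset if g in expr.index]
        if not present:
            raise ValueError("gene subset has no genes on the platform")
        log.info(
            "preservation: %d of %d subset genes represented on the platform",
            len(present), len(gene_subset),
        )
        expr = expr.loc[present]

    groups = metadata["diagnosis"]
    levels = list(pd.unique(groups))
    if reference_group not in levels:
        raise ValueError(f"reference_group {reference_group!r} not in {levels}")
    other = [lv for lv in levels if lv != reference_group][0]
    split = {
        lv: expr.loc[:, (groups == lv).to_numpy()] for lv in (reference_group, other)
    }

    out: dict = {"directions": {}}
    for ref_label, test_label, seed in (
        (reference_group, other, seeds[2]),
        (other, reference_group, seeds[3]),
    ):
        net = CoexpressionNetwork(
            split[ref_label],
            power=config.soft_power,
            min_module_size=config.min_module_size,
            deep_split=config.deep_split,
            hub_kme=config.hub_kme,
        ).fit()
        pres = ModulePreservation(
            split[ref_label],
            split[test_label],
            net.modules,
            power=net.power,
            n_permutations=config.preservation_n_perm,
            seed=seed,
        ).fit()
        test_net = CoexpressionNetwork(
            split[test_label],
            power=net.power,
            min_module_size=config.min_module_size,
            deep_split=config.deep_split,
            hub_kme=config.hub_kme,
        ).fit()
        hub_overlap = {
            m: sorted(
                set(net.hubs.get(m, []))
                & set().union(*test_net.hubs.values())
            )
            for m in net.hubs
        }
        direction = f"{ref_label}_vs_{test_label}"
        entry = {
            "network": net,
            "preservation": pres,
            "test_network": test_net,
            "hub_overlap": hub_overlap,
        }
        if categories is not None:
            enr = {}
            background = set(expr.index)
            for m in net.module_sizes.index:
                if m == "unassigned":
                    continue
                members = set(net.modules.index[net.modules == m])
                rows = enrichment.hypergeom_enrich(members, categories, background)
                enr[m] = enrichment.filter_enrichment(
                    rows, config.enrich_min_genes, config.enrich_max_adjp
                )
            entry["enrichment"] = enr
        out["directions"][direction] = entry

        if outdir is not None:
            sub = outdir / direction
            _emit(sub, "modules.tsv", net.modules.rename_axis("gene_id").reset_index())
            _emit(sub, "preservation.tsv", pres.report.rename_axis("module").reset_index())
            _emit(sub, "hubs.json", {m: h for m, h in net.hubs.items()})
            for m in net.module_sizes.index:
                if m != "unassigned":
                    _emit(sub, f"edges_{m}.tsv", net.edge_list(m))
    _emit(outdir, "config.json", config.to_json())
    return out
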