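"""Synthetic-data generators for every input the pipeline consumes.

The generators plant known structure (co-expression modules, differential
expression, methylation transitions, pH effects) and return the ground truth
alongside the data, so every downstream stage can be tested end to end
without any external download.

Planted co-expression modules follow a single-factor model: gene g in
module m is ``x_g = a * f_m + sqrt(1 - a^2) * noise_sd * eps`` with a shared
per-sample latent factor f_m ~ N(0,1), loading ``a`` in [0, 1] and
independent Gaussian noise.  At ``noise_sd = 1`` the expected pairwise
correlation inside a module is exactly ``a**2``.  A non-preserved module
keeps this structure in the reference (control) samples but replaces the
shared factor with an independent per-gene factor in case samples, which
destroys the correlation structure without shifting means — preservation
statistics measure connectivity, not location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_proportion

CELL_TYPES = ("fibroblast", "hiPSC", "NPC")


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    loading: float = 0.9
    preserved_in_cases: bool = True

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        check_proportion(self.loading, "loading")


@dataclass
class SimCohortConfig:
    """Configuration of the synthetic case/control brain cohort.

    Defaults mirror the study design: 29 cases, 30 controls, modules of at
    least 20 genes, a pH covariate (N(6.5, 0.25), cases shifted -0.2)
    affecting 20% of genes.
    """

    n_cases: int = 29
    n_controls: int = 30
    n_genes: int = 300
    module_specs: list[ModuleSpec] = field(default_factory=list)
    ph_affected_fraction: float = 0.2
    ph_effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    ph_mean: float = 6.5
    ph_sd: float = 0.25
    ph_case_shift: float = -0.2
    deg_fraction: float = 0.0
    deg_effect: float = 0.0

    def __post_init__(self) -> None:
        self.module_specs = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.module_specs
        ]
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        check_proportion(self.ph_affected_fraction, "ph_affected_fraction")
        check_proportion(self.deg_fraction, "deg_fraction")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimTruth:
    """Ground truth planted by a generator run."""

    module_membership: dict[str, str] = field(default_factory=dict)
    deg_genes: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    ph_genes: set[str] = field(default_factory=set)
    methylation_transitions: set[tuple[str, str, str]] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "module_membership": self.module_membership,
            "deg_genes": self.deg_genes,
            "ph_genes": sorted(self.ph_genes),
            "methylation_transitions": sorted(self.methylation_transitions),
        }


def gen_brain_cohort(config: SimCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the case/control expression cohort with planted modules.

    Returns ``(expression, metadata, truth)``: a genes x samples log2
    matrix, a sample metadata table (sample, diagnosis, pH) and the truth.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_cases + config.n_controls
    genes = [f"gene{i:05d}" for i in range(1, config.n_genes + 1)]
    samples = [f"case{i:03d}" for i in range(1, config.n_cases + 1)] + [
        f"ctrl{i:03d}" for i in range(1, config.n_controls + 1)
    ]
    is_case = np.array([s.startswith("case") for s in samples])

    ph = rng.normal(config.ph_mean, config.ph_sd, n_samples)
    ph[is_case] += config.ph_case_shift

    x = np.empty((config.n_genes, n_samples))
    truth = SimTruth()
    module_names = [f"M{i + 1}" for i in range(len(config.module_specs))]

    pos = 0
    for name, spec in zip(module_names, config.module_specs):
        idx = slice(pos, pos + spec.size)
        a = spec.loading
        resid_sd = np.sqrt(max(0.0, 1.0 - a * a)) * config.noise_sd
        factor = rng.normal(size=n_samples)
        block = a * factor[None, :] + resid_sd * rng.normal(size=(spec.size, n_samples))
        if not spec.preserved_in_cases:
            # cases get an independent factor per gene: connectivity gone,
            # marginal variance unchanged
            own = rng.normal(size=(spec.size, int(is_case.sum())))
            block[:, is_case] = a * own + resid_sd * rng.normal(
                size=(spec.size, int(is_case.sum()))
            )
        x[idx] = block
        for g in genes[idx]:
            truth.module_membership[g] = name
        pos += spec.size
    x[pos:] = config.noise_sd * rng.normal(size=(config.n_genes - pos, n_samples))
    for g in genes[pos:]:
        truth.module_membership[g] = "unassigned"

    n_ph = int(round(config.ph_affected_fraction * config.n_genes))
    ph_idx = rng.choice(config.n_genes, size=n_ph, replace=False)
    x[ph_idx] += config.ph_effect_size * (ph - ph.mean())[None, :]
    truth.ph_genes = {genes[i] for i in ph_idx}

    n_deg = int(round(config.deg_fraction * config.n_genes))
    if n_deg:
        deg_idx = rng.choice(config.n_genes, size=n_deg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_deg)
        x[deg_idx] += (signs[:, None] * config.deg_effect) * is_case[None, :]
        truth.deg_genes = {
            genes[i]: ("up" if s > 0 else "down") for i, s in zip(deg_idx, signs)
        }

    expr = pd.DataFrame(x, index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "sample": samples,
            "diagnosis": np.where(is_case, "case", "control"),
            "pH": ph,
        }
    ).set_index("sample", drop=False)
    return expr, meta, truth


def gen_two_channel(
    n_genes: int,
    probes_per_gene: int = 3,
    n_selfself: int = 1,
    n_replicates: int = 3,
    deg_fraction: float = 0.1,
    effect_range: tuple[float, float] = (0.5, 6.8),
    seed: int = 0,
    noise_c0: float = 0.1,
    noise_c1: float = 2.0,
    a_range: tuple[float, float] = (6.0, 16.0),
    reliable_rate: float = 0.97,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate two-channel arrays: self-self nulls plus replicated test arrays.

    Each probe draws a mean log2 intensity A ~ Uniform(*a_range*) and a log2
    ratio ``M = mu_g + eps(A)`` where ``eps(A) ~ N(0, (c0 + c1/A)^2)`` —
    the funnel-shaped, intensity-dependent noise of MA plots.  ``mu_g`` is 0
    on self-self arrays and for non-DEG genes; DEG genes draw a magnitude
    uniform on *effect_range* with random sign, shared by their probes and
    replicates.  Returns ``(selfself_probes, test_probes, truth)``.
    """
    if probes_per_gene < 1 or n_replicates < 1:
        raise ValueError("probes_per_gene and n_replicates must be >= 1")
    check_proportion(deg_fraction, "deg_fraction")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(1, n_genes + 1)]
    n_deg = int(round(deg_fraction * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    lo, hi = effect_range
    mu = np.zeros(n_genes)
    mu[deg_idx] = rng.uniform(lo, hi, n_deg) * rng.choice([-1.0, 1.0], n_deg)

    truth = SimTruth(
        deg_genes={genes[i]: ("up" if mu[i] > 0 else "down") for i in deg_idx}
    )

    def make_array(array_id: str, replicate: str, with_effect: bool) -> pd.DataFrame:
        n = n_genes * probes_per_gene
        a_vals = rng.uniform(a_range[0], a_range[1], n)
        sigma = noise_c0 + noise_c1 / a_vals
        m_vals = rng.normal(0.0, sigma)
        if with_effect:
            m_vals = m_vals + np.repeat(mu, probes_per_gene)
        return pd.DataFrame(
            {
                "probe_id": [
                    f"{g}_p{j + 1}" for g in genes for j in range(probes_per_gene)
                ],
                "gene_id": np.repeat(genes, probes_per_gene),
                "replicate": replicate,
                "array": array_id,
                "A": a_vals,
                "M": m_vals,
                "reliable": rng.random(n) < reliable_rate,
            }
        )

    selfself = pd.concat(
        [make_array(f"selfself{k + 1}", f"selfself{k + 1}", False) for k in range(n_selfself)],
        ignore_index=True,
    )
    test = pd.concat(
        [make_array(f"test{k + 1}", f"rep{k + 1}", True) for k in range(n_replicates)],
        ignore_index=True,
    )
    return selfself, test, truth


def gen_methylation(
    n_cpgs: int,
    planted: list[tuple[str, str, int]],
    seed: int = 0,
    subjects: tuple[str, str] = ("CON", "SCZP"),
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate beta-value panels for two subjects across three cell types.

    *planted* is a list of ``(subject, direction, count)`` with direction
    ``"hypo"`` (hyper in hiPSC -> hypo in NPC) or ``"hyper"`` (the reverse);
    those CpGs flip category between hiPSC and NPC in the stated subject
    only.  All other CpGs stay within one methylation category (beta <= 0.2,
    middle, or beta >= 0.8) in every cell type of both subjects.

    Returns a CpG x sample matrix with columns ``subject:celltype`` plus the
    truth, recording transitions as ``(cpg, subject, "to-hypo"|"to-hyper")``.
    """
    for subject, direction, _count in planted:
        if subject not in subjects:
            raise ValueError(f"unknown subject {subject!r}")
        if direction not in ("hypo", "hyper"):
            raise ValueError(f"direction must be 'hypo' or 'hyper', got {direction!r}")
    n_planted = sum(c for _, _, c in planted)
    if n_planted > n_cpgs:
        raise ValueError("planted counts exceed n_cpgs")

    rng = np.random.default_rng(seed)
    cpgs = [f"cg{i:07d}" for i in range(1, n_cpgs + 1)]
    bands = {
        "hypo": (0.02, 0.18),
        "intermediate": (0.25, 0.75),
        "hyper": (0.82, 0.98),
    }

    def draw(band: str, size=None) -> np.ndarray:
        lo, hi = bands[band]
        return rng.uniform(lo, hi, size)

    columns = [f"{s}:{ct}" for s in subjects for ct in CELL_TYPES]
    beta = pd.DataFrame(index=cpgs, columns=columns, dtype=float)
    truth = SimTruth()

    # stable background: one category per CpG, shared by both subjects
    cats = rng.choice(["hypo", "intermediate", "hyper"], size=n_cpgs)
    for col in columns:
        for cat in bands:
            mask = cats == cat
            beta.loc[mask, col] = draw(cat, int(mask.sum()))

    pos = 0
    for subject, direction, count in planted:
        other = subjects[0] if subject == subjects[1] else subjects[1]
        for cpg in cpgs[pos : pos + count]:
            start, end = ("hyper", "hypo") if direction == "hypo" else ("hypo", "hyper")
            beta.loc[cpg, f"{subject}:hiPSC"] = draw(start)
            beta.loc[cpg, f"{subject}:NPC"] = draw(end)
            beta.loc[cpg, f"{subject}:fibroblast"] = draw(start)
            for ct in CELL_TYPES:  # the other subject stays put
                beta.loc[cpg, f"{other}:{ct}"] = draw(start)
            truth.methylation_transitions.add((cpg, subject, f"to-{direction}"))
        pos += count
    return beta, truth


def gen_stage_panel(
    n_genes: int = 184,
    n_de: int = 73,
    n_foetal: int = 16,
    n_nonfoetal: int = 22,
    fc: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """RPKM panel across foetal/non-foetal samples with planted stage DE.

    The first *n_de* genes get a *fc*-fold mean difference between stages
    (alternating direction); the rest share one mean.  Defaults mirror the
    reported developmental screen: 184 retained genes, 73 of them (40%)
    stage-differential, over 16 foetal and 22 non-foetal samples.
    Returns ``(rpkm, stage labels, planted DE gene set)``.
    """
    if n_de > n_genes:
        raise ValueError("n_de exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(1, n_genes + 1)]
    samples = [f"foetal{i:02d}" for i in range(1, n_foetal + 1)] + [
        f"adult{i:02d}" for i in range(1, n_nonfoetal + 1)
    ]
    stage = pd.Series(
        ["foetal"] * n_foetal + ["non-foetal"] * n_nonfoetal, index=samples
    )
    base = rng.uniform(2.0, 10.0, n_genes)
    x = np.empty((n_genes, len(samples)))
    for i in range(n_genes):
        mean = np.full(len(samples), base[i])
        if i < n_de:
            if i % 2 == 0:
                mean[:n_foetal] *= fc
            else:
                mean[n_foetal:] *= fc
        # mild multiplicative noise keeps group means well separated
        x[i] = mean * rng.uniform(0.9, 1.1, len(samples))
    rpkm = pd.DataFrame(x, index=genes, columns=samples)
    return rpkm, stage, set(genes[:n_de])


def gen_reference_modules(
    n_modules: int,
    sizes: list[int] | int,
    background: list[str],
    seed: int = 0,
    allow_overlap: bool = False,
) -> dict[str, list[str]]:
    """Draw a reference gene-set collection (e.g. developmental modules).

    *sizes* is one size per module (or a single int used for all).  Modules
    are disjoint draws from *background* unless *allow_overlap*.
    """
    if isinstance(sizes, int):
        sizes = [sizes] * n_modules
    if len(sizes) != n_modules:
        raise ValueError("need one size per module")
    if max(sizes, default=0) > len(background):
        raise ValueError("module size exceeds background")
    if not allow_overlap and sum(sizes) > len(background):
        raise ValueError("disjoint module sizes exceed background")
    rng = np.random.default_rng(seed)
    background = list(background)
    modules: dict[str, list[str]] = {}
    if allow_overlap:
        for i, size in enumerate(sizes):
            pick = rng.choice(len(background), size=size, replace=False)
            modules[f"M{i + 1}"] = [background[j] for j in sorted(pick)]
    else:
        order = rng.permutation(len(background))
        pos = 0
        for i, size in enumerate(sizes):
            pick = order[pos : pos + size]
            modules[f"M{i + 1}"] = [background[j] for j in sorted(pick)]
            pos += size
    return modules


def truth_resolves(truth: SimTruth, *, genes=None, cpgs=None) -> bool:
    """Check that every identifier in the truth exists in the data."""
    ok = True
    if genes is not None:
        genes = set(genes)
        ok &= set(truth.module_membership) <= genes if truth.module_membership else True
        ok &= set(truth.deg_genes) <= genes
        ok &= truth.ph_genes <= genes
    if cpgs is not None:
        cpgs = set(cpgs)
        ok &= {c for c, _, _ in truth.methylation_transitions} <= cpgs
    if not ok:
        warnings.warn("simulation truth contains identifiers absent from the data")
    return ok
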