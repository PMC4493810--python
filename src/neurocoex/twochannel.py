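"""Two-channel microarray differential expression with self-self calibration.

The self-self design hybridizes the same sample labelled with both dyes on
one array, so its log2 ratios (M) sample the pure technical null at every
intensity (A).  Per-intensity-bin empirical quantiles of self-self M define
an envelope; on the case-vs-control arrays a probe is called up/down only if
its M escapes the envelope at its own A.  Gene-level calls then require a
probe consensus in every replicate:

a. the gene is represented by at least two probes,
b. more than 50% of its probes give reliable signal,
c. at least 80% of the reliable probes agree on one non-flat direction,

and the agreed direction must be identical across replicates.  Condition-
exclusive genes are obtained by set difference against the comparison
condition's calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

MIN_PROBES_FOR_LOWESS = 10


@dataclass
class IntensityCutoffs:
    """Per intensity-bin lower/upper bounds on the null log-ratio.

    Bounds are interpolated piecewise-linearly between bin midpoints;
    outside the observed A range the nearest bin's bounds extend flat.
    """

    bin_mids: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    credibility: float

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound in some bin")

    def bounds(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(a, dtype=float)
        return (
            np.interp(a, self.bin_mids, self.lower),
            np.interp(a, self.bin_mids, self.upper),
        )


def lowess_normalize(probes: pd.DataFrame, span: float = 0.2) -> pd.DataFrame:
    """Within-array LOWESS normalization of M on A (default span 0.2).

    Per array, the locally weighted regression of M on A is fitted on the
    reliable probes and subtracted from every probe; A is unchanged.  Arrays
    with fewer than 10 reliable probes are refused.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    out = probes.copy()
    for array_id, grp in probes.groupby("array", sort=False):
        rel = grp[grp["reliable"]]
        if len(rel) < MIN_PROBES_FOR_LOWESS:
            raise ValueError(
                f"array {array_id!r} has {len(rel)} reliable probes; "
                f">= {MIN_PROBES_FOR_LOWESS} required for normalization"
            )
        a_rel = rel["A"].to_numpy()
        # delta skips refitting at nearly-identical A values (pure speedup)
        fit = lowess(
            rel["M"].to_numpy(), a_rel, frac=span, it=3,
            delta=0.005 * np.ptp(a_rel),
        )
        # interpolate the fitted curve onto all probes of the array
        trend = np.interp(grp["A"].to_numpy(), fit[:, 0], fit[:, 1])
        out.loc[grp.index, "M"] = grp["M"].to_numpy() - trend
    return out


def fit_selfself_cutoffs(
    selfself_probes: pd.DataFrame,
    n_bins: int = 20,
    credibility: float = 0.99,
    min_per_bin: int = 20,
) -> IntensityCutoffs:
    """Learn intensity-dependent cutoffs from self-self hybridizations.

    A is split into *n_bins* equal-occupancy bins (merged down until every
    bin holds at least *min_per_bin* reliable probes); per bin the lower and
    upper bounds are the (1-q)/2 and 1-(1-q)/2 empirical quantiles of M.
    """
    if len(selfself_probes) == 0:
        raise ValueError("no self-self probes supplied")
    if not 0.5 < credibility < 1:
        raise ValueError("credibility must be in (0.5, 1)")
    rel = selfself_probes[selfself_probes["reliable"]]
    if len(rel) == 0:
        raise ValueError("no reliable self-self probes")
    n_bins = max(1, min(n_bins, len(rel) // min_per_bin or 1))
    a = rel["A"].to_numpy()
    m = rel["M"].to_numpy()
    order = np.argsort(a, kind="stable")
    a, m = a[order], m[order]
    splits = np.array_split(np.arange(len(a)), n_bins)
    tail = (1.0 - credibility) / 2.0
    mids, lo, hi = [], [], []
    for idx in splits:
        mids.append(float(np.mean(a[idx])))
        lo.append(float(np.quantile(m[idx], tail)))
        hi.append(float(np.quantile(m[idx], 1.0 - tail)))
    return IntensityCutoffs(
        bin_mids=np.array(mids), lower=np.array(lo), upper=np.array(hi),
        credibility=credibility,
    )


def classify_probes(probes: pd.DataFrame, cutoffs: IntensityCutoffs) -> pd.DataFrame:
    """Call each probe up/down/flat against the self-self envelope.

    Strict inequalities: a probe exactly on the envelope is flat.
    Unreliable probes are passed through as 'unreliable'.
    """
    out = probes.copy()
    lo, hi = cutoffs.bounds(out["A"].to_numpy())
    m = out["M"].to_numpy()
    call = np.where(m > hi, "up", np.where(m < lo, "down", "flat"))
    call = np.where(out["reliable"].to_numpy(), call, "unreliable")
    out["call"] = call
    return out


def call_gene_deg(
    probe_calls: pd.DataFrame,
    min_probes: int = 2,
    min_reliable_fraction: float = 0.5,
    min_agreement: float = 0.8,
) -> pd.DataFrame:
    """Gene-level DEG calls from per-probe calls, by replicate consensus.

    A gene is called in one direction iff in *every* replicate it has
    >= *min_probes* probes, > *min_reliable_fraction* of them reliable, and
    >= *min_agreement* of the reliable probes share that same non-flat
    direction (agreement is computed over reliable probes only: unreliable
    probes carry no direction).  Genes absent from any replicate are
    excluded.  Returns a table (gene_id, direction, n_probes, agreement
    columns per replicate).
    """
    replicates = sorted(probe_calls["replicate"].unique())
    grouped = probe_calls.groupby(["gene_id", "replicate"], sort=True)
    per_rep: dict[str, dict[str, tuple[str, float, int]]] = {}
    for (gene, rep), grp in grouped:
        n = len(grp)
        rel = grp[grp["call"] != "unreliable"]
        if n < min_probes or len(rel) <= min_reliable_fraction * n:
            verdict = ("none", np.nan, n)
        else:
            n_up = int((rel["call"] == "up").sum())
            n_down = int((rel["call"] == "down").sum())
            if n_up >= n_down:
                direction, agree = "up", n_up / len(rel)
            else:
                direction, agree = "down", n_down / len(rel)
            if agree >= min_agreement and direction in ("up", "down") and max(n_up, n_down) > 0:
                verdict = (direction, agree, n)
            else:
                verdict = ("none", agree, n)
        per_rep.setdefault(gene, {})[rep] = verdict

    rows = []
    skipped_partial = 0
    for gene, reps in per_rep.items():
        if set(reps) != set(replicates):
            skipped_partial += 1
            continue
        verdicts = [reps[r] for r in replicates]
        directions = {v[0] for v in verdicts}
        if len(directions) == 1 and directions != {"none"}:
            row = {
                "gene_id": gene,
                "direction": directions.pop(),
                "n_probes": min(v[2] for v in verdicts),
            }
            for r in replicates:
                row[f"agreement_{r}"] = reps[r][1]
            rows.append(row)
    if skipped_partial:
        warnings.warn(
            f"{skipped_partial} genes present in only a subset of replicates "
            "were excluded"
        )
    cols = ["gene_id", "direction", "n_probes"] + [f"agreement_{r}" for r in replicates]
    return pd.DataFrame(rows, columns=cols)


def exclusive_deg(deg_case: pd.DataFrame, deg_control: pd.DataFrame) -> pd.DataFrame:
    """Case DEG calls whose gene is absent from the control calls.

    A gene regulated in both conditions (either direction) reflects the
    shared process and is excluded; only condition-exclusive genes remain.
    """
    control_genes = set(deg_control["gene_id"]) if len(deg_control) else set()
    keep = ~deg_case["gene_id"].isin(control_genes)
    return deg_case[keep].reset_index(drop=True)


def deg_counts(deg: pd.DataFrame) -> dict[str, int]:
    return {
        "up": int((deg["direction"] == "up").sum()),
        "down": int((deg["direction"] == "down").sum()),
        "total": int(len(deg)),
    }
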