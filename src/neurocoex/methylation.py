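"""Beta-value categorization and hiPSC -> NPC methylation transitions.

CpGs with beta <= 0.2 are hypo-methylated and beta >= 0.8 hyper-methylated
(both bounds inclusive); everything between is intermediate.  A CpG
"transitions" between two cell types of one subject when its category flips
fully between hypo and hyper; case-exclusive transitions are the Venn-style
set difference against the control subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HYPO_MAX = 0.2
HYPER_MIN = 0.8

_CATEGORY_RANK = {"hypo": 0, "intermediate": 1, "hyper": 2}


def categorize_beta(
    beta, hypo_max: float = HYPO_MAX, hyper_min: float = HYPER_MIN
):
    """Map beta-value(s) to 'hypo' / 'intermediate' / 'hyper'.

    Accepts a scalar or array; thresholds are inclusive at both bounds.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("beta-values must lie in [0, 1]")
    cat = np.where(arr <= hypo_max, "hypo", np.where(arr >= hyper_min, "hyper", "intermediate"))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return str(cat)
    return cat


def transition_sites(
    panel: pd.DataFrame,
    subject: str,
    from_type: str = "hiPSC",
    to_type: str = "NPC",
    mode: str = "strict",
) -> set[tuple[str, str]]:
    """CpGs whose methylation category changes between two cell types.

    In ``mode='strict'`` only a full hyper<->hypo flip counts (intermediate
    never transitions).  ``mode='any_change'`` accepts any category change,
    with direction given by whether the category rank decreases (to-hypo)
    or increases (to-hyper).  Returns a set of ``(cpg, direction)`` with
    direction in {'to-hypo', 'to-hyper'}.
    """
    if mode not in ("strict", "any_change"):
        raise ValueError("mode must be 'strict' or 'any_change'")
    cols = {}
    for ct in (from_type, to_type):
        name = f"{subject}:{ct}"
        if name not in panel.columns:
            raise ValueError(f"sample {name!r} missing from the beta matrix")
        cols[ct] = name
    cat_from = pd.Series(categorize_beta(panel[cols[from_type]].to_numpy()), index=panel.index)
    cat_to = pd.Series(categorize_beta(panel[cols[to_type]].to_numpy()), index=panel.index)
    out: set[tuple[str, str]] = set()
    for cpg in panel.index:
        f, t = cat_from[cpg], cat_to[cpg]
        if f == t:
            continue
        if mode == "strict":
            if f == "hyper" and t == "hypo":
                out.add((cpg, "to-hypo"))
            elif f == "hypo" and t == "hyper":
                out.add((cpg, "to-hyper"))
        else:
            direction = "to-hypo" if _CATEGORY_RANK[t] < _CATEGORY_RANK[f] else "to-hyper"
            out.add((cpg, direction))
    return out


def exclusive_transitions(
    case: set[tuple[str, str]], control: set[tuple[str, str]]
) -> tuple[set[str], set[str]]:
    """Case-only transitions, split by direction (Venn difference).

    Returns ``(case_only_hypo, case_only_hyper)`` as sets of CpG ids: the
    (cpg, direction) pairs present in the case subject but not the control.
    """
    only = case - control
    return (
        {cpg for cpg, d in only if d == "to-hypo"},
        {cpg for cpg, d in only if d == "to-hyper"},
    )


def venn_counts(case: set[tuple[str, str]], control: set[tuple[str, str]]) -> dict[str, int]:
    """Counts for Venn export: shared and exclusive transitions."""
    hypo, hyper = exclusive_transitions(case, control)
    ctrl_hypo, ctrl_hyper = exclusive_transitions(control, case)
    return {
        "case_only_hypo": len(hypo),
        "case_only_hyper": len(hyper),
        "control_only_hypo": len(ctrl_hypo),
        "control_only_hyper": len(ctrl_hyper),
        "shared": len(case & control),
    }
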