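"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated text or GMT: expression matrices are genes x
samples with the gene identifier in the first column; probe tables carry one
measurement per row; gene-set collections use the standard GMT layout
(set id, description, then members).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

PROBE_COLUMNS = ["probe_id", "gene_id", "replicate", "array", "A", "M", "reliable"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata table with at least a ``sample`` column."""
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError("metadata table must have a 'sample' column")
    return meta.set_index("sample", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    probes["reliable"] = probes["reliable"].astype(bool)
    return probes


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """CpG x sample matrix of methylation beta-values.

    Columns are named ``subject:celltype`` (e.g. ``SCZP:hiPSC``).
    """
    beta = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in beta.columns if ":" not in c]
    if bad:
        raise ValueError(f"beta-matrix columns must be 'subject:celltype', got {bad}")
    return beta


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="cpg_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: id <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene list, blank lines ignored."""
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
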