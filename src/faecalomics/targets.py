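"""Target-gene intersection and gene-set annotation.

Dysregulated miRNAs/piRNAs are mapped to their target genes (validated
targets for miRNAs; for piRNAs the predicted targets with the highest
alignment support per ncRNA), the per-sample target sets are intersected
to find genes supported by several samples, and the shared genes are
annotated by membership in gene-set collections (GMT). No enrichment
statistic is computed — the reported quantity is the membership count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import DiffRecord

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("ncrna_id", "gene", "evidence", "alignment_support")


class TargetMap:
    """ncRNA → target-gene sets with evidence class and alignment support."""

    def __init__(self, entries: pd.DataFrame):
        self.entries = entries

    def targets_of(self, ncrna_id: str) -> set[str]:
        sub = self.entries[self.entries["ncrna_id"] == ncrna_id]
        return set(sub["gene"])

    @property
    def ncrna_ids(self) -> set[str]:
        return set(self.entries["ncrna_id"])


def load_target_map(path: str | Path, ncrna_class: str) -> TargetMap:
    """Read a target-map TSV snapshot and apply the class-specific filter.

    miRNA maps keep only experimentally validated targets; piRNA maps keep,
    per ncRNA, only the rows achieving that ncRNA's maximum alignment
    support. Gene symbols are uppercased on read-in.
    """
    if ncrna_class not in {"miRNA", "piRNA"}:
        raise ValueError(f"unsupported ncRNA class: {ncrna_class!r}")
    df = pd.read_csv(path, sep="\t", dtype={"ncrna_id": str, "gene": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target map {path} is missing columns: {missing}")
    if len(df) == 0:
        return TargetMap(df)
    df = df.copy()
    df["gene"] = df["gene"].str.upper()
    if (df["gene"].str.len() == 0).any():
        raise ValueError("empty gene symbols in target map")
    if ncrna_class == "miRNA":
        df = df[df["evidence"] == "validated"]
    else:
        best = df.groupby("ncrna_id")["alignment_support"].transform("max")
        df = df[df["alignment_support"] == best]
    df = df.drop_duplicates(subset=["ncrna_id", "gene"]).reset_index(drop=True)
    return TargetMap(df)


def dysregulated_targets(
    de_records: Mapping[str, Sequence[DiffRecord]],
    target_map: TargetMap,
    direction: str = "both",
) -> dict[str, set[str]]:
    """Per sample, the union of targets of its significant ncRNAs.

    ``direction`` restricts to up-regulated (log2FC > 0), down-regulated,
    or both.
    """
    if direction not in {"up", "down", "both"}:
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    out: dict[str, set[str]] = {}
    for sample, records in de_records.items():
        genes: set[str] = set()
        for r in records:
            if not r.significant:
                continue
            if direction == "up" and r.log2fc <= 0:
                continue
            if direction == "down" and r.log2fc >= 0:
                continue
            genes |= target_map.targets_of(r.feature)
        out[sample] = genes
    return out


def common_targets(
    sample_genes: Mapping[str, set[str]],
    min_samples: int = 2,
) -> dict[str, list[str]]:
    """Genes present in at least ``min_samples`` per-sample target sets.

    Returns gene → sorted supporting samples, genes in alphabetical order.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if min_samples > len(sample_genes):
        logger.warning(
            "min_samples %d exceeds the %d available samples; empty result",
            min_samples, len(sample_genes),
        )
        return {}
    support: dict[str, list[str]] = {}
    for sample in sorted(sample_genes):
        for gene in sample_genes[sample]:
            support.setdefault(gene, []).append(sample)
    return {
        gene: support[gene]
        for gene in sorted(support)
        if len(support[gene]) >= min_samples
    }


class GeneSetCollection:
    """Named gene sets with GMT semantics."""

    def __init__(self, sets: Mapping[str, set[str]]):
        self.sets = {name: {g.upper() for g in genes} for name, genes in sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Parse a GMT file: name, description, then one gene per field."""
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: malformed GMT line {lineno} "
                        f"({len(fields)} fields, expected >= 3)"
                    )
                name = fields[0]
                if name in sets:
                    raise ValueError(f"{path}: duplicate gene-set name {name!r}")
                sets[name] = {g for g in fields[2:] if g}
        return cls(sets)


def annotate_gene_sets(
    genes: set[str] | Sequence[str],
    collection: GeneSetCollection,
) -> dict[str, tuple[list[str], int]]:
    """Membership of the query genes in each gene set.

    Returns set name → (sorted hit genes, hit count); sets with no hits are
    omitted.
    """
    query = {g.upper() for g in genes}
    out = {}
    for name in sorted(collection.sets):
        hits = sorted(query & collection.sets[name])
        if hits:
            out[name] = (hits, len(hits))
    return out
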