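"""Shared in-memory containers for the faecal sncRNA + microbiome pipeline.

Count matrices are held as pandas DataFrames (features in rows, samples in
columns) wrapped with explicit per-sample library sizes, because downstream
statistics (Fisher tests on count-vs-library tables, TMM scaling) need the
sequencing depth even after rows have been filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NCRNA_CLASSES = ("miRNA", "piRNA", "other")

TAXONOMY_RANKS = (
    "Kingdom",
    "Phylum",
    "Class",
    "Order",
    "Family",
    "Genus",
    "Species",
)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Reference:
    """One ncRNA reference sequence (DNA alphabet, U already folded to T)."""

    id: str
    sequence: str
    ncrna_class: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"reference {self.id!r} contains non-ACGT symbols")
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(
                f"reference {self.id!r}: unknown ncRNA class {self.ncrna_class!r}"
            )


class ReferenceSet:
    """Ordered collection of unique ncRNA references, the mapping target."""

    def __init__(self, entries: Iterable[Reference]):
        self.entries: list[Reference] = list(entries)
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, ref_id: str) -> Reference:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def classes(self) -> pd.Series:
        return pd.Series(
            {e.id: e.ncrna_class for e in self.entries}, name="ncrna_class"
        )

    @classmethod
    def from_fasta(cls, path: str | Path, classes: Mapping[str, str] | None = None) -> "ReferenceSet":
        """Read references from FASTA, normalizing U to T.

        Class labels may be embedded in the description as ``class=miRNA`` or
        supplied through ``classes``; anything else is labelled ``other``.
        """
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            label = "other"
            if classes is not None and rec.id in classes:
                label = classes[rec.id]
            else:
                for token in rec.description.split():
                    if token.startswith("class="):
                        label = token.split("=", 1)[1]
            entries.append(Reference(rec.id, seq, label))
        return cls(entries)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.id, description=f"class={e.ncrna_class}")
            for e in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")


class CountTable:
    """Non-negative feature × sample matrix with per-sample library sizes.

    ``library_sizes`` defaults to the column sums but is kept separately so a
    filtered table can still refer to the full sequencing depth.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        library_sizes: pd.Series | None = None,
        feature_meta: pd.DataFrame | None = None,
    ):
        values = values.astype(float)
        if (values.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")
        self.values = values
        if library_sizes is None:
            library_sizes = values.sum(axis=0)
        else:
            library_sizes = library_sizes.reindex(values.columns)
            if library_sizes.isna().any():
                missing = list(library_sizes[library_sizes.isna()].index)
                raise ValueError(f"missing library sizes for samples: {missing}")
        self.library_sizes = library_sizes.astype(float)
        self.feature_meta = feature_meta

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, sample: str) -> pd.Series:
        return self.values[sample]

    def copy(self) -> "CountTable":
        return CountTable(
            self.values.copy(),
            self.library_sizes.copy(),
            None if self.feature_meta is None else self.feature_meta.copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        if self.feature_meta is not None:
            out = pd.concat([self.feature_meta, out], axis=1)
        out.index.name = "feature"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        meta_columns: Sequence[str] = (),
        library_sizes: pd.Series | None = None,
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = None
        if meta_columns:
            meta = df[list(meta_columns)]
            df = df.drop(columns=list(meta_columns))
        return cls(df, library_sizes=library_sizes, feature_meta=meta)


@dataclass
class Cluster:
    """Greedy sequence cluster: a virtual-centre sequence plus its members."""

    centre: str
    members: list[str] = field(default_factory=list)
    cardinality: pd.Series | None = None  # per-sample summed read counts


class ClusterSet:
    def __init__(self, clusters: list[Cluster], samples: Sequence[str]):
        self.clusters = clusters
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def membership(self) -> dict[str, str]:
        """Map every member sequence to its cluster centre."""
        out: dict[str, str] = {}
        for c in self.clusters:
            for m in c.members:
                out[m] = c.centre
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for c in self.clusters:
            row = {"centre": c.centre, "n_members": len(c.members)}
            row.update({s: c.cardinality[s] for s in self.samples})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class NormalizationFactors:
    """TMM scaling factors, constrained to geometric mean 1."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")
        log_mean = np.log(self.factors.to_numpy()).mean()
        if abs(log_mean) > 1e-9:
            raise ValueError("scaling factors must have geometric mean 1")

    def effective_library_sizes(self, library_sizes: pd.Series) -> pd.Series:
        return library_sizes * self.factors.reindex(library_sizes.index)

    def to_tsv(self, path: str | Path, library_sizes: pd.Series | None = None) -> None:
        df = pd.DataFrame({"factor": self.factors})
        if library_sizes is not None:
            df["effective_library_size"] = self.effective_library_sizes(library_sizes)
        df.index.name = "sample"
        df.to_csv(path, sep="\t")


class OtuTable:
    """OTU × sample integer counts with a 7-rank lineage per OTU.

    Lineage gaps are encoded with the explicit marker ``unassigned``; sample
    group labels (``case``/``control``) ride along for the group summaries.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        lineage: pd.DataFrame,
        groups: pd.Series,
    ):
        if list(lineage.columns) != list(TAXONOMY_RANKS):
            raise ValueError(
                f"lineage must have exactly the columns {list(TAXONOMY_RANKS)}"
            )
        if not lineage.index.equals(counts.index):
            raise ValueError("lineage and counts must share the same OTU index")
        if (counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        groups = groups.reindex(counts.columns)
        if groups.isna().any():
            missing = list(groups[groups.isna()].index)
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.counts = counts.astype(float)
        self.lineage = lineage.astype(str)
        self.groups = groups

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.lineage, self.counts], axis=1)
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, groups: Mapping[str, str]) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
        if missing:
            raise ValueError(f"OTU table is missing lineage columns: {missing}")
        lineage = df[list(TAXONOMY_RANKS)]
        counts = df.drop(columns=list(TAXONOMY_RANKS))
        return cls(counts, lineage, pd.Series(dict(groups)))
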