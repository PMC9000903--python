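"""Synthetic inputs for every pipeline stage.

The generators emulate the data regimes the analysis assumes: multimapping
read families that share a 20-nt core (so seed-constrained mapping produces
genuine multireads), heterogeneous per-sample reference expression over a
stable shared backbone (the premise of cluster-based normalization),
two-group negative-binomial count tables with spiked log2 effects, and
compositional OTU tables with group-exclusive families.

One root integer seed drives everything; each output type draws from its own
sub-stream (a fixed offset combined with the root seed) so adding one
simulated product never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    TAXONOMY_RANKS,
    UNASSIGNED,
    CountTable,
    OtuTable,
    Reference,
    ReferenceSet,
)

# Fixed sub-stream offsets: one per simulated product.
_STREAM_REFS = 11
_STREAM_READS = 23
_STREAM_COUNTS = 37
_STREAM_OTUS = 53

_BASES = np.array(list("ACGT"))

# Realistic gut-community lineage bank used by the OTU simulator. Genus and
# species are deliberately left unassigned for some families, mirroring the
# rank gaps of marker-gene taxonomy assignment.
_LINEAGE_BANK: list[tuple[str, ...]] = [
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", UNASSIGNED),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", UNASSIGNED),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes", UNASSIGNED),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Barnesiellaceae", "Barnesiella", UNASSIGNED),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae", UNASSIGNED, UNASSIGNED),
    ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Blautia", UNASSIGNED),
    ("Bacteria", "Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae", "Faecalibacterium", UNASSIGNED),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", UNASSIGNED),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", UNASSIGNED),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Dialister", UNASSIGNED),
    ("Bacteria", "Firmicutes", "Negativicutes", "Acidaminococcales", "Acidaminococcaceae", "Phascolarctobacterium", UNASSIGNED),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", UNASSIGNED),
    ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia", UNASSIGNED),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Sutterellaceae", "Sutterella", UNASSIGNED),
    ("Bacteria", "Desulfobacterota", "Desulfovibrionia", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio", UNASSIGNED),
    ("Eukaryota", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Saccharomycetaceae", UNASSIGNED, UNASSIGNED),
    ("Eukaryota", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Debaryomycetaceae", "Candida", UNASSIGNED),
    ("Eukaryota", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Penicillium", UNASSIGNED),
    ("Eukaryota", "Basidiomycota", "Malasseziomycetes", "Malasseziales", "Malasseziaceae", "Malassezia", UNASSIGNED),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with defaults matching its conditions.

    Read lengths span the 15–51 nt window retained after trimming; the cohort
    is 6 cases vs 6 controls; spiked effects default to log2FC 3 on a tenth
    of the features at a base mean of 100 counts, with per-sample sequencing
    depths spread up to 4-fold.
    """

    seed: int = 0
    n_refs: int = 300
    ref_length_range: tuple[int, int] = (15, 51)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"miRNA": 0.2, "piRNA": 0.5, "other": 0.3}
    )
    n_reads_per_sample: int = 5000
    per_base_error_rate: float = 0.001
    multimap_family_sizes: Sequence[int] = (3, 2)
    n_case: int = 6
    n_ctrl: int = 6
    n_features: int = 200
    base_mean: float = 100.0
    de_fraction: float = 0.1
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    libsize_fold_spread: float = 4.0

    def __post_init__(self) -> None:
        lo, hi = self.ref_length_range
        if lo > hi:
            raise ValueError(f"invalid length range: min {lo} > max {hi}")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        mix = dict(self.class_mix)
        if any(not 0.0 <= v <= 1.0 for v in mix.values()):
            raise ValueError("class_mix fractions must be in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_fold_spread < 1:
            raise ValueError("libsize_fold_spread must be >= 1")
        if self.n_refs < 1:
            raise ValueError("n_refs must be >= 1")
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("need at least one case and one control sample")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference_set(cfg: SimulationConfig) -> ReferenceSet:
    """Draw an ncRNA reference universe.

    Multimap families are built first: each family shares one identical
    internal 20-nt core embedded at a random offset, so reads drawn from the
    core align to every family member under the seed rule.
    """
    rng = cfg.rng(_STREAM_REFS)
    lo, hi = cfg.ref_length_range
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes], dtype=float)

    family_total = sum(cfg.multimap_family_sizes)
    if family_total > cfg.n_refs:
        raise ValueError("multimap families require more references than n_refs")

    entries: list[Reference] = []
    idx = 0

    for fam_no, fam_size in enumerate(cfg.multimap_family_sizes):
        core = _random_seq(rng, 20)
        for _ in range(fam_size):
            length = int(rng.integers(max(lo, 24), hi + 1))
            seq = list(_random_seq(rng, length))
            pos = int(rng.integers(0, length - 20 + 1))
            seq[pos : pos + 20] = list(core)
            label = str(rng.choice(classes, p=probs))
            entries.append(Reference(f"ref_{idx:05d}", "".join(seq), label))
            idx += 1

    while idx < cfg.n_refs:
        length = int(rng.integers(lo, hi + 1))
        label = str(rng.choice(classes, p=probs))
        entries.append(Reference(f"ref_{idx:05d}", _random_seq(rng, length), label))
        idx += 1

    return ReferenceSet(entries)


def simulate_reads(
    refs: ReferenceSet,
    abundances: Mapping[str, float],
    cfg: SimulationConfig,
    n_reads: int | None = None,
    stream_salt: int = 0,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Sample reads from references proportional to abundance weights.

    Each read is a contiguous substring of its source molecule (length 15 up
    to the molecule length), with independent per-base substitution errors.
    Returns the reads as (id, sequence) pairs plus the true per-reference
    read counts for recovery tests.
    """
    if len(refs) == 0:
        raise ValueError("cannot simulate reads from an empty reference set")
    weights = np.array([abundances.get(r, 0.0) for r in refs.ids], dtype=float)
    if (weights < 0).any():
        raise ValueError("abundance weights must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("abundance weights must not all be zero")

    rng = np.random.default_rng([_STREAM_READS, stream_salt, cfg.seed])
    n = cfg.n_reads_per_sample if n_reads is None else n_reads
    probs = weights / weights.sum()
    source_idx = rng.choice(len(refs.ids), size=n, p=probs)

    reads: list[tuple[str, str]] = []
    true_counts = pd.Series(0.0, index=pd.Index(refs.ids, name="feature"))
    for i, si in enumerate(source_idx):
        ref = refs.entries[si]
        true_counts.iloc[si] += 1
        max_len = len(ref.sequence)
        read_len = int(rng.integers(min(15, max_len), max_len + 1))
        start = int(rng.integers(0, max_len - read_len + 1))
        seq = np.array(list(ref.sequence[start : start + read_len]))
        if cfg.per_base_error_rate > 0:
            err = rng.random(read_len) < cfg.per_base_error_rate
            if err.any():
                repl = rng.choice(_BASES, size=int(err.sum()))
                # substitution must change the base: shift within the alphabet
                orig = seq[err]
                same = repl == orig
                while same.any():
                    repl[same] = rng.choice(_BASES, size=int(same.sum()))
                    same = repl == orig
                seq[err] = repl
        reads.append((f"read_{i:06d}", "".join(seq)))
    return reads, true_counts


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write reads with a constant quality line (quality is unused downstream)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        reads.append((lines[i][1:].split()[0], lines[i + 1]))
    return reads


def simulate_two_group_counts(
    cfg: SimulationConfig,
) -> tuple[CountTable, pd.Series]:
    """Two-group gamma-Poisson count table with spiked log2 effects.

    A ``de_fraction`` of features carries the effect in case samples, half up
    and half down; per-sample depths vary up to ``libsize_fold_spread``-fold.
    Truth labels are returned per feature: ``up``, ``down`` or ``null``.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    n_feat = cfg.n_features
    features = pd.Index([f"feat_{i:05d}" for i in range(n_feat)], name="feature")
    samples = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i + 1}" for i in range(cfg.n_ctrl)
    ]

    base_means = rng.uniform(0.5 * cfg.base_mean, 2.0 * cfg.base_mean, size=n_feat)

    n_de = int(round(cfg.de_fraction * n_feat))
    de_idx = rng.choice(n_feat, size=n_de, replace=False)
    truth = pd.Series("null", index=features)
    direction = np.ones(n_de)
    direction[1::2] = -1.0
    truth.iloc[de_idx[direction > 0]] = "up"
    truth.iloc[de_idx[direction < 0]] = "down"

    effect = np.zeros(n_feat)
    effect[de_idx] = direction * cfg.effect_log2fc

    depth_factor = rng.uniform(1.0, cfg.libsize_fold_spread, size=len(samples))

    counts = np.empty((n_feat, len(samples)))
    for j, sample in enumerate(samples):
        mean_j = base_means * depth_factor[j]
        if sample.startswith("case_"):
            mean_j = mean_j * np.exp2(effect)
        if cfg.dispersion > 0:
            lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mean_j * cfg.dispersion)
        else:
            lam = mean_j
        counts[:, j] = rng.poisson(lam)

    table = CountTable(pd.DataFrame(counts, index=features, columns=samples))
    return table, truth


def two_group_labels(table: CountTable) -> pd.Series:
    """Group labels implied by the simulated sample naming convention."""
    return pd.Series(
        {
            s: ("case" if str(s).startswith("case_") else "control")
            for s in table.samples
        }
    )


def simulate_otu_table(
    n_otus: int,
    n_samples: int,
    group_assignments: Sequence[str] | Mapping[str, str],
    group_exclusive_families: Mapping[str, str] | None = None,
    seed: int = 0,
    depth: int = 10_000,
    overdispersion: float = 50.0,
) -> OtuTable:
    """Dirichlet-multinomial OTU table with group-exclusive families.

    ``group_exclusive_families`` maps a family name to the single group in
    which it occurs; its OTUs have exactly zero counts in the other group.
    ``overdispersion`` is the Dirichlet concentration: small values give the
    strong compositional sample-to-sample variability typical of stool.
    """
    if isinstance(group_assignments, Mapping):
        samples = list(group_assignments)
        groups = [group_assignments[s] for s in samples]
    else:
        groups = list(group_assignments)
        samples = [f"S{i + 1}" for i in range(len(groups))]
    if len(groups) != n_samples:
        raise ValueError("group_assignments length must equal n_samples")
    bad = set(groups) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")

    exclusive = dict(group_exclusive_families or {})
    bank_families = [lin[4] for lin in _LINEAGE_BANK]
    unknown = sorted(set(exclusive) - set(bank_families))
    if unknown:
        raise ValueError(f"exclusive families not in the lineage bank: {unknown}")
    for fam, grp in exclusive.items():
        if grp not in {"case", "control"}:
            raise ValueError(f"unknown group label for family {fam!r}: {grp!r}")

    rng = np.random.default_rng([_STREAM_OTUS, seed])

    lineage_rows = []
    otu_ids = []
    fam_of_otu = []
    for i in range(n_otus):
        lin = _LINEAGE_BANK[i % len(_LINEAGE_BANK)]
        otu_ids.append(f"OTU_{i + 1:04d}")
        lineage_rows.append(lin)
        fam_of_otu.append(lin[4])
    lineage = pd.DataFrame(
        lineage_rows, index=pd.Index(otu_ids, name="otu_id"), columns=list(TAXONOMY_RANKS)
    )

    base = rng.dirichlet(np.full(n_otus, 0.8))
    counts = np.zeros((n_otus, n_samples))
    for j, grp in enumerate(groups):
        mean = base.copy()
        for fam, keep_grp in exclusive.items():
            if grp != keep_grp:
                mean[[f == fam for f in fam_of_otu]] = 0.0
        if mean.sum() == 0:
            raise ValueError("exclusive-family masking removed every OTU")
        mean = mean / mean.sum()
        pos = mean > 0
        p = rng.dirichlet(mean[pos] * overdispersion)
        counts[pos, j] = rng.multinomial(depth, p)

    table = pd.DataFrame(counts, index=lineage.index, columns=samples)
    return OtuTable(table, lineage, pd.Series(dict(zip(samples, groups))))


def backbone_expression_profiles(
    cfg: SimulationConfig,
    n_shared: int,
    n_private: int,
    n_samples: int,
    shared_scale: float = 100.0,
    private_scale: float = 400.0,
) -> pd.DataFrame:
    """Per-sample reference abundance profiles with a stable shared backbone.

    The first ``n_shared`` references get correlated abundances across all
    samples (the backbone that cluster cardinalities are expected to expose);
    each sample additionally expresses its own private block of
    ``n_private`` references at high level, emulating the heterogeneous
    individual expression the normalization has to survive.
    """
    rng = cfg.rng(_STREAM_READS)
    n_refs = n_shared + n_private * n_samples
    profiles = np.zeros((n_refs, n_samples))
    shared = rng.gamma(shape=2.0, scale=shared_scale / 2.0, size=n_shared)
    for j in range(n_samples):
        jitter = rng.lognormal(mean=0.0, sigma=0.15, size=n_shared)
        profiles[:n_shared, j] = shared * jitter
        start = n_shared + j * n_private
        profiles[start : start + n_private, j] = rng.gamma(
            shape=2.0, scale=private_scale / 2.0, size=n_private
        )
    index = pd.Index([f"ref_{i:05d}" for i in range(n_refs)], name="feature")
    return pd.DataFrame(profiles, index=index, columns=[f"S{j + 1}" for j in range(n_samples)])


def write_truth(truth: pd.Series, path: str | Path, value_name: str = "truth") -> None:
    truth.rename(value_name).to_csv(path, sep="\t", header=True)
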