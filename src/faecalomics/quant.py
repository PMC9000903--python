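"""Small-RNA read mapping and EM multiread resolution.

Reads are length-filtered (15–51 nt, the post-trimming window), aligned
ungapped to the ncRNA reference allowing at most one mismatch in the
leftmost 20 nt of the read, and multireads are resolved by an
expectation-maximization allocation: each read's unit mass is split across
its candidate references in proportion to the current abundance estimates
until the expected counts stabilise.

Candidate alignment positions come from a k-mer seed index; by pigeonhole,
a read whose leftmost 20 nt carry at most one mismatch must contain at
least one exact 10-mer in that window, so the index lookup is lossless.
Reads too short for two disjoint k-mers fall back to an exhaustive scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountTable, ReferenceSet

logger = logging.getLogger(__name__)

Read = tuple[str, str]  # (read id, sequence)

SEED_REGION = 20


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    offset: int  # 0-based position of the read start on the reference
    seed_mismatches: int
    total_mismatches: int


def filter_reads(
    reads: Iterable[Read], min_len: int = 15, max_len: int = 51
) -> list[Read]:
    """Keep reads whose length lies in [min_len, max_len], inclusive."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    reads = list(reads)
    kept = [r for r in reads if min_len <= len(r[1]) <= max_len]
    logger.info("length filter: kept %d of %d reads", len(kept), len(reads))
    return kept


class SeedIndex:
    """Exact k-mer index over the reference sequences."""

    def __init__(self, refs: ReferenceSet, kmer: int = 10):
        if kmer > SEED_REGION:
            raise ValueError(f"kmer must be <= {SEED_REGION}")
        if kmer < 1:
            raise ValueError("kmer must be >= 1")
        self.kmer = kmer
        self.refs = refs
        self._table: dict[str, list[tuple[str, int]]] = {}
        for ref in refs:
            seq = ref.sequence
            for off in range(len(seq) - kmer + 1):
                self._table.setdefault(seq[off : off + kmer], []).append(
                    (ref.id, off)
                )

    def lookup(self, kmer_seq: str) -> list[tuple[str, int]]:
        return self._table.get(kmer_seq, [])

    def __len__(self) -> int:
        return len(self._table)


def build_index(refs: ReferenceSet, kmer: int = 10) -> SeedIndex:
    return SeedIndex(refs, kmer=kmer)


def _score_placement(
    read_seq: str, ref_seq: str, offset: int, seed_len: int
) -> tuple[int, int] | None:
    """Mismatch counts for an ungapped placement fully inside the reference."""
    if offset < 0 or offset + len(read_seq) > len(ref_seq):
        return None
    seed_mm = 0
    total_mm = 0
    for i, base in enumerate(read_seq):
        if base != ref_seq[offset + i]:
            total_mm += 1
            if i < seed_len:
                seed_mm += 1
    return seed_mm, total_mm


def align_read(
    read: Read,
    index: SeedIndex,
    refs: ReferenceSet,
    max_seed_mm: int = 1,
    max_total_mm: int | None = None,
) -> list[AlignmentHit]:
    """All qualifying ungapped forward-strand placements of one read.

    A placement qualifies when the read fits fully inside the reference with
    at most ``max_seed_mm`` mismatches in its leftmost min(20, read length)
    nt; mismatches beyond the seed are unlimited unless ``max_total_mm`` is
    set. Reads with non-ACGT symbols are skipped with a warning.
    """
    read_id, seq = read
    if set(seq) - set("ACGT"):
        logger.warning("read %s contains non-ACGT symbols; skipped", read_id)
        return []
    seed_len = min(SEED_REGION, len(seq))
    k = index.kmer

    candidates: set[tuple[str, int]] = set()
    n_probes = max_seed_mm + 1
    if n_probes * k <= seed_len:
        # pigeonhole: one of these disjoint k-mers inside the seed is exact
        for p in range(n_probes):
            kpos = p * k
            for ref_id, occ in index.lookup(seq[kpos : kpos + k]):
                candidates.add((ref_id, occ - kpos))
    else:
        for ref in refs:
            for off in range(len(ref.sequence) - len(seq) + 1):
                candidates.add((ref.id, off))

    hits = []
    for ref_id, offset in candidates:
        scored = _score_placement(seq, refs[ref_id].sequence, offset, seed_len)
        if scored is None:
            continue
        seed_mm, total_mm = scored
        if seed_mm > max_seed_mm:
            continue
        if max_total_mm is not None and total_mm > max_total_mm:
            continue
        hits.append(AlignmentHit(read_id, ref_id, offset, seed_mm, total_mm))
    hits.sort(key=lambda h: (h.ref_id, h.offset))
    return hits


def em_allocate(
    read_refs: Mapping[str, Sequence[str]],
    refs: ReferenceSet,
    tol: float = 1e-8,
    max_iter: int = 200,
    trace: bool = False,
) -> pd.Series | tuple[pd.Series, list[np.ndarray]]:
    """Expected read counts per reference from the multiread EM.

    ``read_refs`` maps each aligned read to its candidate references. Reads
    with identical candidate sets are collapsed into equivalence classes, so
    the E-step splits class mass proportionally to the current abundances
    and the M-step sums assigned mass. Iterates from a uniform start until
    the largest absolute change in expected counts is below ``tol`` (or
    ``max_iter``); the returned counts sum exactly to the number of reads.
    """
    ref_ids = refs.ids
    ref_pos = {r: i for i, r in enumerate(ref_ids)}
    classes: dict[frozenset[int], int] = {}
    for read_id, cand in read_refs.items():
        if not cand:
            raise ValueError(f"read {read_id} reached EM with no candidates")
        key = frozenset(ref_pos[r] for r in cand)
        classes[key] = classes.get(key, 0) + 1

    n_reads = sum(classes.values())
    counts = np.zeros(len(ref_ids))
    history: list[np.ndarray] = []
    if n_reads == 0:
        empty = pd.Series(counts, index=pd.Index(ref_ids, name="feature"))
        return (empty, history) if trace else empty

    class_members = [np.fromiter(key, dtype=int) for key in classes]
    class_sizes = np.array(list(classes.values()), dtype=float)

    active = np.unique(np.concatenate(class_members))
    theta = np.zeros(len(ref_ids))
    theta[active] = 1.0 / len(active)

    counts = np.zeros(len(ref_ids))
    for _ in range(max_iter):
        new_counts = np.zeros(len(ref_ids))
        for members, size in zip(class_members, class_sizes):
            w = theta[members]
            total = w.sum()
            if total <= 0:
                w = np.full(len(members), 1.0 / len(members))
            else:
                w = w / total
            new_counts[members] += size * w
        if trace:
            history.append(new_counts.copy())
        delta = np.abs(new_counts - counts).max()
        counts = new_counts
        theta = counts / n_reads
        if delta < tol:
            break

    out = pd.Series(counts, index=pd.Index(ref_ids, name="feature"))
    return (out, history) if trace else out


def quantify_sample(
    reads: Iterable[Read],
    refs: ReferenceSet,
    index: SeedIndex | None = None,
    min_len: int = 15,
    max_len: int = 51,
    max_seed_mm: int = 1,
    max_total_mm: int | None = None,
    kmer: int = 10,
) -> tuple[pd.Series, dict]:
    """Filter, align and EM-allocate one sample's reads.

    Returns the expected counts per reference together with run statistics:
    the aligned-read count (the library size) and per-class count totals.
    """
    if index is None:
        index = build_index(refs, kmer=kmer)
    kept = filter_reads(reads, min_len=min_len, max_len=max_len)

    read_refs: dict[str, list[str]] = {}
    for read in kept:
        hits = align_read(read, index, refs, max_seed_mm=max_seed_mm,
                          max_total_mm=max_total_mm)
        if hits:
            read_refs[read[0]] = sorted({h.ref_id for h in hits})

    if not read_refs:
        logger.warning("no reads aligned; returning an empty column")
        counts = pd.Series(0.0, index=pd.Index(refs.ids, name="feature"))
    else:
        counts = em_allocate(read_refs, refs)

    classes = refs.classes()
    class_totals = counts.groupby(classes).sum().to_dict()
    info = {
        "n_input": len(list(kept)),
        "n_aligned": len(read_refs),
        "library_size": float(counts.sum()),
        "class_totals": class_totals,
    }
    logger.info(
        "quantified sample: %d aligned reads; class totals %s",
        info["n_aligned"], class_totals,
    )
    return counts, info


def quantify_samples(
    sample_reads: Mapping[str, Iterable[Read]],
    refs: ReferenceSet,
    **kwargs,
) -> CountTable:
    """Quantify several samples against one shared index."""
    index = build_index(refs, kmer=kwargs.pop("kmer", 10))
    columns = {}
    libsizes = {}
    for sample, reads in sample_reads.items():
        counts, info = quantify_sample(reads, refs, index=index, **kwargs)
        columns[sample] = counts
        libsizes[sample] = info["library_size"]
    values = pd.DataFrame(columns)
    meta = refs.classes().reindex(values.index).to_frame()
    return CountTable(values, pd.Series(libsizes), feature_meta=meta)
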