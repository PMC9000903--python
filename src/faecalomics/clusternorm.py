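"""Cluster-cardinality TMM normalization.

Faecal small-RNA libraries show strong per-reference expression
heterogeneity between individuals, which breaks scaling methods applied to
the reference counts directly. The workaround implemented here clusters the
observed sequences greedily (members may differ from their cluster's
virtual-centre sequence by up to three substitutions and three overhanging
residues), computes per-sample cluster cardinalities — which are far more
stable across samples — derives trimmed-mean-of-M-values (TMM) scaling
factors from the cluster table, and applies those factors to the reference
count table.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Cluster, ClusterSet, CountTable, NormalizationFactors

logger = logging.getLogger(__name__)


def sequences_match(
    member: str,
    centre: str,
    max_mismatch: int = 3,
    max_overhang: int = 3,
    per_end: bool = False,
) -> bool:
    """Whether ``member`` fits ``centre`` under the mismatch/overhang rule.

    The member is slid along the centre at every ungapped shift; at each
    shift the unaligned residues at the two ends (summed over both
    sequences) form the overhang and mismatches are counted over the
    overlap. With ``per_end`` the overhang cap applies to each end
    separately instead of to the total.
    """
    len_m, len_c = len(member), len(centre)
    for shift in range(-(len_m - 1), len_c):
        lo = max(0, shift)
        hi = min(len_c, shift + len_m)
        overlap = hi - lo
        if overlap <= 0:
            continue
        left = abs(shift)
        right = abs(shift + len_m - len_c)
        if per_end:
            if max(left, right) > max_overhang:
                continue
        elif left + right > max_overhang:
            continue
        mm = 0
        for i in range(overlap):
            if member[i + lo - shift] != centre[lo + i]:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return True
    return False


def greedy_cluster(
    seq_abundances: pd.DataFrame,
    max_mismatch: int = 3,
    max_overhang: int = 3,
    per_end: bool = False,
) -> ClusterSet:
    """Greedy single-pass clustering of observed sequences.

    ``seq_abundances`` has one row per unique sequence (the index) and one
    per-sample read-count column. Sequences are processed in decreasing
    total-abundance order (ties broken lexicographically, so the partition
    is deterministic and independent of input record order); each sequence
    joins the first existing cluster whose centre it matches, otherwise it
    founds a new cluster with itself as centre.
    """
    if len(seq_abundances) == 0:
        return ClusterSet([], list(seq_abundances.columns))
    if seq_abundances.index.has_duplicates:
        seq_abundances = seq_abundances.groupby(level=0).sum()

    totals = seq_abundances.sum(axis=1)
    order = sorted(seq_abundances.index, key=lambda s: (-totals[s], s))

    clusters: list[Cluster] = []
    for seq in order:
        placed = False
        for cl in clusters:
            if sequences_match(seq, cl.centre, max_mismatch, max_overhang, per_end):
                cl.members.append(seq)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centre=seq, members=[seq]))

    samples = list(seq_abundances.columns)
    for cl in clusters:
        cl.cardinality = seq_abundances.loc[cl.members].sum(axis=0)
    logger.info("clustered %d sequences into %d clusters", len(order), len(clusters))
    return ClusterSet(clusters, samples)


def cluster_count_table(
    clusters: ClusterSet,
) -> tuple[CountTable, pd.DataFrame]:
    """Cluster cardinality table plus its between-sample Spearman matrix.

    The correlation matrix is the stability diagnostic motivating the
    method: cluster cardinalities correlate better across samples than raw
    per-reference counts do.
    """
    if len(clusters) < 1:
        raise ValueError("need at least one cluster")
    values = pd.DataFrame(
        {cl.centre: cl.cardinality for cl in clusters}
    ).T
    values.index.name = "centre"
    values = values[clusters.samples]
    table = CountTable(values)

    if len(clusters.samples) < 2:
        logger.warning("single sample: correlation matrix is empty")
        corr = pd.DataFrame(index=clusters.samples, columns=clusters.samples, dtype=float)
        return table, corr

    corr = values.corr(method="spearman")
    return table, corr


def mean_intersample_correlation(counts: pd.DataFrame) -> float:
    """Mean off-diagonal Spearman correlation between sample columns."""
    rho = counts.corr(method="spearman").to_numpy()
    n = rho.shape[0]
    off = rho[~np.eye(n, dtype=bool)]
    return float(off.mean())


def _upper_quartile_reference(values: np.ndarray, libsizes: np.ndarray) -> int:
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        pos = col[col > 0] / libsizes[j]
        uq[j] = np.percentile(pos, 75) if len(pos) else 0.0
    return int(np.argmin(np.abs(uq - uq.mean())))


def _doubly_trimmed_keep(
    m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float
) -> np.ndarray:
    """Boolean mask keeping features inside both trimmed ranks.

    Ranks come from a stable argsort, so ties are broken by position and
    the trim is reproducible.
    """
    n = len(m)
    keep = np.ones(n, dtype=bool)
    for arr, frac in ((m, trim_m), (a, trim_a)):
        cut = int(np.floor(n * frac))
        order = np.argsort(arr, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        keep &= (ranks >= cut) & (ranks < n - cut)
    return keep


def tmm_factors(
    counts: CountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper quartile of positive
    count proportions is closest to the mean upper quartile. For every
    other sample, per-feature log ratios M and mean log abundances A are
    computed over features positive in both, the extremes are doubly
    trimmed (30% on M, 5% on A by default), and the scaling factor is 2 to
    the precision-weighted mean of the surviving M values, the weights
    being inverse asymptotic binomial variances. Factors are finally
    rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (counts.library_sizes <= 0).any():
        bad = list(counts.library_sizes[counts.library_sizes <= 0].index)
        raise ValueError(f"samples with non-positive library size: {bad}")

    values = counts.values.to_numpy(dtype=float)
    libsizes = counts.library_sizes.to_numpy(dtype=float)
    samples = list(counts.samples)
    r = _upper_quartile_reference(values, libsizes)

    y_r = values[:, r]
    n_r = libsizes[r]
    log_factors = np.zeros(len(samples))
    for s in range(len(samples)):
        if s == r:
            continue
        y_s = values[:, s]
        n_s = libsizes[s]
        both = (y_s > 0) & (y_r > 0)
        if not both.any():
            logger.warning(
                "sample %s shares no positive features with the reference; factor 1",
                samples[s],
            )
            continue
        ps = y_s[both] / n_s
        pr = y_r[both] / n_r
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        keep = _doubly_trimmed_keep(m, a, trim_m, trim_a)
        if not keep.any():
            logger.warning("trimming removed every feature for sample %s", samples[s])
            continue
        w = 1.0 / (
            (n_s - y_s[both]) / (n_s * y_s[both])
            + (n_r - y_r[both]) / (n_r * y_r[both])
        )
        log_factors[s] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])

    log_factors -= log_factors.mean()  # geometric mean 1
    factors = pd.Series(np.exp2(log_factors), index=pd.Index(samples, name="sample"))
    return NormalizationFactors(factors=factors, reference_sample=samples[r])


def apply_factors(
    ref_counts: CountTable,
    factors: NormalizationFactors,
) -> CountTable:
    """Scale reference counts by effective library size.

    Each value becomes raw / (library size × factor) × mean effective
    library size, i.e. counts per effective library rescaled to a common
    depth so magnitudes stay comparable to raw counts. The output table's
    ``library_sizes`` hold that common depth (the proper denominator for
    downstream count tests on the normalized scale) and the per-sample
    effective library sizes are attached as ``effective_library_sizes``.
    """
    missing = [s for s in ref_counts.samples if s not in factors.factors.index]
    if missing:
        raise ValueError(f"no scaling factor for samples: {missing}")
    eff = factors.effective_library_sizes(ref_counts.library_sizes)
    mean_eff = float(eff.mean())
    values = ref_counts.values.div(eff, axis=1) * mean_eff
    out = CountTable(
        values,
        library_sizes=pd.Series(mean_eff, index=ref_counts.samples),
        feature_meta=ref_counts.feature_meta,
    )
    out.effective_library_sizes = eff
    return out
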