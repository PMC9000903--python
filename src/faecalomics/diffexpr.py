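"""Per-sample differential expression of normalized sncRNA counts.

Each case sample is compared either to the pooled control collection or to
its sibling control. Effect sizes are pseudocount-1 log2 fold changes,
log2((a + 1)/(b + 1)); evidence is a two-sided Fisher exact test on the
2×2 table of feature count versus remainder of the library in each group,
with Benjamini–Hochberg correction across the features of a comparison. A
feature is called significant when |log2FC| ≥ 1 and the Fisher p-value is
below 0.05 (both thresholds configurable), and every feature is also
assigned a presence category: detected in both members of the comparison
or exclusively in one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountTable


@dataclass
class DeConfig:
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")


@dataclass
class DiffRecord:
    feature: str
    group_a_value: float
    group_b_value: float
    log2fc: float
    p_value: float
    fdr: float
    significant: bool
    presence: str  # common / only_a / only_b / absent


def log2fc_pseudo(a: float, b: float, pseudocount: float = 1.0) -> float:
    """log2((a + pseudocount)/(b + pseudocount)) on normalized counts."""
    if a < 0 or b < 0:
        raise ValueError("normalized counts must be non-negative")
    return math.log2((a + pseudocount) / (b + pseudocount))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fisher_count_test(
    count_a: float, libsize_a: float, count_b: float, libsize_b: float
) -> float:
    """Two-sided Fisher exact p for one feature's count in two libraries.

    The 2×2 table is [[count_a, libsize_a − count_a],
    [count_b, libsize_b − count_b]] with fractional normalized counts
    rounded half-up to integers. Two-sidedness follows the point-probability
    rule: the sum of probabilities of all tables at the observed margins no
    more likely than the observed one.
    """
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a > libsize_a or count_b > libsize_b:
        raise ValueError("count exceeds its library size")
    a = int(round_half_up(count_a))
    b = int(round_half_up(libsize_a - count_a))
    c = int(round_half_up(count_b))
    d = int(round_half_up(libsize_b - count_b))
    # two-sided point-probability rule on the conditional (hypergeometric)
    # distribution of the top-left cell at fixed margins
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    # the full-support sum is exactly 1 up to float accumulation error
    return 1.0 if p > 1.0 - 1e-9 else p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _presence(a: float, b: float) -> str:
    if a > 0 and b > 0:
        return "common"
    if a > 0:
        return "only_a"
    if b > 0:
        return "only_b"
    return "absent"


def _build_records(
    features: Sequence[str],
    a_vals: np.ndarray,
    b_vals: np.ndarray,
    lib_a: float,
    lib_b: float,
    cfg: DeConfig,
) -> list[DiffRecord]:
    lfcs = np.empty(len(features))
    pvals = np.empty(len(features))
    for i in range(len(features)):
        a, b = float(a_vals[i]), float(b_vals[i])
        if a == 0 and b == 0:
            lfcs[i], pvals[i] = 0.0, 1.0
        else:
            lfcs[i] = log2fc_pseudo(a, b, cfg.pseudocount)
            pvals[i] = fisher_count_test(a, lib_a, b, lib_b)
    fdrs = bh_adjust(pvals)
    records = []
    for i, feat in enumerate(features):
        a, b = float(a_vals[i]), float(b_vals[i])
        sig = bool(abs(lfcs[i]) >= cfg.lfc_threshold and pvals[i] < cfg.alpha)
        records.append(
            DiffRecord(
                feature=feat,
                group_a_value=a,
                group_b_value=b,
                log2fc=float(lfcs[i]),
                p_value=float(pvals[i]),
                fdr=float(fdrs[i]),
                significant=sig,
                presence=_presence(a, b),
            )
        )
    return records


def per_sample_de(
    norm_counts: CountTable,
    case_sample: str,
    ctrl_samples: Sequence[str],
    cfg: DeConfig | None = None,
) -> list[DiffRecord]:
    """One case sample against the pooled control collection.

    The control value reported per feature is the mean normalized count
    across the controls; the Fisher table pools the control counts (and
    their library sizes), so the pooled column keeps each control's weight.
    """
    cfg = cfg or DeConfig()
    ctrl_samples = list(ctrl_samples)
    if not ctrl_samples:
        raise ValueError("need at least one control sample")
    if case_sample in ctrl_samples:
        raise ValueError(f"case sample {case_sample!r} is also listed as control")
    for s in [case_sample, *ctrl_samples]:
        if s not in norm_counts.samples:
            raise ValueError(f"unknown sample id: {s!r}")

    a_vals = norm_counts.values[case_sample].to_numpy()
    ctrl_block = norm_counts.values[ctrl_samples]
    pooled = ctrl_block.sum(axis=1).to_numpy()
    b_means = ctrl_block.mean(axis=1).to_numpy()
    lib_a = float(norm_counts.library_sizes[case_sample])
    lib_b = float(norm_counts.library_sizes[ctrl_samples].sum())

    features = list(norm_counts.features)
    records = []
    lfcs = np.empty(len(features))
    pvals = np.empty(len(features))
    for i in range(len(features)):
        a, pool, bm = float(a_vals[i]), float(pooled[i]), float(b_means[i])
        if a == 0 and pool == 0:
            lfcs[i], pvals[i] = 0.0, 1.0
        else:
            lfcs[i] = log2fc_pseudo(a, bm, cfg.pseudocount)
            pvals[i] = fisher_count_test(a, lib_a, pool, lib_b)
    fdrs = bh_adjust(pvals)
    for i, feat in enumerate(features):
        a, bm = float(a_vals[i]), float(b_means[i])
        sig = bool(abs(lfcs[i]) >= cfg.lfc_threshold and pvals[i] < cfg.alpha)
        records.append(
            DiffRecord(feat, a, bm, float(lfcs[i]), float(pvals[i]),
                       float(fdrs[i]), sig, _presence(a, bm))
        )
    return records


def sibling_compare(
    norm_counts: CountTable,
    asd_sample: str,
    ctrl_sample: str,
    cfg: DeConfig | None = None,
) -> tuple[list[DiffRecord], pd.DataFrame]:
    """Case versus its sibling control, with a per-class summary.

    The summary counts, per ncRNA class, the features detected in both
    samples (with how many are significantly up/down in the case) and the
    features detected exclusively in one sample — the layout used for
    sibling-pair reporting.
    """
    cfg = cfg or DeConfig()
    if asd_sample == ctrl_sample:
        raise ValueError("sibling comparison needs two distinct samples")
    for s in (asd_sample, ctrl_sample):
        if s not in norm_counts.samples:
            raise ValueError(f"unknown sample id: {s!r}")

    records = _build_records(
        list(norm_counts.features),
        norm_counts.values[asd_sample].to_numpy(),
        norm_counts.values[ctrl_sample].to_numpy(),
        float(norm_counts.library_sizes[asd_sample]),
        float(norm_counts.library_sizes[ctrl_sample]),
        cfg,
    )

    if norm_counts.feature_meta is not None and "ncrna_class" in norm_counts.feature_meta:
        classes = norm_counts.feature_meta["ncrna_class"]
    else:
        classes = pd.Series("all", index=norm_counts.features)

    rows = {}
    for cls in sorted(classes.unique()):
        feats = set(classes[classes == cls].index)
        recs = [r for r in records if r.feature in feats]
        common = [r for r in recs if r.presence == "common"]
        only_a = [r for r in recs if r.presence == "only_a"]
        only_b = [r for r in recs if r.presence == "only_b"]
        rows[cls] = {
            "common_total": len(common),
            "common_significant": sum(r.significant for r in common),
            "common_sig_up": sum(r.significant and r.log2fc > 0 for r in common),
            "common_sig_down": sum(r.significant and r.log2fc < 0 for r in common),
            "only_asd": len(only_a),
            "only_asd_significant": sum(r.significant for r in only_a),
            "only_ctrl": len(only_b),
            "only_ctrl_significant": sum(r.significant for r in only_b),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "ncrna_class"
    return records, summary


def cross_couple_common(
    couple_results: Mapping[str, Sequence[DiffRecord]],
) -> dict[str, list[str]]:
    """Features significant in every comparison with a consistent sign."""
    if len(couple_results) < 2:
        raise ValueError("need results from at least two sibling comparisons")
    up_sets, down_sets = [], []
    for records in couple_results.values():
        up_sets.append({r.feature for r in records if r.significant and r.log2fc > 0})
        down_sets.append({r.feature for r in records if r.significant and r.log2fc < 0})
    common_up = set.intersection(*up_sets)
    common_down = set.intersection(*down_sets)
    return {"up": sorted(common_up), "down": sorted(common_down)}


def records_to_frame(records: Sequence[DiffRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.set_index("feature")


def load_published_sibling_counts() -> pd.DataFrame:
    """Published normalized count pairs for two sibling couples.

    Reference values for the ncRNAs reported as concordantly dysregulated
    in both sibling pairs of a faecal small-RNA study: per couple, the
    normalized ASD and control counts, the reported log2 fold change
    (2 decimals) and the reported Fisher p-value. Used to validate the
    fold-change computation against an external result.
    """
    path = resources.files("faecalomics").joinpath("data/sibling_couple_counts.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
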