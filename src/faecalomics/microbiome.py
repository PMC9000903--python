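"""OTU table summaries: rank aggregation, relative abundance, alpha
diversity, phylum ratios and group prevalence partitions.

Conventions follow the common marker-gene ecology defaults: Shannon in
natural log, Simpson as 1 − Σp² (both on per-sample relative abundances),
group-level abundances as means of member-sample fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skbio_alpha

from .containers import TAXONOMY_RANKS, UNASSIGNED, CountTable, OtuTable

logger = logging.getLogger(__name__)


def aggregate_rank(table: OtuTable, rank: str) -> CountTable:
    """Sum OTU counts over the taxon name at ``rank``.

    OTUs unassigned at that rank are pooled under ``unassigned_<parent>``
    keyed by their deepest assigned ancestor, so aggregation conserves the
    per-sample totals exactly.
    """
    if rank not in TAXONOMY_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {list(TAXONOMY_RANKS)}")
    depth = TAXONOMY_RANKS.index(rank)

    def taxon_for(otu: str) -> str:
        lineage = table.lineage.loc[otu]
        name = lineage.iloc[depth]
        if name != UNASSIGNED:
            return name
        parent = "root"
        for d in range(depth - 1, -1, -1):
            if lineage.iloc[d] != UNASSIGNED:
                parent = lineage.iloc[d]
                break
        return f"{UNASSIGNED}_{parent}"

    taxa = pd.Series({otu: taxon_for(otu) for otu in table.counts.index})
    agg = table.counts.groupby(taxa).sum()
    agg.index.name = rank
    return CountTable(agg)


def relative_abundance(table: CountTable | OtuTable) -> pd.DataFrame:
    """Per-sample fractions; every column sums to 1."""
    counts = table.counts if isinstance(table, OtuTable) else table.values
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    return counts.div(totals, axis=1)


def group_mean_abundance(fractions: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group-level abundance as the mean of member-sample fractions."""
    out = {}
    for grp in sorted(groups.unique()):
        members = list(groups[groups == grp].index)
        out[grp] = fractions[members].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class DiversityResult:
    per_sample: pd.DataFrame  # columns: observed_otus, shannon, simpson

    def __getitem__(self, sample: str) -> pd.Series:
        return self.per_sample.loc[sample]


def alpha_diversity(
    table: CountTable | OtuTable,
    inverse_simpson: bool = False,
) -> DiversityResult:
    """Observed richness, Shannon entropy (natural log) and Simpson index.

    Simpson defaults to 1 − Σp² (a probability in [0, 1]); the inverse
    Simpson 1/Σp² is available behind the flag.
    """
    counts = table.counts if isinstance(table, OtuTable) else table.values
    rows = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        if col.sum() <= 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        observed = int((col > 0).sum())
        shannon = float(skbio_alpha.shannon(col, base=np.e))
        if inverse_simpson:
            simpson = float(skbio_alpha.enspie(col.astype(int)))
        else:
            simpson = float(skbio_alpha.simpson(col))
        rows[sample] = {
            "observed_otus": observed,
            "shannon": shannon,
            "simpson": simpson,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return DiversityResult(df)


def taxon_ratio(
    table: OtuTable,
    numerator_taxon: str,
    denominator_taxon: str,
    rank: str = "Phylum",
) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-group ratio of two taxa's relative abundances.

    The group ratio is the mean of the member samples' ratios; samples with
    a zero denominator are excluded from the group mean with a warning.
    """
    agg = aggregate_rank(table, rank)
    for taxon in (numerator_taxon, denominator_taxon):
        if taxon not in agg.values.index:
            raise ValueError(f"taxon {taxon!r} absent at rank {rank}")
    frac = relative_abundance(agg)
    num = frac.loc[numerator_taxon]
    den = frac.loc[denominator_taxon]
    ratios = pd.Series(np.nan, index=frac.columns, name="ratio")
    usable = den > 0
    if (~usable).any():
        logger.warning(
            "zero %s abundance in samples %s; excluded from group ratios",
            denominator_taxon, list(frac.columns[~usable]),
        )
    ratios[usable] = num[usable] / den[usable]

    group_ratio = {}
    for grp in sorted(table.groups.unique()):
        members = [s for s in table.group_samples(grp) if usable[s]]
        group_ratio[grp] = float(ratios[members].mean()) if members else float("nan")
    return ratios, pd.Series(group_ratio, name="group_ratio")


def prevalence_partition(
    table: OtuTable,
    presence_threshold: float = 0.5,
    detection_floor: float = 1e-4,
    rank: str = "Family",
) -> dict[str, list[str]]:
    """Partition taxa at ``rank`` by group prevalence.

    A taxon is present in a group when more than ``presence_threshold`` of
    the group's samples carry it above ``detection_floor`` relative
    abundance. Returns alphabetical lists under ``both``, ``case_only``,
    ``control_only`` and ``neither``.
    """
    for grp in ("case", "control"):
        if not table.group_samples(grp):
            raise ValueError(f"group {grp!r} has no samples")
    agg = aggregate_rank(table, rank)
    frac = relative_abundance(agg)

    present: dict[str, dict[str, bool]] = {}
    for grp in ("case", "control"):
        members = table.group_samples(grp)
        detected = (frac[members] > detection_floor).sum(axis=1) / len(members)
        present[grp] = (detected > presence_threshold).to_dict()

    partition: dict[str, list[str]] = {
        "both": [], "case_only": [], "control_only": [], "neither": []
    }
    for taxon in sorted(frac.index):
        in_case = present["case"][taxon]
        in_ctrl = present["control"][taxon]
        if in_case and in_ctrl:
            partition["both"].append(taxon)
        elif in_case:
            partition["case_only"].append(taxon)
        elif in_ctrl:
            partition["control_only"].append(taxon)
        else:
            partition["neither"].append(taxon)
    return partition
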