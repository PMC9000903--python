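"""Pipeline orchestration: declarative run configuration, staged execution,
and a one-shot synthetic demo dataset.

A run is described by a single YAML file (paths, sample sheet with group
and optional sibling-couple labels, and the stage parameters). Stages are
stateless: each reads its inputs from the output directory of the previous
stage and writes TSVs, so any stage can be re-run in isolation, and a full
run finishes by writing a manifest with parameters and file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clusternorm, diffexpr, microbiome, quant, synthetic, targets
from .containers import CountTable, OtuTable, ReferenceSet

logger = logging.getLogger(__name__)

STAGES = ("quantify", "cluster", "diff", "targets", "microbiome")


@dataclass
class SampleSheetEntry:
    id: str
    group: str  # case / control
    fastq: str
    couple: str | None = None


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    reference_fasta: Path
    samples: list[SampleSheetEntry]
    otu_table: Path | None = None
    target_maps: Mapping[str, Path] = field(default_factory=dict)
    gene_sets: Sequence[Path] = ()
    de: diffexpr.DeConfig = field(default_factory=diffexpr.DeConfig)
    cluster_params: Mapping[str, float] = field(
        default_factory=lambda: {"max_mismatch": 3, "max_overhang": 3}
    )
    tmm_params: Mapping[str, float] = field(
        default_factory=lambda: {"trim_m": 0.30, "trim_a": 0.05}
    )
    inverse_simpson: bool = False
    target_direction: str = "up"
    min_target_samples: int = 3
    phylum_ratio: tuple[str, str] = ("Bacteroidetes", "Firmicutes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _p(value: str) -> Path:
            p = Path(value)
            return p if p.is_absolute() else base / p

        samples = [
            SampleSheetEntry(
                id=s["id"], group=s["group"], fastq=str(_p(s["fastq"])),
                couple=s.get("couple"),
            )
            for s in raw["samples"]
        ]
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=_p(raw.get("output_dir", "results")),
            reference_fasta=_p(raw["reference_fasta"]),
            samples=samples,
            otu_table=_p(raw["otu_table"]) if raw.get("otu_table") else None,
            target_maps={k: _p(v) for k, v in raw.get("target_maps", {}).items()},
            gene_sets=[_p(v) for v in raw.get("gene_sets", [])],
            de=diffexpr.DeConfig(**raw.get("de", {})),
            cluster_params=raw.get("cluster", {"max_mismatch": 3, "max_overhang": 3}),
            tmm_params=raw.get("tmm", {"trim_m": 0.30, "trim_a": 0.05}),
            inverse_simpson=bool(raw.get("inverse_simpson", False)),
            target_direction=raw.get("target_direction", "up"),
            min_target_samples=int(raw.get("min_target_samples", 3)),
            phylum_ratio=tuple(raw.get("phylum_ratio", ("Bacteroidetes", "Firmicutes"))),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        for s in self.samples:
            if s.group not in {"case", "control"}:
                raise ValueError(f"sample {s.id}: unknown group {s.group!r}")
            if not Path(s.fastq).exists():
                raise FileNotFoundError(f"sample {s.id}: missing FASTQ {s.fastq}")
        if not Path(self.reference_fasta).exists():
            raise FileNotFoundError(f"missing reference FASTA {self.reference_fasta}")
        if self.otu_table is not None and not Path(self.otu_table).exists():
            raise FileNotFoundError(f"missing OTU table {self.otu_table}")
        for cls_name, path in self.target_maps.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing {cls_name} target map {path}")
        for path in self.gene_sets:
            if not Path(path).exists():
                raise FileNotFoundError(f"missing gene-set file {path}")
        for couple, members in self.couples().items():
            groups = sorted(m.group for m in members)
            if groups != ["case", "control"]:
                raise ValueError(
                    f"couple {couple!r} must have exactly one case and one control"
                )

    def couples(self) -> dict[str, list[SampleSheetEntry]]:
        out: dict[str, list[SampleSheetEntry]] = {}
        for s in self.samples:
            if s.couple:
                out.setdefault(s.couple, []).append(s)
        return out

    def case_samples(self) -> list[str]:
        return [s.id for s in self.samples if s.group == "case"]

    def control_samples(self) -> list[str]:
        return [s.id for s in self.samples if s.group == "control"]


# ---------------------------------------------------------------- stages


def _stage_quantify(cfg: RunConfig) -> None:
    refs = ReferenceSet.from_fasta(cfg.reference_fasta)
    sample_reads = {
        s.id: synthetic.read_fastq(s.fastq) for s in cfg.samples
    }
    table = quant.quantify_samples(sample_reads, refs)
    table.to_tsv(cfg.output_dir / "reference_counts.tsv")
    table.library_sizes.rename("library_size").to_csv(
        cfg.output_dir / "library_sizes.tsv", sep="\t", header=True
    )


def _unique_sequence_table(cfg: RunConfig) -> pd.DataFrame:
    columns = {}
    for s in cfg.samples:
        reads = quant.filter_reads(synthetic.read_fastq(s.fastq))
        seqs = pd.Series([seq for _, seq in reads])
        columns[s.id] = seqs.value_counts()
    table = pd.DataFrame(columns).fillna(0.0)
    table.index.name = "sequence"
    return table


def _load_counts(cfg: RunConfig, name: str) -> CountTable:
    libsizes = pd.read_csv(
        cfg.output_dir / "library_sizes.tsv", sep="\t", index_col=0
    )["library_size"]
    return CountTable.from_tsv(
        cfg.output_dir / name, meta_columns=("ncrna_class",), library_sizes=libsizes
    )


def _stage_cluster(cfg: RunConfig) -> None:
    seq_table = _unique_sequence_table(cfg)
    clusters = clusternorm.greedy_cluster(
        seq_table,
        max_mismatch=int(cfg.cluster_params.get("max_mismatch", 3)),
        max_overhang=int(cfg.cluster_params.get("max_overhang", 3)),
    )
    clusters.to_tsv(cfg.output_dir / "clusters.tsv")
    cluster_table, corr = clusternorm.cluster_count_table(clusters)
    corr.to_csv(cfg.output_dir / "cluster_sample_correlation.tsv", sep="\t")

    factors = clusternorm.tmm_factors(
        cluster_table,
        trim_m=float(cfg.tmm_params.get("trim_m", 0.30)),
        trim_a=float(cfg.tmm_params.get("trim_a", 0.05)),
    )
    ref_counts = _load_counts(cfg, "reference_counts.tsv")
    factors.to_tsv(cfg.output_dir / "tmm_factors.tsv", ref_counts.library_sizes)
    normalized = clusternorm.apply_factors(ref_counts, factors)
    normalized.to_tsv(cfg.output_dir / "normalized_counts.tsv")
    normalized.library_sizes.rename("library_size").to_csv(
        cfg.output_dir / "normalized_library_sizes.tsv", sep="\t", header=True
    )


def _load_normalized(cfg: RunConfig) -> CountTable:
    libsizes = pd.read_csv(
        cfg.output_dir / "normalized_library_sizes.tsv", sep="\t", index_col=0
    )["library_size"]
    return CountTable.from_tsv(
        cfg.output_dir / "normalized_counts.tsv",
        meta_columns=("ncrna_class",),
        library_sizes=libsizes,
    )


def _stage_diff(cfg: RunConfig) -> None:
    norm = _load_normalized(cfg)
    ctrls = cfg.control_samples()
    for case in cfg.case_samples():
        records = diffexpr.per_sample_de(norm, case, ctrls, cfg.de)
        diffexpr.records_to_frame(records).to_csv(
            cfg.output_dir / f"de_{case}_vs_controls.tsv", sep="\t"
        )

    couple_records = {}
    for couple, members in sorted(cfg.couples().items()):
        asd = next(m.id for m in members if m.group == "case")
        ctrl = next(m.id for m in members if m.group == "control")
        records, summary = diffexpr.sibling_compare(norm, asd, ctrl, cfg.de)
        couple_records[couple] = records
        diffexpr.records_to_frame(records).to_csv(
            cfg.output_dir / f"de_couple_{couple}.tsv", sep="\t"
        )
        summary.to_csv(cfg.output_dir / f"summary_couple_{couple}.tsv", sep="\t")

    if len(couple_records) >= 2:
        common = diffexpr.cross_couple_common(couple_records)
        with open(cfg.output_dir / "cross_couple_common.json", "w") as fh:
            json.dump(common, fh, indent=2, sort_keys=True)


def _stage_targets(cfg: RunConfig) -> None:
    if not cfg.target_maps:
        logger.info("no target maps configured; skipping target stage")
        return
    de_records = {}
    for case in cfg.case_samples():
        df = pd.read_csv(cfg.output_dir / f"de_{case}_vs_controls.tsv", sep="\t")
        de_records[case] = [
            diffexpr.DiffRecord(
                feature=row.feature,
                group_a_value=row.group_a_value,
                group_b_value=row.group_b_value,
                log2fc=row.log2fc,
                p_value=row.p_value,
                fdr=row.fdr,
                significant=bool(row.significant),
                presence=row.presence,
            )
            for row in df.itertuples()
        ]

    per_sample_sets: dict[str, set[str]] = {c: set() for c in de_records}
    for cls_name, path in sorted(cfg.target_maps.items()):
        tmap = targets.load_target_map(path, cls_name)
        sets = targets.dysregulated_targets(de_records, tmap, cfg.target_direction)
        for sample, genes in sets.items():
            per_sample_sets[sample] |= genes

    common = targets.common_targets(per_sample_sets, cfg.min_target_samples)
    pd.DataFrame(
        [
            {"gene": g, "n_supporting_samples": len(ss), "samples": ",".join(ss)}
            for g, ss in common.items()
        ]
    ).to_csv(cfg.output_dir / "common_targets.tsv", sep="\t", index=False)

    for gmt_path in cfg.gene_sets:
        collection = targets.GeneSetCollection.from_gmt(gmt_path)
        annot = targets.annotate_gene_sets(set(common), collection)
        pd.DataFrame(
            [
                {"gene_set": name, "n_hits": n, "hit_genes": ",".join(hits)}
                for name, (hits, n) in annot.items()
            ]
        ).to_csv(
            cfg.output_dir / f"gene_set_annotation_{Path(gmt_path).stem}.tsv",
            sep="\t",
            index=False,
        )


def _stage_microbiome(cfg: RunConfig) -> None:
    if cfg.otu_table is None:
        logger.info("no OTU table configured; skipping microbiome stage")
        return
    groups = {s.id: s.group for s in cfg.samples}
    otus = OtuTable.from_tsv(cfg.otu_table, groups)

    diversity = microbiome.alpha_diversity(otus, inverse_simpson=cfg.inverse_simpson)
    diversity.per_sample.to_csv(cfg.output_dir / "alpha_diversity.tsv", sep="\t")

    for rank in ("Phylum", "Family", "Genus"):
        agg = microbiome.aggregate_rank(otus, rank)
        frac = microbiome.relative_abundance(agg)
        frac.to_csv(cfg.output_dir / f"relative_abundance_{rank.lower()}.tsv", sep="\t")

    num, den = cfg.phylum_ratio
    phyla = set(otus.lineage["Phylum"])
    if num in phyla and den in phyla:
        per_sample, per_group = microbiome.taxon_ratio(otus, num, den, "Phylum")
        out = per_sample.to_frame()
        out.index.name = "sample"
        out.to_csv(cfg.output_dir / "phylum_ratio_per_sample.tsv", sep="\t")
        per_group.to_frame().to_csv(cfg.output_dir / "phylum_ratio_per_group.tsv", sep="\t")
    else:
        logger.warning("phylum ratio %s/%s not computable for this taxonomy", num, den)

    partition = microbiome.prevalence_partition(otus)
    with open(cfg.output_dir / "family_prevalence_partition.json", "w") as fh:
        json.dump(partition, fh, indent=2, sort_keys=True)


_STAGE_FUNCS = {
    "quantify": _stage_quantify,
    "cluster": _stage_cluster,
    "diff": _stage_diff,
    "targets": _stage_targets,
    "microbiome": _stage_microbiome,
}


def run_stage(cfg: RunConfig, stage: str) -> None:
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {list(STAGES)}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s", stage)
    try:
        _STAGE_FUNCS[stage](cfg)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage in order and write a reproducibility manifest."""
    cfg.validate()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        run_stage(cfg, stage)

    from . import __version__

    outputs = sorted(
        p for p in cfg.output_dir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "de": cfg.de.__dict__,
            "cluster": dict(cfg.cluster_params),
            "tmm": dict(cfg.tmm_params),
            "target_direction": cfg.target_direction,
            "min_target_samples": cfg.min_target_samples,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(cfg.output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ------------------------------------------------------- synthetic demo


def simulate_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_case: int = 2,
    n_ctrl: int = 2,
    n_refs: int = 60,
    n_reads: int = 1200,
    n_otus: int = 60,
) -> Path:
    """Write a complete synthetic input set plus a ready-to-run config.

    Case samples carry spiked up-regulated references so the differential
    and target stages have signal; the OTU table carries one
    control-exclusive family. Returns the path of the written config file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.SimulationConfig(
        seed=seed, n_refs=n_refs, n_reads_per_sample=n_reads,
        n_case=n_case, n_ctrl=n_ctrl, per_base_error_rate=0.001,
    )
    refs = synthetic.make_reference_set(cfg)
    refs.to_fasta(out_dir / "references.fasta")

    rng = np.random.default_rng([97, seed])
    base = rng.gamma(shape=2.0, scale=50.0, size=len(refs))
    spiked = rng.choice(len(refs), size=max(3, len(refs) // 10), replace=False)
    truth = pd.Series("null", index=pd.Index(refs.ids, name="feature"))
    truth.iloc[spiked] = "up"
    synthetic.write_truth(truth, out_dir / "reference_truth.tsv")

    samples = []
    couple_of = {}
    for i in range(n_case):
        couple_of[f"ASD{i + 1}"] = f"c{i + 1}" if i < n_ctrl else None
    for i, (sid, group) in enumerate(
        [(f"ASD{i + 1}", "case") for i in range(n_case)]
        + [(f"CTRL{i + 1}", "control") for i in range(n_ctrl)]
    ):
        weights = base * rng.lognormal(0.0, 0.2, size=len(refs))
        if group == "case":
            weights[spiked] *= 8.0
        reads, _ = synthetic.simulate_reads(
            refs, dict(zip(refs.ids, weights)), cfg, stream_salt=i + 1
        )
        fastq = out_dir / f"{sid}.fastq"
        synthetic.write_fastq(reads, fastq)
        couple = None
        if group == "case" and i < min(n_case, n_ctrl):
            couple = f"c{i + 1}"
        if group == "control" and (i - n_case) < min(n_case, n_ctrl):
            couple = f"c{i - n_case + 1}"
        samples.append(
            {"id": sid, "group": group, "fastq": fastq.name, "couple": couple}
        )

    groups = {s["id"]: s["group"] for s in samples}
    otus = synthetic.simulate_otu_table(
        n_otus, len(samples), groups,
        group_exclusive_families={"Aspergillaceae": "control"},
        seed=seed,
    )
    otus.to_tsv(out_dir / "otu_table.tsv")

    # target map: every reference regulates a handful of synthetic genes
    gene_rows = []
    for i, ref_id in enumerate(refs.ids):
        cls = refs[ref_id].ncrna_class
        if cls == "other":
            continue
        for g in range(3):
            gene = f"GENE{(i * 3 + g) % 40:03d}"
            gene_rows.append(
                {
                    "ncrna_id": ref_id,
                    "gene": gene,
                    "evidence": "validated" if cls == "miRNA" else "predicted",
                    "alignment_support": int(rng.integers(1, 6)),
                }
            )
    tmap = pd.DataFrame(gene_rows)
    tmap[tmap["evidence"] == "validated"].to_csv(
        out_dir / "mirna_targets.tsv", sep="\t", index=False
    )
    tmap[tmap["evidence"] == "predicted"].to_csv(
        out_dir / "pirna_targets.tsv", sep="\t", index=False
    )

    with open(out_dir / "hallmark.gmt", "w") as fh:
        fh.write(
            "SET_EPITHELIUM\tsynthetic\t"
            + "\t".join(f"GENE{i:03d}" for i in range(0, 20))
            + "\n"
        )
        fh.write(
            "SET_INFLAMMATION\tsynthetic\t"
            + "\t".join(f"GENE{i:03d}" for i in range(15, 40))
            + "\n"
        )

    config = {
        "seed": seed,
        "output_dir": "results",
        "reference_fasta": "references.fasta",
        "otu_table": "otu_table.tsv",
        "target_maps": {
            "miRNA": "mirna_targets.tsv",
            "piRNA": "pirna_targets.tsv",
        },
        "gene_sets": ["hallmark.gmt"],
        "min_target_samples": 2,
        "samples": samples,
    }
    config_path = out_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
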