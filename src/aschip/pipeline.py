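"""Pipeline orchestration: stages, single config, provenance.

Stages (in dependency order): simulate, build-genomes, align, count, test,
annotate, motifs, report.  All settings live in one flat YAML config with
per-stage sections; all randomness flows from the single seed; every stage
writes a provenance sidecar (config hash, seed, input digests, version) so
reruns are verifiably idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import align_fastq, write_assignment_tsv
from .annotate import (
    annotate_eqtl,
    annotate_gwas,
    annotation_frame,
    cluster_loci,
    expand_ld,
    load_eqtl_tsv,
    load_gwas_tsv,
    load_ld_table,
    summarize_traits,
    trait_summary_frame,
)
from .counting import count_alleles, deduplicate, read_counts_tsv, write_counts_tsv
from .detect import call_as_snps, filter_regions, write_as_snp_outputs
from .diploid import build_personal_genomes, load_phased_vcf, validate_round_trip, write_personal_genomes
from .io import load_bed_trees, read_fasta
from .motifs import DEFAULT_WEIGHTS, hits_to_frame, load_pwms, score_as_snps, summarize_motifs
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)

STAGES = ["simulate", "build-genomes", "align", "count", "test", "annotate", "motifs", "report"]


@dataclass
class PipelineConfig:
    """Single configuration across all stages."""

    workdir: Path
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    k: int = 16
    max_mismatches: int = 3
    min_mean_quality: float = 20.0
    min_base_quality: int = 20
    deduplicate: bool = True
    min_total: int = 10
    fdr: float = 0.05
    correction: str = "bh"
    pool_marks: bool = False
    ld_threshold: float = 0.8
    locus_window: int = 1_000_000
    delta_min: float = 0.3
    score_min: float = 2.55
    expression_floor: float = 0.0
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw.setdefault("workdir", Path(path).parent / "work")
        raw["workdir"] = Path(raw["workdir"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_canonical(self) -> str:
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in self.__dict__.items()}
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical().encode()).hexdigest()[:16]

    # directory layout
    @property
    def sim_dir(self) -> Path:
        return self.workdir / "sim"

    @property
    def out_dir(self) -> Path:
        return self.workdir / "out"

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(config: PipelineConfig, stage: str, inputs: list[Path], outputs: list[Path]) -> Path:
    record = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "inputs": {p.name: _digest(p) for p in sorted(inputs) if p.exists()},
        "outputs": {p.name: _digest(p) for p in sorted(outputs) if p.exists()},
    }
    path = config.out_dir / f"provenance_{stage.replace('-', '_')}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{produced_by}' stage first"
        )
    return path


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; returns a summary dict of what was produced."""
    if name not in STAGES and name != "run-all":
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    config.workdir.mkdir(parents=True, exist_ok=True)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = {
        "simulate": _stage_simulate,
        "build-genomes": _stage_build_genomes,
        "align": _stage_align,
        "count": _stage_count,
        "test": _stage_test,
        "annotate": _stage_annotate,
        "motifs": _stage_motifs,
        "report": _stage_report,
    }[name]
    logger.info("running stage %s (workdir=%s)", name, config.workdir)
    return handler(config)


def run_all(config: PipelineConfig) -> dict:
    summary = {}
    for stage in STAGES:
        summary[stage] = run_stage(stage, config)
    return summary


def _marks(config: PipelineConfig) -> list[str]:
    return list(config.sim_config().marks)


def _stage_simulate(config: PipelineConfig) -> dict:
    paths, manifest = simulate_all(config.sim_config(), config.sim_dir)
    _provenance(config, "simulate", [], list(paths.values()))
    return {"files": {k: str(v) for k, v in paths.items()},
            "n_as_sites": len(manifest.as_sites)}

def _stage_build_genomes(config: PipelineConfig) -> dict:
    ref_path = _require(config.sim_dir / "reference.fa", "simulate")
    vcf_path = _require(config.sim_dir / "variants.vcf", "simulate")
    reference = read_fasta(ref_path)
    variants, skipped = load_phased_vcf(vcf_path, require_pass=True, snv_only=True)
    pair = build_personal_genomes(reference, variants)
    report = validate_round_trip(pair, reference, variants)
    if not report["ok"]:
        raise RuntimeError(f"personal genome round-trip failed: {report['discrepancies'][:5]}")
    p1, p2 = write_personal_genomes(pair, config.out_dir / "personal")
    skip_path = config.out_dir / "vcf_skip_report.tsv"
    with open(skip_path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason, count in sorted(skipped.items()):
            fh.write(f"{reason}\t{count}\n")
    _provenance(config, "build-genomes", [ref_path, vcf_path], [p1, p2, skip_path])
    return {"n_variants": len(variants), "skipped": skipped}

def _stage_align(config: PipelineConfig) -> dict:
    g1 = read_fasta(_require(config.out_dir / "personal_G1.fa", "build-genomes"))
    g2 = read_fasta(_require(config.out_dir / "personal_G2.fa", "build-genomes"))
    stats_by_mark = {}
    outputs, inputs = [], []
    for mark in _marks(config):
        fq = _require(config.sim_dir / f"reads_{mark}.fastq", "simulate")
        inputs.append(fq)
        alignments, stats = align_fastq(
            fq, g1, g2, k=config.k, max_mismatches=config.max_mismatches,
            min_mean_quality=config.min_mean_quality,
        )
        out = write_assignment_tsv(alignments, config.out_dir / f"assignments_{mark}.tsv")
        outputs.append(out)
        stats_by_mark[mark] = stats
    _provenance(config, "align", inputs, outputs)
    return {"stats": stats_by_mark}

def _stage_count(config: PipelineConfig) -> dict:
    # recompute alignments in memory (assignment TSV lacks sequences by design:
    # it is a human-readable audit trail, not the counting input)
    g1 = read_fasta(_require(config.out_dir / "personal_G1.fa", "build-genomes"))
    g2 = read_fasta(_require(config.out_dir / "personal_G2.fa", "build-genomes"))
    variants, _ = load_phased_vcf(_require(config.sim_dir / "variants.vcf", "simulate"))
    chrom_lengths = {c: len(s) for c, s in g1.items()}
    totals = {}
    outputs, inputs = [], []
    for mark in _marks(config):
        fq = _require(config.sim_dir / f"reads_{mark}.fastq", "simulate")
        inputs.append(fq)
        alignments, _stats = align_fastq(
            fq, g1, g2, k=config.k, max_mismatches=config.max_mismatches,
            min_mean_quality=config.min_mean_quality,
        )
        if config.deduplicate:
            alignments = deduplicate(alignments)
        records = count_alleles(
            alignments, variants, mark,
            min_base_quality=config.min_base_quality, chrom_lengths=chrom_lengths,
        )
        out = write_counts_tsv(records, config.out_dir / f"counts_{mark}.tsv")
        outputs.append(out)
        totals[mark] = sum(r.total for r in records)
    _provenance(config, "count", inputs, outputs)
    return {"informative_reads": totals}

def _stage_test(config: PipelineConfig) -> dict:
    counts_by_mark = {}
    inputs = []
    for mark in _marks(config):
        path = _require(config.out_dir / f"counts_{mark}.tsv", "count")
        inputs.append(path)
        counts_by_mark[mark] = read_counts_tsv(path)
    records = call_as_snps(
        counts_by_mark, min_total=config.min_total, fdr=config.fdr,
        correction=config.correction, pool_marks=config.pool_marks,
    )
    exclusions = {"blacklist": _require(config.sim_dir / "blacklist.bed", "simulate")}
    records = filter_regions(records, exclusions)
    out = write_as_snp_outputs(records, config.out_dir / "as_snps")
    _provenance(config, "test", inputs, list(out.values()))
    n_as = sum(r.is_as_snp for r in records)
    n_filtered = sum(r.filtered_reason is not None for r in records)
    return {"sites_tested": len(records), "as_snps": n_as, "filtered": n_filtered}

def _load_as_records(config: PipelineConfig):
    import pandas as pd

    from .detect import ASSNPRecord

    path = _require(config.out_dir / "as_snps.tsv", "test")
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        if not bool(row.is_as_snp):
            continue
        rec = ASSNPRecord(row.chrom, int(row.pos), row.ref, row.alt, row.hap1, row.hap2)
        rec.is_as_snp = True
        rec.significant_marks = set(str(row.significant_marks).split(","))
        if row.best_mark != ".":
            rec.p_by_mark[row.best_mark] = float(row.p_best)
            rec.q_by_mark[row.best_mark] = float(row.q_best)
            rec.ratio_by_mark[row.best_mark] = float(row.allelic_ratio)
        records.append(rec)
    return records

def _stage_annotate(config: PipelineConfig) -> dict:
    records = _load_as_records(config)
    gwas = load_gwas_tsv(_require(config.sim_dir / "gwas.tsv", "simulate"))
    ld = load_ld_table(_require(config.sim_dir / "ld_pairs.tsv", "simulate"))
    eqtl = load_eqtl_tsv(_require(config.sim_dir / "eqtl.tsv", "simulate"))
    proxy_map = expand_ld(gwas, ld, threshold=config.ld_threshold)
    gwas_ann = annotate_gwas(records, gwas, proxy_map)
    eqtl_genes = annotate_eqtl(records, eqtl)
    ann_df = annotation_frame(records, gwas_ann, eqtl_genes)
    ann_path = config.out_dir / "as_snps_annotated.tsv"
    ann_df.to_csv(ann_path, sep="\t", index=False)
    summaries, total = summarize_traits(gwas_ann, window=config.locus_window)
    ts_path = config.out_dir / "trait_summary.tsv"
    trait_summary_frame(summaries, total).to_csv(ts_path, sep="\t", index=False)
    linked = sorted({(a.chrom, a.pos) for a in gwas_ann if a.status != "unlinked"})
    loci = cluster_loci(linked, window=config.locus_window)
    locus_path = config.out_dir / "gwas_loci.bed"
    with open(locus_path, "w") as fh:
        for (chrom, pos), locus in sorted(loci.items()):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\tlocus_{locus}\n")
    _provenance(config, "annotate", [config.out_dir / "as_snps.tsv"],
                [ann_path, ts_path, locus_path])
    return {
        "gwas_linked": len(linked),
        "gwas_loci": len(set(loci.values())),
        "eqtl_linked": sum(bool(g) for g in eqtl_genes.values()),
    }

def _stage_motifs(config: PipelineConfig) -> dict:
    import pandas as pd

    records = _load_as_records(config)
    g1 = read_fasta(_require(config.out_dir / "personal_G1.fa", "build-genomes"))
    g2 = read_fasta(_require(config.out_dir / "personal_G2.fa", "build-genomes"))
    from .diploid import PersonalGenomePair

    genomes = PersonalGenomePair(g1=g1, g2=g2)
    pwms = load_pwms(_require(config.sim_dir / "pwms.jaspar", "simulate"))
    tracks = {
        name: load_bed_trees(_require(config.sim_dir / fname, "simulate"))
        for name, fname in [
            ("dnase", "dnase.bed"), ("tf_chip", "tf_chip.bed"), ("cage", "cage.bed"),
            ("chromatin_state", "chromatin_states.bed"),
            ("replication_domain", "replication_domains.bed"),
        ]
    }
    expr_df = pd.read_csv(_require(config.sim_dir / "expression.tsv", "simulate"), sep="\t")
    expression = dict(zip(expr_df["tf"], expr_df["tpm"].astype(float)))
    hits = score_as_snps(
        records, pwms, genomes, tracks, expression,
        delta_min=config.delta_min, score_min=config.score_min,
        weights=config.weights, expression_floor=config.expression_floor,
    )
    hits_path = config.out_dir / "motif_hits.tsv"
    hits_to_frame(hits).to_csv(hits_path, sep="\t", index=False)
    tf_df, state_df = summarize_motifs(hits)
    tf_path = config.out_dir / "motif_tf_recurrence.tsv"
    state_path = config.out_dir / "motif_state_distribution.tsv"
    tf_df.to_csv(tf_path, sep="\t", index=False)
    state_df.to_csv(state_path, sep="\t", index=False)
    _provenance(config, "motifs", [config.out_dir / "as_snps.tsv"],
                [hits_path, tf_path, state_path])
    return {
        "hits": len(hits),
        "candidate_functional": sum(h.candidate_functional for h in hits),
    }

def _stage_report(config: PipelineConfig) -> dict:
    """Aggregate per-stage counts into one summary JSON + readable text."""
    import pandas as pd

    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash()}
    as_path = _require(config.out_dir / "as_snps.tsv", "test")
    df = pd.read_csv(as_path, sep="\t")
    summary["sites_tested"] = int(len(df))
    summary["as_snps"] = int(df["is_as_snp"].sum())
    summary["filtered_sites"] = int((df["filtered_reason"] != ".").sum())
    ann_path = config.out_dir / "as_snps_annotated.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t")
        summary["gwas_linked"] = int((ann["gwas_status"] != "unlinked").sum())
        summary["eqtl_linked"] = int((ann["eqtl_genes"] != ".").sum())
        ts = pd.read_csv(config.out_dir / "trait_summary.tsv", sep="\t")
        total_row = ts[ts["trait"] == "Total"]
        if len(total_row):
            summary["gwas_loci"] = int(total_row["n_loci"].iloc[0])
    hits_path = config.out_dir / "motif_hits.tsv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path, sep="\t")
        summary["motif_hits"] = int(len(hits))
        summary["candidate_functional_motifs"] = int(hits["candidate_functional"].sum())
    report_path = config.out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _provenance(config, "report", [as_path], [report_path])
    return summary
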