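"""Seeded synthetic study generator with a ground-truth manifest.

Generates a complete toy allele-specific ChIP-seq study — reference
genome, phased SNVs, per-mark reads with planted allelic imbalance,
exclusion/annotation tracks, GWAS/LD/eQTL tables, PWMs — so that every
downstream stage is testable against known ground truth without any
external download.

Design points:

* one pseudo-random stream per output file, all derived from the master
  seed, so adding a mark or track does not perturb the other files;
* a fixed seed makes every emitted file byte-identical across runs;
* every manifest entry is re-derivable from the emitted files alone
  (VCF positions, BED overlaps, panel r^2);
* fragments are single-end reads of ``read_length`` sampled from fragment
  5' ends on either strand; per-peak fragment count is the configured
  coverage exactly (a degenerate "mean"), trading realism for test power;
* base qualities are constant Q30 with error-injected bases at Q10, so
  the Phred-20 base filter is exercised deterministically.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotate import compute_r2
from .counting import AlleleCountRecord
from .diploid import PhasedVariant
from .io import write_bed, write_fasta, write_fastq
from .motifs import PWM, _normalize_counts

logger = logging.getLogger(__name__)

_Q30, _Q10 = "?", "+"  # Phred+33
DEFAULT_MARKS = ("CTCF", "H3K4me3", "H3K27ac")
_TRAITS = (
    "Type 2 diabetes",
    "Blood protein levels",
    "Cholesterol, total",
    "Obesity-related traits",
    "Fibrinogen",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the shipped study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    variant_spacing: int = 300
    het_fraction: float = 0.5
    n_peaks_per_mark: int = 12
    peak_width: int = 400
    n_as_sites: int = 9
    as_ratio: float = 0.8
    coverage: int = 80  # fragments per peak
    read_length: int = 100
    fragment_length: int = 200
    base_error_rate: float = 0.001
    marks: tuple[str, ...] = DEFAULT_MARKS
    # extra plumbing knobs
    non_pass_fraction: float = 0.05
    n_blacklist_sites: int = 2
    n_blacklist_decoys: int = 3
    n_motif_sites: int = 3
    n_eqtl_links: int = 4
    ld_r2_targets: tuple[float, ...] = (1.0, 0.92, 0.85, 0.5, 0.2)
    panel_haplotypes: int = 100  # must be divisible by 4 for the planted grid

    def validate(self) -> None:
        if not 0.5 <= self.as_ratio <= 1.0:
            raise ValueError("as_ratio must lie in [0.5, 1.0]")
        if self.read_length > self.fragment_length:
            raise ValueError("read_length must be <= fragment_length")
        if self.fragment_length > self.chrom_length:
            raise ValueError("fragment_length must be <= chrom_length")
        if self.variant_spacing < 2:
            raise ValueError("variant_spacing must be >= 2")
        for name in ("n_chroms", "chrom_length", "variant_spacing", "n_peaks_per_mark",
                     "peak_width", "coverage", "read_length", "fragment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must lie in [0, 1)")
        if self.n_as_sites > self.n_peaks_per_mark * len(self.marks):
            raise ValueError("n_as_sites exceeds total peak count")
        if self.panel_haplotypes % 4 != 0:
            raise ValueError("panel_haplotypes must be divisible by 4")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream keyed by (seed, stream name)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruthManifest:
    """Everything the generator planted, for downstream verification."""

    as_sites: list[dict] = field(default_factory=list)  # chrom,pos,mark,true_ratio
    null_het_sites: list[dict] = field(default_factory=list)  # chrom,pos,mark
    blacklisted_planted: list[dict] = field(default_factory=list)  # chrom,pos,mark
    motif_planted: list[dict] = field(default_factory=list)  # chrom,pos,pwm,tf,delta_sign
    gwas_links: list[dict] = field(default_factory=list)  # as site, gwas snp, r2, trait, direct
    eqtl_links: list[dict] = field(default_factory=list)  # chrom,pos,gene
    truth_counts: dict[str, dict] = field(default_factory=dict)  # "chrom:pos:mark" -> counts

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# reference + variants


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Uniform-base random reference, one sequence per chromosome."""
    config.validate()
    ref = {}
    for chrom in config.chrom_names():
        rng = config.rng(f"reference/{chrom}")
        ref[chrom] = "".join(rng.choice(list("ACGT"), size=config.chrom_length))
    return ref


def generate_phased_variants(
    config: SimulationConfig, reference: dict[str, str]
) -> list[PhasedVariant]:
    """Phased SNVs on a jittered grid of mean spacing ``variant_spacing``.

    Heterozygous with probability ``het_fraction`` (phase orientation
    random), homozygous-alt otherwise; a ``non_pass_fraction`` of records
    get a non-PASS FILTER to exercise VCF filtering.
    """
    config.validate()
    variants: list[PhasedVariant] = []
    bases = "ACGT"
    for chrom, seq in reference.items():
        rng = config.rng(f"variants/{chrom}")
        pos = 0
        jitter = max(1, config.variant_spacing // 3)
        while True:
            step = config.variant_spacing + int(rng.integers(-jitter, jitter + 1))
            pos = max(pos + 2, pos + step)
            if pos > len(seq):
                break
            ref_base = seq[pos - 1]
            alt = bases[(bases.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
            is_het = rng.random() < config.het_fraction
            if is_het:
                hap1, hap2 = (ref_base, alt) if rng.random() < 0.5 else (alt, ref_base)
            else:
                hap1 = hap2 = alt
            filt = "lowq" if rng.random() < config.non_pass_fraction else "PASS"
            variants.append(PhasedVariant(chrom, pos, ref_base, alt, hap1, hap2, filter=filt))
    return variants


def write_vcf(
    variants: list[PhasedVariant],
    chrom_lengths: dict[str, int],
    path: str | Path,
    sample: str = "LIVER",
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=aschip-simulate\n")
        fh.write('##FILTER=<ID=lowq,Description="Synthetic low-quality call">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            if v.hap1 == v.hap2 == v.alt:
                gt = "1|1"
            else:
                gt = f"{int(v.hap1 == v.alt)}|{int(v.hap2 == v.alt)}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter}\t.\tGT\t{gt}\n"
            )
    return path


# ---------------------------------------------------------------------------
# PWMs and motif planting


def default_pwms(pseudocount: float = 0.01) -> list[PWM]:
    """Three synthetic 6-bp PWMs with one dominant (high-information) position.

    The dominant position concentrates enough of the attainable score range
    that flipping consensus -> worst base there moves the normalized score
    by more than the 0.3 candidate threshold.
    """
    # Each consensus uses three letters only: the dominant base appears once
    # and its complement not at all, so no alternative placement (either
    # strand) can put the dominant consensus base under the dominant column.
    # Combined with controlled flank planting this makes the planted score
    # change deterministic (see _plant_motif_window).
    specs = [  # (name, tf, consensus, dominant position)
        ("SYN_EGR1", "EGR1", "ATAGTA", 3),
        ("SYN_CTCF", "CTCF", "TAACTT", 3),
        ("SYN_KLF5", "KLF5", "GCGACG", 3),
    ]
    pwms = []
    for name, tf, consensus, dom in specs:
        counts = np.zeros((len(consensus), 4))
        for i, base in enumerate(consensus):
            idx = "ACGT".index(base)
            others = [j for j in range(4) if j != idx]
            if i == dom:
                counts[i, idx] = 197
                counts[i, others] = 1
            else:
                counts[i, idx] = 30
                counts[i, others] = [28, 22, 20]
        pwms.append(PWM(name, tf, _normalize_counts(counts, pseudocount),
                        pseudocount=pseudocount))
    return pwms


def write_pwms_jaspar(pwms: list[PWM], path: str | Path, scale: int = 200) -> Path:
    """Write PWMs as JASPAR-format integer count matrices."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in pwms:
            counts = np.rint(p.matrix * scale).astype(int)
            fh.write(f">{p.name} {p.tf}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{counts[i, bi]:4d}" for i in range(len(p)))
                fh.write(f"{base} [{row} ]\n")
    return path


def _dominant_index(pwm: PWM) -> int:
    info = (pwm.log_odds.max(axis=1) - pwm.log_odds.min(axis=1))
    return int(np.argmax(info))


def _flank_base(pwm: PWM, dom: int) -> str:
    """A base that never shows the dominant consensus under the dominant
    column: neither the dominant base itself nor its complement."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    dom_cons = pwm.consensus[dom]
    return next(b for b in "ACGT" if b not in (dom_cons, comp[dom_cons]))


# ---------------------------------------------------------------------------
# reads


def generate_chipseq_reads(
    config: SimulationConfig,
    reference: dict[str, str],
    variants: list[PhasedVariant],
    manifest: GroundTruthManifest,
    peaks_by_mark: dict[str, list[tuple[str, int]]],
) -> dict[str, list[tuple[str, str, str]]]:
    """Sample reads per mark around peak centers with planted allelic ratios.

    At every heterozygous site covered by a read, the base is drawn from
    hap1 with the site's true ratio for this mark (``as_ratio`` at planted
    sites, 0.5 elsewhere); homozygous-alt sites always show the alt base.
    Sequencing errors are injected per base at ``base_error_rate`` and
    flagged with Q10 qualities; all other bases are Q30.  Realized
    haplotype draws at manifest sites are tallied into
    ``manifest.truth_counts`` (pre-error, read-level).
    """
    config.validate()
    as_index = {
        (s["chrom"], s["pos"], s["mark"]): s["true_ratio"] for s in manifest.as_sites
    }
    het_by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        het_by_chrom.setdefault(v.chrom, []).append(v)
    positions_by_chrom = {
        c: np.array([v.pos - 1 for v in vs]) for c, vs in het_by_chrom.items()
    }
    manifest_keys = {
        (s["chrom"], s["pos"]) for s in manifest.as_sites
    } | {(s["chrom"], s["pos"]) for s in manifest.null_het_sites}

    reads_by_mark: dict[str, list[tuple[str, str, str]]] = {}
    bases = "ACGT"
    for mark, peaks in peaks_by_mark.items():
        rng = config.rng(f"reads/{mark}")
        reads: list[tuple[str, str, str]] = []
        for peak_idx, (chrom, center_pos) in enumerate(peaks):
            seq = reference[chrom]
            center0 = center_pos - 1
            for frag_idx in range(config.coverage):
                frag_start = center0 - config.fragment_length + 1 + int(
                    rng.integers(0, config.fragment_length)
                )
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    rstart = frag_start
                else:
                    rstart = frag_start + config.fragment_length - config.read_length
                rend = rstart + config.read_length
                if rstart < 0 or rend > len(seq):
                    continue  # peaks are placed with margins; belt and braces
                read = list(seq[rstart:rend])
                pos_arr = positions_by_chrom.get(chrom)
                if pos_arr is not None:
                    lo = int(np.searchsorted(pos_arr, rstart, side="left"))
                    hi = int(np.searchsorted(pos_arr, rend - 1, side="right"))
                    for vi in range(lo, hi):
                        v = het_by_chrom[chrom][vi]
                        col = (v.pos - 1) - rstart
                        if v.is_het:
                            ratio = as_index.get((v.chrom, v.pos, mark), 0.5)
                            take_hap1 = rng.random() < ratio
                            read[col] = v.hap1 if take_hap1 else v.hap2
                            if (v.chrom, v.pos) in manifest_keys:
                                key = f"{v.chrom}:{v.pos}:{mark}"
                                tc = manifest.truth_counts.setdefault(
                                    key, {"hap1": 0, "hap2": 0}
                                )
                                tc["hap1" if take_hap1 else "hap2"] += 1
                        else:
                            read[col] = v.alt
                qual = [_Q30] * config.read_length
                if config.base_error_rate > 0:
                    err = rng.random(config.read_length) < config.base_error_rate
                    for col in np.nonzero(err)[0]:
                        cur = read[col]
                        read[col] = bases[(bases.index(cur) + 1 + int(rng.integers(0, 3))) % 4]
                        qual[col] = _Q10
                seq_out = "".join(read)
                qual_out = "".join(qual)
                if strand == "-":
                    seq_out = seq_out.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                    qual_out = qual_out[::-1]
                reads.append((f"{mark}:{chrom}:{peak_idx}:{frag_idx}:{strand}", seq_out, qual_out))
        reads_by_mark[mark] = reads
    return reads_by_mark


# ---------------------------------------------------------------------------
# annotation tracks


def _clip(start: int, end: int, length: int, context: str) -> tuple[int, int]:
    if start < 0 or end > length:
        logger.warning("%s: interval [%d,%d) clipped to chromosome bounds", context, start, end)
    return max(0, start), min(end, length)


def generate_annotation_tracks(
    config: SimulationConfig,
    manifest: GroundTruthManifest,
    chrom_lengths: dict[str, int],
    all_centers: list[tuple[str, int]],
    outdir: Path,
    motif_len: int = 6,
) -> dict[str, Path]:
    """Emit blacklist/DNase/TF-ChIP/CAGE/chromatin-state/replication BEDs + expression TSV.

    The blacklist covers exactly the planted blacklisted sites (plus decoy
    intervals placed away from every peak); DNase covers planted motif
    sites except the last one, so the candidate-functional DNase
    requirement is exercised in both directions.  All intervals are
    0-based half-open and clipped to chromosome bounds with a warning.
    """
    rng = config.rng("tracks")
    paths: dict[str, Path] = {}
    half = 25

    blk: list[tuple[str, int, int]] = []
    for s in manifest.blacklisted_planted:
        a, b = _clip(s["pos"] - 1 - half, s["pos"] - 1 + half + 1,
                     chrom_lengths[s["chrom"]], "blacklist")
        blk.append((s["chrom"], a, b))
    margin = config.peak_width + 2 * config.fragment_length
    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in all_centers:
        centers_by_chrom.setdefault(chrom, []).append(pos)
    for _ in range(config.n_blacklist_decoys):
        chrom = config.chrom_names()[int(rng.integers(0, config.n_chroms))]
        for _attempt in range(100):
            start = int(rng.integers(0, chrom_lengths[chrom] - 200))
            if all(abs(start - (c - 1)) > margin for c in centers_by_chrom.get(chrom, [])):
                blk.append((chrom, start, start + 200))
                break
    paths["blacklist"] = write_bed(outdir / "blacklist.bed", sorted(blk))

    dnase: list[tuple[str, int, int]] = []
    cage: list[tuple[str, int, int]] = []
    tf_chip: list[tuple[str, int, int, str]] = []
    for i, s in enumerate(manifest.motif_planted):
        chrom, pos = s["chrom"], s["pos"]
        a, b = _clip(pos - 1 - 20, pos - 1 + 20 + motif_len, chrom_lengths[chrom], "dnase")
        if i < len(manifest.motif_planted) - 1:  # last motif site gets no DNase
            dnase.append((chrom, a, b))
        if i % 2 == 0:  # alternate sites carry a TF binding event
            tf_chip.append((chrom, a, b, s["tf"]))
        cage.append((chrom, a, b))
    for s in manifest.as_sites[: len(manifest.as_sites) // 2]:
        a, b = _clip(s["pos"] - 1 - 50, s["pos"] + 50, chrom_lengths[s["chrom"]], "dnase")
        dnase.append((s["chrom"], a, b))
    paths["dnase"] = write_bed(outdir / "dnase.bed", sorted(set(dnase)))
    paths["cage"] = write_bed(outdir / "cage.bed", sorted(set(cage)))
    paths["tf_chip"] = write_bed(outdir / "tf_chip.bed", sorted(set(tf_chip)))

    # chromatin states: TssA islands around motif sites, Quies elsewhere
    states: list[tuple[str, int, int, str]] = []
    islands_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in manifest.motif_planted:
        a, b = _clip(s["pos"] - 1 - 500, s["pos"] + 500, chrom_lengths[s["chrom"]], "state")
        islands_by_chrom.setdefault(s["chrom"], []).append((a, b))
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for a, b in sorted(islands_by_chrom.get(chrom, [])):
            a = max(a, cursor)
            if a > cursor:
                states.append((chrom, cursor, a, "Quies"))
            if b > a:
                states.append((chrom, a, b, "TssA"))
            cursor = max(cursor, b)
        if cursor < length:
            states.append((chrom, cursor, length, "Quies"))
    paths["chromatin_state"] = write_bed(outdir / "chromatin_states.bed", states)

    repl = []
    for chrom, length in chrom_lengths.items():
        repl.append((chrom, 0, length // 2, "early"))
        repl.append((chrom, length // 2, length, "late"))
    paths["replication_domain"] = write_bed(outdir / "replication_domains.bed", repl)

    expr = {"EGR1": 12.5, "CTCF": 8.0, "KLF5": 0.0}
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("tf\ttpm\n")
        for tf, tpm in expr.items():
            fh.write(f"{tf}\t{tpm}\n")
    paths["expression"] = expr_path
    return paths


# ---------------------------------------------------------------------------
# GWAS / LD / eQTL


def generate_gwas_eqtl_ld_tables(
    config: SimulationConfig,
    manifest: GroundTruthManifest,
    variant_positions: set[tuple[str, int]],
    chrom_lengths: dict[str, int],
    as_candidates: list[dict],
    outdir: Path,
) -> dict[str, Path]:
    """Emit GWAS catalog extract, eQTL table, haplotype panel and LD pairs.

    Each planted LD link gets a GWAS tag SNP and a two-column block in the
    phased panel whose haplotype counts realize the nearest achievable r^2
    on the panel grid (recorded in the manifest, along with whether it
    clears the 0.8 proxy threshold).  The first link is a direct hit: the
    AS-SNP itself is the GWAS top hit.  eQTL links attach gene symbols to
    planted AS sites.
    """
    rng = config.rng("gwas")
    n_hap = config.panel_haplotypes
    half = n_hap // 2
    gwas_rows: list[tuple[str, str, int, str]] = []
    panel_cols: dict[str, np.ndarray] = {}
    ld_rows: list[tuple[str, str, float]] = []

    usable = [s for s in as_candidates]
    trait_cycle = list(_TRAITS)
    rs_counter = 1000

    if usable:  # direct hit: first AS site is itself a GWAS top hit
        s = usable[0]
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        trait = trait_cycle[0]
        gwas_rows.append((rsid, s["chrom"], s["pos"], trait))
        manifest.gwas_links.append(
            {"as_chrom": s["chrom"], "as_pos": s["pos"], "gwas_rsid": rsid,
             "gwas_chrom": s["chrom"], "gwas_pos": s["pos"], "r2": 1.0,
             "trait": trait, "direct": True}
        )

    proxies = usable[1:]
    for i, r2_target in enumerate(config.ld_r2_targets):
        if i >= len(proxies):
            break
        s = proxies[i]
        chrom = s["chrom"]
        # GWAS tag SNP at a nearby position not carrying a variant
        gpos = None
        for delta in range(937, 937 + 5000):
            for cand in (s["pos"] + delta, s["pos"] - delta):
                if 1 <= cand <= chrom_lengths[chrom] and (chrom, cand) not in variant_positions:
                    gpos = cand
                    break
            if gpos is not None:
                break
        if gpos is None:
            continue
        rsid = f"rs{rs_counter}"
        rs_counter += 1
        trait = trait_cycle[(i + 1) % len(trait_cycle)]
        gwas_rows.append((rsid, chrom, gpos, trait))
        # nearest achievable r^2 on the panel grid: r2 = (k / (n/4))^2 grid
        quarter = n_hap // 4
        k = int(round(quarter * float(np.sqrt(r2_target))))
        x = quarter + k  # haplotype count AB (= ab); Ab = aB = half - x
        a_col = np.zeros(n_hap, dtype=int)
        a_col[:half] = 1
        b_col = np.zeros(n_hap, dtype=int)
        b_col[:x] = 1
        b_col[half : half + (half - x)] = 1
        achieved = compute_r2(x, half - x, half - x, x)
        if abs(achieved - r2_target) > 1e-12:
            logger.info("link %s:%d: requested r2=%.4f, nearest achievable %.6f",
                        chrom, s["pos"], r2_target, achieved)
        a_id = f"{chrom}:{s['pos']}"
        b_id = f"{chrom}:{gpos}"
        panel_cols[a_id] = a_col
        panel_cols[b_id] = b_col
        ld_rows.append((b_id, a_id, achieved))
        manifest.gwas_links.append(
            {"as_chrom": chrom, "as_pos": s["pos"], "gwas_rsid": rsid,
             "gwas_chrom": chrom, "gwas_pos": gpos, "r2": achieved,
             "trait": trait, "direct": False}
        )

    paths: dict[str, Path] = {}
    gwas_path = outdir / "gwas.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("rsid\tchrom\tpos\ttrait\n")
        for rsid, chrom, pos, trait in gwas_rows:
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{trait}\n")
    paths["gwas"] = gwas_path

    panel_path = outdir / "haplotype_panel.tsv"
    with open(panel_path, "w") as fh:
        cols = sorted(panel_cols)
        fh.write("\t".join(cols) + "\n")
        for row in range(n_hap):
            fh.write("\t".join(str(panel_cols[c][row]) for c in cols) + "\n")
    paths["panel"] = panel_path

    ld_path = outdir / "ld_pairs.tsv"
    with open(ld_path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in ld_rows:
            fh.write(f"{a}\t{b}\t{r2:.12f}\n")
    paths["ld"] = ld_path

    eqtl_path = outdir / "eqtl.tsv"
    with open(eqtl_path, "w") as fh:
        fh.write("variant_id\tgene\ttissue\tp\n")
        for i, s in enumerate(usable[: config.n_eqtl_links]):
            gene = f"GENE{chr(ord('A') + i)}"
            p = float(10.0 ** -(4 + int(rng.integers(0, 4))))
            fh.write(f"{s['chrom']}:{s['pos']}\t{gene}\tliver\t{p:g}\n")
            manifest.eqtl_links.append({"chrom": s["chrom"], "pos": s["pos"], "gene": gene})
    paths["eqtl"] = eqtl_path
    return paths


# ---------------------------------------------------------------------------
# count-level simulators for calibration/power studies


def simulate_count_table(
    n_null: int,
    n_planted: int,
    coverage: int,
    as_ratio: float,
    seed: int,
    mark: str = "SIM",
) -> tuple[list[AlleleCountRecord], set[tuple[str, int]]]:
    """Direct count-level draw: Binomial(coverage, ratio) per het site.

    Bypasses read simulation for calibration studies where only the count
    model matters (the read pipeline reduces to exactly this draw at
    error-free sites).  Returns the records and the planted site keys.
    """
    rng = np.random.default_rng(seed)
    records: list[AlleleCountRecord] = []
    planted: set[tuple[str, int]] = set()
    for i in range(n_null + n_planted):
        ratio = as_ratio if i < n_planted else 0.5
        k = int(rng.binomial(coverage, ratio))
        pos = (i + 1) * 10
        rec = AlleleCountRecord("chrS", pos, "A", "G", "A", "G", mark,
                                count_g1=k, count_g2=coverage - k)
        records.append(rec)
        if i < n_planted:
            planted.add(("chrS", pos))
    return records, planted


# ---------------------------------------------------------------------------
# top-level orchestration


def simulate_all(config: SimulationConfig, outdir: str | Path) -> tuple[dict[str, Path], GroundTruthManifest]:
    """Generate the full synthetic study into ``outdir``.

    Returns the emitted file paths and the ground-truth manifest (also
    written as manifest.json).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = GroundTruthManifest()

    reference = generate_reference(config)
    variants = generate_phased_variants(config, reference)
    chrom_lengths = {c: len(s) for c, s in reference.items()}

    # --- choose peak centers (het PASS variants, global non-overlap) ---
    margin = 2 * config.fragment_length
    min_sep = config.peak_width + 2 * config.fragment_length
    het_pass = [v for v in variants if v.is_het and v.filter == "PASS"
                and margin <= v.pos <= chrom_lengths[v.chrom] - margin]
    used: list[tuple[str, int]] = []
    peaks_by_mark: dict[str, list[tuple[str, int]]] = {}
    rng_peaks = config.rng("peaks")
    shuffled = list(het_pass)
    rng_peaks.shuffle(shuffled)
    cursor = 0
    for mark in config.marks:
        chosen: list[tuple[str, int]] = []
        while len(chosen) < config.n_peaks_per_mark and cursor < len(shuffled):
            v = shuffled[cursor]
            cursor += 1
            if all(v.chrom != c or abs(v.pos - p) >= min_sep for c, p in used):
                chosen.append((v.chrom, v.pos))
                used.append((v.chrom, v.pos))
        if len(chosen) < config.n_peaks_per_mark:
            raise ValueError(
                "could not place requested peaks; increase chrom_length or variant density"
            )
        peaks_by_mark[mark] = chosen

    # --- designate AS sites (round-robin across marks) and null centers ---
    quota = {mark: 0 for mark in config.marks}
    for i in range(config.n_as_sites):
        quota[config.marks[i % len(config.marks)]] += 1
    for mark in config.marks:
        for j, (chrom, pos) in enumerate(peaks_by_mark[mark]):
            if j < quota[mark]:
                manifest.as_sites.append(
                    {"chrom": chrom, "pos": pos, "mark": mark, "true_ratio": config.as_ratio}
                )
            else:
                manifest.null_het_sites.append({"chrom": chrom, "pos": pos, "mark": mark})

    # --- blacklist planting: the last n AS sites stay imbalanced but get
    # covered by a blacklist interval, so detection-then-filtering is exercised
    if config.n_blacklist_sites:
        for s in manifest.as_sites[-config.n_blacklist_sites:]:
            manifest.blacklisted_planted.append(dict(s))

    # --- motif planting on AS sites (not blacklisted) ---
    pwms = default_pwms()
    blacklisted_keys = {(s["chrom"], s["pos"]) for s in manifest.blacklisted_planted}
    motif_pool = [s for s in manifest.as_sites
                  if (s["chrom"], s["pos"]) not in blacklisted_keys]
    by_pos = {(v.chrom, v.pos): v for v in variants}
    ref_mut = {c: bytearray(s, "ascii") for c, s in reference.items()}
    planted_spans: list[tuple[str, int, int]] = []
    removed: set[tuple[str, int]] = set()
    for i in range(min(config.n_motif_sites, len(motif_pool))):
        site = motif_pool[i]
        pwm = pwms[i % len(pwms)]
        dom = _dominant_index(pwm)
        chrom, pos = site["chrom"], site["pos"]
        start0 = (pos - 1) - dom
        L = len(pwm)
        if start0 - (L - 1) < 0 or start0 + 2 * L - 1 > chrom_lengths[chrom]:
            continue
        consensus = pwm.consensus
        worst = pwm.anticonsensus[dom]
        flank = _flank_base(pwm, dom)
        # controlled flanks: no placement covering the SNP can show the
        # dominant consensus base under the dominant column on either strand,
        # so the planted score change is deterministic
        for off in range(-(L - 1), 2 * L - 1):
            base = consensus[off] if 0 <= off < L else flank
            ref_mut[chrom][start0 + off] = ord(base)
        # reconcile variants inside the edited window with the new reference
        for p in range(start0 - L + 2, start0 + 2 * L):  # 1-based positions
            v = by_pos.get((chrom, p))
            if v is None:
                continue
            if p == pos:
                hap1, hap2 = consensus[dom], worst
                sign = 1
                if i % 2 == 1:  # alternate phase orientation; delta is symmetric
                    hap1, hap2 = hap2, hap1
                    sign = -1
                by_pos[(chrom, p)] = PhasedVariant(
                    chrom, p, ref=consensus[dom], alt=worst, hap1=hap1, hap2=hap2,
                    filter="PASS",
                )
                manifest.motif_planted.append(
                    {"chrom": chrom, "pos": p, "pwm": pwm.name, "tf": pwm.tf,
                     "delta_sign": sign}
                )
            else:
                removed.add((chrom, p))  # neighbours would perturb planted scores
        planted_spans.append((chrom, start0, start0 + L))
    variants = [v for (c, p), v in sorted(by_pos.items()) if (c, p) not in removed]
    reference = {c: s.decode("ascii") for c, s in ref_mut.items()}

    # --- emit reference, VCF, reads ---
    paths: dict[str, Path] = {}
    paths["reference"] = write_fasta(outdir / "reference.fa", reference)
    paths["vcf"] = write_vcf(variants, chrom_lengths, outdir / "variants.vcf")
    reads_by_mark = generate_chipseq_reads(config, reference, variants, manifest, peaks_by_mark)
    for mark, reads in reads_by_mark.items():
        paths[f"reads_{mark}"] = write_fastq(outdir / f"reads_{mark}.fastq", reads)

    # --- annotation tracks and association tables ---
    paths.update(
        generate_annotation_tracks(config, manifest, chrom_lengths, used, outdir)
    )
    variant_positions = {(v.chrom, v.pos) for v in variants}
    as_candidates = [s for s in manifest.as_sites
                     if (s["chrom"], s["pos"]) not in blacklisted_keys]
    paths.update(
        generate_gwas_eqtl_ld_tables(
            config, manifest, variant_positions, chrom_lengths, as_candidates, outdir
        )
    )
    paths["pwms"] = write_pwms_jaspar(pwms, outdir / "pwms.jaspar")
    paths["manifest"] = manifest.save(outdir / "manifest.json")
    logger.info("simulated study in %s: %d variants, %d AS sites, %d marks",
                outdir, len(variants), len(manifest.as_sites), len(config.marks))
    return paths, manifest
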