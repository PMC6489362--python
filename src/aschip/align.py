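"""Allele-aware read alignment to the two personal genomes.

Each read is placed on both haplotype genomes (which share coordinates)
and assigned to the genome it matches with fewer mismatches; equal counts
are a TIE and contribute no allelic evidence.  The internal aligner is
ungapped — personal genomes differ from reads only by SNVs and base
errors at this scale — with exact k-mer seeding followed by full-length
Hamming comparison.  Gapped/spliced alignment is delegated to external
aligners via :func:`import_alignment_pair`.

Reads whose mean base quality is below the Phred-20 floor are discarded
before alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

G1, G2, TIE, UNMAPPED = "G1", "G2", "TIE", "UNMAPPED"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadAlignment:
    """One read placed against both personal genomes.

    ``start`` is 0-based on the shared coordinate system; ``aligned_sequence``
    and ``base_qualities`` are stored in genome-forward orientation so that
    per-site base lookups need no strand logic downstream.
    """

    read_id: str
    chrom: str | None
    start: int | None
    strand: str | None
    mismatches_g1: int | None
    mismatches_g2: int | None
    assignment: str
    aligned_sequence: str | None = None
    base_qualities: np.ndarray | None = None


class KmerIndex:
    """Exact k-mer -> start-position map over the forward strand of a genome.

    Reverse-strand placements are found by querying with the reverse
    complement of the read, so indexing the forward strand covers both
    orientations.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k < 8:
            raise ValueError("k must be >= 8")
        shortest = min(len(s) for s in genome.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest chromosome length {shortest}")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def query(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._index.values())


def build_kmer_index(genome: dict[str, str], k: int = 16) -> KmerIndex:
    return KmerIndex(genome, k)


def mean_quality(quals: np.ndarray) -> float:
    return float(np.mean(quals)) if len(quals) else 0.0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _candidate_loci(seq: str, index: KmerIndex) -> set[tuple[str, int]]:
    """Seed candidate start positions for one read orientation."""
    k, n = index.k, len(seq)
    out: set[tuple[str, int]] = set()
    for offset in {0, (n - k) // 2, n - k}:
        for chrom, hit in index.query(seq[offset : offset + k]):
            start = hit - offset
            if start >= 0:
                out.add((chrom, start))
    return out


def align_read(
    read_id: str,
    seq: str,
    quals: np.ndarray,
    index_g1: KmerIndex,
    index_g2: KmerIndex,
    g1: dict[str, str],
    g2: dict[str, str],
    max_mismatches: int = 3,
) -> ReadAlignment:
    """Place one read on both genomes and assign a haplotype.

    Candidate loci come from k-mer seeds in either genome's index (the
    genomes share coordinates, so candidates are pooled); each candidate is
    scored by full-length Hamming distance against both genomes and ranked
    by the better of the two counts.  Multiple distinct equally-best loci,
    or both counts above ``max_mismatches``, yield UNMAPPED.
    """
    seq = seq.upper()
    n = len(seq)
    if n < index_g1.k:
        return ReadAlignment(read_id, None, None, None, None, None, UNMAPPED)
    best: list[tuple[str, int, str, int, int]] = []  # (chrom, start, strand, mm1, mm2)
    best_score: int | None = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        cands = _candidate_loci(oriented, index_g1) | _candidate_loci(oriented, index_g2)
        for chrom, start in cands:
            if start + n > len(g1[chrom]):
                continue
            mm1 = _hamming(oriented, g1[chrom][start : start + n])
            mm2 = _hamming(oriented, g2[chrom][start : start + n])
            score = min(mm1, mm2)
            if best_score is None or score < best_score:
                best_score = score
                best = [(chrom, start, strand, mm1, mm2)]
            elif score == best_score:
                best.append((chrom, start, strand, mm1, mm2))
    if best_score is None or best_score > max_mismatches:
        return ReadAlignment(read_id, None, None, None, None, None, UNMAPPED)
    distinct_loci = {(c, s) for c, s, *_ in best}
    if len(distinct_loci) > 1:
        return ReadAlignment(read_id, None, None, None, None, None, UNMAPPED)
    chrom, start, strand, mm1, mm2 = best[0]
    assignment = TIE if mm1 == mm2 else (G1 if mm1 < mm2 else G2)
    oriented_seq = seq if strand == "+" else revcomp(seq)
    oriented_quals = quals if strand == "+" else quals[::-1]
    return ReadAlignment(
        read_id, chrom, start, strand, mm1, mm2, assignment,
        aligned_sequence=oriented_seq, base_qualities=np.asarray(oriented_quals),
    )


def align_fastq(
    fastq_path: str | Path,
    g1: dict[str, str],
    g2: dict[str, str],
    k: int = 16,
    max_mismatches: int = 3,
    min_mean_quality: float = 20.0,
) -> tuple[list[ReadAlignment], dict[str, int]]:
    """Align a FASTQ against both personal genomes.

    Reads with mean base quality below ``min_mean_quality`` are dropped
    before alignment (quality screen, Phred scale).
    """
    index_g1 = build_kmer_index(g1, k)
    index_g2 = build_kmer_index(g2, k)
    alignments: list[ReadAlignment] = []
    stats = {"total": 0, "low_quality": 0, "unmapped": 0, "tie": 0, "g1": 0, "g2": 0}
    with pysam.FastxFile(str(fastq_path)) as fq:
        for entry in fq:
            stats["total"] += 1
            quals = np.array(entry.get_quality_array(), dtype=np.int32)
            if mean_quality(quals) < min_mean_quality:
                stats["low_quality"] += 1
                continue
            aln = align_read(
                entry.name, entry.sequence, quals, index_g1, index_g2, g1, g2, max_mismatches
            )
            stats[aln.assignment.lower() if aln.assignment != UNMAPPED else "unmapped"] += 1
            alignments.append(aln)
    logger.info("aligned %s: %s", fastq_path, stats)
    return alignments, stats


def import_alignment_pair(
    sam_g1: str | Path,
    sam_g2: str | Path,
    g1: dict[str, str] | None = None,
    g2: dict[str, str] | None = None,
    min_mapq: int = 0,
) -> tuple[list[ReadAlignment], dict[str, int]]:
    """Ingest external per-genome alignments (SAM) and assign haplotypes.

    Mismatch counts come from the NM tag when present, otherwise they are
    recomputed against the loaded genome sequences.  Reads below the
    mapping-quality floor, unmapped in both files, or present in only one
    file with no mapped mate record, are handled per read and tallied.
    """

    def _load(path: str | Path, genome: dict[str, str] | None) -> dict[str, dict]:
        out: dict[str, dict] = {}
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_secondary or rec.is_supplementary:
                    continue
                info: dict = {"mapped": not rec.is_unmapped}
                if info["mapped"]:
                    if rec.has_tag("NM"):
                        nm = int(rec.get_tag("NM"))
                    elif genome is not None:
                        seq = (rec.query_sequence or "").upper()
                        ref = genome[rec.reference_name][
                            rec.reference_start : rec.reference_start + len(seq)
                        ]
                        nm = _hamming(seq, ref)
                    else:
                        raise ValueError(
                            f"{path}: read {rec.query_name} lacks NM and no genome given"
                        )
                    info.update(
                        chrom=rec.reference_name,
                        start=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        nm=nm,
                        mapq=rec.mapping_quality,
                        seq=(rec.query_sequence or "").upper(),
                        quals=np.array(rec.query_qualities or [], dtype=np.int32),
                    )
                out[rec.query_name] = info
        return out

    recs1 = _load(sam_g1, g1)
    recs2 = _load(sam_g2, g2)
    report = {"only_in_one": 0, "low_mapq": 0}
    alignments: list[ReadAlignment] = []
    for name in sorted(set(recs1) | set(recs2)):
        r1, r2 = recs1.get(name), recs2.get(name)
        if r1 is None or r2 is None:
            report["only_in_one"] += 1
        m1 = r1 if (r1 and r1["mapped"]) else None
        m2 = r2 if (r2 and r2["mapped"]) else None
        if m1 and m1["mapq"] < min_mapq:
            m1 = None
            report["low_mapq"] += 1
        if m2 and m2["mapq"] < min_mapq:
            m2 = None
            report["low_mapq"] += 1
        if m1 is None and m2 is None:
            alignments.append(ReadAlignment(name, None, None, None, None, None, UNMAPPED))
            continue
        anchor = m1 if m1 is not None else m2
        mm1 = m1["nm"] if m1 else None
        mm2 = m2["nm"] if m2 else None
        if mm1 is None:
            assignment = G2
        elif mm2 is None:
            assignment = G1
        elif mm1 < mm2:
            assignment = G1
        elif mm2 < mm1:
            assignment = G2
        else:
            assignment = TIE
        alignments.append(
            ReadAlignment(
                name, anchor["chrom"], anchor["start"], anchor["strand"], mm1, mm2,
                assignment, aligned_sequence=anchor["seq"] or None,
                base_qualities=anchor["quals"] if len(anchor["quals"]) else None,
            )
        )
    return alignments, report


def write_assignment_tsv(alignments: list[ReadAlignment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tstrand\tmm_g1\tmm_g2\tassignment\n")
        for a in alignments:
            fh.write(
                "\t".join(
                    str(x) if x is not None else "."
                    for x in (a.read_id, a.chrom, a.start, a.strand,
                              a.mismatches_g1, a.mismatches_g2, a.assignment)
                )
                + "\n"
            )
    return path
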