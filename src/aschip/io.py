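"""Plain-text readers/writers for the pipeline's file formats.

Readers lean on the standard libraries (pyfaidx for FASTA, pysam for
VCF/SAM elsewhere); writers are deliberate plain-text emitters because the
synthetic-data module guarantees byte-identical output under a fixed seed,
and that guarantee must not depend on library header defaults.

Coordinate conventions: FASTA/VCF positions are 1-based; BED intervals are
0-based half-open.  All conversions happen at these boundaries, nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

from intervaltree import IntervalTree
from pyfaidx import Faidx, Fasta

logger = logging.getLogger(__name__)

_FASTA_WIDTH = 60


def write_fasta(path: str | Path, sequences: Mapping[str, str], build_index: bool = True) -> Path:
    """Write sequences as FASTA (60-column wrap) and build a .fai sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i : i + _FASTA_WIDTH] + "\n")
    if build_index:
        Faidx(str(path), rebuild=True)  # writes <path>.fai sidecar
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory, uppercased (soft-masking is irrelevant here)."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> Path:
    """Write (read_id, sequence, quality-string) triples as Phred+33 FASTQ."""
    path = Path(path)
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {read_id}: sequence/quality length mismatch")
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
    return path


def write_bed(path: str | Path, intervals: Iterable[tuple]) -> Path:
    """Write BED3/BED4 rows: (chrom, start, end[, name]); 0-based half-open."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            if not 0 <= start < end:
                raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
            fields = [chrom, str(start), str(end)] + [str(x) for x in row[3:]]
            fh.write("\t".join(fields) + "\n")
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int, str | None]]:
    """Parse BED3/BED4. Malformed lines are a hard error naming the line."""
    rows: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start},{end})")
            rows.append((fields[0], start, end, fields[3] if len(fields) > 3 else None))
    return rows


def bed_to_trees(rows: Iterable[tuple]) -> dict[str, IntervalTree]:
    """Index BED rows as per-chromosome interval trees (data = name or None)."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, *rest in rows:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, rest[0] if rest else None)
    return trees


def load_bed_trees(path: str | Path) -> dict[str, IntervalTree]:
    return bed_to_trees(read_bed(path))
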