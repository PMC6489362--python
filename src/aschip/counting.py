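"""Haplotype-resolved allele counting at heterozygous sites.

Counting keys on the *observed base* at the SNP column of each assigned
read, not merely on the read's genome assignment: a read spanning two het
sites contributes correct per-site evidence even if one of its bases is a
sequencing error.  Bases matching neither haplotype allele are tallied
separately (``count_other``) and excluded from testing, so sequencing
error cannot masquerade as allelic signal.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import G1, G2, UNMAPPED, ReadAlignment, mean_quality
from .diploid import PhasedVariant

logger = logging.getLogger(__name__)


@dataclass
class AlleleCountRecord:
    """Per-mark haplotype-resolved read counts at one heterozygous site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    hap1_allele: str
    hap2_allele: str
    mark: str
    count_g1: int = 0
    count_g2: int = 0
    count_other: int = 0

    @property
    def total(self) -> int:
        return self.count_g1 + self.count_g2


def deduplicate(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse PCR-style duplicates: one representative per (chrom, start, strand).

    The survivor is the read with the highest mean base quality, ties broken
    by lexicographically smallest read_id.  Unmapped reads pass through.
    """
    groups: dict[tuple, ReadAlignment] = {}
    passthrough: list[ReadAlignment] = []
    for a in alignments:
        if a.assignment == UNMAPPED or a.chrom is None:
            passthrough.append(a)
            continue
        key = (a.chrom, a.start, a.strand)
        cur = groups.get(key)
        if cur is None:
            groups[key] = a
            continue
        a_key = (-mean_quality(a.base_qualities), a.read_id)
        cur_key = (-mean_quality(cur.base_qualities), cur.read_id)
        if a_key < cur_key:
            groups[key] = a
    return list(groups.values()) + passthrough


def count_alleles(
    alignments: list[ReadAlignment],
    variants: list[PhasedVariant],
    mark: str,
    min_base_quality: int = 20,
    chrom_lengths: dict[str, int] | None = None,
) -> list[AlleleCountRecord]:
    """Count reads per haplotype allele at every heterozygous site.

    For each non-TIE, non-UNMAPPED read overlapping a het site, the read's
    base at the site (requiring base quality >= ``min_base_quality``)
    increments count_g1 if it equals the hap1 allele, count_g2 if hap2, and
    count_other otherwise.  TIE reads carry no allelic information and are
    never counted.  Output order follows the (sorted) variant list.
    """
    het = sorted((v for v in variants if v.is_het), key=lambda v: (v.chrom, v.pos))
    by_chrom: dict[str, tuple[list[int], list[PhasedVariant]]] = {}
    records: dict[tuple[str, int], AlleleCountRecord] = {}
    for v in het:
        positions, vs = by_chrom.setdefault(v.chrom, ([], []))
        positions.append(v.pos - 1)  # 0-based for overlap arithmetic
        vs.append(v)
        records[(v.chrom, v.pos)] = AlleleCountRecord(
            v.chrom, v.pos, v.ref, v.alt, v.hap1, v.hap2, mark
        )
    for a in alignments:
        if a.assignment not in (G1, G2):
            continue
        if a.chrom not in by_chrom:
            continue
        if a.aligned_sequence is None or a.base_qualities is None:
            continue
        n = len(a.aligned_sequence)
        positions, vs = by_chrom[a.chrom]
        if a.start < 0 or (
            chrom_lengths is not None and a.start + n > chrom_lengths[a.chrom]
        ):
            raise ValueError(f"read {a.read_id}: alignment outside chromosome bounds")
        lo = bisect_left(positions, a.start)
        hi = bisect_right(positions, a.start + n - 1)
        for idx in range(lo, hi):
            v = vs[idx]
            col = positions[idx] - a.start
            if a.base_qualities[col] < min_base_quality:
                continue
            base = a.aligned_sequence[col]
            rec = records[(v.chrom, v.pos)]
            if base == v.hap1:
                rec.count_g1 += 1
            elif base == v.hap2:
                rec.count_g2 += 1
            else:
                rec.count_other += 1
    return list(records.values())


def counts_to_frame(records: list[AlleleCountRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "hap1": r.hap1_allele, "hap2": r.hap2_allele, "mark": r.mark,
                "count_g1": r.count_g1, "count_g2": r.count_g2,
                "count_other": r.count_other, "total": r.total,
            }
            for r in records
        ],
        columns=["chrom", "pos", "ref", "alt", "hap1", "hap2", "mark",
                 "count_g1", "count_g2", "count_other", "total"],
    )


def write_counts_tsv(records: list[AlleleCountRecord], path: str | Path) -> Path:
    path = Path(path)
    counts_to_frame(records).to_csv(path, sep="\t", index=False)
    return path


def read_counts_tsv(path: str | Path) -> list[AlleleCountRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlleleCountRecord(
            row.chrom, int(row.pos), row.ref, row.alt, row.hap1, row.hap2,
            row.mark, int(row.count_g1), int(row.count_g2), int(row.count_other),
        )
        for row in df.itertuples()
    ]
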