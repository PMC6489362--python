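"""AS-SNP calling: exact binomial test, FDR control, region filtering.

Per ChIP-seq mark, every heterozygous site with at least ``min_total``
informative reads is tested with an exact two-sided binomial test against
an even allelic split; Benjamini-Hochberg correction is applied within
each mark across all tested sites (genome-wide), and a site is an AS-SNP
if significant in at least one mark.  Sites inside exclusion tracks
(ENCODE-style blacklist, centromere/telomere-proximal duplicated regions)
are filtered out with the responsible track recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import AlleleCountRecord
from .io import load_bed_trees
from .stats import bh_adjust, binom_two_sided, bonferroni_adjust

logger = logging.getLogger(__name__)


@dataclass
class ASSNPRecord:
    """A tested heterozygous site with per-mark p/q-values and annotation flags."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    hap1_allele: str
    hap2_allele: str
    p_by_mark: dict[str, float] = field(default_factory=dict)
    q_by_mark: dict[str, float] = field(default_factory=dict)
    ratio_by_mark: dict[str, float] = field(default_factory=dict)  # count_g1/total
    total_by_mark: dict[str, int] = field(default_factory=dict)
    significant_marks: set[str] = field(default_factory=set)
    is_as_snp: bool = False
    filtered_reason: str | None = None

    @property
    def marks_tested(self) -> set[str]:
        return set(self.p_by_mark)

    @property
    def best_mark(self) -> str | None:
        """Mark with the smallest q-value (ties: smallest p, then name)."""
        if not self.q_by_mark:
            return None
        return min(self.q_by_mark, key=lambda m: (self.q_by_mark[m], self.p_by_mark[m], m))

    @property
    def allelic_ratio(self) -> float | None:
        """count_g1/total for the mark with the smallest q-value."""
        m = self.best_mark
        return None if m is None else self.ratio_by_mark[m]


def call_as_snps(
    counts_by_mark: dict[str, list[AlleleCountRecord]],
    min_total: int = 10,
    fdr: float = 0.05,
    correction: str = "bh",
    pool_marks: bool = False,
) -> list[ASSNPRecord]:
    """Test allelic imbalance per mark and union significant sites.

    Parameters
    ----------
    counts_by_mark : haplotype-resolved counts per ChIP-seq mark
    min_total : minimum informative reads (count_g1 + count_g2) for a site
        to be testable
    fdr : significance level on adjusted p-values
    correction : "bh" (Benjamini-Hochberg) or "bonferroni"
    pool_marks : correct across all marks jointly instead of within mark

    Returns records unique by (chrom, pos); a site significant in several
    marks yields one record with all of them in ``significant_marks``.
    """
    adjust = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}.get(correction)
    if adjust is None:
        raise ValueError(f"unknown correction {correction!r}")
    records: dict[tuple[str, int], ASSNPRecord] = {}
    tested: list[tuple[str, AlleleCountRecord, float]] = []  # (mark, rec, p)
    for mark, counts in counts_by_mark.items():
        testable = [c for c in counts if c.total >= min_total]
        if not testable:
            continue
        k = np.array([c.count_g1 for c in testable])
        n = np.array([c.total for c in testable])
        p = np.atleast_1d(binom_two_sided(k, n))
        for c, pv in zip(testable, p):
            tested.append((mark, c, float(pv)))
    if not tested:
        logger.warning("no testable sites (min_total=%d)", min_total)
        return []

    if pool_marks:
        q_all = adjust([p for _, _, p in tested])
        q_iter = [(mark, c, p, q) for (mark, c, p), q in zip(tested, q_all)]
    else:
        q_iter = []
        for mark in counts_by_mark:
            sub = [(m, c, p) for m, c, p in tested if m == mark]
            if not sub:
                continue
            q_vals = adjust([p for _, _, p in sub])
            q_iter.extend((m, c, p, float(q)) for (m, c, p), q in zip(sub, q_vals))

    for mark, c, p, q in q_iter:
        key = (c.chrom, c.pos)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = ASSNPRecord(
                c.chrom, c.pos, c.ref, c.alt, c.hap1_allele, c.hap2_allele
            )
        rec.p_by_mark[mark] = p
        rec.q_by_mark[mark] = float(q)
        rec.ratio_by_mark[mark] = c.count_g1 / c.total
        rec.total_by_mark[mark] = c.total
        if q <= fdr:
            rec.significant_marks.add(mark)
            rec.is_as_snp = True
    return sorted(records.values(), key=lambda r: (r.chrom, r.pos))


def filter_regions(
    records: list[ASSNPRecord],
    exclusion_beds: dict[str, str | Path],
) -> list[ASSNPRecord]:
    """Flag records inside exclusion tracks (blacklist, centromere/telomere).

    A 1-based site at ``pos`` is excluded iff (pos - 1) falls in some
    0-based half-open BED interval.  Excluded records keep
    ``filtered_reason`` naming the track and lose AS-SNP status; the list
    is returned in full so reporting can count what was removed.
    """
    trees_by_track = {name: load_bed_trees(path) for name, path in exclusion_beds.items()}
    for rec in records:
        for track, trees in trees_by_track.items():
            tree = trees.get(rec.chrom)
            if tree is not None and tree.overlaps_point(rec.pos - 1):
                rec.filtered_reason = track
                rec.is_as_snp = False
                break
    return records


def as_snps_to_frame(records: list[ASSNPRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "hap1": r.hap1_allele, "hap2": r.hap2_allele,
                "marks_tested": ",".join(sorted(r.marks_tested)),
                "significant_marks": ",".join(sorted(r.significant_marks)) or ".",
                "best_mark": r.best_mark or ".",
                "p_best": f"{r.p_by_mark[r.best_mark]:.6g}" if r.best_mark else ".",
                "q_best": f"{r.q_by_mark[r.best_mark]:.6g}" if r.best_mark else ".",
                "allelic_ratio": f"{r.allelic_ratio:.4f}" if r.allelic_ratio is not None else ".",
                "is_as_snp": int(r.is_as_snp),
                "filtered_reason": r.filtered_reason or ".",
            }
        )
    cols = ["chrom", "pos", "ref", "alt", "hap1", "hap2", "marks_tested",
            "significant_marks", "best_mark", "p_best", "q_best",
            "allelic_ratio", "is_as_snp", "filtered_reason"]
    return pd.DataFrame(rows, columns=cols)


def write_as_snp_outputs(records: list[ASSNPRecord], prefix: str | Path) -> dict[str, Path]:
    """Write the AS-SNP table (TSV), positions (BED) and a minimal VCF."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    as_snps_to_frame(records).to_csv(tsv, sep="\t", index=False)
    kept = [r for r in records if r.is_as_snp]
    bed = prefix.with_suffix(".bed")
    with open(bed, "w") as fh:
        for r in kept:
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\tAS_SNP\n")
    vcf = prefix.with_suffix(".vcf")
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QMIN,Number=1,Type=Float,Description="Smallest adjusted p-value">\n')
        fh.write('##INFO=<ID=MARKS,Number=.,Type=String,Description="Significant marks">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in kept:
            info = f"QMIN={r.q_by_mark[r.best_mark]:.6g};MARKS={','.join(sorted(r.significant_marks))}"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")
    return {"tsv": tsv, "bed": bed, "vcf": vcf}
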