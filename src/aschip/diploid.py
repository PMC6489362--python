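"""Personal diploid genome construction from phased SNVs.

Two haplotype genomes G1/G2 are built by substituting each variant's
phased alleles into the reference.  Substitution is SNV-only, so both
genomes keep reference coordinates — the property the whole downstream
pipeline relies on (read counts at a site are comparable across haplotypes
without liftover).

Homozygous-alt variants are substituted into both genomes (they matter for
read alignment) but only heterozygous sites are ever tested for allele
specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .io import write_fasta

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PhasedVariant:
    """One phased SNV call; the unit of heterozygous-site testing.

    ``pos`` is 1-based (VCF convention).  ``hap1``/``hap2`` are the alleles
    carried by personal genomes G1/G2; both are drawn from {ref, alt}.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hap1: str
    hap2: str
    filter: str = "PASS"
    phase_set: str | None = None

    @property
    def is_het(self) -> bool:
        return self.hap1 != self.hap2

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")
        for allele in (self.ref, self.alt, self.hap1, self.hap2):
            if allele not in _BASES:
                raise ValueError(f"{self.chrom}:{self.pos}: non-SNV allele {allele!r}")
        if not {self.hap1, self.hap2} <= {self.ref, self.alt}:
            raise ValueError(f"{self.chrom}:{self.pos}: haplotype alleles outside ref/alt")
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")


@dataclass
class PersonalGenomePair:
    """The two substituted haplotype genomes, in reference coordinates."""

    g1: dict[str, str]
    g2: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.g1.items()}


def load_phased_vcf(
    path: str | Path,
    require_pass: bool = True,
    snv_only: bool = True,
) -> tuple[list[PhasedVariant], dict[str, int]]:
    """Load phased SNVs from a VCF, with a skip report.

    Records are dropped (and counted) when they fail FILTER=PASS (with
    ``require_pass``), are not biallelic SNVs (with ``snv_only``), are
    heterozygous but unphased, or are homozygous-reference.  A file with
    zero usable variants is a hard error.
    """
    variants: list[PhasedVariant] = []
    skipped = {"non_pass": 0, "non_snv": 0, "unphased_het": 0, "hom_ref": 0, "no_genotype": 0}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            filter_str = ";".join(filters) if filters else "."
            if require_pass and filters != ["PASS"]:
                skipped["non_pass"] += 1
                continue
            alts = rec.alts or ()
            if snv_only and (
                len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES or alts[0].upper() not in _BASES
            ):
                skipped["non_snv"] += 1
                continue
            if not rec.samples:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} has no sample column")
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                skipped["no_genotype"] += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            alleles = [ref if a == 0 else alt for a in gt]
            if alleles[0] != alleles[1] and not sample.phased:
                skipped["unphased_het"] += 1
                continue
            if alleles == [ref, ref]:
                skipped["hom_ref"] += 1
                continue
            ps = sample.get("PS") if "PS" in sample else None
            variants.append(
                PhasedVariant(
                    chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                    hap1=alleles[0], hap2=alleles[1],
                    filter=filter_str, phase_set=str(ps) if ps is not None else None,
                )
            )
    if not variants:
        raise ValueError(f"{path}: no usable phased SNVs after filtering (skipped: {skipped})")
    logger.info("loaded %d variants from %s (skipped %s)", len(variants), path, skipped)
    return variants, skipped


def build_personal_genomes(
    reference: dict[str, str],
    variants: list[PhasedVariant],
) -> PersonalGenomePair:
    """Substitute phased alleles into the reference to build G1 and G2.

    Every variant's ref base must match the (uppercased) reference at its
    position; a mismatch or a duplicate position is a hard error — silent
    overwrites would corrupt downstream counts.
    """
    g1 = {c: bytearray(s.upper(), "ascii") for c, s in reference.items()}
    g2 = {c: bytearray(s.upper(), "ascii") for c, s in reference.items()}
    seen: set[tuple[str, int]] = set()
    for v in variants:
        if v.chrom not in g1:
            raise KeyError(f"variant chromosome {v.chrom!r} absent from reference")
        if v.pos > len(g1[v.chrom]):
            raise ValueError(f"{v.chrom}:{v.pos} beyond chromosome end ({len(g1[v.chrom])})")
        key = (v.chrom, v.pos)
        if key in seen:
            raise ValueError(f"duplicate variant position {v.chrom}:{v.pos}")
        seen.add(key)
        i = v.pos - 1  # 1-based VCF -> 0-based sequence
        ref_base = chr(g1[v.chrom][i])
        if ref_base != v.ref:
            raise ValueError(
                f"{v.chrom}:{v.pos}: VCF ref {v.ref} does not match reference base {ref_base}"
            )
        g1[v.chrom][i] = ord(v.hap1)
        g2[v.chrom][i] = ord(v.hap2)
    return PersonalGenomePair(
        g1={c: s.decode("ascii") for c, s in g1.items()},
        g2={c: s.decode("ascii") for c, s in g2.items()},
        provenance={"n_variants": len(variants)},
    )


def validate_round_trip(
    pair: PersonalGenomePair,
    reference: dict[str, str],
    variants: list[PhasedVariant],
) -> dict:
    """Re-derive the variant set by comparing G1/G2 to the reference.

    Report-only: lists positions where the recovered alleles disagree with
    the input variants, plus differing positions not explained by any
    variant.  A freshly built pair yields zero discrepancies.
    """
    by_pos = {(v.chrom, v.pos): v for v in variants}
    discrepancies: list[str] = []
    recovered = 0
    for chrom, ref_seq in reference.items():
        ref_u = ref_seq.upper()
        s1, s2 = pair.g1[chrom], pair.g2[chrom]
        if len(s1) != len(ref_u) or len(s2) != len(ref_u):
            discrepancies.append(f"{chrom}: length mismatch")
            continue
        for i, (r, a, b) in enumerate(zip(ref_u, s1, s2)):
            if r == a == b:
                continue
            v = by_pos.get((chrom, i + 1))
            if v is None:
                discrepancies.append(f"{chrom}:{i + 1}: unexplained difference {r}->{a}/{b}")
            elif (a, b) != (v.hap1, v.hap2):
                discrepancies.append(
                    f"{chrom}:{i + 1}: alleles {a}/{b} != expected {v.hap1}/{v.hap2}"
                )
            else:
                recovered += 1
    # variants whose substitution left no trace (hap1 == hap2 == ref is impossible
    # by construction; a corrupted pair can miss them)
    for (chrom, pos), v in by_pos.items():
        i = pos - 1
        if pair.g1[chrom][i] != v.hap1 or pair.g2[chrom][i] != v.hap2:
            msg = f"{chrom}:{pos}: variant not recovered"
            if msg not in discrepancies and not any(f"{chrom}:{pos}:" in d for d in discrepancies):
                discrepancies.append(msg)
    return {
        "n_variants": len(variants),
        "n_recovered": recovered,
        "discrepancies": discrepancies,
        "ok": not discrepancies,
    }


def write_personal_genomes(
    pair: PersonalGenomePair, prefix: str | Path
) -> tuple[Path, Path]:
    """Write G1/G2 as FASTA files with _G1/_G2 suffixes (plus .fai sidecars)."""
    prefix = Path(prefix)
    p1 = write_fasta(prefix.with_name(prefix.name + "_G1.fa"), pair.g1)
    p2 = write_fasta(prefix.with_name(prefix.name + "_G2.fa"), pair.g2)
    return p1, p2
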