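"""GWAS, LD, and eQTL annotation of AS-SNPs; 1-Mb locus clustering.

Connects the AS-SNP catalog to disease and expression: direct positional
intersection with GWAS catalog top hits, LD expansion of those hits to
proxies with r^2 above a strict threshold (0.8 by default, matching the
usual high-LD convention), positional intersection with an eQTL
association table, single-linkage clustering of linked AS-SNPs into loci
with a 1-Mb gap rule, and a per-trait summary table.

r^2 between two sites is the squared correlation of their allele states
across phased haplotypes: with haplotype frequency p_AB and allele
frequencies p_A, p_B, D = p_AB - p_A*p_B and r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import ASSNPRecord

logger = logging.getLogger(__name__)

SnpKey = tuple[str, int]  # (chrom, 1-based pos)


@dataclass(frozen=True)
class GWASRecord:
    rsid: str
    chrom: str
    pos: int  # 1-based
    trait: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1")


@dataclass(frozen=True)
class EQTLRecord:
    chrom: str
    pos: int
    variant_id: str
    gene: str
    tissue: str
    association_p: float


@dataclass(frozen=True)
class LDProxy:
    """A proxy SNP in high LD with a source GWAS SNP."""

    chrom: str
    pos: int
    r2: float
    source_rsid: str


@dataclass
class GWASAnnotation:
    """GWAS status of one AS-SNP: direct hit, LD proxy, or unlinked."""

    chrom: str
    pos: int
    status: str  # direct_hit | ld_proxy | unlinked
    source_rsid: str | None = None
    r2: float | None = None
    traits: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n_as_snps: int
    n_loci: int


def compute_r2(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float | None:
    """r^2 from haplotype counts in conventional (AB, Ab, aB, ab) order.

    Returns None (explicit not-computable marker) if either site is
    monomorphic in the panel.
    """
    counts = np.array([n_AB, n_Ab, n_aB, n_ab], dtype=float)
    if np.any(counts < 0):
        raise ValueError("haplotype counts must be nonnegative")
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one haplotype")
    p_AB, p_Ab, p_aB, _ = counts / total
    p_A = p_AB + p_Ab  # freq of allele A at site 1
    p_B = p_AB + p_aB  # freq of allele B at site 2
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    if denom == 0:
        return None
    d = p_AB - p_A * p_B
    return float(d * d / denom)


def r2_from_haplotypes(col_a: np.ndarray, col_b: np.ndarray) -> float | None:
    """r^2 from two 0/1 haplotype indicator vectors (shared row order)."""
    a = np.asarray(col_a, dtype=int)
    b = np.asarray(col_b, dtype=int)
    n_AB = int(np.sum((a == 1) & (b == 1)))
    n_Ab = int(np.sum((a == 1) & (b == 0)))
    n_aB = int(np.sum((a == 0) & (b == 1)))
    n_ab = int(np.sum((a == 0) & (b == 0)))
    return compute_r2(n_AB, n_Ab, n_aB, n_ab)


def load_gwas_tsv(path: str | Path) -> list[GWASRecord]:
    df = pd.read_csv(path, sep="\t")
    return [GWASRecord(r.rsid, r.chrom, int(r.pos), r.trait) for r in df.itertuples()]


def load_eqtl_tsv(path: str | Path) -> list[EQTLRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        chrom, pos = str(r.variant_id).split(":")[:2]
        out.append(EQTLRecord(chrom, int(pos), r.variant_id, r.gene, r.tissue, float(r.p)))
    return out


def load_ld_table(path: str | Path) -> pd.DataFrame:
    """LD pair table with snp ids encoded as 'chrom:pos' (columns snp_a, snp_b, r2)."""
    return pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})


def load_haplotype_panel(path: str | Path) -> pd.DataFrame:
    """Phased panel: one column per SNP ('chrom:pos'), one row per haplotype, 0/1."""
    return pd.read_csv(path, sep="\t")


def _key(snp_id: str) -> SnpKey:
    chrom, pos = snp_id.split(":")[:2]
    return chrom, int(pos)


def expand_ld(
    gwas: list[GWASRecord],
    ld_source: pd.DataFrame,
    threshold: float = 0.8,
    panel: bool = False,
) -> dict[SnpKey, list[LDProxy]]:
    """Expand GWAS top hits to proxies with r^2 strictly above ``threshold``.

    ``ld_source`` is either a precomputed pair table (snp_a, snp_b, r2) or,
    with ``panel=True``, a phased haplotype matrix from which r^2 is
    computed against every other panel SNP on the same chromosome.  GWAS
    SNPs absent from the source are logged and skipped.  Proxies at
    exactly the threshold are excluded (strict inequality).
    """
    gwas_by_key: dict[SnpKey, list[GWASRecord]] = {}
    for g in gwas:
        gwas_by_key.setdefault((g.chrom, g.pos), []).append(g)
    proxies: dict[SnpKey, list[LDProxy]] = {}

    if panel:
        keys = {col: _key(col) for col in ld_source.columns}
        for gkey, grecs in gwas_by_key.items():
            gcol = next((c for c, k in keys.items() if k == gkey), None)
            if gcol is None:
                logger.warning("GWAS SNP %s:%d absent from haplotype panel", *gkey)
                continue
            for col, key in keys.items():
                if key == gkey or key[0] != gkey[0]:
                    continue
                r2 = r2_from_haplotypes(ld_source[gcol].values, ld_source[col].values)
                if r2 is not None and r2 > threshold:
                    proxies.setdefault(gkey, []).append(
                        LDProxy(key[0], key[1], r2, grecs[0].rsid)
                    )
        return proxies

    pair_index: dict[SnpKey, list[tuple[SnpKey, float]]] = {}
    for row in ld_source.itertuples():
        a, b, r2 = _key(row.snp_a), _key(row.snp_b), float(row.r2)
        pair_index.setdefault(a, []).append((b, r2))
        pair_index.setdefault(b, []).append((a, r2))  # LD is symmetric in a/b
    for gkey, grecs in gwas_by_key.items():
        if gkey not in pair_index:
            logger.warning("GWAS SNP %s:%d absent from LD table", *gkey)
            continue
        for pkey, r2 in pair_index[gkey]:
            if r2 > threshold:
                proxies.setdefault(gkey, []).append(LDProxy(pkey[0], pkey[1], r2, grecs[0].rsid))
    return proxies


def annotate_gwas(
    as_snps: list[ASSNPRecord],
    gwas: list[GWASRecord],
    proxy_map: dict[SnpKey, list[LDProxy]],
) -> list[GWASAnnotation]:
    """Label each AS-SNP as direct GWAS hit, LD proxy, or unlinked.

    Matching is positional ((chrom, pos) on one build).  A direct hit takes
    precedence over proxy status; a proxy annotation carries the source
    GWAS SNP and the r^2 that linked it.  Duplicate rsids at conflicting
    positions are a hard error.
    """
    pos_by_rsid: dict[str, SnpKey] = {}
    traits_by_key: dict[SnpKey, set[str]] = {}
    for g in gwas:
        key = (g.chrom, g.pos)
        if g.rsid in pos_by_rsid and pos_by_rsid[g.rsid] != key:
            raise ValueError(f"rsid {g.rsid} reported at conflicting positions")
        pos_by_rsid[g.rsid] = key
        traits_by_key.setdefault(key, set()).add(g.trait)
    proxy_by_pos: dict[SnpKey, LDProxy] = {}
    for gkey, plist in proxy_map.items():
        for p in plist:
            cur = proxy_by_pos.get((p.chrom, p.pos))
            if cur is None or p.r2 > cur.r2:  # keep strongest link
                proxy_by_pos[(p.chrom, p.pos)] = p
    out: list[GWASAnnotation] = []
    for rec in as_snps:
        key = (rec.chrom, rec.pos)
        if key in traits_by_key:
            out.append(GWASAnnotation(rec.chrom, rec.pos, "direct_hit",
                                      traits=frozenset(traits_by_key[key])))
        elif key in proxy_by_pos:
            p = proxy_by_pos[key]
            src_traits = traits_by_key.get(pos_by_rsid.get(p.source_rsid, ("", -1)), set())
            out.append(GWASAnnotation(rec.chrom, rec.pos, "ld_proxy",
                                      source_rsid=p.source_rsid, r2=p.r2,
                                      traits=frozenset(src_traits)))
        else:
            out.append(GWASAnnotation(rec.chrom, rec.pos, "unlinked"))
    return out


def annotate_eqtl(
    as_snps: list[ASSNPRecord],
    eqtl: list[EQTLRecord],
) -> dict[SnpKey, list[str]]:
    """Attach the gene list of all eQTL records at each AS-SNP position."""
    genes_by_key: dict[SnpKey, list[str]] = {}
    for e in eqtl:
        genes_by_key.setdefault((e.chrom, e.pos), []).append(e.gene)
    return {
        (r.chrom, r.pos): sorted(set(genes_by_key.get((r.chrom, r.pos), [])))
        for r in as_snps
    }


def cluster_loci(
    positions: list[SnpKey],
    window: int = 1_000_000,
) -> dict[SnpKey, int]:
    """Single-linkage 1-Mb chaining of SNPs into loci.

    Consecutive sorted positions on one chromosome join a locus iff their
    gap is <= ``window``; loci never span chromosomes.  Returns a locus id
    per SNP; ids are dense and ordered by (chrom, first position).
    """
    assignment: dict[SnpKey, int] = {}
    locus = -1
    prev_chrom, prev_pos = None, None
    for chrom, pos in sorted(set(positions)):
        if chrom != prev_chrom or pos - prev_pos > window:
            locus += 1
        assignment[(chrom, pos)] = locus
        prev_chrom, prev_pos = chrom, pos
    return assignment


def summarize_traits(
    annotations: list[GWASAnnotation],
    window: int = 1_000_000,
) -> tuple[list[TraitSummary], TraitSummary]:
    """Per-trait AS-SNP and locus counts, plus a unique-count totals row.

    An AS-SNP linked (directly or by proxy) to several traits appears in
    each trait's row but is counted once in the totals.
    """
    linked = [a for a in annotations if a.status in ("direct_hit", "ld_proxy")]
    by_trait: dict[str, set[SnpKey]] = {}
    for a in linked:
        for t in sorted(a.traits) or ["(unspecified)"]:
            by_trait.setdefault(t, set()).add((a.chrom, a.pos))
    summaries = []
    for trait in sorted(by_trait, key=lambda t: (-len(by_trait[t]), t)):
        keys = sorted(by_trait[trait])
        loci = cluster_loci(keys, window)
        summaries.append(TraitSummary(trait, len(keys), len(set(loci.values()))))
    all_keys = sorted({(a.chrom, a.pos) for a in linked})
    total_loci = len(set(cluster_loci(all_keys, window).values())) if all_keys else 0
    return summaries, TraitSummary("Total", len(all_keys), total_loci)


def annotation_frame(
    as_snps: list[ASSNPRecord],
    gwas_ann: list[GWASAnnotation],
    eqtl_genes: dict[SnpKey, list[str]],
) -> pd.DataFrame:
    """Combined annotated AS-SNP table (one row per AS-SNP)."""
    ann_by_key = {(a.chrom, a.pos): a for a in gwas_ann}
    rows = []
    for r in as_snps:
        key = (r.chrom, r.pos)
        a = ann_by_key.get(key)
        genes = eqtl_genes.get(key, [])
        rows.append({
            "chrom": r.chrom, "pos": r.pos,
            "significant_marks": ",".join(sorted(r.significant_marks)) or ".",
            "allelic_ratio": f"{r.allelic_ratio:.4f}" if r.allelic_ratio is not None else ".",
            "gwas_status": a.status if a else "unlinked",
            "gwas_source": (a.source_rsid or ".") if a else ".",
            "gwas_r2": f"{a.r2:.4f}" if a and a.r2 is not None else ".",
            "traits": ";".join(sorted(a.traits)) if a and a.traits else ".",
            "eqtl_genes": ";".join(genes) if genes else ".",
        })
    cols = ["chrom", "pos", "significant_marks", "allelic_ratio", "gwas_status",
            "gwas_source", "gwas_r2", "traits", "eqtl_genes"]
    return pd.DataFrame(rows, columns=cols)


def trait_summary_frame(summaries: list[TraitSummary], total: TraitSummary) -> pd.DataFrame:
    rows = [{"trait": s.trait, "n_as_snps": s.n_as_snps, "n_loci": s.n_loci}
            for s in summaries + [total]]
    return pd.DataFrame(rows, columns=["trait", "n_as_snps", "n_loci"])
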