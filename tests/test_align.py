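"""Allele-aware alignment: k-mer index, assignment, SAM import, oracle equivalence."""

import numpy as np
import pytest

from aschip.align import (
    G1,
    G2,
    TIE,
    UNMAPPED,
    align_fastq,
    align_read,
    build_kmer_index,
    import_alignment_pair,
    revcomp,
)
from aschip.diploid import PhasedVariant, build_personal_genomes

Q30 = np.full(100, 30)


def _indexes(g1, g2, k=16):
    return build_kmer_index(g1, k), build_kmer_index(g2, k)


def brute_force_assign(seq, g1, g2, max_mismatches=3):
    """Oracle: all-positions Hamming scan on both strands, same selection rule."""

    def windows(genome_seq, n):
        arr = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
        return np.lib.stride_tricks.sliding_window_view(arr, n)

    n = len(seq)
    best_score, best = None, []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        q = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for chrom in g1:
            w1 = windows(g1[chrom], n)
            w2 = windows(g2[chrom], n)
            mm1 = (w1 != q).sum(axis=1)
            mm2 = (w2 != q).sum(axis=1)
            score = np.minimum(mm1, mm2)
            for pos in range(len(score)):
                s = int(score[pos])
                if best_score is None or s < best_score:
                    best_score, best = s, [(chrom, pos, strand, int(mm1[pos]), int(mm2[pos]))]
                elif s == best_score:
                    best.append((chrom, pos, strand, int(mm1[pos]), int(mm2[pos])))
    if best_score is None or best_score > max_mismatches:
        return UNMAPPED, None, None
    if len({(c, p) for c, p, *_ in best}) > 1:
        return UNMAPPED, None, None
    chrom, pos, strand, mm1, mm2 = best[0]
    assignment = TIE if mm1 == mm2 else (G1 if mm1 < mm2 else G2)
    return assignment, (chrom, pos), (mm1, mm2)


def test_kmer_index_counts_and_queries():
    idx = build_kmer_index({"c": "ACGTACGTACGTACGTACGT"}, k=10)
    assert len(idx) == 11  # n - k + 1 forward start positions
    # a k-mer present several times returns every position
    assert idx.query("ACGTACGTAC") == [("c", 0), ("c", 4), ("c", 8)]
    assert idx.query("TTTTTTTTTT") == []


def test_kmer_index_validation():
    with pytest.raises(ValueError, match="k must be >= 8"):
        build_kmer_index({"c": "ACGTACGTAC"}, k=4)
    with pytest.raises(ValueError, match="shortest chromosome"):
        build_kmer_index({"c": "ACGTACGTAC"}, k=16)


@pytest.fixture()
def toy_genomes():
    rng = np.random.default_rng(3)
    ref = {"c": "".join(rng.choice(list("ACGT"), 2000))}
    variants = [
        PhasedVariant("c", 500, ref["c"][499], _other(ref["c"][499]),
                      ref["c"][499], _other(ref["c"][499])),
        PhasedVariant("c", 540, ref["c"][539], _other(ref["c"][539]),
                      ref["c"][539], _other(ref["c"][539])),
    ]
    pair = build_personal_genomes(ref, variants)
    return pair.g1, pair.g2


def _other(base):
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]


def test_read_from_g2_assigned_g2(toy_genomes):
    g1, g2 = toy_genomes
    read = g2["c"][480:530]  # covers het site at 0-based 499
    aln = align_read("r", read, np.full(50, 30), *_indexes(g1, g2), g1, g2)
    assert aln.assignment == G2 and aln.mismatches_g2 == 0 and aln.mismatches_g1 == 1
    assert aln.start == 480


def test_read_outside_variants_is_tie(toy_genomes):
    g1, g2 = toy_genomes
    read = g1["c"][1000:1050]
    aln = align_read("r", read, np.full(50, 30), *_indexes(g1, g2), g1, g2)
    assert aln.assignment == TIE and aln.mismatches_g1 == aln.mismatches_g2 == 0


def test_two_het_sites_one_error(toy_genomes):
    # read matches hap1 at both het sites with one error elsewhere:
    # mm_g1 = 1 (the error), mm_g2 = 3 (error + two het sites)
    g1, g2 = toy_genomes
    read = list(g1["c"][495:545])
    read[30] = _other(read[30])  # error at a non-variant column
    aln = align_read("r", "".join(read), np.full(50, 30), *_indexes(g1, g2), g1, g2)
    assert (aln.mismatches_g1, aln.mismatches_g2, aln.assignment) == (1, 3, G1)


def test_reverse_strand_read_is_oriented_back(toy_genomes):
    g1, g2 = toy_genomes
    read = revcomp(g1["c"][490:540])
    aln = align_read("r", read, np.full(50, 30), *_indexes(g1, g2), g1, g2)
    assert aln.strand == "-" and aln.assignment == G1
    assert aln.aligned_sequence == g1["c"][490:540]  # genome-forward orientation


def test_symmetry_swapping_genomes(toy_genomes):
    g1, g2 = toy_genomes
    rng = np.random.default_rng(9)
    for _ in range(20):
        start = int(rng.integers(0, 1950))
        src = g1 if rng.random() < 0.5 else g2
        read = src["c"][start : start + 50]
        a = align_read("r", read, np.full(50, 30), *_indexes(g1, g2), g1, g2)
        b = align_read("r", read, np.full(50, 30), *_indexes(g2, g1), g2, g1)
        swap = {G1: G2, G2: G1, TIE: TIE, UNMAPPED: UNMAPPED}
        assert b.assignment == swap[a.assignment]
        assert (a.mismatches_g1, a.mismatches_g2) == (b.mismatches_g2, b.mismatches_g1)


def test_agrees_with_brute_force_oracle(toy_genomes):
    g1, g2 = toy_genomes
    idx1, idx2 = _indexes(g1, g2)
    rng = np.random.default_rng(17)
    n_checked = 0
    for _ in range(60):
        start = int(rng.integers(0, 1900))
        src = g1 if rng.random() < 0.5 else g2
        read = list(src["c"][start : start + 80])
        for _e in range(int(rng.integers(0, 3))):  # up to 2 errors
            col = int(rng.integers(0, 80))
            read[col] = _other(read[col])
        if rng.random() < 0.5:
            read = list(revcomp("".join(read)))
        seq = "".join(read)
        aln = align_read("r", seq, np.full(80, 30), idx1, idx2, g1, g2)
        expected, locus, mms = brute_force_assign(seq, g1, g2)
        assert aln.assignment == expected
        if expected not in (UNMAPPED,):
            assert (aln.chrom, aln.start) == locus
            assert (aln.mismatches_g1, aln.mismatches_g2) == mms
            n_checked += 1
    assert n_checked > 30  # the comparison actually exercised mapped reads


def test_error_free_reads_follow_haplotype_of_origin(toy_genomes):
    # property: reads overlapping >=1 het site go to their haplotype; others TIE
    g1, g2 = toy_genomes
    idx1, idx2 = _indexes(g1, g2)
    het0 = {499, 539}
    rng = np.random.default_rng(23)
    for _ in range(40):
        start = int(rng.integers(0, 1920))
        hap, src = (G1, g1) if rng.random() < 0.5 else (G2, g2)
        read = src["c"][start : start + 60]
        aln = align_read("r", read, np.full(60, 30), idx1, idx2, g1, g2)
        overlaps = any(start <= h < start + 60 for h in het0)
        assert aln.assignment == (hap if overlaps else TIE)


def test_align_fastq_quality_screen(tmp_path, toy_genomes):
    g1, g2 = toy_genomes
    fq = tmp_path / "reads.fastq"
    good = g1["c"][100:150]
    fq.write_text(
        f"@ok\n{good}\n+\n{'?' * 50}\n"      # Q30
        f"@bad\n{good}\n+\n{'+' * 50}\n"     # Q10 mean < 20 -> screened out
    )
    alignments, stats = align_fastq(fq, g1, g2)
    assert stats["low_quality"] == 1 and len(alignments) == 1
    assert alignments[0].read_id == "ok"


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:c\tLN:2000\n"


def test_import_alignment_pair_hand_labeled(tmp_path, toy_genomes):
    g1, g2 = toy_genomes
    seq = g1["c"][100:150]
    rows = [  # (name, nm_g1, nm_g2) -> expected assignment
        ("r1", 0, 1, G1),
        ("r2", 1, 2, G1),
        ("r3", 2, 0, G2),
        ("r4", 1, 1, TIE),
        ("r5", 0, 0, TIE),
    ]
    sam1 = SAM_HEADER + "".join(
        f"{n}\t0\tc\t101\t60\t50M\t*\t0\t0\t{seq}\t{'?' * 50}\tNM:i:{a}\n" for n, a, _b, _e in rows
    ) + "r6\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
    sam2 = SAM_HEADER + "".join(
        f"{n}\t0\tc\t101\t60\t50M\t*\t0\t0\t{seq}\t{'?' * 50}\tNM:i:{b}\n" for n, _a, b, _e in rows
    ) + "r6\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
    p1, p2 = tmp_path / "g1.sam", tmp_path / "g2.sam"
    p1.write_text(sam1)
    p2.write_text(sam2)
    alignments, report = import_alignment_pair(p1, p2)
    got = {a.read_id: a.assignment for a in alignments}
    assert got == {"r1": G1, "r2": G1, "r3": G2, "r4": TIE, "r5": TIE, "r6": UNMAPPED}
    assert report["only_in_one"] == 0


def test_import_alignment_recomputes_missing_nm(tmp_path, toy_genomes):
    g1, g2 = toy_genomes
    seq = g2["c"][480:530]  # hap2 across the het site
    line = f"r1\t0\tc\t481\t60\t50M\t*\t0\t0\t{seq}\t{'?' * 50}\n"
    (tmp_path / "g1.sam").write_text(SAM_HEADER + line)
    (tmp_path / "g2.sam").write_text(SAM_HEADER + line)
    alignments, _ = import_alignment_pair(
        tmp_path / "g1.sam", tmp_path / "g2.sam", g1=g1, g2=g2
    )
    assert alignments[0].assignment == G2
    assert (alignments[0].mismatches_g1, alignments[0].mismatches_g2) == (1, 0)
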