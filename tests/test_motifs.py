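"""PWM loading, scanning, allele-pair scoring, candidate-functional rule."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from aschip.diploid import PersonalGenomePair
from aschip.motifs import (
    PWM,
    AnnotationBundle,
    MotifHit,
    _normalize_counts,
    annotate_hit,
    call_candidate_functional,
    functionality_score,
    load_pwms,
    normalized_score,
    scan_scores,
    score_allele_pair,
    summarize_motifs,
)

JASPAR_TEXT = """\
>M1 TFA
A [ 8 0 1 2 ]
C [ 0 8 1 2 ]
G [ 0 0 6 2 ]
T [ 0 0 0 2 ]
"""


def test_load_pwms_pseudocount_arithmetic(tmp_path):
    path = tmp_path / "m.jaspar"
    path.write_text(JASPAR_TEXT)
    (pwm,) = load_pwms(path, pseudocount=0.01)
    # count column (8,0,0,0) with pc 0.01 -> 8.01/8.04, 0.01/8.04 x3
    assert pwm.matrix[0] == pytest.approx([8.01 / 8.04, 0.01 / 8.04, 0.01 / 8.04, 0.01 / 8.04])
    assert pwm.tf == "TFA" and len(pwm) == 4


def test_load_pwms_duplicate_names_error(tmp_path):
    path = tmp_path / "dup.jaspar"
    path.write_text(JASPAR_TEXT + JASPAR_TEXT)
    with pytest.raises(ValueError, match="duplicate"):
        load_pwms(path)


def test_probability_matrix_stable_under_pseudocount_mixing():
    probs = np.array([[0.7, 0.1, 0.1, 0.1]] * 4)
    mixed = _normalize_counts(probs, 0.01)
    assert mixed[0] == pytest.approx((probs[0] + 0.01) / 1.04)
    assert np.allclose(mixed.sum(axis=1), 1.0)


@pytest.fixture()
def pwm():
    counts = np.array(
        [[90, 4, 3, 3], [2, 88, 5, 5], [1, 1, 97, 1], [10, 10, 10, 70], [60, 20, 15, 5]]
    )
    return PWM("P1", "TF1", _normalize_counts(counts, 0.01))


def test_consensus_scores_one_anticonsensus_zero(pwm):
    assert normalized_score(pwm.consensus, pwm) == pytest.approx(1.0, abs=1e-12)
    assert normalized_score(pwm.anticonsensus, pwm) == pytest.approx(0.0, abs=1e-12)


def test_scan_matches_per_position_summation_oracle(pwm):
    rng = np.random.default_rng(31)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(10):
        window = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 50))))
        scores = scan_scores(window, pwm)
        L = len(pwm)
        assert scores.shape == (len(window) - L + 1, 2)
        for off in range(scores.shape[0]):
            sub = window[off : off + L]
            raw_fwd = sum(
                np.log2(pwm.matrix[i, "ACGT".index(b)] / 0.25) for i, b in enumerate(sub)
            )
            rc = "".join(comp[b] for b in reversed(sub))
            raw_rev = sum(
                np.log2(pwm.matrix[i, "ACGT".index(b)] / 0.25) for i, b in enumerate(rc)
            )
            span = pwm.raw_max - pwm.raw_min
            assert scores[off, 0] == pytest.approx((raw_fwd - pwm.raw_min) / span, abs=1e-9)
            assert scores[off, 1] == pytest.approx((raw_rev - pwm.raw_min) / span, abs=1e-9)


def test_scan_skips_ambiguous_bases(pwm):
    scores = scan_scores("ACGNTACGTA", pwm)
    assert np.isnan(scores[: 4]).all()  # placements covering the N
    assert np.isfinite(scores[4:]).all()


def _genomes_with_snp(pwm, flank="TTTTTTTT"):
    """Embed the consensus; allele 2 carries the anticonsensus base at the
    dominant position."""
    info = pwm.log_odds.max(axis=1) - pwm.log_odds.min(axis=1)
    dom = int(np.argmax(info))
    g1_seq = flank + pwm.consensus + flank
    worst = pwm.anticonsensus[dom]
    g2_seq = flank + pwm.consensus[:dom] + worst + pwm.consensus[dom + 1 :] + flank
    pos = len(flank) + dom + 1  # 1-based SNP position
    return PersonalGenomePair(g1={"c": g1_seq}, g2={"c": g2_seq}), pos, dom


def test_score_allele_pair_delta_matches_brute_force(pwm):
    genomes, pos, dom = _genomes_with_snp(pwm)
    hit = score_allele_pair("c", pos, pwm, genomes)
    assert hit is not None
    assert hit.score_allele1 == pytest.approx(1.0, abs=1e-12)
    # brute-force: best placement x strand over the allele-2 window
    L = len(pwm)
    lo, hi = pos - L, pos + L - 1
    window2 = genomes.g2["c"][lo:hi]
    best2 = -1.0
    scores = scan_scores(window2, pwm)
    for off in range(scores.shape[0]):
        start = lo + off
        if start <= pos - 1 < start + L:
            best2 = max(best2, np.nanmax(scores[off]))
    assert hit.score_allele2 == pytest.approx(best2, abs=1e-9)
    assert hit.delta == pytest.approx(1.0 - best2, abs=1e-9)
    assert hit.delta > 0.1  # dominant-position flip moves the bounded score


def test_score_allele_pair_symmetry_and_null(pwm):
    genomes, pos, _ = _genomes_with_snp(pwm)
    swapped = PersonalGenomePair(g1=genomes.g2, g2=genomes.g1)
    h1 = score_allele_pair("c", pos, pwm, genomes)
    h2 = score_allele_pair("c", pos, pwm, swapped)
    assert h1.delta == pytest.approx(h2.delta, abs=1e-12)
    same = PersonalGenomePair(g1=genomes.g1, g2=genomes.g1)
    assert score_allele_pair("c", pos, pwm, same).delta == 0.0


def test_score_allele_pair_clips_at_chromosome_start(pwm):
    genomes, _, dom = _genomes_with_snp(pwm, flank="")
    hit = score_allele_pair("c", dom + 1, pwm, genomes)
    assert hit is not None and hit.placement_start == 0


def test_functionality_score_arithmetic():
    assert functionality_score(AnnotationBundle()) == 0.0
    bundle = AnnotationBundle(dnase=True, tf_chip=True, tf_expressed=True)
    weights = {"dnase": 1.0, "tf_chip": 1.0, "cage": 1.0, "tf_expressed": 1.0}
    assert functionality_score(bundle, weights) == 3.0
    # shipped default weights: dnase + tf_chip + expressed + TssA state
    full = AnnotationBundle(dnase=True, tf_chip=True, tf_expressed=True,
                            chromatin_state="TssA", replication_domain="early")
    assert functionality_score(full) == pytest.approx(1 + 1 + 1 + 1 + 0.25)
    with pytest.raises(ValueError, match="unknown annotation"):
        functionality_score(bundle, {"nonsense": 1.0})


def _hit(delta, dnase=True, expressed=True, tf_chip=False, score=0.0):
    # scores chosen so delta is exact in binary floating point
    h = MotifHit("c", 10, "P1", "TF1", "+", 5, delta, 0.0)
    h.annotations = AnnotationBundle(dnase=dnase, tf_expressed=expressed, tf_chip=tf_chip)
    h.functionality_score = score
    return h


@pytest.mark.parametrize(
    "hit, expected",
    [
        (_hit(0.35, dnase=False, tf_chip=True, score=9.0), False),  # DNase required
        (_hit(0.35, tf_chip=True, score=0.0), True),                # binding event suffices
        (_hit(0.35, tf_chip=False, score=2.55), True),              # "no less than 2.55"
        (_hit(0.35, tf_chip=False, score=2.54), False),
        (_hit(0.30, tf_chip=True), True),                           # delta boundary inclusive
        (_hit(0.29, tf_chip=True), False),
        (_hit(0.35, expressed=False, tf_chip=True), False),
    ],
)
def test_candidate_functional_rule(hit, expected):
    assert call_candidate_functional(hit) is expected


def test_candidate_functional_monotonicity():
    # increasing any satisfied margin never flips true -> false
    base = _hit(0.31, tf_chip=False, score=2.6)
    assert call_candidate_functional(base)
    assert call_candidate_functional(_hit(0.9, tf_chip=False, score=2.6))
    assert call_candidate_functional(_hit(0.31, tf_chip=False, score=99.0))
    assert call_candidate_functional(_hit(0.31, tf_chip=True, score=2.6))


def test_annotate_hit_overlap_semantics():
    hit = MotifHit("c", 10, "P1", "TF1", "+", 9, 1.0, 0.5)  # placement [9, 14)
    tracks = {
        "dnase": {"c": IntervalTree.from_tuples([(13, 20)])},      # 1-base overlap
        "tf_chip": {"c": IntervalTree.from_tuples([(0, 50)])},
        "chromatin_state": {"c": IntervalTree.from_tuples([(0, 50)])},
    }
    tracks["tf_chip"]["c"] = IntervalTree()
    tracks["tf_chip"]["c"].addi(0, 50, "OTHER_TF")
    tracks["chromatin_state"]["c"] = IntervalTree()
    tracks["chromatin_state"]["c"].addi(0, 50, "Enh")
    bundle = annotate_hit(hit, 5, tracks, {"TF1": 3.0})
    assert bundle.dnase is True
    assert bundle.tf_chip is False  # TF name must match
    assert bundle.chromatin_state == "Enh"
    assert bundle.tf_expressed is True
    miss = MotifHit("c", 30, "P1", "TF1", "+", 25, 1.0, 0.5)
    assert annotate_hit(miss, 5, {"dnase": {}}, {}).dnase is False


def test_summarize_motifs_counts():
    hits = [_hit(0.4, tf_chip=True) for _ in range(3)]
    for h in hits:
        h.candidate_functional = True
    other = _hit(0.4, tf_chip=True)
    other.tf = "KLF5"
    other.candidate_functional = True
    tf_df, state_df = summarize_motifs(hits + [other, _hit(0.1)])
    assert tf_df.set_index("tf")["n_candidate_hits"].to_dict() == {"TF1": 3, "KLF5": 1}
    assert tf_df.iloc[0]["tf"] == "TF1"  # sorted descending
    empty_tf, _ = summarize_motifs([_hit(0.1)])
    assert len(empty_tf) == 0
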