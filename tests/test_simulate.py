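"""Synthetic study generator: determinism, statistics, manifest consistency."""

import filecmp
import json

import numpy as np
import pysam
import pytest
from scipy.stats import binom

from aschip.annotate import r2_from_haplotypes
from aschip.io import read_bed, read_fasta
from aschip.simulate import (
    SimulationConfig,
    generate_phased_variants,
    generate_reference,
    simulate_all,
)
from tests.conftest import small_sim_config


def binom_ci99(n, p):
    lo, hi = binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)
    return lo, hi


def test_config_validation_errors():
    with pytest.raises(ValueError, match="as_ratio"):
        SimulationConfig(as_ratio=0.4).validate()
    with pytest.raises(ValueError, match="read_length"):
        SimulationConfig(read_length=300, fragment_length=200).validate()
    with pytest.raises(ValueError, match="variant_spacing"):
        SimulationConfig(variant_spacing=1).validate()
    with pytest.raises(ValueError, match="fragment_length"):
        SimulationConfig(chrom_length=100, fragment_length=200).validate()
    with pytest.raises(ValueError, match="positive"):
        SimulationConfig(coverage=0).validate()


def test_reference_shape_and_determinism():
    cfg = SimulationConfig(seed=1, n_chroms=2, chrom_length=10_000)
    ref1 = generate_reference(cfg)
    ref2 = generate_reference(cfg)
    assert ref1 == ref2
    assert sorted(ref1) == ["chr1", "chr2"]
    assert all(len(s) == 10_000 and set(s) <= set("ACGT") for s in ref1.values())


def test_reference_gc_content_in_binomial_band():
    # uniform sampling: GC of 100 kb within the 99% binomial band around 0.5
    cfg = SimulationConfig(seed=3, n_chroms=1, chrom_length=100_000)
    seq = generate_reference(cfg)["chr1"]
    gc = seq.count("G") + seq.count("C")
    lo, hi = binom_ci99(100_000, 0.5)
    assert lo <= gc <= hi


def test_variants_het_fraction_and_alleles():
    cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=300_000,
                           variant_spacing=300, het_fraction=0.5)
    ref = generate_reference(cfg)
    variants = generate_phased_variants(cfg, ref)
    assert 900 <= len(variants) <= 1100
    assert all(v.ref == ref[v.chrom][v.pos - 1] for v in variants)
    assert all(v.ref != v.alt for v in variants)
    n_het = sum(v.is_het for v in variants)
    lo, hi = binom_ci99(len(variants), 0.5)
    assert lo <= n_het <= hi

    all_het = generate_phased_variants(
        SimulationConfig(seed=5, n_chroms=1, chrom_length=50_000, het_fraction=1.0,
                         non_pass_fraction=0.0), ref
    )
    assert all(v.is_het for v in all_het)


def test_simulation_is_byte_identical_across_runs(tmp_path):
    cfg = small_sim_config(seed=9)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    paths1, _ = simulate_all(cfg, d1)
    paths2, _ = simulate_all(cfg, d2)
    for key in paths1:
        assert filecmp.cmp(paths1[key], paths2[key], shallow=False), key


def test_emitted_vcf_is_consistent_with_manifest_and_reference(small_sim):
    paths, manifest, cfg = small_sim
    ref = read_fasta(paths["reference"])
    by_key = {}
    with pysam.VariantFile(str(paths["vcf"])) as vcf:
        for rec in vcf:
            by_key[(rec.chrom, rec.pos)] = rec
    for site in manifest.as_sites + manifest.null_het_sites:
        rec = by_key[(site["chrom"], site["pos"])]
        assert rec.ref == ref[site["chrom"]][site["pos"] - 1]
        gt = rec.samples[0]["GT"]
        assert gt in ((0, 1), (1, 0)) and rec.samples[0].phased  # heterozygous


def test_blacklist_covers_planted_sites_and_intervals_valid(small_sim):
    paths, manifest, cfg = small_sim
    rows = read_bed(paths["blacklist"])
    for s in manifest.blacklisted_planted:
        assert any(c == s["chrom"] and a <= s["pos"] - 1 < b for c, a, b, _ in rows), s
    for name in ("blacklist", "dnase", "cage", "tf_chip", "chromatin_state",
                 "replication_domain"):
        for chrom, start, end, _ in read_bed(paths[name]):
            assert 0 <= start < end <= cfg.chrom_length


def test_empty_blacklist_config_yields_valid_empty_bed(tmp_path):
    cfg = small_sim_config(seed=2, n_blacklist_sites=0, n_blacklist_decoys=0)
    paths, _ = simulate_all(cfg, tmp_path)
    assert read_bed(paths["blacklist"]) == []


def test_panel_reproduces_manifest_r2(small_sim):
    import pandas as pd

    paths, manifest, _ = small_sim
    panel = pd.read_csv(paths["panel"], sep="\t")
    checked = 0
    for link in manifest.gwas_links:
        if link["direct"]:
            continue
        a = f"{link['as_chrom']}:{link['as_pos']}"
        b = f"{link['gwas_chrom']}:{link['gwas_pos']}"
        r2 = r2_from_haplotypes(panel[a].values, panel[b].values)
        assert r2 == pytest.approx(link["r2"], abs=1e-9)
        checked += 1
    assert checked >= 2


def test_planted_sites_exist_as_het_pass_in_vcf(small_sim):
    paths, manifest, _ = small_sim
    with pysam.VariantFile(str(paths["vcf"])) as vcf:
        pass_het = {
            (r.chrom, r.pos)
            for r in vcf
            if list(r.filter.keys()) == ["PASS"]
            and r.samples[0]["GT"] in ((0, 1), (1, 0))
        }
    for s in manifest.as_sites + manifest.motif_planted:
        assert (s["chrom"], s["pos"]) in pass_het


def test_read_allelic_draws_match_configured_ratios(tmp_path):
    # planted ratio 1.0 with no errors: every covering read carries hap1
    cfg = small_sim_config(seed=6, as_ratio=1.0, base_error_rate=0.0)
    _, manifest = simulate_all(cfg, tmp_path / "pure")
    for s in manifest.as_sites:
        tc = manifest.truth_counts[f"{s['chrom']}:{s['pos']}:{s['mark']}"]
        assert tc["hap2"] == 0 and tc["hap1"] > 0

    # planted 0.8 and null 0.5 draws sit inside their 99% binomial bands
    cfg = small_sim_config(seed=8, coverage=100)
    _, manifest = simulate_all(cfg, tmp_path / "mix")
    for s in manifest.as_sites + manifest.null_het_sites:
        ratio = s.get("true_ratio", 0.5)
        tc = manifest.truth_counts[f"{s['chrom']}:{s['pos']}:{s['mark']}"]
        n = tc["hap1"] + tc["hap2"]
        lo, hi = binom_ci99(n, ratio)
        assert lo <= tc["hap1"] <= hi, (s, tc)


def test_fastq_qualities_and_lengths(small_sim):
    paths, _, cfg = small_sim
    with open(paths["reads_CTCF"]) as fh:
        lines = fh.read().splitlines()
    assert len(lines) % 4 == 0 and len(lines) >= 4 * cfg.coverage
    for i in range(0, min(len(lines), 400), 4):
        assert lines[i].startswith("@CTCF:")
        assert len(lines[i + 1]) == cfg.read_length == len(lines[i + 3])
        assert set(lines[i + 3]) <= {"?", "+"}  # Q30 and Q10 only


def test_manifest_roundtrip(tmp_path, small_sim):
    from aschip.simulate import GroundTruthManifest

    paths, manifest, _ = small_sim
    loaded = GroundTruthManifest.load(paths["manifest"])
    assert loaded.as_sites == manifest.as_sites
    assert loaded.truth_counts == manifest.truth_counts
    assert json.load(open(paths["manifest"]))  # valid JSON on disk
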