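"""Shared fixtures: a small synthetic study and a full pipeline run.

The end-to-end fixture uses the package's shipped default study conditions
with seed 7; golden files under tests/data/golden were produced by exactly
this run and pin byte-level reproducibility.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from aschip.pipeline import PipelineConfig, run_all
from aschip.simulate import GroundTruthManifest, SimulationConfig, simulate_all

GOLDEN_SEED = 7

DATA_DIR = Path(__file__).parent / "data"


def small_sim_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A reduced single-mark study for fast unit tests."""
    params = dict(
        seed=seed,
        n_chroms=1,
        chrom_length=80_000,
        variant_spacing=300,
        n_peaks_per_mark=6,
        n_as_sites=4,
        coverage=40,
        marks=("CTCF",),
        n_blacklist_sites=1,
        n_blacklist_decoys=1,
        n_motif_sites=1,
        n_eqtl_links=1,
        ld_r2_targets=(1.0, 0.85, 0.5),
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> tuple[dict, GroundTruthManifest, SimulationConfig]:
    cfg = small_sim_config()
    outdir = tmp_path_factory.mktemp("small_sim")
    paths, manifest = simulate_all(cfg, outdir)
    return paths, manifest, cfg


@pytest.fixture(scope="session")
def e2e(tmp_path_factory) -> tuple[PipelineConfig, dict, GroundTruthManifest]:
    """Full default-condition pipeline run (the golden fixture conditions)."""
    workdir = tmp_path_factory.mktemp("e2e")
    config = PipelineConfig(workdir=workdir, seed=GOLDEN_SEED)
    summary = run_all(config)
    manifest = GroundTruthManifest.load(config.sim_dir / "manifest.json")
    return config, summary, manifest
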