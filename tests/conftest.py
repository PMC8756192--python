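"""Shared fixtures: simulated datasets at two scales.

``default_dataset`` is the study-condition simulation (~60 kb genome,
60x/30x); the heavier equivalence fixtures run the full pipeline on it
once per (n_regions, workers) configuration and are shared by every test
that needs those artifacts.  ``small_dataset`` is a faster 12 kb variant
for unit-level pipeline tests.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest

from shardcall.pipeline_engine import PipelineConfig, run_pipeline
from shardcall.synthetic_data import SimulationParams, simulate_dataset

DEFAULT_SEED = 1
SMALL_PARAMS = dict(
    contig_lengths=(8_000, 4_000),
    tumor_depth=30.0,
    normal_depth=15.0,
    somatic_count=10,
    boundary_pair_count=30,
    seed=3,
)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("default_ds")
    return simulate_dataset(SimulationParams(seed=DEFAULT_SEED), out)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_ds")
    return simulate_dataset(SimulationParams(**SMALL_PARAMS), out)


def _pipeline_config(dataset, out_dir, n_regions, workers, **kw):
    return PipelineConfig(
        tumor=dataset.tumor_sam, normal=dataset.normal_sam,
        genome=dataset.reference_fa, known_sites=dataset.known_vcf,
        out_dir=str(out_dir), n_regions=n_regions, workers=workers,
        seed=7, **kw)


@pytest.fixture(scope="session")
def equivalence_runs(default_dataset, tmp_path_factory):
    """Full pipeline on the default dataset for N in {1,4,16} x workers {1,4}.

    Returns {(n_regions, workers): output-path dict}.
    """
    base = tmp_path_factory.mktemp("equiv")
    runs = {}
    for n in (1, 4, 16):
        for w in (1, 4):
            out_dir = base / f"n{n}_w{w}"
            cfg = _pipeline_config(default_dataset, out_dir, n, w)
            runs[(n, w)] = run_pipeline(cfg)
    return runs


def vcf_body(path) -> list[str]:
    """VCF record lines, header excluded."""
    with open(path) as fh:
        return [line for line in fh if not line.startswith("#")]
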