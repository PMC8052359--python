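import dataclasses

import numpy as np
import pytest

from beredit.config import PipelineConfig
from beredit.synthetic_data import (
    SimParams, simulate_pileups, simulate_transcriptome,
)

SEED = 1  # fixed once for the whole suite


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(
        n_transcripts=60, transcript_length=(150, 300),
        motif_site_count=12, background_site_count=20,
        endogenous_site_count=6, mean_depth=80, seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_params):
    """(transcriptome, truth, treated, control) on a small simulation."""
    rng = np.random.default_rng(small_params.seed)
    tx, truth = simulate_transcriptome(small_params, rng)
    treated, control = simulate_pileups(tx, truth, small_params, rng)
    return tx, truth, treated, control


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full-size default pipeline run (the study conditions): ~2000
    transcripts, 500 planted edits, mean depth 50."""
    from beredit.pipeline import run_all

    outdir = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=SEED, outdir=str(outdir))
    report = run_all(cfg)
    return cfg, report, outdir


@pytest.fixture(scope="session")
def fold_scenario():
    """Caller-mode fold conditions: 75% of planted edits below 10%
    efficiency, high depth, negligible error."""
    params = SimParams(
        n_transcripts=1000, transcript_length=(200, 600),
        motif_site_count=125, background_site_count=375,
        endogenous_site_count=0,
        motif_eff_distribution=(10.0, 2.0),
        background_eff_distribution=(8.0, 150.0),
        mean_depth=300.0, depth_dispersion=20.0,
        per_base_error_rate=1e-5, seed=SEED,
    )
    rng = np.random.default_rng(params.seed)
    tx, truth = simulate_transcriptome(params, rng)
    treated, control = simulate_pileups(tx, truth, params, rng)
    return tx, truth, treated, control
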