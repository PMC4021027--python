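"""Shared fixtures: canonical synthetic records and the benchmark table."""
from __future__ import annotations

import numpy as np
import pytest

from ppgclean import (ArtifactModelParams, PpgModelParams, TwoChannelPPG,
                      generate_artifact, generate_clean_ppg, mix_two_channel,
                      monte_carlo)

BENCH_SEED = 7  # master seed of the shared Monte-Carlo benchmark


@pytest.fixture(scope="session")
def clean_ppg():
    """Default 20 s clean record: 1.25 Hz pulse at 200 Hz sampling."""
    return generate_clean_ppg(PpgModelParams())


@pytest.fixture(scope="session")
def artifact():
    """Default band-noise artifact overlapping the pulse band."""
    return generate_artifact(ArtifactModelParams(seed=100))


@pytest.fixture(scope="session")
def mixed_0db(clean_ppg, artifact) -> TwoChannelPPG:
    """Both channels corrupted by the same artifact, IR at 0 dB."""
    mixed, _, _ = mix_two_channel(clean_ppg, artifact, 0.0)
    return mixed


@pytest.fixture(scope="session")
def mc_table():
    """Scaled Monte-Carlo benchmark: 21-point SNR grid, 30 replicates.

    Shared across the pipeline property tests and the acceptance suite so
    the simulation runs once per session.
    """
    return monte_carlo(snr_grid_db=np.arange(-10, 11, 1), n_reps=30,
                       master_seed=BENCH_SEED, include_mixture=True)
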