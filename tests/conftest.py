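"""Shared fixtures: one default synthetic session, reused across modules.

The heavy artefacts (full-size synthetic session, its cross-validated
decoding) are session-scoped so the expensive pipeline runs once.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from decabt.evaluation import loro_cv
from decabt.pipeline import label_dataset
from decabt.preprocess import build_features
from decabt.synthetic_data import SimConfig, gen_dataset


#: scaled-down study used by multi-seed property tests (3 runs of 20 gaming +
#: 10 neutral trials, 50 voxels of which 6 informative / 2 dead / 2 noisy)
FAST = SimConfig(
    n_runs_per_participant=3,
    n_gaming_per_block=20,
    n_neutral_per_block=10,
    volumes_per_run=140,
    n_voxels=50,
    n_informative_voxels=6,
    n_dead_voxels=2,
    n_noisy_voxels=2,
)


def fast_config(**overrides) -> SimConfig:
    return replace(FAST, **overrides)


@pytest.fixture(scope="session")
def default_session():
    """Full-size default synthetic session: trials, truth, runs, labels, features."""
    cfg = SimConfig(seed=11)
    trials, truth, runs = gen_dataset(cfg)
    labeled = label_dataset(trials, condition="gaming")
    feats = build_features(list(runs.values()), labeled)
    return {
        "config": cfg,
        "trials": trials,
        "truth": truth,
        "runs": runs,
        "labeled": labeled,
        "features": feats,
    }


@pytest.fixture(scope="session")
def default_cv(default_session):
    """Balanced LORO-CV of the default session (3 resamples)."""
    return loro_cv(default_session["features"], n_resamples=3, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
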