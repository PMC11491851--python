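"""End-to-end convenience chains over the synthetic study.

These wire the stage modules together in the canonical order — generate (or
take) trials and runs, filter, compute block baselines, label, QC/normalise,
extract pre-stimulus features, cross-validate — so studies (and the
acceptance checks) can run the whole analysis with one call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import FilterConfig, block_baselines, filter_trials, label_trials
from .decoder import SLRHyper
from .evaluation import CVResult, loro_cv
from .preprocess import FeatureMatrix, build_features
from .synthetic_data import SimConfig, gen_dataset

__all__ = [
    "label_dataset",
    "synthetic_features",
    "decode_synthetic",
    "permuted_label_chance",
]


def label_dataset(
    trials: pd.DataFrame,
    condition: str = "gaming",
    rules: FilterConfig = FilterConfig(),
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Filter -> block baselines -> trial labels, in one step."""
    filtered = filter_trials(trials, rules)
    baselines = block_baselines(filtered)
    return label_trials(filtered, baselines, condition=condition, leave_one_out=leave_one_out)


def synthetic_features(
    config: SimConfig,
    participant: int = 0,
    condition: str = "gaming",
) -> tuple[FeatureMatrix, pd.DataFrame, np.ndarray]:
    """Generate one participant's synthetic session and extract features.

    Returns the feature matrix, the labelled trial table, and the latent
    ground-truth state aligned with the trial table rows.
    """
    trials, truth, runs = gen_dataset(config)
    labeled = label_dataset(trials, condition=condition)
    part_runs = [runs[(participant, r)] for r in range(config.n_runs_per_participant)]
    feats = build_features(part_runs, labeled, shift_tr=config.shift_tr)
    return feats, labeled, truth.latent_state


def decode_synthetic(
    config: SimConfig,
    n_resamples: int = 10,
    seed: int = 0,
    permute_labels: bool = False,
    n_islr_iter: int = 10,
    hyper: SLRHyper | None = None,
) -> CVResult:
    """Full pipeline on one synthetic participant, optionally label-permuted.

    ``permute_labels`` shuffles the positive/negative labels uniformly at
    random (seeded by ``seed``) before cross-validation, which destroys any
    label-signal association and should drive accuracy to the 50% theoretical
    chance level.
    """
    feats, _, _ = synthetic_features(config)
    if permute_labels:
        rng = np.random.default_rng(seed)
        feats.y = rng.permutation(feats.y)
    return loro_cv(
        feats, n_resamples=n_resamples, seed=seed, n_islr_iter=n_islr_iter, hyper=hyper
    )


def permuted_label_chance(
    n_seeds: int = 20,
    seed: int = 0,
    n_resamples: int = 3,
    config: SimConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Mean LORO-CV accuracy (%) under permuted labels over ``n_seeds`` seeds.

    Each seed generates a fresh default synthetic session (4 runs, 200
    voxels, planted signal), permutes the labels, and runs the balanced
    LORO-CV iterative-classifier pipeline.  The mean over seeds
    operationalises the 50% theoretical chance level of the decoder.
    """
    from dataclasses import replace

    accs = np.empty(n_seeds)
    for i in range(n_seeds):
        cfg = replace(config or SimConfig(), seed=seed + 1000 * i)
        res = decode_synthetic(
            cfg, n_resamples=n_resamples, seed=seed + i, permute_labels=True
        )
        accs[i] = res.accuracy
    return float(accs.mean() * 100.0), accs * 100.0
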