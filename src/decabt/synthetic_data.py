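"""Synthetic approach-avoidance task and fMRI data with known ground truth.

The generator reproduces the statistical structure the decoding analysis
assumes, with every latent quantity exposed so parameter-recovery tests are
possible:

* a block design of 56 gaming + 24 neutral trials following a 21 s baseline,
  in 348-volume runs at TR = 1.75 s (one block per run);
* lognormal reaction times modulated by a latent two-state (biased/unbiased)
  first-order Markov process: in the biased state, gaming approach RTs speed
  up and gaming avoidance RTs slow down (attention drawn towards gaming
  stimuli), and vice versa in the unbiased state; neutral RTs are
  state-independent;
* voxel time series in which a sparse informative subset carries the latent
  state as a mean offset in exactly the volume the preprocessing stage will
  extract as the pre-stimulus feature, on top of per-block linear drift and
  AR(1) noise; planted dead (raw mean < 80) and noisy (raw s.d. > 8) voxels
  exercise the QC stage;
* blob-like synthetic parcellations standing in for a whole-brain atlas
  (166 regions by default).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RunSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_rt_dataset",
    "gen_voxel_timeseries",
    "gen_dataset",
    "gen_parcellation",
    "decabt_assessment_config",
]

TRIAL_COLUMNS = [
    "participant_id",
    "run",
    "block",
    "trial",
    "condition",
    "direction",
    "rt_ms",
    "onset_volume",
    "iti_onset_volume",
    "valid",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults mirror the reference acquisition: 56 gaming + 24 neutral trials
    per block after a 21 s baseline, 348 volumes per run at TR = 1.75 s.
    Voxel-level defaults (200 voxels, 10 informative, 5 dead, 5 noisy,
    standardized effect 1.0) define the desk-scale decoding problem used
    throughout the test suite.
    """

    n_participants: int = 1
    n_runs_per_participant: int = 4
    n_gaming_per_block: int = 56
    n_neutral_per_block: int = 24
    baseline_duration_s: float = 21.0
    tr_s: float = 1.75
    volumes_per_run: int = 348
    n_voxels: int = 200
    n_informative_voxels: int = 10
    signal_effect: float = 1.0
    state_transition_prob: float = 0.2
    rt_state_effect_ms: float = 150.0
    rt_median_ms: float = 600.0
    rt_noise_sd_log: float = 0.15
    noise_sd: float = 2.0
    baseline_signal: float = 100.0
    dead_signal: float = 50.0
    noisy_sd: float = 12.0
    drift_slope_range: float = 0.02
    ar1_coef: float = 0.3
    n_dead_voxels: int = 5
    n_noisy_voxels: int = 5
    iti_tr: int = 2
    stim_tr: int = 2
    shift_tr: int = 3
    seed: int = 0

    @property
    def baseline_volumes(self) -> int:
        return math.ceil(self.baseline_duration_s / self.tr_s)

    @property
    def trials_per_block(self) -> int:
        return self.n_gaming_per_block + self.n_neutral_per_block

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_runs_per_participant": self.n_runs_per_participant,
            "n_gaming_per_block": self.n_gaming_per_block,
            "n_neutral_per_block": self.n_neutral_per_block,
            "volumes_per_run": self.volumes_per_run,
            "n_voxels": self.n_voxels,
            "n_informative_voxels": self.n_informative_voxels,
            "n_dead_voxels": self.n_dead_voxels,
            "n_noisy_voxels": self.n_noisy_voxels,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_neutral_per_block == 0:
            raise ValueError(
                "n_neutral_per_block must be >= 1: the labelling baseline is the "
                "mean neutral RT and is undefined without neutral trials"
            )
        if not 0.0 <= self.state_transition_prob <= 1.0:
            raise ValueError("state_transition_prob must lie in [0, 1]")
        if self.tr_s <= 0 or self.rt_median_ms <= 0:
            raise ValueError("tr_s and rt_median_ms must be positive")
        planted = self.n_informative_voxels + self.n_dead_voxels + self.n_noisy_voxels
        if planted > self.n_voxels:
            raise ValueError(
                f"planted voxel sets ({planted}) exceed n_voxels ({self.n_voxels})"
            )
        needed = self.baseline_volumes + self.trials_per_block * (self.iti_tr + self.stim_tr)
        if needed > self.volumes_per_run:
            raise ValueError(
                f"block design needs {needed} volumes but volumes_per_run is "
                f"{self.volumes_per_run}"
            )
        # the shifted pre-stimulus feature volume of the last trial must exist
        last_iti = needed - self.iti_tr - self.stim_tr
        if last_iti + self.shift_tr >= self.volumes_per_run:
            raise ValueError("shifted feature volume falls beyond the run end")


@dataclass
class GroundTruth:
    """Latent quantities of a generated dataset (for recovery tests)."""

    latent_state: np.ndarray  # 1 = biased / 0 = unbiased, one entry per trial row
    informative_voxel_ids: np.ndarray
    dead_voxel_ids: np.ndarray
    noisy_voxel_ids: np.ndarray

    def __post_init__(self) -> None:
        sets = [
            set(self.informative_voxel_ids.tolist()),
            set(self.dead_voxel_ids.tolist()),
            set(self.noisy_voxel_ids.tolist()),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted voxel index sets must be disjoint")


def _run_rng(config: SimConfig, participant: int, run: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, participant, run, stream])


def gen_rt_dataset(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the trial table of every participant/run plus its ground truth.

    Per block: exactly ``n_gaming_per_block`` gaming and ``n_neutral_per_block``
    neutral trials in pseudo-random order.  A latent biased/unbiased Markov
    chain (switch probability ``state_transition_prob`` per trial) shifts
    gaming RTs by ``-rt_state_effect_ms`` (approach) / ``+rt_state_effect_ms``
    (avoidance) in the biased state and the opposite way in the unbiased
    state, so the RT labelling rule can recover the state.  RTs are lognormal
    around ``rt_median_ms`` with log-s.d. ``rt_noise_sd_log``.
    """
    config.validate()
    rows = []
    states = []
    for pid in range(config.n_participants):
        for run in range(config.n_runs_per_participant):
            rng = _run_rng(config, pid, run, 0)
            conditions = np.array(
                ["gaming"] * config.n_gaming_per_block
                + ["neutral"] * config.n_neutral_per_block
            )
            rng.shuffle(conditions)
            directions = np.where(
                rng.integers(0, 2, size=conditions.size) == 1, "approach", "avoidance"
            )
            state = int(rng.integers(0, 2))
            cursor = config.baseline_volumes
            for t, (cond, direction) in enumerate(zip(conditions, directions)):
                base = float(
                    np.exp(np.log(config.rt_median_ms) + config.rt_noise_sd_log * rng.standard_normal())
                )
                if cond == "gaming":
                    sign = -1.0 if direction == "approach" else 1.0
                    sign *= 1.0 if state == 1 else -1.0
                    rt = max(base + sign * config.rt_state_effect_ms, 50.0)
                else:
                    rt = base
                iti_onset = cursor
                onset = cursor + config.iti_tr
                cursor = onset + config.stim_tr
                rows.append(
                    (pid, run, run, t, cond, direction, rt, onset, iti_onset, 1)
                )
                states.append(state)
                if rng.random() < config.state_transition_prob:
                    state = 1 - state
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    vox_rng = np.random.default_rng([config.seed, 991])
    perm = vox_rng.permutation(config.n_voxels)
    ni, nd, nn = (
        config.n_informative_voxels,
        config.n_dead_voxels,
        config.n_noisy_voxels,
    )
    truth = GroundTruth(
        latent_state=np.asarray(states, dtype=int),
        informative_voxel_ids=np.sort(perm[:ni]),
        dead_voxel_ids=np.sort(perm[ni : ni + nd]),
        noisy_voxel_ids=np.sort(perm[ni + nd : ni + nd + nn]),
    )
    return trials, truth


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], coef: float) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance."""
    n_vox, n_vol = shape
    innov_sd = math.sqrt(max(1.0 - coef**2, 1e-12))
    out = np.empty(shape)
    out[:, 0] = rng.standard_normal(n_vox)
    eps = rng.standard_normal((n_vox, n_vol - 1)) * innov_sd
    for t in range(1, n_vol):
        out[:, t] = coef * out[:, t - 1] + eps[:, t - 1]
    return out


def gen_voxel_timeseries(
    config: SimConfig,
    trials: pd.DataFrame,
    truth: GroundTruth,
    participant_id: int = 0,
    run: int = 0,
) -> RunSeries:
    """Generate the raw BOLD matrix of one run.

    Live voxels sit at a baseline of ``baseline_signal`` with AR(1) noise of
    marginal s.d. ``noise_sd`` plus a per-block linear drift of random slope.
    In informative voxels, the volume that preprocessing will extract as the
    trial's feature (``iti_onset_volume + shift_tr``) carries a mean offset of
    ``+signal_effect * noise_sd`` when the trial's latent state is biased and
    ``-signal_effect * noise_sd`` otherwise.  Dead voxels sit near
    ``dead_signal`` (raw mean < 80); noisy voxels get noise s.d. ``noisy_sd``
    (raw s.d. > 8).
    """
    config.validate()
    mask = (trials["participant_id"] == participant_id) & (trials["run"] == run)
    sub = trials[mask]
    if sub.empty:
        raise ValueError(f"no trials for participant {participant_id}, run {run}")
    feature_vols = sub["iti_onset_volume"].to_numpy(dtype=int) + config.shift_tr
    if feature_vols.max() >= config.volumes_per_run:
        raise ValueError("shifted feature volume beyond run end; reject configuration")
    rng = _run_rng(config, participant_id, run, 1)
    n_vox, n_vol = config.n_voxels, config.volumes_per_run

    sd_per_voxel = np.full(n_vox, config.noise_sd)
    sd_per_voxel[truth.noisy_voxel_ids] = config.noisy_sd
    level = np.full(n_vox, config.baseline_signal)
    level[truth.dead_voxel_ids] = config.dead_signal

    data = level[:, None] + _ar1_noise(rng, (n_vox, n_vol), config.ar1_coef) * sd_per_voxel[:, None]
    slopes = rng.uniform(-config.drift_slope_range, config.drift_slope_range, size=n_vox)
    for start, end in [(0, n_vol)]:
        tt = np.arange(end - start)
        data[:, start:end] += slopes[:, None] * tt[None, :]

    amp = config.signal_effect * config.noise_sd
    state = truth.latent_state[mask.to_numpy()]
    signs = np.where(state == 1, 1.0, -1.0)
    for vol, s in zip(feature_vols, signs):
        data[truth.informative_voxel_ids, vol] += s * amp
    return RunSeries(
        data=data,
        tr_s=config.tr_s,
        block_bounds=[(0, n_vol)],
        voxel_ids=np.arange(n_vox),
        participant_id=participant_id,
        run=run,
    )


def gen_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth, dict[tuple[int, int], RunSeries]]:
    """Trial table, ground truth and every run's raw BOLD series."""
    trials, truth = gen_rt_dataset(config)
    runs = {
        (pid, run): gen_voxel_timeseries(config, trials, truth, pid, run)
        for pid in range(config.n_participants)
        for run in range(config.n_runs_per_participant)
    }
    return trials, truth, runs


def gen_parcellation(
    grid_shape: tuple[int, int, int],
    n_regions: int = 166,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Partition a voxel grid into contiguous-ish labelled regions.

    Regions are grown breadth-first from random seed voxels, giving blob-like
    parcels akin to an anatomical atlas (166 regions by default).  Every
    in-brain voxel receives exactly one label in ``1..n_regions``; background
    voxels (outside ``mask``) are 0.
    """
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid_shape):
        raise ValueError("mask shape must equal grid_shape")
    in_brain = np.argwhere(mask)
    if n_regions < 1 or n_regions > len(in_brain):
        raise ValueError(
            f"n_regions must be in [1, {len(in_brain)}], got {n_regions}"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid_shape, dtype=int)
    seed_rows = rng.choice(len(in_brain), size=n_regions, replace=False)
    queues = []
    for label, row in enumerate(seed_rows, start=1):
        pos = tuple(in_brain[row])
        labels[pos] = label
        queues.append(deque([pos]))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    grown = True
    while grown:
        grown = False
        for label, q in enumerate(queues, start=1):
            if not q:
                continue
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < grid_shape[0]
                    and 0 <= ny < grid_shape[1]
                    and 0 <= nz < grid_shape[2]
                    and mask[nx, ny, nz]
                    and labels[nx, ny, nz] == 0
                ):
                    labels[nx, ny, nz] = label
                    q.append((nx, ny, nz))
                    grown = True
            if q:
                grown = True
    # disconnected mask components may stay unlabelled: assign nearest seed
    left = np.argwhere(mask & (labels == 0))
    if len(left):
        seeds_xyz = in_brain[seed_rows]
        for pos in left:
            d = np.sum((seeds_xyz - pos) ** 2, axis=1)
            labels[tuple(pos)] = int(np.argmin(d)) + 1
    return labels


def decabt_assessment_config(**overrides) -> SimConfig:
    """Configuration of the pre/post training bias assessment.

    The closed-loop training protocol brackets training with a shorter
    approach-avoidance assessment: 80 trials (40 gaming / 40 neutral) over two
    blocks, in 210-volume runs.
    """
    defaults = dict(
        n_runs_per_participant=2,
        n_gaming_per_block=20,
        n_neutral_per_block=20,
        volumes_per_run=210,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
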