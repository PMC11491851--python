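"""Turn raw per-run voxel time series into trial-wise pre-stimulus feature vectors.

The decoding pipeline never looks at stimulus-evoked activity: each trial
contributes a single multivoxel sample, the BOLD volume acquired
``shift_tr`` TRs (default 3, i.e. 5.25 s at TR = 1.75 s) after the first
fixation volume of the trial's inter-trial interval.  The shift compensates
the hemodynamic delay, so that volume reflects *pre-stimulus* endogenous
activity.  Before extraction, voxels with implausibly low raw intensity
(mean < 80) or excessive raw variance (s.d. > 8) are discarded, and each
retained voxel is linearly detrended and z-scored within each task block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "RunSeries",
    "FeatureMatrix",
    "voxel_qc",
    "qc_intersection",
    "detrend_normalize",
    "extract_features",
    "build_features",
]


@dataclass
class RunSeries:
    """Voxels x volumes BOLD matrix for one scanner run.

    Parameters
    ----------
    data:
        Array of shape ``(n_voxels, n_volumes)``; arbitrary BOLD units for raw
        series, z-units after :func:`detrend_normalize`.
    tr_s:
        Repetition time in seconds (1.75 in the reference acquisition).
    block_bounds:
        Half-open ``[start, end)`` volume intervals of the task blocks;
        disjoint and ordered.
    voxel_ids:
        Global voxel identifiers for the rows of ``data``.  Subsetting
        operations preserve these, so features extracted from different runs
        can be aligned.
    voxel_coords:
        Optional ``(n_voxels, 3)`` integer grid coordinates, used to intersect
        the run with masks and parcellations.
    """

    data: np.ndarray
    tr_s: float = 1.75
    block_bounds: Sequence[tuple[int, int]] = field(default_factory=list)
    voxel_ids: np.ndarray | None = None
    voxel_coords: np.ndarray | None = None
    participant_id: int = 0
    run: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RunSeries.data must be 2-D (voxels x volumes)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        n_vol = self.data.shape[1]
        prev_end = 0
        for start, end in self.block_bounds:
            if not (0 <= start < end <= n_vol):
                raise ValueError(f"block [{start}, {end}) outside run of {n_vol} volumes")
            if start < prev_end:
                raise ValueError("block_bounds must be disjoint and ordered")
            prev_end = end
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.data.shape[0])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def subset(self, rows: np.ndarray) -> "RunSeries":
        """Return a new RunSeries restricted to the given voxel rows."""
        rows = np.asarray(rows)
        coords = None if self.voxel_coords is None else self.voxel_coords[rows]
        return replace(
            self,
            data=self.data[rows],
            voxel_ids=self.voxel_ids[rows],
            voxel_coords=coords,
        )


@dataclass
class FeatureMatrix:
    """Trials x voxels pre-stimulus feature samples with per-trial metadata."""

    X: np.ndarray
    y: np.ndarray  # 1 = positive (biased) / 0 = negative (unbiased)
    run: np.ndarray
    direction: np.ndarray
    condition: np.ndarray
    trial: np.ndarray
    voxel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        n = self.X.shape[0]
        for name in ("y", "run", "direction", "condition", "trial"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"FeatureMatrix field {name!r} length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("FeatureMatrix contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            X=self.X[mask],
            y=self.y[mask],
            run=np.asarray(self.run)[mask],
            direction=np.asarray(self.direction)[mask],
            condition=np.asarray(self.condition)[mask],
            trial=np.asarray(self.trial)[mask],
            voxel_ids=self.voxel_ids,
        )

    @classmethod
    def concat(cls, parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        ref = parts[0].voxel_ids
        for p in parts[1:]:
            if not np.array_equal(p.voxel_ids, ref):
                raise ValueError("voxel spaces differ across runs")
        return cls(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            run=np.concatenate([np.asarray(p.run) for p in parts]),
            direction=np.concatenate([np.asarray(p.direction) for p in parts]),
            condition=np.concatenate([np.asarray(p.condition) for p in parts]),
            trial=np.concatenate([np.asarray(p.trial) for p in parts]),
            voxel_ids=ref,
        )


def voxel_qc(run: RunSeries, mean_min: float = 80.0, sd_max: float = 8.0) -> np.ndarray:
    """Quality-control voxel selection on a *raw* run.

    A voxel is retained iff its raw whole-run mean is >= ``mean_min`` and its
    raw whole-run s.d. is <= ``sd_max`` (population s.d.).  Voxels failing the
    first test are out-of-brain / signal-dropout voxels; voxels failing the
    second carry artefactual variance.

    Returns the retained row positions (into ``run.data``).
    """
    means = run.data.mean(axis=1)
    sds = run.data.std(axis=1)
    retained = np.flatnonzero((means >= mean_min) & (sds <= sd_max))
    if retained.size == 0:
        raise ValueError(
            f"no voxel passed QC (mean >= {mean_min}, s.d. <= {sd_max})"
        )
    return retained


def qc_intersection(
    runs: Sequence[RunSeries], mean_min: float = 80.0, sd_max: float = 8.0
) -> np.ndarray:
    """Row positions retained by :func:`voxel_qc` in *every* run.

    Runs must share an aligned voxel ordering (same ``voxel_ids``).
    """
    if not runs:
        raise ValueError("no runs given")
    ref = runs[0].voxel_ids
    for r in runs[1:]:
        if not np.array_equal(r.voxel_ids, ref):
            raise ValueError("runs are not voxel-aligned")
    retained = voxel_qc(runs[0], mean_min, sd_max)
    for r in runs[1:]:
        retained = np.intersect1d(retained, voxel_qc(r, mean_min, sd_max))
    if retained.size == 0:
        raise ValueError(
            f"no voxel passed QC in all runs (mean >= {mean_min}, s.d. <= {sd_max})"
        )
    return retained


def detrend_normalize(
    run: RunSeries,
    retained: np.ndarray | None = None,
    on_zero_variance: str = "drop",
) -> RunSeries:
    """Per-voxel, per-block linear detrend followed by within-block z-scoring.

    Each retained voxel's time course is processed block by block: an ordinary
    least-squares linear trend is removed, then the residuals are standardised
    to mean 0 / s.d. 1 (population s.d.) within the block.  Volumes outside
    every block are left untouched.

    ``on_zero_variance`` controls voxels whose detrended residual is constant
    in some block: ``"drop"`` removes them with a warning, ``"error"`` raises.
    """
    if on_zero_variance not in ("drop", "error"):
        raise ValueError("on_zero_variance must be 'drop' or 'error'")
    sub = run if retained is None else run.subset(np.asarray(retained))
    if not sub.block_bounds:
        raise ValueError("run has no block boundaries")
    data = sub.data.copy()
    dead_rows: set[int] = set()
    for start, end in sub.block_bounds:
        if end - start < 3:
            raise ValueError(f"block [{start}, {end}) has fewer than 3 volumes")
        raw_sd = data[:, start:end].std(axis=1)
        seg = _signal.detrend(data[:, start:end], axis=1, type="linear")
        sd = seg.std(axis=1)
        # residual variance at numerical-noise level counts as degenerate
        zero = np.flatnonzero(sd <= 1e-10 * np.maximum(raw_sd, 1e-30))
        if zero.size:
            if on_zero_variance == "error":
                raise ValueError(f"zero-variance residual in block [{start}, {end})")
            dead_rows.update(zero.tolist())
            sd[zero] = 1.0
        data[:, start:end] = (seg - seg.mean(axis=1, keepdims=True)) / sd[:, None]
    out = replace(sub, data=data)
    if dead_rows:
        warnings.warn(
            f"dropping {len(dead_rows)} voxel(s) with zero residual variance",
            stacklevel=2,
        )
        keep = np.setdiff1d(np.arange(out.n_voxels), sorted(dead_rows))
        out = out.subset(keep)
    return out


def zero_variance_rows(run: RunSeries, retained: np.ndarray) -> np.ndarray:
    """Row positions (into ``retained``) with a constant detrended block residual."""
    bad: set[int] = set()
    data = run.data[np.asarray(retained)]
    for start, end in run.block_bounds:
        raw_sd = data[:, start:end].std(axis=1)
        seg = _signal.detrend(data[:, start:end], axis=1, type="linear")
        bad.update(
            np.flatnonzero(seg.std(axis=1) <= 1e-10 * np.maximum(raw_sd, 1e-30)).tolist()
        )
    return np.asarray(sorted(bad), dtype=int)


def extract_features(
    run: RunSeries,
    labeled: pd.DataFrame,
    shift_tr: int = 3,
    condition: str | None = None,
) -> FeatureMatrix:
    """Extract one pre-stimulus feature vector per labelled trial of this run.

    The feature volume of trial *t* is ``iti_onset_volume(t) + shift_tr``: the
    first TR of the pre-stimulus fixation period, read ``shift_tr`` volumes
    later to account for the hemodynamic delay.  Trials whose label is
    ``excluded`` are skipped; trials whose shifted index falls outside the run
    are dropped (they have no usable feature volume).

    ``run`` must already be detrended/normalised; ``labeled`` is the output of
    :func:`decabt.behavior.label_trials` and must carry ``iti_onset_volume``.
    """
    df = labeled
    df = df[(df["participant_id"] == run.participant_id) & (df["run"] == run.run)]
    if condition is not None:
        df = df[df["condition"] == condition]
    df = df[df["label"].isin(["positive", "negative"])]
    idx = df["iti_onset_volume"].to_numpy(dtype=int) + int(shift_tr)
    in_range = (idx >= 0) & (idx < run.n_volumes)
    if not np.all(in_range):
        warnings.warn(
            f"{int((~in_range).sum())} trial(s) dropped: shifted feature volume "
            "outside the run",
            stacklevel=2,
        )
    df = df[in_range]
    idx = idx[in_range]
    X = run.data[:, idx].T
    return FeatureMatrix(
        X=X,
        y=(df["label"] == "positive").to_numpy(dtype=int),
        run=np.full(len(df), run.run),
        direction=df["direction"].to_numpy(),
        condition=df["condition"].to_numpy(),
        trial=df["trial"].to_numpy(),
        voxel_ids=run.voxel_ids.copy(),
    )


def build_features(
    runs: Sequence[RunSeries],
    labeled: pd.DataFrame,
    mean_min: float = 80.0,
    sd_max: float = 8.0,
    shift_tr: int = 3,
    condition: str | None = None,
) -> FeatureMatrix:
    """Full preprocessing chain over several voxel-aligned runs.

    QC thresholds are applied to each raw run and intersected, voxels with a
    degenerate (constant) residual in any run are additionally removed so the
    feature space is identical across runs, then each run is detrended,
    z-scored and sampled at the shifted pre-stimulus volume of every labelled
    trial.
    """
    retained = qc_intersection(runs, mean_min=mean_min, sd_max=sd_max)
    bad: set[int] = set()
    for r in runs:
        bad.update(zero_variance_rows(r, retained).tolist())
    if bad:
        retained = np.delete(retained, sorted(bad))
        if retained.size == 0:
            raise ValueError("all QC-retained voxels have degenerate residuals")
    parts = []
    for r in runs:
        norm = detrend_normalize(r, retained, on_zero_variance="error")
        parts.append(extract_features(norm, labeled, shift_tr=shift_tr, condition=condition))
    return FeatureMatrix.concat(parts)
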