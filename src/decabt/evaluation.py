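"""Cross-validated decoding, condition crossings, region sweeps, group stats.

Decoding accuracy is estimated with leave-one-run-out cross-validation.
Because positive/negative label counts are unbalanced, the majority class of
each training fold is randomly downsampled (without replacement) to the
minority size, independently ``n_resamples`` times; the iterative sparse
classifier is refit per resample and the fold accuracy is the mean over
resamples.  The same machinery supports the four condition crossings
(gaming, gaming->neutral, neutral, neutral->gaming), per-direction accuracy
splits, and an exploratory sweep over every region of a parcellation.
Group-level inference is one-sample / paired t statistics against the 50%
theoretical chance level with Benjamini-Hochberg FDR control over the
declared family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoder import SLRHyper, fit_islr, predict_islr
from .preprocess import FeatureMatrix, RunSeries, build_features

__all__ = [
    "CVResult",
    "loro_cv",
    "cross_condition_decode",
    "direction_split_accuracy",
    "search_roi_sweep",
    "group_tests",
    "paired_tests",
    "bootstrap_balance_test",
    "BootstrapResult",
]


@dataclass
class CVResult:
    """Held-out predictions of a cross-validated decoding analysis.

    ``predictions`` has one row per (fold run, resample, trial) with columns
    run, resample, trial, direction, y_true, y_pred, prob.  The headline
    ``accuracy`` is the mean over folds of the mean over resamples, matching
    the reference protocol; ``pooled_accuracy`` weights every held-out
    prediction equally.
    """

    predictions: pd.DataFrame
    n_resamples: int
    fold_runs: list

    @property
    def fold_accuracies(self) -> pd.Series:
        per = self.predictions.assign(correct=lambda d: d.y_true == d.y_pred)
        return per.groupby(["run", "resample"])["correct"].mean().groupby("run").mean()

    @property
    def accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def pooled_accuracy(self) -> float:
        return float((self.predictions.y_true == self.predictions.y_pred).mean())


def _balanced_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices after downsampling the majority class to the minority size."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m = min(pos.size, neg.size)
    keep_pos = rng.choice(pos, size=m, replace=False) if pos.size > m else pos
    keep_neg = rng.choice(neg, size=m, replace=False) if neg.size > m else neg
    return np.sort(np.concatenate([keep_pos, keep_neg]))


def cross_condition_decode(
    train: FeatureMatrix,
    test: FeatureMatrix,
    n_resamples: int = 10,
    seed: int = 0,
    n_islr_iter: int = 10,
    hyper: SLRHyper | None = None,
) -> CVResult:
    """LORO-style decoding with training and testing conditions decoupled.

    For each run r present in the test set, the classifier is trained on the
    training-condition trials of every other run (class-balanced by
    downsampling, ``n_resamples`` independent resamples) and scored on the
    test-condition trials of run r.  ``train is test`` reduces to ordinary
    leave-one-run-out cross-validation.
    """
    if not np.array_equal(train.voxel_ids, test.voxel_ids):
        raise ValueError("train and test feature matrices use different voxel spaces")
    runs = sorted(set(np.asarray(test.run).tolist()))
    if len(set(np.asarray(train.run).tolist())) < 2:
        raise ValueError("need >= 2 runs for leave-one-run-out cross-validation")
    rows = []
    for fold_i, r in enumerate(runs):
        tr = train.select(np.asarray(train.run) != r)
        te = test.select(np.asarray(test.run) == r)
        if te.n_trials == 0:
            continue
        if len(np.unique(tr.y)) < 2:
            warnings.warn(f"fold {r}: single-class training data, fold skipped", stacklevel=2)
            continue
        for j in range(n_resamples):
            rng = np.random.default_rng([seed, fold_i, j])
            idx = _balanced_indices(tr.y, rng)
            model = fit_islr(tr.X[idx], tr.y[idx], n_iter=n_islr_iter, hyper=hyper)
            prob, pred = predict_islr(model, te.X)
            for t in range(te.n_trials):
                rows.append(
                    (
                        r,
                        j,
                        np.asarray(te.trial)[t],
                        np.asarray(te.direction)[t],
                        int(te.y[t]),
                        int(pred[t]),
                        float(prob[t]),
                    )
                )
    predictions = pd.DataFrame(
        rows, columns=["run", "resample", "trial", "direction", "y_true", "y_pred", "prob"]
    )
    if predictions.empty:
        raise ValueError("no usable cross-validation folds")
    return CVResult(predictions=predictions, n_resamples=n_resamples, fold_runs=runs)


def loro_cv(
    features: FeatureMatrix,
    n_resamples: int = 10,
    seed: int = 0,
    n_islr_iter: int = 10,
    hyper: SLRHyper | None = None,
) -> CVResult:
    """Leave-one-run-out cross-validation with bootstrap class balancing."""
    return cross_condition_decode(
        features, features, n_resamples=n_resamples, seed=seed,
        n_islr_iter=n_islr_iter, hyper=hyper,
    )


def direction_split_accuracy(result: CVResult) -> dict[str, float]:
    """Held-out accuracy computed separately for approach and avoidance trials.

    Accuracies are pooled over every held-out prediction, so the overall
    pooled accuracy is exactly the trial-count-weighted mean of the two
    directions.  A direction absent from the held-out data maps to NaN.
    """
    out = {}
    for direction in ("approach", "avoidance"):
        sub = result.predictions[result.predictions.direction == direction]
        out[direction] = float((sub.y_true == sub.y_pred).mean()) if len(sub) else float("nan")
    return out


def search_roi_sweep(
    parcellation: np.ndarray,
    datasets: Sequence[tuple[Sequence[RunSeries], pd.DataFrame]],
    mean_min: float = 80.0,
    sd_max: float = 8.0,
    shift_tr: int = 3,
    n_resamples: int = 10,
    seed: int = 0,
    n_islr_iter: int = 10,
    hyper: SLRHyper | None = None,
    chance: float = 0.5,
) -> pd.DataFrame:
    """Run the whole decoding pipeline independently in every atlas region.

    ``parcellation`` is a 3-D integer label volume (0 = background); each
    dataset is one participant's ``(runs, labelled trial table)`` where every
    RunSeries carries ``voxel_coords`` indexing into the parcellation grid.
    Per region: QC -> detrend/z-score -> pre-stimulus feature extraction ->
    balanced LORO-CV, per participant; the output row reports the group mean
    accuracy (in %), its s.e.m., the one-sample t statistic vs chance and
    Cohen's d.  Regions in which no voxel survives QC for some participant
    are marked undecodable (NaN accuracy).
    """
    parcellation = np.asarray(parcellation)
    region_ids = np.unique(parcellation)
    region_ids = region_ids[region_ids > 0]
    rows = []
    for region in region_ids:
        accs = []
        undecodable = False
        for p_i, (runs, labeled) in enumerate(datasets):
            coords = runs[0].voxel_coords
            if coords is None:
                raise ValueError("RunSeries.voxel_coords required for a region sweep")
            in_region = np.flatnonzero(
                parcellation[coords[:, 0], coords[:, 1], coords[:, 2]] == region
            )
            if in_region.size == 0:
                undecodable = True
                break
            try:
                feats = build_features(
                    [r.subset(in_region) for r in runs], labeled,
                    mean_min=mean_min, sd_max=sd_max, shift_tr=shift_tr,
                )
                res = loro_cv(
                    feats, n_resamples=n_resamples, seed=seed + p_i,
                    n_islr_iter=n_islr_iter, hyper=hyper,
                )
            except ValueError:
                undecodable = True
                break
            accs.append(res.accuracy)
        if undecodable or not accs:
            rows.append((int(region), 0, np.nan, np.nan, np.nan, np.nan))
            continue
        a = np.asarray(accs) * 100.0
        mean = a.mean()
        sem = a.std(ddof=1) / math.sqrt(len(a)) if len(a) > 1 else np.nan
        if len(a) > 1 and a.std(ddof=1) > 0:
            t, _ = stats.ttest_1samp(a, chance * 100.0)
            d = (mean - chance * 100.0) / a.std(ddof=1)
        else:
            t, d = np.nan, np.nan
        rows.append((int(region), in_region.size, mean, sem, float(t), float(d)))
    return pd.DataFrame(
        rows, columns=["region", "n_voxels", "accuracy", "sem", "t_stat", "cohen_d"]
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over one declared family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def _one_sample_row(values: np.ndarray, popmean: float) -> tuple[float, int, float, float]:
    values = np.asarray(values, dtype=float)
    df = values.size - 1
    sd = values.std(ddof=1)
    if sd == 0:
        if np.allclose(values.mean(), popmean):
            return 0.0, df, 1.0, 0.0
        return float("nan"), df, float("nan"), float("nan")
    t, p = stats.ttest_1samp(values, popmean)
    d = (values.mean() - popmean) / sd
    return float(t), df, float(p), float(d)


def group_tests(
    accuracies: pd.DataFrame,
    chance: float = 0.5,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """One-sample two-sided t vs chance per (roi, condition) cell with BH-FDR.

    ``accuracies`` must have columns participant, roi, condition, accuracy
    (proportions in [0, 1]).  The BH family is every (roi, condition) cell in
    the table, matching the reference analysis (all ROIs x four conditions).
    Zero-variance cells yield an undefined (NaN) t that is excluded from the
    correction but kept in the output.
    """
    required = {"participant", "roi", "condition", "accuracy"}
    if not required.issubset(accuracies.columns):
        raise ValueError(f"accuracies must have columns {sorted(required)}")
    rows = []
    for (roi_, cond), grp in accuracies.groupby(["roi", "condition"], sort=True):
        vals = grp["accuracy"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError("group tests need >= 2 participants per cell")
        t, df, p, d = _one_sample_row(vals, chance)
        rows.append((roi_, cond, vals.mean(), t, df, p, d))
    out = pd.DataFrame(
        rows, columns=["roi", "condition", "mean_accuracy", "t_stat", "df", "p", "cohen_d"]
    )
    out["p_fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["p_fdr"] < fdr_q
    return out


def paired_tests(
    accuracies: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Paired two-sided t for condition contrasts within each ROI, BH-corrected.

    Each contrast is a (condition_a, condition_b) pair; participants are
    matched by id.  The BH family is every (roi, contrast) cell produced.
    """
    rows = []
    for roi_, grp in accuracies.groupby("roi", sort=True):
        wide = grp.pivot(index="participant", columns="condition", values="accuracy")
        for ca, cb in contrasts:
            if ca not in wide or cb not in wide:
                raise ValueError(f"condition {ca!r} or {cb!r} missing for roi {roi_!r}")
            diff = (wide[ca] - wide[cb]).dropna().to_numpy(dtype=float)
            t, df, p, d = _one_sample_row(diff, 0.0)
            rows.append((roi_, f"{ca} - {cb}", diff.mean(), t, df, p, d))
    out = pd.DataFrame(
        rows, columns=["roi", "contrast", "mean_diff", "t_stat", "df", "p", "cohen_d"]
    )
    out["p_fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


@dataclass
class BootstrapResult:
    p_value: float
    observed: float
    n_draws: int
    exact: bool


def bootstrap_balance_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_sub: int = 13,
    n_boot: int = 100_000,
    seed: int = 0,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> BootstrapResult:
    """Sample-size-balanced comparison of two groups by subsampling the larger.

    Repeatedly draws ``n_sub`` participants from ``group_a`` without
    replacement and evaluates ``statistic(subsample, group_b)`` (default:
    difference of means).  The two-sided p-value counts the draws whose
    statistic lands on the far side of zero (ties included) from the
    full-sample statistic, with a +1 continuity correction:
    p = (count + 1) / (n_draws + 1).

    When the number of distinct subsets C(|a|, n_sub) does not exceed
    ``n_boot`` the test enumerates all of them exactly instead of sampling.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if n_sub > a.size:
        raise ValueError(f"n_sub ({n_sub}) exceeds group_a size ({a.size})")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    stat = statistic or (lambda sub, other: float(sub.mean() - other.mean()))
    observed = stat(a, b)

    n_subsets = math.comb(a.size, n_sub)
    exact = n_subsets <= n_boot
    if exact:
        draws = np.array([stat(a[list(c)], b) for c in combinations(range(a.size), n_sub)])
    else:
        rng = np.random.default_rng(seed)
        draws = np.array(
            [stat(a[rng.choice(a.size, size=n_sub, replace=False)], b) for _ in range(n_boot)]
        )
    if observed > 0:
        count = int(np.sum(draws <= 0.0))
    elif observed < 0:
        count = int(np.sum(draws >= 0.0))
    else:
        return BootstrapResult(1.0, observed, draws.size, exact)
    p = (count + 1) / (draws.size + 1)
    return BootstrapResult(min(p, 1.0), observed, draws.size, exact)
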