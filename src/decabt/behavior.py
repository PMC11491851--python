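"""Trial-level attentional-bias labels from approach-avoidance reaction times.

The block's mean neutral RT (separately for approach and avoidance) is the
baseline.  A gaming trial is labelled *positive* (attention drawn towards
gaming stimuli) when the participant pulled faster than the approach baseline
or pushed slower than the avoidance baseline, and *negative* in the strict
opposite case; ties are excluded.  The same rule applied to neutral trials
against the same baselines yields the *fake* index, a control for generic RT
fluctuation.  Split-half reliability of the per-label mean deviations is
quantified with the Spearman-Brown-corrected half correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterConfig",
    "ReliabilityResult",
    "filter_trials",
    "block_baselines",
    "label_trials",
    "split_half_reliability",
]

#: exclusion reasons attached by filter_trials (as opposed to task-recorded
#: response errors), used to keep re-filtering idempotent
_FILTER_REASONS = frozenset({"rt_below_min", "rt_outlier"})


@dataclass(frozen=True)
class FilterConfig:
    """Trial-exclusion rules; all thresholds configurable.

    rt_min:
        Anticipation floor in ms; faster responses cannot be stimulus-driven.
    outlier_k:
        Trials slower than the participant's mean + ``outlier_k`` s.d. are
        treated as lapses.  Set to ``None`` to disable.
    """

    rt_min: float = 150.0
    outlier_k: float | None = 3.0


def filter_trials(trials: pd.DataFrame, rules: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Flag inappropriate trials (``valid`` -> 0) with an ``exclusion_reason``.

    Rules: task-recorded wrong/no response (input ``valid == 0``), RT below
    ``rules.rt_min``, and RT above the per-participant mean + k s.d.  The
    outlier statistics are computed over response-valid trials at or above the
    RT floor, independent of any outlier flag a previous pass set, so the
    operation is idempotent.
    """
    out = trials.copy()
    if "exclusion_reason" not in out.columns:
        out["exclusion_reason"] = ""
    reason = out["exclusion_reason"].fillna("").astype(str)
    # response validity as recorded by the task, undoing our own RT flags
    resp_ok = (out["valid"].astype(int) == 1) | reason.isin(_FILTER_REASONS)
    rt = out["rt_ms"].astype(float)
    below = rt < rules.rt_min

    outlier = pd.Series(False, index=out.index)
    if rules.outlier_k is not None:
        base = resp_ok & ~below
        stats_df = (
            out.loc[base]
            .groupby("participant_id")["rt_ms"]
            .agg(["mean", "std"])
            .rename(columns={"mean": "_m", "std": "_s"})
        )
        joined = out[["participant_id"]].join(stats_df, on="participant_id")
        cutoff = joined["_m"] + rules.outlier_k * joined["_s"].fillna(0.0)
        outlier = base & (rt > cutoff)

    new_reason = pd.Series("", index=out.index)
    new_reason[outlier] = "rt_outlier"
    new_reason[below] = "rt_below_min"
    new_reason[~resp_ok] = "invalid_response"
    out["valid"] = (resp_ok & ~below & ~outlier).astype(int)
    out["exclusion_reason"] = new_reason
    return out


def block_baselines(trials: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    """Per-(participant, block) mean valid neutral RT by direction.

    Returns one row per (participant_id, block) with columns ``BL_app``,
    ``BL_avo``, ``n_app``, ``n_avo``.  A baseline whose trial count is below
    ``min_count`` is left NaN (undefined); dependent labels downstream become
    ``excluded``.
    """
    valid = trials[trials["valid"].astype(int) == 1]
    if valid.empty:
        raise ValueError("no valid trials: cannot compute baselines")
    keys = trials[["participant_id", "block"]].drop_duplicates()
    neutral = valid[valid["condition"] == "neutral"]
    rows = []
    for _, (pid, block) in keys.iterrows():
        blk = neutral[(neutral["participant_id"] == pid) & (neutral["block"] == block)]
        entry = {"participant_id": pid, "block": block}
        for direction, tag in (("approach", "app"), ("avoidance", "avo")):
            rts = blk.loc[blk["direction"] == direction, "rt_ms"].astype(float)
            entry[f"n_{tag}"] = len(rts)
            entry[f"BL_{tag}"] = rts.mean() if len(rts) >= min_count else np.nan
        rows.append(entry)
    return pd.DataFrame(rows)


def label_trials(
    trials: pd.DataFrame,
    baselines: pd.DataFrame,
    condition: str = "gaming",
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Label valid trials of one condition against their block baselines.

    ``condition="gaming"`` yields the real trial-level index;
    ``condition="neutral"`` yields the fake index, in which each neutral trial
    is compared with a baseline that (by default) includes the trial itself.
    ``leave_one_out=True`` removes the trial's own RT from its baseline, which
    avoids the self-inclusion shrinkage of deviations towards zero.

    Adds columns ``label`` (positive/negative/excluded), ``deviation_ms``
    (RT - directional baseline), ``index_kind`` (real/fake) and
    ``exclusion_reason``.  An undefined baseline excludes the trial rather
    than raising.
    """
    if condition not in ("gaming", "neutral"):
        raise ValueError("condition must be 'gaming' or 'neutral'")
    sel = trials[(trials["valid"].astype(int) == 1) & (trials["condition"] == condition)].copy()
    sel = sel.merge(baselines, on=["participant_id", "block"], how="left", validate="m:1")

    is_app = sel["direction"] == "approach"
    bl = np.where(is_app, sel["BL_app"], sel["BL_avo"]).astype(float)
    n_bl = np.where(is_app, sel["n_app"], sel["n_avo"]).astype(float)
    rt = sel["rt_ms"].to_numpy(dtype=float)

    if leave_one_out and condition == "neutral":
        with np.errstate(invalid="ignore", divide="ignore"):
            bl = np.where(n_bl > 1, (n_bl * bl - rt) / (n_bl - 1), np.nan)

    deviation = rt - bl
    # positive = faster pull / slower push than baseline
    positive = np.where(is_app, rt < bl, rt > bl)
    negative = np.where(is_app, rt > bl, rt < bl)
    label = np.full(len(sel), "excluded", dtype=object)
    label[positive] = "positive"
    label[negative] = "negative"

    reason = np.full(len(sel), "", dtype=object)
    reason[(label == "excluded") & np.isfinite(deviation)] = "tie"
    reason[~np.isfinite(bl)] = "undefined_baseline"
    label[~np.isfinite(bl)] = "excluded"

    sel["label"] = label
    sel["deviation_ms"] = deviation
    sel["index_kind"] = "real" if condition == "gaming" else "fake"
    sel["exclusion_reason"] = reason
    return sel.drop(columns=["BL_app", "BL_avo", "n_app", "n_avo"])


@dataclass
class ReliabilityResult:
    """Split-half reliability of the per-label mean RT deviation."""

    label: str
    participants: np.ndarray
    half1_means: np.ndarray
    half2_means: np.ndarray
    r_half: float
    rho_sb: float
    p_value: float
    n_dropped: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_sb <= 1.0:
            raise ValueError("Spearman-Brown reliability must lie in [-1, 1]")


def spearman_brown(r: float) -> float:
    """Step-up correction for a split-half correlation: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    labeled: pd.DataFrame,
    label: str = "positive",
    method: str = "pearson",
) -> ReliabilityResult:
    """Within-participant split-half reliability of the trial-level bias index.

    Per participant, the labelled trials (of the requested label) are ordered
    chronologically (run, block, trial) and split into first/second halves;
    the mean ``deviation_ms`` of each half forms one point per participant.
    Reliability is the across-participant correlation of half-means with the
    Spearman-Brown correction 2r/(1+r).  ``method="spearman"`` swaps the
    Pearson correlation for a rank correlation before correction.

    Requires >= 3 participants contributing the label in both halves;
    participants lacking the label in one half are dropped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    sub = labeled[labeled["label"] == label].sort_values(["run", "block", "trial"])
    pids, h1, h2 = [], [], []
    n_dropped = 0
    for pid, grp in sub.groupby("participant_id"):
        dev = grp["deviation_ms"].to_numpy(dtype=float)
        k = len(dev) // 2
        if k == 0:
            warnings.warn(
                f"participant {pid} lacks {label!r} trials in one half; dropped",
                stacklevel=2,
            )
            n_dropped += 1
            continue
        pids.append(pid)
        h1.append(dev[:k].mean())
        h2.append(dev[k:].mean())
    if len(pids) < 3:
        raise ValueError(
            f"split-half reliability needs >= 3 usable participants, got {len(pids)}"
        )
    h1a, h2a = np.asarray(h1), np.asarray(h2)
    if method == "pearson":
        res = stats.pearsonr(h1a, h2a)
    else:
        res = stats.spearmanr(h1a, h2a)
    r = float(res.statistic)
    return ReliabilityResult(
        label=label,
        participants=np.asarray(pids),
        half1_means=h1a,
        half2_means=h2a,
        r_half=r,
        rho_sb=spearman_brown(r),
        p_value=float(res.pvalue),
        n_dropped=n_dropped,
    )
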