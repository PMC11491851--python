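"""Closed-loop decoded attentional-bias training (DecABT) simulator.

During training the participant fixates while the decoder scores each fMRI
volume: the probability that the current multivoxel pattern reflects a
biased-towards-gaming attentional state.  The moment that probability
exceeds the trigger threshold (strictly above 0.95 by default) a stimulus is
presented — gaming with probability ``p_gaming``, neutral otherwise — with a
fixed cue contingency: gaming images always carry the avoidance cue (green
frame, push) and neutral images the approach cue (red frame, pull).  If the
probability never crosses the threshold within ``window_tr`` volumes the
trial ends without a stimulus (NG trial).

The simulator consumes either a precomputed per-TR probability stream or a
per-TR feature stream scored online with a fitted iterative sparse
classifier, so the trigger logic is testable independently of the decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import ISLRModel, predict_islr

__all__ = [
    "ClosedLoopConfig",
    "TrialLog",
    "SessionLog",
    "run_decabt_block",
    "summarize_session",
    "session_to_jsonl",
]

#: fixed training contingency: stimulus type -> (frame colour, required response)
CONTINGENCY = {
    "gaming": ("green", "avoidance"),
    "neutral": ("red", "approach"),
}


@dataclass(frozen=True)
class ClosedLoopConfig:
    """Trigger-algorithm parameters of one training block.

    prob_threshold:
        Decoded bias probability that must be strictly exceeded to trigger.
    window_tr:
        Volumes to wait for a trigger before declaring the trial NG.
    p_gaming:
        Probability that a triggered stimulus is a gaming image (the
        remainder are neutral); the empirical gaming fraction of the
        reference protocol was ~69%.
    post_trigger_tr:
        Volumes consumed by the stimulus/response epoch after a trigger.
    """

    prob_threshold: float = 0.95
    window_tr: int = 15
    p_gaming: float = 0.7
    trials_per_block: int = 10
    volumes_per_run: int = 210
    post_trigger_tr: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.window_tr < 1:
            raise ValueError("window_tr must be >= 1")
        if not 0.0 <= self.p_gaming <= 1.0:
            raise ValueError("p_gaming must lie in [0, 1]")


@dataclass
class TrialLog:
    """One simulated trial: the probabilities seen and what happened."""

    index: int
    start_tr: int
    probs: np.ndarray
    outcome: str  # "triggered" | "ng"
    trigger_tr: int | None = None  # within-trial TR index of the trigger
    stimulus: str | None = None
    cue_colour: str | None = None
    required_response: str | None = None


@dataclass
class SessionLog:
    """Record of one simulated training block."""

    config: ClosedLoopConfig
    trials: list[TrialLog] = field(default_factory=list)
    n_tr_consumed: int = 0

    @property
    def ng_count(self) -> int:
        return sum(t.outcome == "ng" for t in self.trials)

    @property
    def triggered(self) -> list[TrialLog]:
        return [t for t in self.trials if t.outcome == "triggered"]


def _probability_stream(
    stream: np.ndarray, decoder: ISLRModel | None
) -> np.ndarray:
    stream = np.asarray(stream, dtype=float)
    if stream.ndim == 1:
        if decoder is not None:
            raise ValueError("1-D streams are probabilities; decoder must be None")
        if np.any((stream < 0) | (stream > 1)):
            raise ValueError("probability stream must lie in [0, 1]")
        return stream
    if stream.ndim == 2:
        if decoder is None:
            raise ValueError("2-D feature streams require a fitted decoder")
        probs, _ = predict_islr(decoder, stream)
        return probs
    raise ValueError("stream must be 1-D probabilities or 2-D features")


def run_decabt_block(
    stream: np.ndarray,
    config: ClosedLoopConfig = ClosedLoopConfig(),
    decoder: ISLRModel | None = None,
) -> SessionLog:
    """Simulate one training block on a per-TR stream.

    Trials run back to back: each observes up to ``window_tr`` decoder
    probabilities; the first strictly above ``prob_threshold`` triggers a
    stimulus (ending the observation window and consuming a
    ``post_trigger_tr``-volume stimulus/response epoch), otherwise the trial
    is NG after exactly ``window_tr`` volumes.  The block ends after
    ``trials_per_block`` trials or when the stream cannot host a further full
    window (a partially observed trial is discarded).
    """
    probs = _probability_stream(stream, decoder)
    rng = np.random.default_rng(config.seed)
    log = SessionLog(config=config)
    cursor = 0
    for trial_idx in range(config.trials_per_block):
        if cursor + config.window_tr > probs.size:
            break
        window = probs[cursor : cursor + config.window_tr]
        above = np.flatnonzero(window > config.prob_threshold)
        if above.size:
            k = int(above[0])
            stimulus = "gaming" if rng.random() < config.p_gaming else "neutral"
            cue, response = CONTINGENCY[stimulus]
            log.trials.append(
                TrialLog(
                    index=trial_idx,
                    start_tr=cursor,
                    probs=window[: k + 1].copy(),
                    outcome="triggered",
                    trigger_tr=k,
                    stimulus=stimulus,
                    cue_colour=cue,
                    required_response=response,
                )
            )
            cursor += k + 1 + config.post_trigger_tr
        else:
            log.trials.append(
                TrialLog(
                    index=trial_idx,
                    start_tr=cursor,
                    probs=window.copy(),
                    outcome="ng",
                )
            )
            cursor += config.window_tr
    log.n_tr_consumed = min(cursor, probs.size)
    if not log.trials:
        raise ValueError("stream too short to host a single trial window")
    return log


def summarize_session(logs: list[SessionLog]) -> dict:
    """Aggregate statistics over simulated blocks.

    Returns the mean and s.e.m. of per-block NG counts, the empirical gaming
    fraction among triggered stimuli, and the trigger-latency distribution
    (latency = number of volumes observed up to and including the trigger).
    """
    if not logs:
        raise ValueError("no session logs to summarise")
    ng = np.array([log.ng_count for log in logs], dtype=float)
    triggered = [t for log in logs for t in log.triggered]
    latencies = np.array([t.trigger_tr + 1 for t in triggered], dtype=float)
    gaming = np.array([t.stimulus == "gaming" for t in triggered], dtype=float)
    return {
        "n_blocks": len(logs),
        "n_trials": sum(len(log.trials) for log in logs),
        "n_triggered": len(triggered),
        "ng_mean": float(ng.mean()),
        "ng_sem": float(ng.std(ddof=1) / np.sqrt(len(ng))) if len(ng) > 1 else float("nan"),
        "gaming_fraction": float(gaming.mean()) if len(triggered) else float("nan"),
        "latency_mean_tr": float(latencies.mean()) if len(triggered) else float("nan"),
        "latency_median_tr": float(np.median(latencies)) if len(triggered) else float("nan"),
    }


def session_to_jsonl(log: SessionLog, path: str | Path) -> None:
    """Write one record per TR event as JSON lines."""
    with open(path, "w") as fh:
        for t in log.trials:
            for k, p in enumerate(t.probs):
                fh.write(
                    json.dumps(
                        {
                            "trial": t.index,
                            "tr": t.start_tr + k,
                            "prob": float(p),
                            "event": (
                                "trigger"
                                if t.outcome == "triggered" and k == t.trigger_tr
                                else "fixation"
                            ),
                            "stimulus": t.stimulus if k == t.trigger_tr else None,
                        }
                    )
                    + "\n"
                )


def blocks_summary_table(logs: list[SessionLog]) -> pd.DataFrame:
    """Per-block summary rows (NG count, triggers, gaming fraction)."""
    rows = []
    for i, log in enumerate(logs):
        trig = log.triggered
        rows.append(
            {
                "block": i,
                "n_trials": len(log.trials),
                "ng_count": log.ng_count,
                "n_triggered": len(trig),
                "gaming_fraction": (
                    float(np.mean([t.stimulus == "gaming" for t in trig])) if trig else np.nan
                ),
                "mean_latency_tr": (
                    float(np.mean([t.trigger_tr + 1 for t in trig])) if trig else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
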