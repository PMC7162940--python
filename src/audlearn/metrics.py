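"""Block and cumulative performance coefficients.

Two coefficients summarise how well a participant tells targets from
non-targets.  For a contiguous block of trials,

    block sensitivity = hits / targets            (hit rate)
    block specificity = correct rejections / non-targets

and their running counterparts at trial i use the strict prefix of trials
1..i-1:

    cumulative sensitivity_i = hits(1..i-1) / targets(1..i-1)
    cumulative specificity_i = CRs(1..i-1) / non-targets(1..i-1)

A cumulative value whose denominator is still zero is *undefined* and is
represented as NaN; group means skip undefined entries rather than
imputing, so early-trial means average over fewer participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord, TRIALS_PER_SESSION, cohort_to_frame

__all__ = [
    "BlockSeries",
    "block_sensitivity",
    "block_specificity",
    "cumulative_sensitivity",
    "cumulative_specificity",
    "cumulative_curve",
    "block_series",
    "mean_cumulative_curves",
    "block_series_frame",
]

COEFFICIENTS = ("sensitivity", "specificity")


@dataclass
class BlockSeries:
    """Per-block coefficient values for one participant, in trial order."""

    participant_id: str
    coefficient: str
    block_size: int
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _trial_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    """(is_target, pressed_target) boolean arrays from a trial-log frame
    slice or a list of Trial objects."""
    if isinstance(trials, pd.DataFrame):
        is_target = trials["is_target"].to_numpy(dtype=bool)
        pressed = (trials["response"] == "target_button").to_numpy()
    else:
        is_target = np.array([t.is_target for t in trials], dtype=bool)
        pressed = np.array([t.response == "target_button" for t in trials])
    return is_target, pressed


def block_sensitivity(trials) -> float:
    """Hit rate within a block; raises if the block holds no target."""
    is_target, pressed = _trial_arrays(trials)
    n_targets = int(is_target.sum())
    if n_targets == 0:
        raise ValueError("block contains no target trial")
    return float((is_target & pressed).sum() / n_targets)


def block_specificity(trials) -> float:
    """Correct-rejection rate within a block; raises if all trials are
    targets."""
    is_target, pressed = _trial_arrays(trials)
    n_nontargets = int((~is_target).sum())
    if n_nontargets == 0:
        raise ValueError("block contains no non-target trial")
    return float((~is_target & ~pressed).sum() / n_nontargets)


def _cumulative(trials, i: int, want_target: bool) -> float:
    if i < 2:
        raise ValueError("cumulative coefficients need i >= 2 (strict prefix)")
    is_target, pressed = _trial_arrays(trials)
    if i - 1 > len(is_target):
        raise ValueError(f"prefix 1..{i - 1} exceeds the {len(is_target)} trials given")
    is_target = is_target[: i - 1]
    pressed = pressed[: i - 1]
    if want_target:
        denom = int(is_target.sum())
        num = int((is_target & pressed).sum())
    else:
        denom = int((~is_target).sum())
        num = int((~is_target & ~pressed).sum())
    if denom == 0:
        return float("nan")
    return num / denom


def cumulative_sensitivity(trials, i: int) -> float:
    """Hit rate over trials 1..i-1; NaN while no target has occurred."""
    return _cumulative(trials, i, want_target=True)


def cumulative_specificity(trials, i: int) -> float:
    """Correct-rejection rate over trials 1..i-1; NaN while no non-target
    has occurred."""
    return _cumulative(trials, i, want_target=False)


def cumulative_curve(trials, coefficient: str) -> pd.Series:
    """Full cumulative curve, indexed by trial i = 2..n; vectorised."""
    if coefficient not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    is_target, pressed = _trial_arrays(trials)
    if coefficient == "sensitivity":
        event, success = is_target, is_target & pressed
    else:
        event, success = ~is_target, ~is_target & ~pressed
    denom = np.cumsum(event)[:-1].astype(float)
    num = np.cumsum(success)[:-1].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, num / np.where(denom > 0, denom, 1), np.nan)
    index = pd.RangeIndex(2, len(is_target) + 1, name="trial")
    return pd.Series(values, index=index, name=coefficient)


def block_series(participant, coefficient: str, block_size: int) -> BlockSeries:
    """Per-block coefficient vector; ``block_size`` must divide the session
    length (240 trials -> 24 blocks of 10, or 6 blocks of 40)."""
    if coefficient not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    if isinstance(participant, ParticipantRecord):
        pid = participant.id
        frame = cohort_to_frame([participant])
    else:
        frame = participant.sort_values("trial_index")
        pids = frame["participant_id"].unique()
        if len(pids) != 1:
            raise ValueError("block_series expects trials of a single participant")
        pid = str(pids[0])
    n = len(frame)
    if n % block_size != 0:
        raise ValueError(f"block_size {block_size} does not divide {n} trials")
    fn = block_sensitivity if coefficient == "sensitivity" else block_specificity
    values = np.array(
        [fn(frame.iloc[b * block_size : (b + 1) * block_size]) for b in range(n // block_size)]
    )
    return BlockSeries(pid, coefficient, block_size, values)


def block_series_frame(cohort: pd.DataFrame, coefficient: str, block_size: int) -> pd.DataFrame:
    """Tidy table of per-block values for a whole cohort:
    (participant_id, block_index, value)."""
    rows = []
    for pid, grp in cohort.groupby("participant_id", sort=False):
        bs = block_series(grp, coefficient, block_size)
        for b, v in enumerate(bs.values, start=1):
            rows.append((pid, b, v))
    if not rows:
        raise ValueError("empty cohort")
    return pd.DataFrame(rows, columns=["participant_id", "block_index", "value"])


def mean_cumulative_curves(
    cohort: pd.DataFrame, coefficient: str, by: tuple[str, ...] = ("config", "button")
) -> pd.DataFrame:
    """Pointwise mean cumulative curve per group (default config x button).

    Participants whose curve is undefined at a trial are skipped at that
    trial, so early means may average fewer participants.  Returns a wide
    frame indexed by trial with one column per group.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    curves: dict = {}
    for key, grp in cohort.groupby(list(by), sort=True):
        per_participant = [
            cumulative_curve(g.sort_values("trial_index"), coefficient)
            for _, g in grp.groupby("participant_id", sort=False)
        ]
        stacked = pd.concat(per_participant, axis=1)
        curves[key] = stacked.mean(axis=1, skipna=True)
    out = pd.DataFrame(curves)
    out.columns.names = list(by)
    return out
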