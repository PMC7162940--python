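"""Evolution toward learning: high-performance-block counts and
design-effect tests.

Each participant's 24-block state sequence is reduced to the number of
high-performance blocks, overall and within three contiguous partitions of
8 blocks (beginning / middle / end of the session).  Mann-Whitney U tests
then compare these counts between the two response buttons and between
every pair of target configurations.  Following the original screening
intent, no multiple-comparison correction is applied and two significance
bands are reported: significant (p < 0.05) and marginally significant
(0.05 <= p < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UTestResult",
    "mann_whitney_u",
    "count_state_blocks",
    "partition_counts",
    "high_block_counts",
    "button_effect_test",
    "pairwise_config_tests",
    "significance_category",
]

STATE_NAMES = ("low", "med", "high")

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class UTestResult:
    """Mann-Whitney U for the first sample, with its two-sided/one-sided p."""

    U: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "normal_tie_corrected"


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> UTestResult:
    """Mann-Whitney U test, U reported for the first sample.

    Ties are handled with midranks.  The p-value is exact (full
    enumeration) when the pooled sample is small (n1 + n2 <= 12) and
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        method, label = "exact", "exact"
    else:
        method, label = "asymptotic", "normal_tie_corrected"
    res = stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    return UTestResult(
        U=float(res.statistic), p=float(res.pvalue), n1=x.size, n2=y.size, method=label
    )


def count_state_blocks(state_seq: Sequence[str], state: str) -> int:
    """Occurrences of one state in a block-state sequence."""
    unknown = set(state_seq) - set(STATE_NAMES)
    if unknown:
        raise ValueError(f"unknown state labels in sequence: {sorted(unknown)}")
    if state not in STATE_NAMES:
        raise ValueError(f"unknown state {state!r}")
    return sum(1 for s in state_seq if s == state)


def partition_counts(
    state_seq: Sequence[str], state: str = "high", n_partitions: int = 3
) -> tuple[int, ...]:
    """Occurrences of a state within contiguous equal partitions of the
    sequence (default: beginning / middle / end thirds)."""
    n = len(state_seq)
    if n % n_partitions != 0:
        raise ValueError(f"{n} blocks cannot be split into {n_partitions} equal partitions")
    size = n // n_partitions
    return tuple(
        count_state_blocks(state_seq[i * size : (i + 1) * size], state)
        for i in range(n_partitions)
    )


def high_block_counts(
    states: pd.DataFrame, meta: pd.DataFrame, n_partitions: int = 3
) -> pd.DataFrame:
    """Per-participant high-block counts, total and per partition.

    ``states``: tidy (participant_id, block_index, state);
    ``meta``: one row per participant with config, button (label optional).
    """
    meta_cols = [c for c in ("config", "button", "label") if c in meta.columns]
    meta_idx = meta.drop_duplicates("participant_id").set_index("participant_id")
    rows = []
    for pid, grp in states.groupby("participant_id", sort=False):
        seq = list(grp.sort_values("block_index")["state"])
        parts = partition_counts(seq, "high", n_partitions)
        m = meta_idx.loc[pid]
        rows.append((pid, *[m[c] for c in meta_cols], sum(parts), *parts))
    part_cols = [f"partition_{i + 1}" for i in range(n_partitions)]
    return pd.DataFrame(
        rows, columns=["participant_id", *meta_cols, "count_total", *part_cols]
    )


def significance_category(p: float) -> str:
    """Two-band screening scheme: significant / marginal / n.s."""
    if p < 0.05:
        return "significant"
    if p < 0.2:
        return "marginal"
    return "n.s."


def _scope_column(scope: str) -> str:
    if scope == "total":
        return "count_total"
    if scope.startswith("partition"):
        return f"partition_{scope.split()[-1].strip('_')}" if " " in scope else scope
    raise ValueError(f"unknown scope {scope!r}")


def button_effect_test(
    counts: pd.DataFrame, alternative: str = "two_sided", scope: str = "total"
) -> UTestResult:
    """U test of high-block counts between left- and right-button groups
    (left is the first sample)."""
    col = _scope_column(scope)
    left = counts.loc[counts["button"] == "left", col]
    right = counts.loc[counts["button"] == "right", col]
    if left.empty or right.empty:
        raise ValueError("both button groups must be non-empty")
    return mann_whitney_u(left, right, alternative)


def pairwise_config_tests(
    counts: pd.DataFrame, scope: str = "total", alternative: str = "two_sided"
) -> pd.DataFrame:
    """Two-sided U tests between every pair of target configurations.

    Returns one row per ordered pair (config_a, config_b) with U for the
    first group, p, and the significance category; p is symmetric in the
    pair, U maps to n1*n2 - U.  No multiple-comparison correction.
    """
    col = _scope_column(scope)
    configs = sorted(counts["config"].unique())
    missing = set(range(1, 5)) - set(int(c) for c in configs)
    if missing:
        raise ValueError(f"missing config groups: {sorted(missing)}")
    groups = {c: counts.loc[counts["config"] == c, col].to_numpy() for c in configs}
    rows = []
    for a in configs:
        for b in configs:
            if a == b:
                continue
            res = mann_whitney_u(groups[a], groups[b], alternative)
            rows.append(
                (int(a), int(b), res.U, res.p, significance_category(res.p), res.method)
            )
    return pd.DataFrame(
        rows, columns=["config_a", "config_b", "U", "p", "category", "method"]
    )
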