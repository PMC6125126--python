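"""Freezing quantification per tone, pretone, and two-trial block.

Freezing bouts arrive as (start, end) intervals; a window score is the
percent of the window covered by the union of the bouts (overlaps merged,
bouts clipped to the window first, so bouts spanning window edges count
only their inside part).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def merge_intervals(intervals) -> list[tuple[float, float]]:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if a >= b:
            raise ValueError(f"ill-formed interval ({a}, {b})")
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def freezing_percent(intervals, window: tuple[float, float]) -> float:
    """100 x |union(intervals) ∩ window| / |window|."""
    w0, w1 = float(window[0]), float(window[1])
    if w1 <= w0:
        raise ValueError("zero-length scoring window")
    covered = 0.0
    for a, b in merge_intervals(intervals):
        covered += max(0.0, min(b, w1) - max(a, w0))
    return 100.0 * covered / (w1 - w0)


def block_scores(trial_scores, block_size: int = 2) -> np.ndarray:
    """Means over consecutive non-overlapping trial blocks; a trailing
    incomplete block (e.g. the 15th extinction trial) is excluded and
    logged."""
    scores = np.asarray(list(trial_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no trial scores")
    if scores.size < block_size:
        raise ValueError("fewer trials than one block")
    n_blocks = scores.size // block_size
    dropped = scores.size - n_blocks * block_size
    if dropped:
        log.info("block_scores: excluding %d trailing unpaired trial(s)", dropped)
    return scores[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)


def score_session(freezing: pd.DataFrame, tone_onsets, tone_duration: float = 30.0,
                  pretone: bool = True) -> pd.DataFrame:
    """Per-trial percent scores from a freezing-interval table
    (trial_index, start_s, end_s); trial_index 0 holds pretone bouts.
    The pretone score uses the 30 s window ending at the first tone onset."""
    rows = []
    ivs = list(zip(freezing["start_s"], freezing["end_s"]))
    if pretone:
        first = float(tone_onsets[0])
        rows.append((0, freezing_percent(ivs, (first - 30.0, first))))
    for k, onset in enumerate(tone_onsets, start=1):
        rows.append((k, freezing_percent(ivs, (float(onset), float(onset) + tone_duration))))
    return pd.DataFrame(rows, columns=["trial_index", "percent_freezing"])
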