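"""Read/write session containers: HDF5 signals + CSV event tables.

Conventions: timestamps in seconds with 0 at recording start; all
windows are half-open ``[start, end)``; one composite LFP trace per
region. Event files are sorted on load so trial/pip bookkeeping is
invariant to row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .simulate import REGIONS, SESSION_LABELS

log = logging.getLogger(__name__)

TIMEPOINTS = ("before_conditioning", "fear_recall", "extinction_recall")

# timepoint -> (session label, which two trials)
_TIMEPOINT_RULE = {
    "before_conditioning": ("tone_habituation", "last"),
    "fear_recall": ("fear_recall_extinction", "first"),
    "extinction_recall": ("extinction_recall", "first"),
}


class SessionValidationError(ValueError):
    """A session file violates the recording contract."""


@dataclass
class SessionRecording:
    """One animal-session: two labeled channels, event timeline, trials."""

    channels: dict               # region -> µV sample vector
    rate: float                  # Hz
    events: pd.DataFrame         # timestamp_s, kind, trial_index
    trials: pd.DataFrame         # trial_index, session_label, tone_onset_s
    animal_id: str = "unknown"
    group: str = "control"
    tone_duration: float = 30.0

    @property
    def session_label(self) -> str:
        return str(self.trials["session_label"].iloc[0])

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def pip_onsets(self, trial_index: int) -> np.ndarray:
        ev = self.events
        m = (ev["kind"] == "pip_onset") & (ev["trial_index"] == trial_index)
        return ev.loc[m, "timestamp_s"].to_numpy()

    def validate(self, pips_per_tone: int | None = None) -> None:
        lengths = {r: len(v) for r, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SessionValidationError(f"channel length mismatch: {lengths}")
        ts = self.events["timestamp_s"].to_numpy()
        if np.any(np.diff(ts) < 0):
            raise SessionValidationError("events not sorted by timestamp")
        label = self.session_label
        if label not in SESSION_LABELS:
            raise SessionValidationError(f"unknown session_label {label!r}")
        counts = set()
        for _, row in self.trials.iterrows():
            k = int(row["trial_index"])
            onset = float(row["tone_onset_s"])
            pips = self.pip_onsets(k)
            inside = (pips >= onset) & (pips < onset + self.tone_duration)
            if not np.all(inside):
                raise SessionValidationError(
                    f"trial {k}: pip onset outside its tone window")
            counts.add(len(pips))
        if len(counts) > 1:
            raise SessionValidationError(
                f"inconsistent pip counts across trials: {sorted(counts)}")
        if pips_per_tone is not None and counts and counts != {pips_per_tone}:
            raise SessionValidationError(
                f"expected {pips_per_tone} pips per tone, found {counts.pop()}")


def save_session(rec: SessionRecording, signal_path, events_path) -> None:
    """HDF5 for the channels (lossless float64), CSV for events+trials."""
    with h5py.File(signal_path, "w") as h5:
        h5.attrs["rate"] = rec.rate
        h5.attrs["animal_id"] = rec.animal_id
        h5.attrs["group"] = rec.group
        h5.attrs["tone_duration"] = rec.tone_duration
        grp = h5.create_group("channels")
        for region, data in rec.channels.items():
            ds = grp.create_dataset(region, data=np.asarray(data, dtype=np.float64))
            ds.attrs["units"] = "uV"
            ds.attrs["region"] = region
    rows = []
    for _, tr in rec.trials.iterrows():
        k = int(tr["trial_index"])
        pips = rec.pip_onsets(k)
        us = rec.events.query("kind == 'us_onset' and trial_index == @k")
        rows.append({
            "trial_index": k,
            "session_label": tr["session_label"],
            "tone_onset_s": repr(float(tr["tone_onset_s"])),
            "pip_onsets_s": ";".join(repr(float(p)) for p in pips),
            "us_onset_s": repr(float(us["timestamp_s"].iloc[0])) if len(us) else "",
        })
    pd.DataFrame(rows).to_csv(events_path, index=False)


def load_session(signal_path, events_path,
                 pips_per_tone: int | None = None) -> SessionRecording:
    """Load and validate one session; inverse of :func:`save_session`."""
    with h5py.File(signal_path, "r") as h5:
        rate = float(h5.attrs["rate"])
        animal_id = str(h5.attrs.get("animal_id", "unknown"))
        group = str(h5.attrs.get("group", "control"))
        tone_duration = float(h5.attrs.get("tone_duration", 30.0))
        channels = {r: h5["channels"][r][()] for r in h5["channels"]}
    tab = pd.read_csv(events_path)
    required = {"trial_index", "session_label", "tone_onset_s", "pip_onsets_s"}
    if not required.issubset(tab.columns):
        raise SessionValidationError(
            f"events file missing columns {sorted(required - set(tab.columns))}")
    tab = tab.sort_values("trial_index").reset_index(drop=True)
    ev_rows, tr_rows = [], []
    for _, row in tab.iterrows():
        k = int(row["trial_index"])
        onset = float(row["tone_onset_s"])
        tr_rows.append((k, row["session_label"], onset))
        ev_rows.append((onset, "tone_onset", k))
        for p in str(row["pip_onsets_s"]).split(";"):
            ev_rows.append((float(p), "pip_onset", k))
        if "us_onset_s" in row and pd.notna(row["us_onset_s"]) and str(row["us_onset_s"]).strip():
            ev_rows.append((float(row["us_onset_s"]), "us_onset", k))
    events = pd.DataFrame(ev_rows, columns=["timestamp_s", "kind", "trial_index"])
    events = events.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    trials = pd.DataFrame(tr_rows, columns=["trial_index", "session_label", "tone_onset_s"])
    rec = SessionRecording(channels=channels, rate=rate, events=events,
                           trials=trials, animal_id=animal_id, group=group,
                           tone_duration=tone_duration)
    rec.validate(pips_per_tone=pips_per_tone)
    return rec


# ---------------------------------------------------------------------------
# trial selection and blocking
# ---------------------------------------------------------------------------

def select_block_trials(rec: SessionRecording, timepoint: str) -> list[int]:
    """The two trials scored at a behavioral timepoint.

    Convention: the last two tone-habituation trials define the
    before-conditioning baseline; the first two trials of the
    fear-recall/extinction and extinction-recall sessions define the two
    recall timepoints.
    """
    if timepoint not in _TIMEPOINT_RULE:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    label, which = _TIMEPOINT_RULE[timepoint]
    if rec.session_label != label:
        raise ValueError(
            f"timepoint {timepoint!r} requires session {label!r}, "
            f"recording holds {rec.session_label!r}")
    idx = sorted(int(i) for i in rec.trials["trial_index"])
    if len(idx) < 2:
        raise ValueError(f"need at least two trials, session has {len(idx)}")
    return idx[:2] if which == "first" else idx[-2:]


def make_block_table(trial_indices, block_size: int = 2) -> pd.DataFrame:
    """Partition trials in order into consecutive blocks of ``block_size``;
    a trailing incomplete block is dropped with a log message (15
    extinction trials are scored as 7 two-trial blocks)."""
    idx = list(trial_indices)
    n_blocks = len(idx) // block_size
    dropped = len(idx) - n_blocks * block_size
    if dropped:
        log.info("make_block_table: dropping %d trailing unpaired trial(s)", dropped)
    rows = [(b + 1, idx[b * block_size + j])
            for b in range(n_blocks) for j in range(block_size)]
    return pd.DataFrame(rows, columns=["block_index", "trial_index"])
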