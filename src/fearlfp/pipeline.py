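"""End-to-end orchestration: simulate a cohort, compute per-animal
measures at the three behavioral timepoints, run the group statistics,
and write summary tables with full provenance.

A cohort couples a scenario (per-group, per-timepoint theta gains, AEP
amplitudes, coupling, lag, freezing fractions) to the session designs.
The built-in scenarios encode the two qualitative patterns of interest:

* ``control``: theta gain and AEP amplitude rise at fear recall in both
  regions and return to baseline at extinction recall; dmPFC-BLA
  coupling is high during both recalls with the dmPFC leading by +20 ms.
* ``cis`` (chronic immobilization stress): BLA theta gain and AEP stay
  elevated through extinction recall, dmPFC theta rises then reverses,
  dmPFC AEP never changes, and inter-regional coupling is absent.

One master seed spawns per-animal, per-session child seeds through
``numpy.random.SeedSequence([master, group_key, animal, session])`` so cohorts are
reproducible and extensible animal by animal.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aep as aep_mod
from . import behavior, connectivity, spectral, stats
from .session_io import SessionRecording, select_block_trials, TIMEPOINTS
from .simulate import (SessionDesign, SimulationParams, default_design,
                       simulate_session, simulate_freezing, REGIONS)

TP_SESSION = {
    "before_conditioning": "tone_habituation",
    "fear_recall": "fear_recall_extinction",
    "extinction_recall": "extinction_recall",
}


def control_scenario() -> dict:
    """Per-timepoint injections for the unstressed pattern."""
    return {
        "theta_gain": {
            "before_conditioning": {"dmPFC": 1.0, "BLA": 1.0},
            "fear_recall": {"dmPFC": 2.5, "BLA": 2.5},
            "extinction_recall": {"dmPFC": 1.0, "BLA": 1.0},
        },
        "aep_uv": {
            "before_conditioning": {"dmPFC": 75.0, "BLA": 75.0},
            "fear_recall": {"dmPFC": 112.0, "BLA": 112.0},
            "extinction_recall": {"dmPFC": 75.0, "BLA": 75.0},
        },
        "coupling": {"before_conditioning": 0.3, "fear_recall": 0.9,
                     "extinction_recall": 0.9},
        "lag": {"before_conditioning": 0.02, "fear_recall": 0.02,
                "extinction_recall": 0.02},
        "freeze_frac": {"before_conditioning": 0.05, "fear_recall": 0.7,
                        "extinction_recall": 0.2},
        "pretone_frac": 0.05,
    }


def cis_scenario() -> dict:
    """Chronically stressed pattern: persistent BLA theta/AEP elevation,
    normal bidirectional dmPFC theta, no dmPFC AEP change, no coupling."""
    sc = control_scenario()
    sc["theta_gain"] = {
        "before_conditioning": {"dmPFC": 1.0, "BLA": 1.0},
        "fear_recall": {"dmPFC": 2.5, "BLA": 2.5},
        "extinction_recall": {"dmPFC": 1.0, "BLA": 2.5},
    }
    sc["aep_uv"] = {
        "before_conditioning": {"dmPFC": 75.0, "BLA": 75.0},
        "fear_recall": {"dmPFC": 75.0, "BLA": 112.0},
        "extinction_recall": {"dmPFC": 75.0, "BLA": 112.0},
    }
    sc["coupling"] = {tp: 0.0 for tp in TIMEPOINTS}
    return sc


@dataclass
class RunConfig:
    n_control: int = 7
    n_cis: int = 8
    scenarios: dict = field(default_factory=lambda: {
        "control": control_scenario(), "CIS": cis_scenario()})
    n_tones_habituation: int = 5
    n_tones_recall: int = 15
    n_surrogates: int = 100
    master_seed: int = 0
    outdir: str | None = None
    sim: dict = field(default_factory=dict)   # overrides for SimulationParams

    def hash(self) -> str:
        # outdir is storage, not analysis; it must not change the hash
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _group_key(group: str) -> int:
    # stable across processes (unlike builtin hash)
    return zlib.crc32(group.encode()) & 0xFFFF


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_animal(config: RunConfig, group: str, animal_index: int):
    """Three sessions (habituation, fear recall/extinction, extinction
    recall) for one simulated animal under its group scenario."""
    sc = config.scenarios[group]
    animal_id = f"{group}{animal_index:02d}"
    sessions = {}
    for j, tp in enumerate(TIMEPOINTS):
        label = TP_SESSION[tp]
        n_tones = (config.n_tones_habituation if label == "tone_habituation"
                   else config.n_tones_recall)
        design = SessionDesign(session_label=label, n_tones=n_tones)
        params = SimulationParams(
            coupling=sc["coupling"][tp], lag=sc["lag"][tp],
            region_theta_gain=sc["theta_gain"][tp],
            aep_amplitude=sc["aep_uv"][tp],
            seed=_child_seed(config.master_seed, _group_key(group),
                             animal_index, j),
            **config.sim)
        rec, truth = simulate_session(design, params, animal_id=animal_id,
                                      group=group)
        sessions[tp] = (rec, truth)
    return animal_id, sessions


def analyze_animal(sessions: dict, config: RunConfig, animal_id: str,
                   group: str) -> dict:
    """Per-animal measures at the three timepoints.

    AEP amplitude and evoked theta power per region (normalized as
    percent of the before-conditioning value), tone-evoked theta
    coherence, envelope lead/lag with surrogate significance, and
    freezing percent per scored window.
    """
    theta_grid = np.round(np.arange(20, 122) * 0.1, 10)  # 2-12.1 Hz rows
    rows_aep, rows_theta, rows_conn, rows_freeze = [], [], [], []
    base_amp: dict[str, float] = {}
    base_theta: dict[str, float] = {}
    for j, tp in enumerate(TIMEPOINTS):
        rec, truth = sessions[tp]
        trials = select_block_trials(rec, tp)
        for region in REGIONS:
            segs = aep_mod.epoch_pips(rec, trials, region, window_ms=(-100, 400))
            ev = aep_mod.average_aep(
                segs, aep_mod.epoch_times_ms((-100, 400), rec.rate),
                region=region, timepoint=tp)
            ev = aep_mod.score_amplitude(ev)
            if tp == "before_conditioning":
                base_amp[region] = ev.amplitude
            rows_aep.append({
                "animal_id": animal_id, "group": group, "region": region,
                "timepoint": tp, "amplitude_uv": ev.amplitude,
                "amplitude_pct_baseline": aep_mod.normalize_percent(
                    ev.amplitude, base_amp[region]),
                "n_pips": ev.n_pips,
            })
            tsegs = aep_mod.epoch_pips(rec, trials, region, window_ms=(-200, 400))
            tev = aep_mod.average_aep(
                tsegs, aep_mod.epoch_times_ms((-200, 400), rec.rate))
            tf = spectral.morlet_tfr(tev.waveform, rec.rate, tev.times_ms,
                                     freqs=theta_grid)
            theta = spectral.evoked_theta_power(spectral.zscore_and_baseline(tf))
            if tp == "before_conditioning":
                base_theta[region] = theta
            pos = base_theta[region] > 0
            rows_theta.append({
                "animal_id": animal_id, "group": group, "region": region,
                "timepoint": tp, "theta_power_z": theta,
                "theta_pct_baseline": 100.0 * theta / base_theta[region]
                if pos else np.nan,
                "theta_minus_baseline": theta - base_theta[region],
                "baseline_positive": bool(pos),
            })
        coh = np.mean([
            connectivity.coherence_spectrum(
                rec.channels["dmPFC"][i0:i1], rec.channels["BLA"][i0:i1],
                rec.rate).theta_summary
            for i0, i1 in _cs_bounds(rec, trials)])
        ll_seed = _child_seed(config.master_seed, _group_key(group),
                              int(animal_id[-2:]), j, 99)
        ll = connectivity.lead_lag(
            connectivity.cs_window_segments(rec, trials), rec.rate,
            n_surrogates=config.n_surrogates, seed=ll_seed)
        rows_conn.append({
            "animal_id": animal_id, "group": group, "timepoint": tp,
            "theta_coherence": float(coh), "summary_lag_s": ll.summary_lag,
            "significant": ll.significant, "n_segments": len(ll.peak_lags),
            "n_surrogates": config.n_surrogates, "seed": ll_seed,
        })
        sc = config.scenarios[group]
        onsets = rec.trials.set_index("trial_index").loc[trials, "tone_onset_s"].to_numpy()
        fr = simulate_freezing([sc["freeze_frac"][tp]] * len(trials), onsets,
                               pretone_frac=sc["pretone_frac"],
                               seed=_child_seed(config.master_seed,
                                                _group_key(group),
                                                int(animal_id[-2:]), j, 7))
        scored = behavior.score_session(fr, onsets)
        rows_freeze.append({
            "animal_id": animal_id, "group": group, "timepoint": tp,
            "percent_freezing": scored.loc[scored.trial_index > 0,
                                           "percent_freezing"].mean(),
            "pretone_percent": scored.loc[scored.trial_index == 0,
                                          "percent_freezing"].iloc[0],
        })
    return {"aep": rows_aep, "theta": rows_theta, "conn": rows_conn,
            "freezing": rows_freeze}


def _cs_bounds(rec: SessionRecording, trials):
    out = []
    for k in trials:
        onset = float(rec.trials.loc[rec.trials.trial_index == int(k),
                                     "tone_onset_s"].iloc[0])
        i0 = int(round(onset * rec.rate))
        out.append((i0, i0 + int(round(rec.tone_duration * rec.rate))))
    return out


def run_experiment(config: RunConfig) -> dict:
    """Simulate the cohort, compute all per-animal measures, run the
    group statistics, and (if ``config.outdir`` is set) write summary
    CSVs plus a provenance manifest."""
    tables = {"aep": [], "theta": [], "conn": [], "freezing": []}
    for group, n in (("control", config.n_control), ("CIS", config.n_cis)):
        for i in range(n):
            animal_id, sessions = simulate_animal(config, group, i)
            res = analyze_animal(sessions, config, animal_id, group)
            for key in tables:
                tables[key].extend(res[key])
    frames = {k: pd.DataFrame(v) for k, v in tables.items()}

    anovas = {}
    frz = frames["freezing"]
    anovas["freezing_mixed"] = stats.rm_anova_2way_mixed(
        frz, dv="percent_freezing", within="timepoint", between="group",
        subject="animal_id")
    for group in ("control", "CIS"):
        for measure, frame, col in (
                ("aep", frames["aep"], "amplitude_pct_baseline"),
                ("theta", frames["theta"], "theta_pct_baseline")):
            for region in REGIONS:
                sub = frame[(frame.group == group) & (frame.region == region)]
                if sub[col].notna().all():
                    anovas[f"{measure}_{region}_{group}"] = stats.rm_anova_1way(
                        sub, dv=col, within="timepoint", subject="animal_id")

    bundle = {"tables": frames, "anovas": anovas, "config_hash": config.hash()}
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            f = frame.copy()
            f["config_hash"] = config.hash()
            f["master_seed"] = config.master_seed
            f.to_csv(out / f"{name}_summary.csv", index=False)
        manifest = {"config": asdict(config), "config_hash": config.hash(),
                    "anova": {k: {"F": v.F, "df": [v.df1, v.df2], "p": v.p}
                              for k, v in anovas.items()
                              if isinstance(v, stats.AnovaResult)}}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle


# ---------------------------------------------------------------------------
# source-data import
# ---------------------------------------------------------------------------

def import_source_data(path, measure: str, level_map: dict,
                       animal_col: str = "animal_id",
                       group_col: str | None = None,
                       sheet: int | str = 0,
                       ignore: tuple = ()) -> pd.DataFrame:
    """Convert a wide per-animal workbook (XLSX or CSV) into the long
    AnimalSummary schema.

    ``level_map`` maps workbook column names to repeated-factor levels
    explicitly; any unexpected column raises rather than being guessed.
    Returns columns (animal_id, group, measure, level, value).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        wide = pd.read_excel(path, sheet_name=sheet)
    else:
        wide = pd.read_csv(path)
    expected = {animal_col, *level_map, *ignore}
    if group_col:
        expected.add(group_col)
    missing = set(level_map) - set(wide.columns)
    if missing:
        raise ValueError(f"schema mismatch: missing columns {sorted(missing)}; "
                         f"file has {list(wide.columns)}")
    extra = set(wide.columns) - expected
    if extra:
        raise ValueError(
            f"unmapped columns {sorted(extra)}: extend level_map or ignore")
    rows = []
    for _, r in wide.iterrows():
        for col, level in level_map.items():
            rows.append({
                "animal_id": r[animal_col],
                "group": r[group_col] if group_col else "all",
                "measure": measure, "level": level,
                "value": float(r[col]),
            })
    return pd.DataFrame(rows)
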