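"""From raw recording sessions to the standardized observation table.

Stages, in the order the analysis applies them:

1. segment each session into per-trial windows (music onset to offset; prompt
   and rating periods are excluded because events mark the music span only);
2. extract a continuous feature series per trial and measure (EMG envelopes,
   heart/respiration rate on a regular grid, skin-conductance phasic series);
3. standardize each participant x measure to mean 0 / SD 1, pooling samples
   over all trials of both tasks;
4. average the first and second half of each trial (15 s intervals for 30 s
   trials) -> one value per (participant, stimulus, task, interval, measure);
5. assemble the long observation table, attaching each stimulus's three
   dimension levels and the participant's z-scored felt-intensity ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sigproc
from . import stimuli as stim_mod
from .errors import (
    BoundsError,
    DegenerateChannelError,
    DomainError,
    JoinError,
    MusicPhysError,
)
from .synth import CHANNEL_OF, MEASURES

OBSERVATION_COLUMNS = (
    "participant",
    "stimulus",
    "task",
    "interval",
    "measure",
    "value",
    "valence_level",
    "energy_level",
    "tension_level",
    "intensity_z",
)


@dataclass
class TrialWindow:
    """One trial's slice of one raw channel."""

    stimulus_id: int
    task: str
    block: int
    onset: float
    duration: float
    channel: str
    samples: np.ndarray
    fs: float


def segment_trials(session, events=None) -> list[TrialWindow]:
    """Cut every channel into per-event windows [onset, onset+duration).

    Events must lie within the recording and must not overlap (the design has
    prompt/rating gaps between trials).
    """
    if events is None:
        events = session.events
    if not events:
        warnings.warn("empty event list: no trial windows produced")
        return []
    ordered = sorted(events, key=lambda e: e.onset)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.onset + prev.duration > nxt.onset:
            raise MusicPhysError(
                f"overlapping events at {prev.onset:.2f}s and {nxt.onset:.2f}s"
            )
    n = session.n_samples
    fs = session.fs
    windows = []
    for ev in ordered:
        i0 = int(round(ev.onset * fs))
        i1 = int(round((ev.onset + ev.duration) * fs))
        if i0 < 0 or i1 > n:
            raise BoundsError(
                f"event at {ev.onset}s (+{ev.duration}s) exceeds recording "
                f"of {n / fs:.1f}s"
            )
        for channel, series in session.channels.items():
            windows.append(
                TrialWindow(
                    stimulus_id=ev.stimulus_id,
                    task=ev.task,
                    block=ev.block,
                    onset=ev.onset,
                    duration=ev.duration,
                    channel=channel,
                    samples=series[i0:i1],
                    fs=fs,
                )
            )
    return windows


def extract_continuous_features(session, grid_fs=sigproc.RATE_GRID_FS) -> dict:
    """Per-trial continuous feature series for every measure of one session.

    Returns ``{measure: [(event, series), ...]}`` where ``series`` is the
    trial's continuous feature at the measure's native grid (EMG envelope at
    the raw rate; heart/respiration rate and SC phasic at ``grid_fs``).

    EMG filtering and pulse-peak detection run on the whole channel once (so
    filter warm-up and peak context fall outside the windows); the SC
    decomposition runs per trial window.
    """
    fs = session.fs
    events = sorted(session.events, key=lambda e: e.onset)
    out = {m: [] for m in MEASURES}

    env = {
        "EMGZ": sigproc.emg_envelope(session.channels[CHANNEL_OF["EMGZ"]], fs),
        "EMGC": sigproc.emg_envelope(session.channels[CHANNEL_OF["EMGC"]], fs),
    }
    rate = {}
    for m, min_iv in (("HR", sigproc.MIN_INTERVAL["bvp"]),
                      ("RR", sigproc.MIN_INTERVAL["respiration"])):
        cond = sigproc.condition_pulsatile(session.channels[CHANNEL_OF[m]], fs)
        peaks = sigproc.detect_peaks(cond, fs, min_iv)
        rate[m] = sigproc.rate_from_peaks(peaks)

    for ev in events:
        i0 = int(round(ev.onset * fs))
        i1 = int(round((ev.onset + ev.duration) * fs))
        for m in ("EMGZ", "EMGC"):
            out[m].append((ev, env[m][i0:i1]))
        for m in ("HR", "RR"):
            _, vals = sigproc.resample_rate(
                rate[m], grid_fs, (ev.onset, ev.onset + ev.duration)
            )
            out[m].append((ev, vals * 60.0))  # Hz -> events/min
        decomp = sigproc.decompose_sc(session.channels[CHANNEL_OF["SC"]][i0:i1], fs)
        out["SC"].append((ev, decomp.phasic))
    return out


def standardize_within_participant(trial_series: dict) -> tuple[dict, dict]:
    """Standardize pooled samples to mean 0 / SD 1 per participant x measure.

    ``trial_series`` maps measure -> list of (event, series).  Returns the
    standardized mapping plus ``{measure: (mean, sd)}`` with the constants
    used (handy for ground-truth comparisons).
    """
    standardized, constants = {}, {}
    for measure, pairs in trial_series.items():
        if len(pairs) < 2:
            raise DomainError(
                f"need >= 2 trials per participant x measure, got {len(pairs)} "
                f"for {measure}"
            )
        pooled = np.concatenate([np.asarray(s, dtype=float) for _, s in pairs])
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=0))
        if sd == 0.0:
            raise DegenerateChannelError(participant_id=None, measure=measure)
        standardized[measure] = [(ev, (np.asarray(s) - mean) / sd) for ev, s in pairs]
        constants[measure] = (mean, sd)
    return standardized, constants


def interval_means(window) -> tuple[float, float]:
    """Means of the first and second half of a trial window.

    For odd lengths the middle sample joins the first half.  For even lengths
    the mean of the two values equals the whole-window mean exactly.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise DomainError(f"window of {w.size} samples cannot be halved")
    cut = (w.size + 1) // 2
    return float(w[:cut].mean()), float(w[cut:].mean())


def session_features(session, grid_fs=sigproc.RATE_GRID_FS) -> pd.DataFrame:
    """Steps 1-4 for one session: long frame of interval-averaged values."""
    continuous = extract_continuous_features(session, grid_fs)
    try:
        standardized, _ = standardize_within_participant(continuous)
    except DegenerateChannelError as exc:
        raise DegenerateChannelError(session.participant_id, exc.measure) from exc
    rows = []
    for measure, pairs in standardized.items():
        for ev, series in pairs:
            v1, v2 = interval_means(series)
            for interval, value in ((1, v1), (2, v2)):
                rows.append(
                    {
                        "participant": session.participant_id,
                        "stimulus": ev.stimulus_id,
                        "task": ev.task,
                        "interval": interval,
                        "measure": measure,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def build_observation_table(
    feature_rows: pd.DataFrame,
    stimuli,
    intensity: pd.DataFrame | None = None,
    edges=stim_mod.DEFAULT_EDGES,
) -> pd.DataFrame:
    """Assemble the analysis-ready long table.

    Attaches each stimulus's three dimension levels (nearest-integer binning
    with the given edges) and, where ``intensity`` (participant, stimulus,
    rating) is given, the rating z-scored across each participant's felt
    trials, carried on the felt-task rows.

    Raises :class:`JoinError` if a stimulus in the features has no row in the
    stimulus table.
    """
    frame = stim_mod.stimulus_frame(stimuli, edges).reset_index(drop=True)
    missing = set(feature_rows["stimulus"]) - set(frame["stimulus_id"])
    if missing:
        raise JoinError(f"stimuli missing from the stimulus table: {sorted(missing)}")
    df = feature_rows.merge(
        frame[["stimulus_id", "valence_level", "energy_level", "tension_level"]],
        left_on="stimulus",
        right_on="stimulus_id",
        how="left",
    ).drop(columns="stimulus_id")

    df["intensity_z"] = np.nan
    if intensity is not None and len(intensity):
        inten = intensity.copy()
        z = inten.groupby("participant")["rating"].transform(
            lambda v: (v - v.mean()) / v.std(ddof=0)
        )
        inten["intensity_z"] = z
        df = df.drop(columns="intensity_z").merge(
            inten[["participant", "stimulus", "intensity_z"]],
            on=["participant", "stimulus"],
            how="left",
        )
        df.loc[df["task"] != "felt", "intensity_z"] = np.nan

    dupes = df.duplicated(
        subset=["participant", "stimulus", "task", "interval", "measure"]
    )
    if dupes.any():
        raise MusicPhysError(f"{int(dupes.sum())} duplicate observation rows")
    return df[list(OBSERVATION_COLUMNS)]


def cohort_observation_table(cohort, stimuli=None, grid_fs=sigproc.RATE_GRID_FS) -> pd.DataFrame:
    """Steps 1-5 over a rendered cohort."""
    if stimuli is None:
        stimuli = stim_mod.load_stimulus_table()
    frames = [session_features(s, grid_fs) for s in cohort.sessions]
    features = pd.concat(frames, ignore_index=True)
    return build_observation_table(features, stimuli, intensity=cohort.truth.intensity)
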