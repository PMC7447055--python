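"""Configuration, file formats, validation and the end-to-end pipeline.

Stages: simulate (synthetic cohort -> session container + intensity ratings)
-> preprocess (continuous per-trial features) -> features (standardized
observation table) -> fit (mixed-model reports).  A one-shot
:func:`run_pipeline` chains all four on synthetic data and writes a
provenance manifest; re-running with the same config reproduces identical
observation tables.

Formats: HDF5 (or per-channel CSV) for signals, TSV for events, stimuli,
intensity ratings and observations, JSON for model reports, YAML for config.
All onsets/durations are seconds from recording start, sample indices are
0-based, windows are half-open [onset, onset + duration).  Every output
carries the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import features as feat_mod
from . import stats as stats_mod
from . import stimuli as stim_mod
from .errors import MusicPhysError, SchemaError
from .synth import (
    MEASURES,
    Cohort,
    GeneratorConfig,
    RecordingSession,
    TrialEvent,
    simulate_cohort,
)

log = logging.getLogger("musicphys")


def _log(stage: str, entity: str, message: str):
    log.info("stage=%s entity=%s msg=%s", stage, entity, message)


class PipelineStageError(MusicPhysError):
    """A pipeline stage failed; names the stage and the offending entity."""

    def __init__(self, stage, entity, cause):
        self.stage = stage
        self.entity = entity
        super().__init__(f"stage {stage!r} failed on {entity!r}: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    measures: tuple = MEASURES
    dimensions: tuple = ("valence", "energy", "tension")
    fit_intensity: bool = True
    grid_fs: float = 10.0
    signal_format: str = "hdf5"  # "hdf5" | "csv"

    def __post_init__(self):
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig.from_dict(self.generator)
        if self.signal_format not in ("hdf5", "csv"):
            raise SchemaError(f"unknown signal_format {self.signal_format!r}")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise SchemaError(f"unknown measures {unknown}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["measures"] = list(self.measures)
        d["dimensions"] = list(self.dimensions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("measures", "dimensions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """Reduced-size configuration for the one-shot reproduction run."""
    return RunConfig(
        generator=GeneratorConfig(n_participants=4, n_stimuli=8, seed=seed)
    )


# ---------------------------------------------------------------------------
# session container I/O

_EVENT_FIELDS = ("onset", "duration", "stimulus_id", "task", "block")


def _events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset, e.duration, e.stimulus_id, e.task, e.block) for e in events],
        columns=_EVENT_FIELDS,
    )


def _events_from_frame(df) -> list:
    return [
        TrialEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            stimulus_id=int(r.stimulus_id),
            task=str(r.task),
            block=int(r.block),
        )
        for r in df.itertuples()
    ]


def write_sessions_hdf5(path, sessions, config_hash: str, seed: int):
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config_hash
        fh.attrs["seed"] = seed
        fh.attrs["musicphys_version"] = _pkg_version
        for s in sessions:
            grp = fh.create_group(s.participant_id)
            grp.attrs["fs"] = s.fs
            for name, series in s.channels.items():
                grp.create_dataset(f"channels/{name}", data=series, compression="gzip")
            ev = _events_frame(s.events)
            egrp = grp.create_group("events")
            for col in ("onset", "duration"):
                egrp.create_dataset(col, data=ev[col].to_numpy(float))
            for col in ("stimulus_id", "block"):
                egrp.create_dataset(col, data=ev[col].to_numpy(int))
            egrp.create_dataset(
                "task", data=np.array(ev["task"], dtype=h5py.string_dtype())
            )


def read_sessions_hdf5(path):
    sessions, meta = [], {}
    with h5py.File(path, "r") as fh:
        meta = {k: fh.attrs[k] for k in fh.attrs}
        for pid in sorted(fh.keys()):
            grp = fh[pid]
            channels = {name: grp["channels"][name][()] for name in grp["channels"]}
            ev = pd.DataFrame(
                {
                    "onset": grp["events"]["onset"][()],
                    "duration": grp["events"]["duration"][()],
                    "stimulus_id": grp["events"]["stimulus_id"][()],
                    "task": [t.decode() for t in grp["events"]["task"][()]],
                    "block": grp["events"]["block"][()],
                }
            )
            sessions.append(
                RecordingSession(
                    participant_id=pid,
                    fs=float(grp.attrs["fs"]),
                    channels=channels,
                    events=_events_from_frame(ev),
                )
            )
    return sessions, meta


def write_sessions_csv(outdir, sessions, config_hash: str, seed: int):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        df = pd.DataFrame(s.channels)
        sig_path = outdir / f"{s.participant_id}_signals.csv"
        with open(sig_path, "w") as fh:
            fh.write(f"# config_hash={config_hash} seed={seed} fs={s.fs}\n")
            df.to_csv(fh, index=False)
        ev_path = outdir / f"{s.participant_id}_events.tsv"
        with open(ev_path, "w") as fh:
            fh.write(f"# config_hash={config_hash} seed={seed}\n")
            _events_frame(s.events).to_csv(fh, sep="\t", index=False)


def read_sessions_csv(outdir):
    outdir = Path(outdir)
    sessions = []
    meta = {}
    for sig_path in sorted(outdir.glob("*_signals.csv")):
        pid = sig_path.name.replace("_signals.csv", "")
        with open(sig_path) as fh:
            header = fh.readline()
        meta = dict(
            kv.split("=") for kv in header.lstrip("# ").strip().split(" ") if "=" in kv
        )
        df = pd.read_csv(sig_path, comment="#")
        ev = pd.read_csv(outdir / f"{pid}_events.tsv", sep="\t", comment="#")
        sessions.append(
            RecordingSession(
                participant_id=pid,
                fs=float(meta["fs"]),
                channels={c: df[c].to_numpy(float) for c in df.columns},
                events=_events_from_frame(ev),
            )
        )
    return sessions, meta


# ---------------------------------------------------------------------------
# tabular I/O with provenance headers


def write_table(df: pd.DataFrame, path, config_hash: str, seed: int, sep="\t"):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed} version={_pkg_version}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep="\t") -> tuple[pd.DataFrame, dict]:
    with open(path) as fh:
        first = fh.readline()
    prov = {}
    if first.startswith("#"):
        prov = dict(
            kv.split("=") for kv in first.lstrip("# ").strip().split(" ") if "=" in kv
        )
    return pd.read_csv(path, sep=sep, comment="#"), prov


# ---------------------------------------------------------------------------
# continuous per-trial features container


def write_trial_features(path, per_session: dict, config_hash: str, seed: int):
    """``per_session``: participant -> {measure: [(event, series), ...]}."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config_hash
        fh.attrs["seed"] = seed
        for pid, by_measure in per_session.items():
            grp = fh.create_group(pid)
            for measure, pairs in by_measure.items():
                for k, (ev, series) in enumerate(pairs):
                    ds = grp.create_dataset(f"{measure}/trial{k:04d}", data=series)
                    ds.attrs["stimulus_id"] = ev.stimulus_id
                    ds.attrs["task"] = ev.task
                    ds.attrs["block"] = ev.block
                    ds.attrs["onset"] = ev.onset
                    ds.attrs["duration"] = ev.duration


def read_trial_features(path):
    out = {}
    with h5py.File(path, "r") as fh:
        meta = {k: fh.attrs[k] for k in fh.attrs}
        for pid in sorted(fh.keys()):
            by_measure = {}
            for measure in fh[pid]:
                pairs = []
                for name in sorted(fh[pid][measure]):
                    ds = fh[pid][measure][name]
                    ev = TrialEvent(
                        onset=float(ds.attrs["onset"]),
                        duration=float(ds.attrs["duration"]),
                        stimulus_id=int(ds.attrs["stimulus_id"]),
                        task=str(ds.attrs["task"]),
                        block=int(ds.attrs["block"]),
                    )
                    pairs.append((ev, ds[()]))
                by_measure[measure] = pairs
            out[pid] = by_measure
    return out, meta


# ---------------------------------------------------------------------------
# pipeline stages


def stage_simulate(config: RunConfig, outdir: Path) -> Cohort:
    cohort = simulate_cohort(config.generator)
    _log("simulate", f"{len(cohort.sessions)} sessions", "cohort rendered")
    if config.signal_format == "hdf5":
        write_sessions_hdf5(
            outdir / "sessions.h5", cohort.sessions, config.config_hash,
            config.generator.seed,
        )
    else:
        write_sessions_csv(
            outdir / "sessions", cohort.sessions, config.config_hash,
            config.generator.seed,
        )
    write_table(
        cohort.truth.intensity, outdir / "intensity.tsv", config.config_hash,
        config.generator.seed,
    )
    write_table(
        cohort.truth.trial_means, outdir / "ground_truth.tsv", config.config_hash,
        config.generator.seed,
    )
    return cohort


def stage_preprocess(config: RunConfig, sessions, outdir: Path) -> dict:
    per_session = {}
    for s in sessions:
        try:
            per_session[s.participant_id] = feat_mod.extract_continuous_features(
                s, grid_fs=config.grid_fs
            )
        except MusicPhysError as exc:
            raise PipelineStageError("preprocess", s.participant_id, exc) from exc
        _log("preprocess", s.participant_id, "continuous features extracted")
    write_trial_features(
        outdir / "trial_features.h5", per_session, config.config_hash,
        config.generator.seed,
    )
    return per_session


def stage_features(config: RunConfig, per_session: dict, intensity, outdir: Path):
    rows = []
    for pid, by_measure in per_session.items():
        try:
            standardized, _ = feat_mod.standardize_within_participant(by_measure)
        except MusicPhysError as exc:
            raise PipelineStageError("features", pid, exc) from exc
        for measure, pairs in standardized.items():
            for ev, series in pairs:
                v1, v2 = feat_mod.interval_means(series)
                for interval, value in ((1, v1), (2, v2)):
                    rows.append(
                        {
                            "participant": pid,
                            "stimulus": ev.stimulus_id,
                            "task": ev.task,
                            "interval": interval,
                            "measure": measure,
                            "value": value,
                        }
                    )
    stimuli = stim_mod.load_stimulus_table()
    obs = feat_mod.build_observation_table(
        pd.DataFrame(rows), stimuli, intensity=intensity
    )
    write_table(obs, outdir / "observations.tsv", config.config_hash,
                config.generator.seed)
    _log("features", f"{len(obs)} rows", "observation table built")
    return obs


def stage_fit(config: RunConfig, obs: pd.DataFrame, outdir: Path) -> dict:
    fits = []
    for measure in config.measures:
        for dim in config.dimensions:
            try:
                fits.append(
                    stats_mod.fit_measure_model(obs, stats_mod.ModelSpec(measure, dim))
                )
            except MusicPhysError as exc:
                raise PipelineStageError("fit", f"{measure}~{dim}", exc) from exc
            _log("fit", f"{measure}~{dim}", "model fitted")
        if config.fit_intensity:
            try:
                fits.append(stats_mod.fit_intensity_model(obs, measure))
            except MusicPhysError as exc:
                raise PipelineStageError("fit", f"{measure}~intensity", exc) from exc
    report = stats_mod.model_report(fits)
    report["provenance"] = {
        "config_hash": config.config_hash,
        "seed": config.generator.seed,
        "version": _pkg_version,
    }
    with open(outdir / "model_reports.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> preprocess -> features -> fit, with a provenance manifest.

    Returns a bundle with the cohort, observation table, report and paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    cohort = stage_simulate(config, outdir)
    per_session = stage_preprocess(config, cohort.sessions, outdir)
    obs = stage_features(config, per_session, cohort.truth.intensity, outdir)
    report = stage_fit(config, obs, outdir)

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.generator.seed,
        "version": _pkg_version,
        "n_sessions": len(cohort.sessions),
        "n_observations": int(len(obs)),
        "n_models": len(report["models"]),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    _log("pipeline", str(outdir), "run complete")
    return {
        "cohort": cohort,
        "observations": obs,
        "report": report,
        "manifest": manifest,
        "outdir": outdir,
    }


# ---------------------------------------------------------------------------
# validation


def validate_inputs(
    sessions_path=None, observations_path=None, stimulus_path=None
) -> list:
    """Non-throwing integrity checks; returns a list of findings.

    Each finding is ``{"stage", "entity", "message"}``.  Checks the session
    container schema (channel lengths, event bounds/overlap), stimulus rating
    ranges, and the observation/stimulus join.
    """
    findings = []

    def add(stage, entity, message):
        findings.append({"stage": stage, "entity": str(entity), "message": message})

    stimuli = None
    try:
        stimuli = stim_mod.load_stimulus_table(stimulus_path)
    except MusicPhysError as exc:
        add("stimuli", stimulus_path or "packaged", str(exc))

    if sessions_path is not None:
        try:
            p = Path(sessions_path)
            if p.is_dir():
                sessions, _ = read_sessions_csv(p)
            else:
                sessions, _ = read_sessions_hdf5(p)
        except Exception as exc:  # corrupt container must not throw
            add("container", sessions_path, f"unreadable container: {exc}")
            sessions = []
        for s in sessions:
            lengths = {name: len(x) for name, x in s.channels.items()}
            if len(set(lengths.values())) > 1:
                add("container", s.participant_id, f"unequal channel lengths {lengths}")
            n = s.n_samples
            ordered = sorted(s.events, key=lambda e: e.onset)
            for ev in ordered:
                if ev.onset < 0 or (ev.onset + ev.duration) * s.fs > n:
                    add("events", s.participant_id,
                        f"event at {ev.onset}s exceeds recording")
            for a, b in zip(ordered, ordered[1:]):
                if a.onset + a.duration > b.onset:
                    add("events", s.participant_id,
                        f"events at {a.onset}s and {b.onset}s overlap")
            counts = pd.Series(
                [(e.stimulus_id, e.task) for e in s.events]
            ).value_counts()
            if (counts > 1).any():
                add("events", s.participant_id, "duplicate (stimulus, task) trials")

    if stimuli is not None:
        for s in stimuli:
            for dim in ("valence", "energy", "tension"):
                v = s.rating(dim)
                if not 1.0 <= v <= 9.0:
                    add("stimuli", s.index_ref, f"{dim} rating {v} outside [1, 9]")

    if observations_path is not None:
        try:
            obs, _ = read_table(observations_path)
        except Exception as exc:
            add("observations", observations_path, f"unreadable table: {exc}")
            obs = None
        if obs is not None:
            missing = set(feat_mod.OBSERVATION_COLUMNS) - set(obs.columns)
            if missing:
                add("observations", observations_path, f"missing columns {sorted(missing)}")
            elif stimuli is not None:
                known = {s.index_ref for s in stimuli}
                orphans = sorted(set(obs["stimulus"]) - known)
                if orphans:
                    add("observations", observations_path,
                        f"stimuli absent from stimulus table: {orphans}")
                if not np.isfinite(obs["value"]).all():
                    add("observations", observations_path, "non-finite values")
    return findings
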