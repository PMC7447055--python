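"""Seeded synthetic cohort generator with known ground-truth effects.

Emulates the study design: every participant hears every excerpt twice, once
per task (assess the emotion the music expresses vs the intensity of the
emotion it induces), trials of ~30 s grouped in four blocks each starting with
a 30 s rest, five channels sampled at 500 Hz (zygomaticus EMG, corrugator EMG,
blood-volume pulse, respiration belt, skin conductance).

The latent structure is additive on a dimensionless per-trial scale:

    z = level effects (stimulus category) + task shift + item offset
        + interval offset + participant offset + residual

and is rendered into channel units by a per-measure affine map (e.g. heart
rate = 70 + 3*z beats/min).  The channel-level generative models (noise
spectra, pulse shapes, tonic drift) are artifact choices exposed in the
config, chosen so every downstream conditioning stage has something
nontrivial to remove.  Identical (config, seed) yields identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import stimuli as stim_mod
from .errors import ConfigError, DomainError
from .sigproc import bateman_irf

MEASURES = ("EMGZ", "EMGC", "SC", "HR", "RR")
TASKS = ("felt", "perceived")

#: channel name in the session container for each derived measure
CHANNEL_OF = {
    "EMGZ": "emg_zyg",
    "EMGC": "emg_corr",
    "SC": "sc",
    "HR": "bvp",
    "RR": "respiration",
}

#: mean of |analytic signal| for unit-RMS Gaussian noise (Rayleigh mean).
EMG_ENVELOPE_GAIN = float(np.sqrt(np.pi / 2.0))

HR_BOUNDS = (40.0, 180.0)  # beats/min
RR_BOUNDS = (6.0, 30.0)  # breaths/min


def _default_level_effects():
    # Latent shifts per dimension level relative to the model reference
    # levels (valence: neutral; energy/tension: high), magnitudes anchored to
    # the effect sizes reported for this design.
    return {
        "EMGZ": {"valence": {"negative": 0.00, "positive": 0.19},
                 "energy": {"low": -0.33, "medium": -0.17}},
        "EMGC": {"valence": {"negative": 0.03, "positive": -0.09},
                 "energy": {"low": 0.19, "medium": 0.08}},
        "SC": {"valence": {"negative": 0.02, "positive": 0.12},
               "energy": {"low": -0.26, "medium": -0.12}},
        "HR": {"valence": {"negative": 0.02, "positive": 0.06},
               "energy": {"low": -0.23, "medium": -0.07}},
        "RR": {"valence": {"negative": -0.01, "positive": 0.05},
               "energy": {"low": -0.17, "medium": -0.05}},
    }


@dataclass
class GeneratorConfig:
    """Design, effect structure and channel-rendering parameters."""

    n_participants: int = 40
    n_stimuli: int | None = None  # None = all packaged stimuli
    sampling_rate: float = 500.0
    trial_duration: float = 30.0
    rest_duration: float = 30.0
    prompt_duration: float = 4.0  # task prompt before music onset
    rating_duration: float = 2.0  # rating screen after music offset
    n_blocks: int = 4

    # channel-unit anchors and units per latent SD
    baselines: dict = field(default_factory=lambda: {
        "EMGZ": 20.0, "EMGC": 15.0, "SC": 0.4, "HR": 70.0, "RR": 14.0})
    scales: dict = field(default_factory=lambda: {
        "EMGZ": 6.0, "EMGC": 4.5, "SC": 0.12, "HR": 3.0, "RR": 1.5})

    # latent effect structure (dimensionless)
    task_effect: dict = field(default_factory=lambda: {m: 0.2 for m in MEASURES})
    level_effects: dict = field(default_factory=_default_level_effects)
    sd_item: float = 0.07
    sd_interval: float = 0.1
    sd_participant: float = 0.15
    sd_residual: float = 0.8

    # channel nuisance parameters
    emg_band: tuple = (20.0, 249.0)
    bvp_jitter_sd: float = 0.02  # fractional inter-beat jitter
    bvp_noise_sd: float = 0.05
    bvp_drift_amp: float = 0.3
    bvp_drift_freq: float = 0.02  # Hz, below the 0.05 Hz high-pass
    resp_noise_sd: float = 0.05
    resp_drift_amp: float = 0.3
    resp_drift_freq: float = 0.01
    sc_event_rate: float = 8.0  # driver events per minute
    sc_tau1: float = 2.0
    sc_tau2: float = 0.75
    sc_tonic_level: float = 2.0  # microsiemens
    sc_tonic_drift_amp: float = 0.15
    sc_tonic_drift_freq: float = 0.005
    sc_noise_sd: float = 0.005

    # felt-intensity rating model: linear in the stimulus energy rating plus
    # item-, participant- and trial-level noise, mapped to the 1-5 scale
    intensity_slope: float = 0.25
    intensity_item_sd: float = 0.9
    intensity_participant_sd: float = 0.5
    intensity_trial_sd: float = 0.6

    seed: int = 0

    def __post_init__(self):
        for name in ("sd_item", "sd_interval", "sd_participant", "sd_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sampling_rate <= 2 * self.emg_band[1]:
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} cannot represent the "
                f"EMG band edge {self.emg_band[1]} Hz"
            )
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ConfigError("need at least one participant and one block")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["emg_band"] = list(d["emg_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "emg_band" in d:
            d["emg_band"] = tuple(d["emg_band"])
        return cls(**d)


@dataclass(frozen=True)
class TrialEvent:
    onset: float  # s, music onset
    duration: float  # s
    stimulus_id: int
    task: str
    block: int


@dataclass
class RecordingSession:
    participant_id: str
    fs: float
    channels: dict  # channel name -> np.ndarray
    events: list

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class GroundTruth:
    """Realized latent structure of a simulated cohort."""

    trial_means: pd.DataFrame  # participant, stimulus, task, block, interval, measure, latent
    item_offsets: dict  # measure -> {stimulus_id: offset}
    interval_offsets: dict  # measure -> {1: offset, 2: offset}
    participant_offsets: dict  # measure -> {participant_id: offset}
    intensity: pd.DataFrame  # participant, stimulus, rating (felt task)
    config: GeneratorConfig


@dataclass
class Cohort:
    sessions: list
    truth: GroundTruth


# ---------------------------------------------------------------------------
# channel-level simulators


def simulate_emg(latent_amplitude, fs, seed=None, band=(20.0, 249.0)):
    """Raw EMG: band-limited unit-RMS Gaussian noise modulated by an envelope.

    The extracted envelope of the output tracks ``latent_amplitude`` times
    :data:`EMG_ENVELOPE_GAIN` (the Rayleigh-mean calibration constant).
    """
    amp = np.asarray(latent_amplitude, dtype=float)
    if np.any(amp < 0):
        raise DomainError("latent EMG amplitude must be non-negative")
    if fs <= 2 * band[1]:
        raise ConfigError(f"fs={fs} cannot represent band edge {band[1]} Hz")
    if not np.any(amp > 0):
        return np.zeros_like(amp)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(amp.size)
    nyq = fs / 2.0
    sos = sps.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    carrier = sps.sosfilt(sos, white)
    carrier /= np.std(carrier)
    return amp * carrier


def _rate_profile(profile, fs, bounds, name):
    prof = np.atleast_1d(np.asarray(profile, dtype=float))
    lo, hi = bounds
    if np.any(prof < lo) or np.any(prof > hi):
        raise DomainError(
            f"{name} profile outside physiological bounds [{lo}, {hi}]"
        )
    return prof


def simulate_bvp(
    hr_profile,
    fs,
    seed=None,
    duration=None,
    pulse_width=0.30,
    jitter_sd=0.02,
    noise_sd=0.05,
    drift_amp=0.3,
    drift_freq=0.02,
):
    """Blood-volume pulse: a train of smooth unimodal pulses.

    ``hr_profile`` is beats/min, scalar or a series sampled at ``fs``.
    Inter-beat intervals are 60/rate with optional fractional jitter; slow
    sinusoidal drift and white noise exercise the downstream conditioning.
    """
    prof = _rate_profile(hr_profile, fs, HR_BOUNDS, "heart-rate")
    if prof.size == 1:
        if duration is None:
            raise ConfigError("scalar rate profile needs an explicit duration")
        n = int(round(duration * fs))
        prof = np.full(n, prof[0])
    n = prof.size
    rng = np.random.default_rng(seed)

    beat_times = []
    t = 0.0
    horizon = n / fs
    while t < horizon:
        beat_times.append(t)
        rate = prof[min(int(t * fs), n - 1)]
        ibi = 60.0 / rate
        if jitter_sd > 0:
            ibi *= max(0.5, 1.0 + jitter_sd * rng.standard_normal())
        t += ibi

    x = np.zeros(n)
    klen = int(round(pulse_width * fs))
    kernel = np.sin(np.pi * np.arange(klen) / klen) ** 2
    for bt in beat_times:
        i = int(round(bt * fs))
        stop = min(n, i + klen)
        x[i:stop] += kernel[: stop - i]
    tgrid = np.arange(n) / fs
    if drift_amp > 0:
        x += drift_amp * np.sin(2 * np.pi * drift_freq * tgrid)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return x


def simulate_respiration(
    rr_profile,
    fs,
    seed=None,
    duration=None,
    noise_sd=0.05,
    drift_amp=0.3,
    drift_freq=0.01,
):
    """Respiration belt: sinusoid with instantaneous frequency rate/60.

    ``rr_profile`` is breaths/min, scalar or a series sampled at ``fs``.
    One local maximum per breath cycle, so peak spacing is 60/rate.
    """
    prof = _rate_profile(rr_profile, fs, RR_BOUNDS, "respiration-rate")
    if prof.size == 1:
        if duration is None:
            raise ConfigError("scalar rate profile needs an explicit duration")
        n = int(round(duration * fs))
        prof = np.full(n, prof[0])
    n = prof.size
    rng = np.random.default_rng(seed)
    phase = np.cumsum(prof / 60.0) / fs
    x = -np.cos(2 * np.pi * phase)
    tgrid = np.arange(n) / fs
    if drift_amp > 0:
        x += drift_amp * np.sin(2 * np.pi * drift_freq * tgrid)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return x


def sc_from_events(event_times, event_amps, n, fs, tau1, tau2, tonic=0.0):
    """Skin conductance from explicit driver impulses (deterministic).

    Each event of amplitude ``a`` contributes ``a * bateman_irf(t - t_i)``;
    ``tonic`` may be a scalar or a series of length ``n``.
    """
    impulses = np.zeros(n)
    for et, a in zip(event_times, event_amps):
        i = int(round(et * fs))
        if 0 <= i < n:
            impulses[i] += a
    kernel = bateman_irf(np.arange(n) / fs, tau1, tau2)
    phasic = sps.fftconvolve(impulses, kernel)[:n]
    return np.asarray(tonic) + phasic, impulses


def simulate_sc(
    driver_rate,
    fs,
    seed=None,
    duration=None,
    amp_scale=1.0,
    tau1=2.0,
    tau2=0.75,
    tonic_level=2.0,
    tonic_drift_amp=0.15,
    tonic_drift_freq=0.005,
    noise_sd=0.005,
):
    """Skin conductance: sparse Poisson driver convolved with a Bateman kernel
    riding on a slowly drifting tonic level.

    ``driver_rate`` is events/min (scalar or series at ``fs``); ``amp_scale``
    sets the mean event amplitude (scalar or series, evaluated at the event
    time).  Returns ``(signal, truth)`` where ``truth`` carries the exact
    event times/amplitudes and the tonic series for round-trip tests.
    """
    rate = np.atleast_1d(np.asarray(driver_rate, dtype=float))
    if np.any(rate < 0):
        raise DomainError("driver rate must be non-negative")
    if rate.size == 1:
        if duration is None:
            raise ConfigError("scalar driver rate needs an explicit duration")
        n = int(round(duration * fs))
        rate = np.full(n, rate[0])
    n = rate.size
    rng = np.random.default_rng(seed)

    # inhomogeneous Poisson by thinning
    rmax = float(rate.max())
    event_times, event_amps = [], []
    if rmax > 0:
        t = 0.0
        horizon = n / fs
        scale_arr = np.atleast_1d(np.asarray(amp_scale, dtype=float))
        while True:
            t += rng.exponential(60.0 / rmax)
            if t >= horizon:
                break
            i = int(t * fs)
            if rng.uniform() * rmax <= rate[i]:
                mean_amp = scale_arr[i] if scale_arr.size > 1 else scale_arr[0]
                if mean_amp > 0:
                    event_times.append(t)
                    event_amps.append(rng.gamma(4.0, mean_amp / 4.0))

    tgrid = np.arange(n) / fs
    tonic = tonic_level + tonic_drift_amp * np.sin(2 * np.pi * tonic_drift_freq * tgrid)
    x, impulses = sc_from_events(event_times, event_amps, n, fs, tau1, tau2, tonic)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    truth = {
        "event_times": np.array(event_times),
        "event_amps": np.array(event_amps),
        "tonic": tonic,
        "driver": impulses,
    }
    return x, truth


# ---------------------------------------------------------------------------
# design schedule


def build_schedule(config: GeneratorConfig, stimulus_ids, rng) -> list:
    """Randomized block schedule: every stimulus once per task, tasks balanced
    within blocks, each block opening with a rest period."""
    n_stim = len(stimulus_ids)
    n_trials = 2 * n_stim
    if n_trials % config.n_blocks != 0:
        raise ConfigError(
            f"{n_trials} trials do not divide into {config.n_blocks} blocks"
        )
    per_block = n_trials // config.n_blocks
    if per_block % 2 != 0:
        raise ConfigError("trials per block must be even to balance tasks")

    felt = [(s, "felt") for s in stimulus_ids]
    perceived = [(s, "perceived") for s in stimulus_ids]
    rng.shuffle(felt)
    rng.shuffle(perceived)

    events = []
    t = 0.0
    half = per_block // 2
    for b in range(config.n_blocks):
        t += config.rest_duration
        block_trials = felt[b * half:(b + 1) * half] + perceived[b * half:(b + 1) * half]
        rng.shuffle(block_trials)
        for stim_id, task in block_trials:
            t += config.prompt_duration
            events.append(
                TrialEvent(
                    onset=t,
                    duration=config.trial_duration,
                    stimulus_id=int(stim_id),
                    task=task,
                    block=b + 1,
                )
            )
            t += config.trial_duration + config.rating_duration
    return events, t


# ---------------------------------------------------------------------------
# latent effect structure


def _select_stimuli(config: GeneratorConfig, stimuli=None):
    if stimuli is None:
        stimuli = stim_mod.load_stimulus_table()
    if config.n_stimuli is not None:
        if config.n_stimuli > len(stimuli):
            raise ConfigError(
                f"n_stimuli={config.n_stimuli} exceeds table size {len(stimuli)}"
            )
        stimuli = stimuli[: config.n_stimuli]
    return stimuli


def _level_shift(config: GeneratorConfig, measure: str, levels: dict) -> float:
    total = 0.0
    per_measure = config.level_effects.get(measure, {})
    for dim, lv in levels.items():
        total += per_measure.get(dim, {}).get(lv, 0.0)
    return total


def draw_latent_structure(config: GeneratorConfig, stimuli, seed_seq) -> GroundTruth:
    """Draw all random offsets and per-trial latent means for a cohort."""
    rng = np.random.default_rng(seed_seq)
    participant_ids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    levels = {s.index_ref: s.levels() for s in stimuli}
    energy = {s.index_ref: s.energy for s in stimuli}
    mean_energy = float(np.mean(list(energy.values())))

    item_off = {
        m: {s.index_ref: rng.normal(0, config.sd_item) for s in stimuli}
        for m in MEASURES
    }
    interval_off = {
        m: {1: rng.normal(0, config.sd_interval), 2: rng.normal(0, config.sd_interval)}
        for m in MEASURES
    }
    part_off = {
        m: {p: rng.normal(0, config.sd_participant) for p in participant_ids}
        for m in MEASURES
    }
    intensity_item = {
        s.index_ref: rng.normal(0, config.intensity_item_sd) for s in stimuli
    }
    intensity_part = {
        p: rng.normal(0, config.intensity_participant_sd) for p in participant_ids
    }

    rows = []
    intensity_rows = []
    for p in participant_ids:
        for s in stimuli:
            sid = s.index_ref
            for task in TASKS:
                for interval in (1, 2):
                    for m in MEASURES:
                        z = (
                            _level_shift(config, m, levels[sid])
                            + (config.task_effect.get(m, 0.0) if task == "perceived" else 0.0)
                            + item_off[m][sid]
                            + interval_off[m][interval]
                            + part_off[m][p]
                            + rng.normal(0, config.sd_residual)
                        )
                        rows.append((p, sid, task, interval, m, z))
            latent_int = (
                3.0
                + config.intensity_slope * (energy[sid] - mean_energy)
                + intensity_item[sid]
                + intensity_part[p]
                + rng.normal(0, config.intensity_trial_sd)
            )
            rating = int(np.clip(np.rint(latent_int), 1, 5))
            intensity_rows.append((p, sid, rating))

    trial_means = pd.DataFrame(
        rows,
        columns=["participant", "stimulus", "task", "interval", "measure", "latent"],
    )
    intensity = pd.DataFrame(
        intensity_rows, columns=["participant", "stimulus", "rating"]
    )
    return GroundTruth(
        trial_means=trial_means,
        item_offsets=item_off,
        interval_offsets=interval_off,
        participant_offsets=part_off,
        intensity=intensity,
        config=config,
    )


# ---------------------------------------------------------------------------
# full cohort


def _render_session(config, participant_id, events, total_dur, latents, child_seq):
    """Render one participant's five raw channels from per-trial latents.

    ``latents`` maps (stimulus, task, interval, measure) -> latent z.
    """
    fs = config.sampling_rate
    n = int(round(total_dur * fs))
    seeds = child_seq.spawn(5)

    def param_profile(measure, clip_lo=None):
        base = config.baselines[measure]
        scale = config.scales[measure]
        prof = np.full(n, base)
        for ev in events:
            i0 = int(round(ev.onset * fs))
            i1 = int(round((ev.onset + ev.duration) * fs))
            mid = i0 + (i1 - i0 + 1) // 2  # middle sample joins the first half
            z1 = latents[(ev.stimulus_id, ev.task, 1, measure)]
            z2 = latents[(ev.stimulus_id, ev.task, 2, measure)]
            prof[i0:mid] = base + scale * z1
            prof[mid:i1] = base + scale * z2
        if clip_lo is not None:
            np.clip(prof, clip_lo, None, out=prof)
        return prof

    channels = {}
    channels["emg_zyg"] = simulate_emg(
        param_profile("EMGZ", clip_lo=0.05 * config.baselines["EMGZ"]),
        fs, seed=seeds[0], band=config.emg_band,
    )
    channels["emg_corr"] = simulate_emg(
        param_profile("EMGC", clip_lo=0.05 * config.baselines["EMGC"]),
        fs, seed=seeds[1], band=config.emg_band,
    )
    channels["bvp"] = simulate_bvp(
        np.clip(param_profile("HR"), *HR_BOUNDS), fs, seed=seeds[2],
        jitter_sd=config.bvp_jitter_sd, noise_sd=config.bvp_noise_sd,
        drift_amp=config.bvp_drift_amp, drift_freq=config.bvp_drift_freq,
    )
    channels["respiration"] = simulate_respiration(
        np.clip(param_profile("RR"), *RR_BOUNDS), fs, seed=seeds[3],
        noise_sd=config.resp_noise_sd, drift_amp=config.resp_drift_amp,
        drift_freq=config.resp_drift_freq,
    )
    sc_sig, _ = simulate_sc(
        config.sc_event_rate, fs, seed=seeds[4],
        duration=total_dur,
        amp_scale=param_profile("SC", clip_lo=0.02),
        tau1=config.sc_tau1, tau2=config.sc_tau2,
        tonic_level=config.sc_tonic_level,
        tonic_drift_amp=config.sc_tonic_drift_amp,
        tonic_drift_freq=config.sc_tonic_drift_freq,
        noise_sd=config.sc_noise_sd,
    )
    channels["sc"] = sc_sig[:n]
    return RecordingSession(
        participant_id=participant_id, fs=fs, channels=channels, events=events
    )


def simulate_cohort(config: GeneratorConfig, stimuli=None, render: bool = True) -> Cohort:
    """Simulate a full cohort.

    With ``render=True`` every participant's raw channels are synthesized;
    with ``render=False`` only the latent structure (ground truth) is drawn,
    which is orders of magnitude faster and sufficient for statistical
    simulation studies.
    """
    stimuli = _select_stimuli(config, stimuli)
    root = np.random.SeedSequence(config.seed)
    latent_seq, schedule_seq, render_seq = root.spawn(3)
    truth = draw_latent_structure(config, stimuli, latent_seq)

    sessions = []
    if render:
        stim_ids = [s.index_ref for s in stimuli]
        sched_rngs = np.random.default_rng(schedule_seq).spawn(config.n_participants)
        render_children = render_seq.spawn(config.n_participants)
        tm = truth.trial_means
        for i, p in enumerate(sorted(tm["participant"].unique())):
            sub = tm[tm["participant"] == p]
            latents = {
                (r.stimulus, r.task, r.interval, r.measure): r.latent
                for r in sub.itertuples()
            }
            events, total_dur = build_schedule(config, stim_ids, sched_rngs[i])
            sessions.append(
                _render_session(config, p, events, total_dur, latents, render_children[i])
            )
    return Cohort(sessions=sessions, truth=truth)


def simulate_observations(config: GeneratorConfig, stimuli=None) -> pd.DataFrame:
    """Observation table drawn directly from the latent model (no signals).

    Mirrors the table the feature stage would produce, with dimension levels
    and z-scored felt-intensity ratings attached.  The latent scale is the
    standardized scale by construction, so values are only centered within
    participant x measure (as the within-participant normalization would do);
    injected effects therefore keep their configured magnitude exactly, which
    is what parameter-recovery studies need.  Used for statistical simulation
    studies where rendering raw channels would add nothing.
    """
    stimuli = _select_stimuli(config, stimuli)
    root = np.random.SeedSequence(config.seed)
    truth = draw_latent_structure(config, stimuli, root.spawn(1)[0])
    df = truth.trial_means.rename(columns={"latent": "value"}).copy()

    grp = df.groupby(["participant", "measure"])["value"]
    df["value"] = df["value"] - grp.transform("mean")

    frame = stim_mod.stimulus_frame(stimuli).reset_index(drop=True)
    df = df.merge(
        frame[["stimulus_id", "valence_level", "energy_level", "tension_level"]],
        left_on="stimulus", right_on="stimulus_id", how="left",
    ).drop(columns="stimulus_id")

    inten = truth.intensity.copy()
    z = inten.groupby("participant")["rating"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=0)
    )
    inten["intensity_z"] = z
    df = df.merge(
        inten[["participant", "stimulus", "intensity_z"]],
        on=["participant", "stimulus"], how="left",
    )
    df.loc[df["task"] != "felt", "intensity_z"] = np.nan
    return df
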