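"""Continuous-signal transformations for the physiological channels.

Four channel families are handled:

* facial EMG (zygomaticus, corrugator): band-pass 20-249 Hz, magnitude of the
  analytic (Hilbert) signal, moving-average smoothing -> amplitude envelope;
* pulsatile channels (blood-volume pulse, respiration belt): zero-phase
  band conditioning (high-pass 0.05 Hz, low-pass 40 Hz), local-maximum peak
  detection, rate = reciprocal of adjacent peak intervals, linear resampling
  of the rate tachogram onto a regular grid;
* skin conductance: tonic baseline (sliding-percentile), non-negative
  regularized deconvolution of the remainder against a bi-exponential
  (Bateman) impulse response -> driver and phasic component.

All filters are applied forward-backward (zero phase) so peak timings are not
shifted.  Every operation is deterministic for fixed inputs and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len
from scipy.ndimage import percentile_filter, uniform_filter1d
from scipy.optimize import nnls

from .errors import ConfigError, DomainError, InsufficientDataError, SolverError

# ---------------------------------------------------------------------------
# defaults

EMG_BAND = (20.0, 249.0)  # Hz
EMG_SMOOTH_MS = 100.0  # moving-average window for the envelope
PULSE_HIGHPASS = 0.05  # Hz, drift removal
PULSE_LOWPASS = 40.0  # Hz, movement/line-noise removal
FILTER_ORDER = 4  # Butterworth, applied zero-phase

#: per-channel refractory intervals for peak detection (s):
#: 0.33 s for BVP caps heart rate at ~180 beats/min, 2 s for respiration
#: caps breathing at 30 breaths/min.
MIN_INTERVAL = {"bvp": 0.33, "respiration": 2.0}
PROMINENCE_SD = 0.5  # prominence floor in units of signal SD
RATE_GRID_FS = 10.0  # Hz, regular grid for resampled rate series

SC_TAU1 = 2.0  # s, decay time constant of the Bateman kernel
SC_TAU2 = 0.75  # s, rise time constant
SC_WORKING_FS = 10.0  # Hz, grid on which the deconvolution is solved
SC_TONIC_WINDOW = 10.0  # s, sliding window of the percentile baseline
SC_TONIC_PERCENTILE = 10.0
SC_RIDGE = 1e-3  # Tikhonov weight of the non-negative deconvolution


# ---------------------------------------------------------------------------
# Bateman impulse response


def bateman_irf(t, tau1: float, tau2: float, normalize: bool = False):
    """Bi-exponential impulse response exp(-t/tau1) - exp(-t/tau2).

    ``tau1`` is the (slow) decay constant and ``tau2`` the (fast) rise
    constant; the kernel is zero at t = 0, peaks at
    ``tau1*tau2/(tau1-tau2) * ln(tau1/tau2)`` and decays back to zero.
    With ``normalize=True`` the peak is scaled to one.
    """
    if not tau1 > tau2 > 0:
        raise DomainError(f"need tau1 > tau2 > 0, got tau1={tau1}, tau2={tau2}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("bateman_irf defined for t >= 0")
    out = np.exp(-t / tau1) - np.exp(-t / tau2)
    if normalize:
        t_peak = bateman_peak_time(tau1, tau2)
        out = out / (np.exp(-t_peak / tau1) - np.exp(-t_peak / tau2))
    return out


def bateman_peak_time(tau1: float, tau2: float) -> float:
    """Argmax of the Bateman kernel (closed form)."""
    if not tau1 > tau2 > 0:
        raise DomainError(f"need tau1 > tau2 > 0, got tau1={tau1}, tau2={tau2}")
    return tau1 * tau2 / (tau1 - tau2) * np.log(tau1 / tau2)


# ---------------------------------------------------------------------------
# EMG envelope


def _band_sos(band, fs, order=FILTER_ORDER):
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ConfigError(f"band {band} infeasible at fs={fs} (Nyquist {nyq})")
    return sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def emg_envelope(x, fs, band=EMG_BAND, smooth_ms=EMG_SMOOTH_MS, order=FILTER_ORDER):
    """Amplitude envelope of a raw EMG trace.

    Band-pass -> |analytic signal| -> centered moving average.  The result is
    non-negative and the same length as the input.  For a pure in-band tone
    the envelope equals its amplitude (away from the filter warm-up edges).
    """
    x = np.asarray(x, dtype=float)
    sos = _band_sos(band, fs, order)
    if x.size <= 3 * (2 * order + 1):
        raise ConfigError("signal shorter than filter warm-up")
    filtered = sps.sosfiltfilt(sos, x)
    n = filtered.size
    analytic = sps.hilbert(filtered, N=next_fast_len(n))[:n]
    env = np.abs(analytic)
    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    if win > 1:
        env = uniform_filter1d(env, size=win, mode="nearest")
    return env


# ---------------------------------------------------------------------------
# pulsatile conditioning and rate estimation


def condition_pulsatile(
    x, fs, highpass=PULSE_HIGHPASS, lowpass=PULSE_LOWPASS, order=FILTER_ORDER
):
    """Drift and noise removal for BVP / respiration before peak detection.

    High-pass (default 0.05 Hz) and low-pass (default 40 Hz) Butterworth
    stages applied zero-phase, so peak timings are preserved.
    """
    if fs <= 2 * lowpass:
        raise ConfigError(f"fs={fs} too low for low-pass at {lowpass} Hz")
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    sos_hp = sps.butter(order, highpass / nyq, btype="highpass", output="sos")
    sos_lp = sps.butter(order, lowpass / nyq, btype="lowpass", output="sos")
    # the high-pass settles over ~1/highpass seconds; pad accordingly
    padlen = int(min(x.size - 1, 3 * fs / highpass))
    return sps.sosfiltfilt(sos_lp, sps.sosfiltfilt(sos_hp, x, padlen=padlen))


def detect_peaks(x, fs, min_interval: float, min_prominence_sd: float = PROMINENCE_SD):
    """Times (s) of local maxima under refractory and prominence constraints.

    ``min_interval`` is the smallest admissible spacing between kept peaks
    (of two closer peaks the larger survives); ``min_prominence_sd`` is the
    prominence floor in units of the signal's standard deviation.
    """
    if min_interval <= 0:
        raise DomainError("min_interval must be positive")
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        return np.array([], dtype=float)
    idx, _ = sps.find_peaks(
        x,
        distance=max(1, int(round(min_interval * fs))),
        prominence=min_prominence_sd * sd,
    )
    return idx / float(fs)


@dataclass
class RateSeries:
    """Instantaneous event rate from peak timings.

    ``rates[k] = 1 / (t[k+1] - t[k])`` in Hz, placed at the midpoint of the
    interval it was measured over (``times``).
    """

    times: np.ndarray  # s, strictly increasing interval midpoints
    rates: np.ndarray  # Hz

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("RateSeries times must be strictly increasing")
        if np.any(self.rates <= 0):
            raise DomainError("RateSeries rates must be positive")


def rate_from_peaks(peak_times) -> RateSeries:
    """Reciprocal of adjacent peak intervals, at interval midpoints."""
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 peaks to estimate a rate, got {t.size}"
        )
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DomainError("peak times must be strictly increasing")
    return RateSeries(times=(t[:-1] + t[1:]) / 2.0, rates=1.0 / dt)


def resample_rate(rate: RateSeries, grid_fs: float, span) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of a rate series onto a regular grid.

    ``span`` is (start, stop) in seconds; outside the measured midpoints the
    first/last rate is held constant.  Returns (grid_times, rates_on_grid).
    """
    if rate.times.size == 0:
        raise InsufficientDataError("empty rate series")
    start, stop = span
    if stop <= start:
        raise DomainError(f"empty span {span}")
    n = int(np.floor((stop - start) * grid_fs)) + 1
    grid = start + np.arange(n) / grid_fs
    vals = np.interp(grid, rate.times, rate.rates)
    return grid, vals


def estimate_rate(
    x,
    fs,
    channel: str,
    span=None,
    grid_fs: float = RATE_GRID_FS,
    min_prominence_sd: float = PROMINENCE_SD,
):
    """Condition a pulsatile channel and return its uniform rate series (Hz).

    Convenience composition of :func:`condition_pulsatile`,
    :func:`detect_peaks`, :func:`rate_from_peaks` and :func:`resample_rate`.
    """
    if channel not in MIN_INTERVAL:
        raise DomainError(f"unknown pulsatile channel {channel!r}")
    cond = condition_pulsatile(x, fs)
    peaks = detect_peaks(cond, fs, MIN_INTERVAL[channel], min_prominence_sd)
    rate = rate_from_peaks(peaks)
    if span is None:
        span = (0.0, len(np.asarray(x)) / fs)
    return resample_rate(rate, grid_fs, span)


# ---------------------------------------------------------------------------
# skin-conductance decomposition


@dataclass
class SCDecomposition:
    """Tonic/driver/phasic split of one skin-conductance trace.

    All series live on a regular working grid (``fs`` Hz, ``times`` s).  By
    construction ``tonic + phasic + residual`` reconstructs the (decimated)
    input exactly; the quality of the fit shows in ``residual``.
    ``driver`` is the non-negative latent input whose convolution with the
    Bateman kernel gives ``phasic``; the sum of driver samples is the
    response "mass" (one unit of mass = one kernel-shaped response of unit
    amplitude scale).
    """

    times: np.ndarray
    fs: float
    tonic: np.ndarray
    driver: np.ndarray
    phasic: np.ndarray
    residual: np.ndarray
    tau1: float
    tau2: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def driver_mass(self) -> float:
        return float(np.sum(self.driver))


def _decimate_to(x, fs, working_fs):
    """Anti-aliased decimation onto the working grid (integer factor)."""
    factor = int(round(fs / working_fs))
    if factor <= 1:
        return np.asarray(x, dtype=float), float(fs)
    if abs(fs / factor - working_fs) > 1e-9:
        raise ConfigError(
            f"fs={fs} is not an integer multiple of working_fs={working_fs}"
        )
    y = sps.resample_poly(np.asarray(x, dtype=float), up=1, down=factor, padtype="line")
    return y, fs / factor


def decompose_sc(
    x,
    fs,
    tau1: float = SC_TAU1,
    tau2: float = SC_TAU2,
    working_fs: float = SC_WORKING_FS,
    tonic_window: float = SC_TONIC_WINDOW,
    tonic_percentile: float = SC_TONIC_PERCENTILE,
    ridge: float = SC_RIDGE,
) -> SCDecomposition:
    """Tonic/phasic decomposition of a skin-conductance trace.

    Steps: (1) decimate to ``working_fs``; (2) tonic = sliding
    ``tonic_percentile``-th percentile over ``tonic_window``, smoothed by a
    moving average of the same width; (3) non-negative least squares
    deconvolution of (signal - tonic) against the Bateman kernel with ridge
    weight ``ridge`` (the smallest-norm admissible driver); (4) phasic =
    driver convolved with the kernel.  No amplitude threshold is applied to
    the driver or phasic series.
    """
    if not tau1 > tau2 > 0:
        raise DomainError(f"need tau1 > tau2 > 0, got tau1={tau1}, tau2={tau2}")
    x = np.asarray(x, dtype=float)
    if x.size / fs < 3 * tau1:
        raise InsufficientDataError(
            f"signal of {x.size / fs:.1f}s shorter than 3*tau1 = {3 * tau1}s"
        )
    y, wfs = _decimate_to(x, fs, working_fs)
    n = y.size
    times = np.arange(n) / wfs

    win = max(1, int(round(tonic_window * wfs)))
    tonic = percentile_filter(y, percentile=tonic_percentile, size=win, mode="nearest")
    tonic = uniform_filter1d(tonic, size=win, mode="nearest")

    resid0 = y - tonic
    # kernel truncated once it has decayed to a negligible tail
    klen = min(n, int(round(8 * tau1 * wfs)) + 1)
    kernel = bateman_irf(np.arange(klen) / wfs, tau1, tau2)

    # lower-triangular Toeplitz convolution matrix, ridge-augmented NNLS
    conv = np.zeros((n, n))
    for j in range(n):
        stop = min(n, j + klen)
        conv[j:stop, j] = kernel[: stop - j]
    aug = np.vstack([conv, np.sqrt(ridge) * np.eye(n)])
    rhs = np.concatenate([resid0, np.zeros(n)])
    try:
        driver, rnorm = nnls(aug, rhs, maxiter=50 * n)
    except RuntimeError as exc:
        raise SolverError(
            "non-negative deconvolution did not converge",
            diagnostics={"n": n, "ridge": ridge, "error": str(exc)},
        ) from exc

    phasic = conv @ driver
    residual = y - tonic - phasic
    return SCDecomposition(
        times=times,
        fs=wfs,
        tonic=tonic,
        driver=driver,
        phasic=phasic,
        residual=residual,
        tau1=tau1,
        tau2=tau2,
        diagnostics={"nnls_rnorm": float(rnorm), "ridge": ridge},
    )


def mean_phasic(decomp: SCDecomposition, window) -> float:
    """Time-average of the phasic series over ``window`` = (start, stop) s.

    The continuous phasic activity is integrated (trapezoid rule) and divided
    by the window duration; no amplitude threshold is applied.
    """
    start, stop = window
    if stop <= start:
        raise DomainError(f"empty window {window}")
    t0, t1 = decomp.times[0], decomp.times[-1]
    if start < t0 - 0.5 / decomp.fs or stop > t1 + 0.5 / decomp.fs:
        raise DomainError(f"window {window} outside decomposed span ({t0}, {t1})")
    m = (decomp.times >= start) & (decomp.times <= stop)
    if m.sum() < 2:
        raise DomainError("window covers fewer than 2 samples")
    return float(
        np.trapezoid(decomp.phasic[m], decomp.times[m])
        / (decomp.times[m][-1] - decomp.times[m][0])
    )
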