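"""Filter-bank time-frequency decomposition, epoching, and power.

The decomposition follows the standard iEEG recipe: band-pass the
z-normalized trace at log-spaced center frequencies with a two-pass
(zero-phase) windowed-sinc FIR, take the Hilbert transform for instantaneous
phase and amplitude, and cut inhale-onset-aligned epochs. The default bank
spans 0.5-200 Hz over 50 log-spaced centers with bandwidth growing
logarithmically from 1 to 2 Hz; an alternative short-filter mode (2 cycles
per center frequency) provides a temporal-leakage control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

logger = logging.getLogger(__name__)

FIXED_BANDWIDTH = "fixed_bandwidth"
N_CYCLES = "n_cycles"


class SignalTooShortError(ValueError):
    """Raised when a signal cannot support the requested filter length."""


def preprocess(
    x: np.ndarray, fs: float, target_rate_hz: float = 500.0
) -> tuple[np.ndarray, float]:
    """Anti-aliased downsample to ``target_rate_hz``, then z-score.

    In single-channel operation the common-average re-reference degenerates
    to mean removal, which the z-scoring performs. Returns the processed
    trace and its (new) sampling rate.
    """
    x = np.asarray(x, dtype=float)
    if target_rate_hz > fs:
        raise ValueError(f"target rate {target_rate_hz} Hz exceeds source rate {fs} Hz")
    if target_rate_hz != fs:
        from fractions import Fraction

        frac = Fraction(target_rate_hz / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    sd = np.std(x)
    if sd == 0:
        raise ValueError("constant signal cannot be normalized")
    return (x - np.mean(x)) / sd, target_rate_hz


@dataclass
class FilterBank:
    """Log-spaced band-pass filter bank.

    ``fixed_bandwidth`` mode uses the per-center bandwidths with filter
    order equal to ``cycles`` periods of the band's low edge.  ``n_cycles``
    mode keeps the same bands but shortens the filter to ``cycles`` periods
    of the center frequency (the temporal-leakage control).
    """

    center_freqs_hz: np.ndarray
    bandwidths_hz: np.ndarray
    mode: str = FIXED_BANDWIDTH
    cycles: float = 3.0
    low_edge_floor_frac: float = 0.25  # clip low edges below this fraction of center

    def __post_init__(self) -> None:
        self.center_freqs_hz = np.asarray(self.center_freqs_hz, dtype=float)
        self.bandwidths_hz = np.asarray(self.bandwidths_hz, dtype=float)
        if self.center_freqs_hz.size != self.bandwidths_hz.size:
            raise ValueError("centers and bandwidths must have equal length")
        if np.any(np.diff(self.center_freqs_hz) <= 0):
            raise ValueError("center frequencies must be strictly increasing")
        if self.mode not in (FIXED_BANDWIDTH, N_CYCLES):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return self.center_freqs_hz.size

    def band_edges(self, i: int) -> tuple[float, float]:
        c = self.center_freqs_hz[i]
        half = self.bandwidths_hz[i] / 2.0
        lo, hi = c - half, c + half
        floor = self.low_edge_floor_frac * c
        if lo < floor:
            lo = floor
        return lo, hi

    def numtaps(self, i: int, fs: float) -> int:
        lo, _ = self.band_edges(i)
        ref = lo if self.mode == FIXED_BANDWIDTH else self.center_freqs_hz[i]
        cyc = self.cycles if self.mode == FIXED_BANDWIDTH else 2.0
        n = int(round(cyc * fs / ref))
        return n + 1 - n % 2  # odd (type-I linear phase)


def make_filter_bank(
    f_lo: float = 0.5,
    f_hi: float = 200.0,
    n: int = 50,
    bw_lo: float = 1.0,
    bw_hi: float = 2.0,
    mode: str = FIXED_BANDWIDTH,
) -> FilterBank:
    """Build the log-spaced bank (endpoints inclusive).

    Centers are log-spaced from ``f_lo`` to ``f_hi``; bandwidths log-spaced
    from ``bw_lo`` to ``bw_hi``. Low band edges that would fall at or below
    0 Hz are clipped (with a warning) to a fraction of the center frequency.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    if n < 2:
        raise ValueError("need at least 2 bands")
    centers = np.geomspace(f_lo, f_hi, n)
    bws = np.geomspace(bw_lo, bw_hi, n)
    bank = FilterBank(centers, bws, mode=mode)
    if np.any(centers - bws / 2.0 <= 0):
        warnings.warn(
            "some low band edges fall at or below 0 Hz; clipping above 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return bank


def _two_pass_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Forward-backward application of an FIR kernel via FFT convolution.

    Odd-reflection padding (as in filtfilt) suppresses edge transients; the
    forward and reversed passes cancel the kernel's phase, leaving zero net
    phase shift and the squared magnitude response.
    """
    n = x.size
    pad = min(h.size, n - 1)
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right])
    y = sps.fftconvolve(xp, h, mode="same")
    y = sps.fftconvolve(y[::-1], h, mode="same")[::-1]
    return y[pad : pad + n]


def bandpass_zero_phase(
    x: np.ndarray,
    band: tuple[float, float],
    fs: float,
    numtaps: int | None = None,
    cycles: float = 3.0,
) -> np.ndarray:
    """Two-pass zero-phase windowed-sinc band-pass filter.

    ``numtaps`` defaults to ``cycles`` periods of the band's low edge
    (rounded to odd). The signal must be longer than three filter lengths.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < lo < hi")
    if numtaps is None:
        numtaps = int(round(cycles * fs / lo))
        numtaps += 1 - numtaps % 2
    if x.size <= 3 * numtaps:
        raise SignalTooShortError(
            f"signal of {x.size} samples is too short for a {numtaps}-tap "
            f"filter; need more than {3 * numtaps} samples"
        )
    h = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return _two_pass_fir(x, h)


def analytic_signal(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude via the Hilbert transform.

    Phase is the angle of the analytic signal, 0 at the peak of a cosine,
    wrapped to (-pi, pi]; amplitude is its modulus.
    """
    x = np.asarray(filtered, dtype=float)
    if not np.any(x):
        raise ValueError("all-zero signal has undefined phase")
    n = x.size
    analytic = sps.hilbert(x, N=next_fast_len(n))[:n]
    return np.angle(analytic), np.abs(analytic)


def decompose(
    x: np.ndarray, fs: float, bank: FilterBank
) -> tuple[np.ndarray, np.ndarray]:
    """Filter-bank phase/amplitude decomposition of a continuous trace.

    Returns ``(phase, amplitude)`` arrays of shape (n_bands, n_samples).
    """
    x = np.asarray(x, dtype=float)
    nb = len(bank)
    phase = np.empty((nb, x.size))
    amp = np.empty((nb, x.size))
    for i in range(nb):
        y = bandpass_zero_phase(x, bank.band_edges(i), fs, numtaps=bank.numtaps(i, fs))
        phase[i], amp[i] = analytic_signal(y)
    return phase, amp


@dataclass
class PhaseAmplitudeTensor:
    """Epoched instantaneous phase and amplitude, (trial, frequency, time).

    ``time_axis_s`` is relative to inhale onset (half-open window, onset
    sample included at t=0); ``labels`` carries the per-trial event rows
    (condition, accuracy, ...) aligned with the trial axis.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    time_axis_s: np.ndarray
    freq_axis_hz: np.ndarray
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude shapes differ")
        nt, nf, ns = self.phase.shape
        if nf != self.freq_axis_hz.size or ns != self.time_axis_s.size:
            raise ValueError("axis lengths do not match tensor shape")
        if self.labels is not None and len(self.labels) != nt:
            raise ValueError("labels length does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def select(self, mask) -> "PhaseAmplitudeTensor":
        mask = np.asarray(mask)
        labels = None
        if self.labels is not None:
            labels = self.labels.loc[mask].reset_index(drop=True)
        return PhaseAmplitudeTensor(
            self.phase[mask], self.amplitude[mask], self.time_axis_s,
            self.freq_axis_hz, labels,
        )


def epoch(
    series: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    window: tuple[float, float] = (-1.0, 3.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut onset-aligned epochs from a (bands, time) or (time,) series.

    The sample window is half-open, ``[onset+w0, onset+w1)``, with the onset
    sample included at t=0. Epochs that would run past the recording edges
    are dropped (their count is logged). Returns ``(epochs, kept_indices,
    time_axis_s)`` where epochs has shape (n_kept, ..., n_samples).

    Raises if no epoch survives.
    """
    arr = np.atleast_2d(np.asarray(series))
    n = arr.shape[-1]
    w0, w1 = window
    n_samp = int(round((w1 - w0) * fs))
    starts = np.round((np.asarray(onsets_s, dtype=float) + w0) * fs).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= n)
    if not np.any(ok):
        raise ValueError("no epochs fit within the recording")
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d epochs at recording edges", dropped)
    idx = starts[ok, None] + np.arange(n_samp)[None, :]
    out = arr[:, idx]  # (bands, n_kept, n_samp)
    out = np.moveaxis(out, 1, 0)
    if np.asarray(series).ndim == 1:
        out = out[:, 0, :]
    time_axis = w0 + np.arange(n_samp) / fs
    return out, np.flatnonzero(ok), time_axis


def epoch_tensor(
    phase: np.ndarray,
    amplitude: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    freq_axis_hz: np.ndarray,
    window: tuple[float, float] = (-1.0, 3.0),
    labels: pd.DataFrame | None = None,
) -> PhaseAmplitudeTensor:
    """Epoch a full (bands, time) phase/amplitude decomposition."""
    ph, kept, taxis = epoch(phase, fs, onsets_s, window)
    am, _, _ = epoch(amplitude, fs, onsets_s, window)
    if labels is not None:
        labels = labels.iloc[kept].reset_index(drop=True)
    return PhaseAmplitudeTensor(ph, am, taxis, np.asarray(freq_axis_hz), labels)


def smooth_amplitude(
    amplitude: np.ndarray, fs: float, kernel_ms: float = 10.0
) -> np.ndarray:
    """Centered moving-average smoothing along the time (last) axis.

    Edge samples use shrinking windows (the average of however much of the
    kernel fits), so constants pass through unchanged and interior mass is
    conserved.
    """
    from scipy.ndimage import convolve1d

    k = max(1, int(round(kernel_ms / 1000.0 * fs)))
    if k == 1:
        return np.asarray(amplitude, dtype=float).copy()
    a = np.asarray(amplitude, dtype=float)
    w = np.ones(k)
    sums = convolve1d(a, w, axis=-1, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(a.shape[-1]), w, mode="constant", cval=0.0)
    return sums / counts


@dataclass
class PowerMap:
    """Trial-averaged power in dB, (frequency, time)."""

    db: np.ndarray
    freq_axis_hz: np.ndarray
    time_axis_s: np.ndarray
    mode: str = "raw"


def power_map(
    tensor: PhaseAmplitudeTensor,
    mode: str = "raw",
    baseline_window: tuple[float, float] = (-1.0, 0.0),
) -> PowerMap:
    """Trial-averaged dB power map from an epoched amplitude tensor.

    Power is amplitude squared, averaged over trials, then 10*log10.  In
    ``baseline_db`` mode the per-frequency average over ``baseline_window``
    is additionally subtracted; ``raw`` performs no baseline correction.
    """
    if tensor.n_trials == 0:
        raise ValueError("empty tensor")
    power = np.mean(tensor.amplitude**2, axis=0)  # (freq, time)
    db = 10.0 * np.log10(power)
    if mode == "baseline_db":
        t0, t1 = baseline_window
        sel = (tensor.time_axis_s >= t0) & (tensor.time_axis_s < t1)
        if not np.any(sel):
            raise ValueError("baseline window lies outside the epoch")
        db = db - db[:, sel].mean(axis=1, keepdims=True)
    elif mode != "raw":
        raise ValueError(f"unknown power mode {mode!r}")
    return PowerMap(db, tensor.freq_axis_hz, tensor.time_axis_s, mode)


def welch_psd(
    segment: np.ndarray,
    fs: float,
    f_max: float = 200.0,
    step_hz: float = 0.05,
    seg_s: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD on a fixed frequency grid, in dB.

    Hann-tapered segments (``seg_s`` long, 50% overlap, shortened if the
    signal is briefer), zero-padded to the ``step_hz`` grid. Returns
    (frequencies up to ``f_max``, PSD in dB).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 8:
        raise ValueError("segment too short for spectral estimation")
    nperseg = min(x.size, int(round(seg_s * fs)))
    nfft = max(nperseg, int(round(fs / step_hz)))
    f, p = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft
    )
    sel = f <= f_max
    with np.errstate(divide="ignore"):
        return f[sel], 10.0 * np.log10(p[sel])
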