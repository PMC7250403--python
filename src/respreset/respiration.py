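"""Nasal-airflow preprocessing and inhale-event extraction.

A piezoelectric pressure transducer on a nasal cannula yields a continuous
airflow trace in which inhalation is positive and exhalation negative. All
event timing downstream (epoching, ITPC, behavioral analyses) is anchored to
inhale onsets, defined as upward zero-crossings of the z-normalized trace.
Inhale duration is the time from onset to the first subsequent zero-crossing
and the inhale peak is the maximum airflow over that span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANTICIPATORY = "anticipatory"
NONANTICIPATORY = "nonanticipatory"


class ZeroVarianceError(ValueError):
    """Raised when a constant trace cannot be normalized."""


class TruncatedInhaleError(ValueError):
    """Raised when the trace ends before an inhale's closing zero-crossing."""


@dataclass
class RespirationTrace:
    """Continuous airflow recording.

    Parameters
    ----------
    samples : ndarray
        Airflow values, arbitrary units; inhalation positive.
    sampling_rate_hz : float
        Sampling rate, Hz.
    normalized : bool
        True once the trace has been z-scored (zero mean, unit sample SD).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("respiration trace must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiration trace contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


def normalize_trace(trace: RespirationTrace, ddof: int = 1) -> RespirationTrace:
    """Z-score an airflow trace (subtract mean, divide by sample SD).

    Uses the n-1 (sample) standard deviation by default so that e.g.
    (1, 2, 3) maps to (-1, 0, 1). Raises :class:`ZeroVarianceError` for a
    constant trace.
    """
    x = trace.samples
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise ZeroVarianceError("trace has zero variance; cannot normalize")
    return RespirationTrace(
        (x - float(np.mean(x))) / sd, trace.sampling_rate_hz, normalized=True
    )


def detect_inhale_onsets(
    trace: RespirationTrace,
    min_pause_s: float = 0.2,
    min_excursion: float = 0.2,
) -> np.ndarray:
    """Detect inhale onsets as qualified upward zero-crossings.

    An onset is the first sample at or above zero following a run of
    ``min_pause_s`` of strictly sub-zero signal (the natural pause at the end
    of exhalation), and must be followed by an airflow excursion of at least
    ``min_excursion`` normalized units before the signal returns below zero.
    Both criteria reject transducer jitter around the zero line.

    Returns onset times in seconds, sorted and unique.
    """
    if not trace.normalized:
        raise ValueError(
            "trace is not normalized; call normalize_trace() before detection"
        )
    x = trace.samples
    fs = trace.sampling_rate_hz
    n_pause = max(1, int(round(min_pause_s * fs)))

    up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1
    onsets = []
    for i in up:
        if i < n_pause or np.max(x[i - n_pause : i]) >= 0:
            continue
        # following excursion until the signal drops below zero again
        below = np.flatnonzero(x[i:] < 0)
        j = i + below[0] if below.size else x.size
        if np.max(x[i:j], initial=-np.inf) < min_excursion:
            continue
        onsets.append(i / fs)
    return np.unique(onsets)


def inhale_features(trace: RespirationTrace, onset_s: float) -> tuple[float, float]:
    """Inhale peak and duration for the breath starting at ``onset_s``.

    Duration is the time from the onset to the first downward zero-crossing;
    the peak is the maximum airflow value over that span.
    """
    fs = trace.sampling_rate_hz
    x = trace.samples
    i0 = int(round(onset_s * fs))
    if not 0 <= i0 < x.size:
        raise ValueError(f"onset {onset_s} s is outside the trace")
    below = np.flatnonzero(x[i0 + 1 :] < 0)
    if below.size == 0:
        raise TruncatedInhaleError(
            f"trace ends before the inhale at {onset_s} s crosses zero"
        )
    j = i0 + 1 + below[0]
    duration_s = (j - i0) / fs
    peak = float(np.max(x[i0:j]))
    return peak, duration_s


def label_events(
    onsets: np.ndarray,
    trial_windows: list[tuple[float, float]],
    guard_s: float = 2.0,
) -> pd.DataFrame:
    """Label inhale onsets by anticipatory condition.

    Onsets inside a trial window ``[start, end)`` are anticipatory; onsets
    farther than ``guard_s`` from every window are nonanticipatory; onsets in
    the guard band are dropped so that cue-contaminated breaths never enter
    the nonanticipatory pool. The number of dropped onsets is recorded in
    ``result.attrs['n_dropped']``.
    """
    windows = sorted(trial_windows)
    for (s0, e0), (s1, _e1) in zip(windows, windows[1:]):
        if e0 > s1:
            raise ValueError(f"trial windows overlap: ({s0}, {e0}) and ({s1}, ...)")
    starts = np.array([w[0] for w in windows], dtype=float)
    ends = np.array([w[1] for w in windows], dtype=float)

    rows = []
    n_dropped = 0
    for t in np.asarray(onsets, dtype=float):
        inside = (t >= starts) & (t < ends)
        if inside.any():
            rows.append((t, ANTICIPATORY))
            continue
        # distance to the nearest window
        dist = np.minimum(np.abs(t - starts), np.abs(t - ends))
        dist[(t >= starts) & (t < ends)] = 0.0
        if starts.size == 0 or np.min(dist) > guard_s:
            rows.append((t, NONANTICIPATORY))
        else:
            n_dropped += 1
    out = pd.DataFrame(rows, columns=["onset_s", "condition"])
    out.attrs["n_dropped"] = n_dropped
    logger.info(
        "labeled %d anticipatory, %d nonanticipatory; dropped %d in guard band",
        int((out["condition"] == ANTICIPATORY).sum()),
        int((out["condition"] == NONANTICIPATORY).sum()),
        n_dropped,
    )
    return out


def subsample_nonanticipatory(
    events: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Randomly subsample nonanticipatory events to match anticipatory count.

    Sampling is without replacement and reproducible from ``seed``. Mirrors
    the equal-N control used when there are more intertrial breaths than
    trial breaths.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    is_ant = events["condition"] == ANTICIPATORY
    n_ant = int(is_ant.sum())
    non_idx = events.index[events["condition"] == NONANTICIPATORY].to_numpy()
    if non_idx.size < n_ant:
        raise ValueError(
            f"only {non_idx.size} nonanticipatory events for {n_ant} anticipatory"
        )
    chosen = rng.choice(non_idx, size=n_ant, replace=False)
    keep = np.concatenate([events.index[is_ant].to_numpy(), chosen])
    out = events.loc[np.sort(keep)].reset_index(drop=True)
    out.attrs.update(events.attrs)
    return out
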