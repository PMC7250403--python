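"""Circular statistics for event-locked phase: ITPC, Rayleigh test, DMP.

ITPC (inter-trial phase coherence, identical to the phase-locking value
across trials) is the modulus of the trial-averaged unit phasor

    ITPC = | (1/n) sum_j exp(i * phi_j) |

at a fixed time-frequency point: 0 means no phase clustering, 1 perfect
clustering. Its significance per bin is assessed with the Rayleigh test of
circular uniformity (z = n R^2) and corrected across the map by FDR.

The deviation from the mean phase (DMP) is the single-trial counterpart:
the unsigned circular distance between a trial's phase at event onset and
the circular mean phase over trials, in [0, pi]; small DMP marks a
well-aligned (strongly reset) trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

_TWO_PI = 2.0 * np.pi


def _wrap(angle):
    return -((-np.asarray(angle) + np.pi) % _TWO_PI - np.pi)


def itpc(phases: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Mean resultant length of phase angles along ``axis`` (trials)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[axis]
    if n < 2:
        raise ValueError("ITPC requires at least 2 trials")
    r = np.abs(np.mean(np.exp(1j * phases), axis=axis))
    return float(r) if np.ndim(r) == 0 else r


def itpc_unbiased(phases: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Small-sample bias-corrected ITPC.

    The raw mean resultant length is inflated for finite n (uniform phases
    give E[R] ~ sqrt(pi/(4n)) rather than 0). Since n R^2 has expectation
    1 + (n-1) rho^2 for population resultant rho, sqrt(max(0,
    (n R^2 - 1)/(n - 1))) estimates rho without that floor, which matters
    when comparing a measured ITPC against its population value.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[axis]
    r = itpc(phases, axis=axis)
    return np.sqrt(np.maximum(0.0, (n * np.asarray(r) ** 2 - 1.0) / (n - 1.0)))


def rayleigh_test(phases: np.ndarray, axis: int = 0):
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` with z = n R^2 and the standard finite-n
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n)).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[axis]
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 trials")
    r = np.abs(np.mean(np.exp(1j * phases), axis=axis))
    z = n * r**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (n * r) ** 2)) - (1.0 + 2.0 * n))
    p = np.minimum(p, 1.0)
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def fdr_mask(pvals: np.ndarray, q: float = 0.05, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) FDR mask over all bins."""
    flat = np.asarray(pvals, dtype=float).ravel()
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, *_ = multipletests(flat, alpha=q, method=sm_method)
    return reject.reshape(np.shape(pvals))


@dataclass
class ITPCMap:
    """Per (frequency, time) coherence with Rayleigh statistics and FDR mask."""

    itpc: np.ndarray
    rayleigh_z: np.ndarray
    rayleigh_p: np.ndarray
    sig_mask: np.ndarray
    n_trials: int
    freq_axis_hz: np.ndarray
    time_axis_s: np.ndarray
    fdr_q: float = 0.05


def itpc_map(tensor, fdr_q: float = 0.05, fdr_method: str = "bh") -> ITPCMap:
    """ITPC map over an epoched phase tensor with per-bin Rayleigh p and FDR.

    FDR is applied jointly across all (frequency, time) bins of the map.
    """
    n = tensor.n_trials
    if n < 2:
        raise ValueError("ITPC map requires at least 2 trials")
    z, p = rayleigh_test(tensor.phase, axis=0)
    r = np.sqrt(z / n)
    mask = fdr_mask(p, q=fdr_q, method=fdr_method)
    return ITPCMap(r, z, p, mask, n, tensor.freq_axis_hz, tensor.time_axis_s, fdr_q)


def max_itpc(
    m: ITPCMap,
    freq_window: tuple[float, float],
    time_window: tuple[float, float],
) -> tuple[float, float, float]:
    """Maximum ITPC over an inclusive frequency x time sub-grid.

    Ties break deterministically to the lowest frequency, then the earliest
    time. Returns ``(value, argmax_freq_hz, argmax_time_s)``.
    """
    fsel = (m.freq_axis_hz >= freq_window[0]) & (m.freq_axis_hz <= freq_window[1])
    tsel = (m.time_axis_s >= time_window[0]) & (m.time_axis_s <= time_window[1])
    if not np.any(fsel) or not np.any(tsel):
        raise ValueError("window does not intersect the map axes")
    sub = m.itpc[np.ix_(fsel, tsel)]
    flat = int(np.argmax(sub))  # first occurrence: lowest freq, earliest time
    fi, ti = np.unravel_index(flat, sub.shape)
    return (
        float(sub[fi, ti]),
        float(m.freq_axis_hz[fsel][fi]),
        float(m.time_axis_s[tsel][ti]),
    )


def rayleigh_z_timeseries(
    tensor, freq_hz: float, nearest: bool = True
) -> tuple[np.ndarray, float]:
    """Rayleigh z over time at one frequency: z(t) = n R(t)^2.

    With ``nearest`` (default) an off-grid frequency snaps to the closest
    bank center; otherwise it must match a grid value exactly.
    """
    freqs = tensor.freq_axis_hz
    i = int(np.argmin(np.abs(freqs - freq_hz)))
    if not nearest and not np.isclose(freqs[i], freq_hz):
        raise ValueError(f"{freq_hz} Hz is not on the frequency grid")
    z, _ = rayleigh_test(tensor.phase[:, i, :], axis=0)
    return z, float(freqs[i])


def circular_distance(a, b):
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    return _wrap(np.asarray(a) - np.asarray(b))


@dataclass
class DMPResult:
    """Single-trial deviation-from-mean-phase values at event onset.

    ``table`` has one row per trial with the trial's DMP in [0, pi] plus
    any labels carried on the input tensor; ``peak_freq_hz`` is the
    frequency of maximal onset ITPC within the search band and
    ``mean_phase_rad`` the circular mean phase there.
    """

    table: pd.DataFrame
    peak_freq_hz: float
    mean_phase_rad: float
    at_time_s: float


def dmp(
    tensor,
    at_time: float = 0.0,
    freq_band: tuple[float, float] = (0.5, 2.0),
) -> DMPResult:
    """Deviation from the mean phase, per trial, at ``at_time``.

    The frequency is chosen as the in-band maximum of onset-column ITPC
    (ties to the lowest frequency); each trial's DMP is the absolute
    circular distance between its phase and the circular mean phase across
    trials at that frequency and time.
    """
    if tensor.n_trials < 2:
        raise ValueError("DMP requires at least 2 trials")
    ti = int(np.argmin(np.abs(tensor.time_axis_s - at_time)))
    fsel = (tensor.freq_axis_hz >= freq_band[0]) & (tensor.freq_axis_hz <= freq_band[1])
    if not np.any(fsel):
        raise ValueError("freq_band does not intersect the frequency grid")
    onset_phases = tensor.phase[:, fsel, ti]  # (trial, freq-in-band)
    r = np.abs(np.mean(np.exp(1j * onset_phases), axis=0))
    fi = int(np.argmax(r))  # first occurrence = lowest in-band frequency
    phases = onset_phases[:, fi]
    mean_vec = np.mean(np.exp(1j * phases))
    if np.abs(mean_vec) < 1e-12:
        raise ValueError(
            "circular mean phase is undefined (resultant length ~ 0)"
        )
    mean_phase = float(np.angle(mean_vec))
    values = np.abs(circular_distance(phases, mean_phase))
    table = pd.DataFrame({"dmp": values})
    if tensor.labels is not None:
        table = pd.concat([tensor.labels.reset_index(drop=True), table], axis=1)
    return DMPResult(
        table=table,
        peak_freq_hz=float(tensor.freq_axis_hz[fsel][fi]),
        mean_phase_rad=mean_phase,
        at_time_s=float(tensor.time_axis_s[ti]),
    )
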