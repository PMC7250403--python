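"""Synthetic coupled LFP + respiration + behavior generator.

Emulates the statistical structure assumed by the anticipatory phase-reset
analysis so that every downstream stage is testable without recorded data:

* breathing as a train of half-sine inhales followed by exponentially
  decaying exhales, with jittered period and condition-dependent inhale
  peaks and durations;
* an ongoing respiration-coupled delta oscillation that is steered by
  continuous frequency modulation toward a target phase ahead of every
  inhale onset; anticipatory targets are von Mises draws (concentration
  ``reset_kappa`` around ``reset_mean_phase_rad``) — the phase reset —
  while nonanticipatory targets are arbitrary (uniform) per breath, so both
  conditions share identical spectral statistics and differ only in phase
  consistency;
* a post-inhale theta burst on every breath (inhalation itself drives
  piriform theta), whose amplitude on anticipatory trials is additionally
  scaled by the alignment of the onset phase with the preferred phase —
  the odor-evoked response;
* behavioral accuracy whose probability follows a logistic function of the
  trial's true deviation from the preferred phase (DMP);
* 1/f^alpha Gaussian background noise.

The generator is fully deterministic given a seed.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.special import expit, ive

from .respiration import ANTICIPATORY, NONANTICIPATORY, RespirationTrace

_TWO_PI = 2.0 * np.pi


def _wrap(angle):
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(angle) + np.pi) % _TWO_PI - np.pi)


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording.

    Notable fields
    --------------
    reset_kappa : float
        von Mises concentration of the delta phase at anticipatory onsets;
        0 leaves those phases uniform (no reset).
    cue_lead_s : float
        Length of the pre-inhale phase-steering window (and of the trial
        window preceding each anticipatory onset). The oscillator's phase
        is driven continuously over this interval so it lands on the
        breath's target phase exactly at onset; anticipation determines
        the target's distribution, not the steering itself.
    theta_gain : float
        Coupling of post-inhale theta burst amplitude to phase alignment:
        amplitude = base * (1 + gain * cos(onset_phase - preferred_phase)).
    accuracy_slope : float
        Logistic slope of P(correct) on the trial's true DMP (rad).
    inhale_peak_dmp_coupling : float
        Optional deterministic coupling of anticipatory inhale peak to phase
        alignment; 0 (default) keeps sniff vigor independent of the reset.
    """

    sampling_rate_hz: float = 500.0
    duration_s: float | None = None
    n_anticipatory: int = 20
    n_nonanticipatory: int = 20
    breath_period_s: float = 3.0
    period_jitter_frac: float = 0.15
    delta_freq_hz: float = 1.0
    delta_amp: float = 2.0
    reset_kappa: float = 4.0
    reset_mean_phase_rad: float = 0.0
    cue_lead_s: float = 2.0
    theta_freq_hz: float = 6.0
    theta_base_amp: float = 1.5
    theta_gain: float = 0.5
    theta_burst_center_s: float = 0.6
    theta_burst_sigma_s: float = 0.12
    accuracy_slope: float = 2.0
    accuracy_intercept: float = 2.3
    inhale_peak_anticipatory: float = 1.3
    inhale_peak_nonanticipatory: float = 1.0
    inhale_duration_anticipatory_s: float = 1.2
    inhale_duration_nonanticipatory_s: float = 1.0
    inhale_jitter_frac: float = 0.08
    inhale_peak_dmp_coupling: float = 0.0
    noise_exponent: float = 1.5
    noise_std: float = 1.0
    hardware_highpass_hz: float = 0.0
    gap_breaths: int = 8
    guard_s: float = 2.0
    trial_post_s: float = 2.0
    subject: str = "s01"
    seed: int = 0

    def validate(self) -> None:
        if self.reset_kappa < 0:
            raise ValueError("reset_kappa must be nonnegative")
        if not 0.5 <= self.delta_freq_hz <= 2.0:
            raise ValueError("delta_freq_hz must lie in [0.5, 2]")
        if not 4.0 <= self.theta_freq_hz <= 8.0:
            raise ValueError("theta_freq_hz must lie in [4, 8]")
        if not -np.pi < self.reset_mean_phase_rad <= np.pi:
            raise ValueError("reset_mean_phase_rad must lie in (-pi, pi]")
        for name in (
            "sampling_rate_hz",
            "breath_period_s",
            "inhale_peak_anticipatory",
            "inhale_peak_nonanticipatory",
            "inhale_duration_anticipatory_s",
            "inhale_duration_nonanticipatory_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_anticipatory < 1:
            raise ValueError("n_anticipatory must be a positive integer")
        if self.n_nonanticipatory < 0:
            raise ValueError("n_nonanticipatory must be nonnegative")
        if self.accuracy_slope < 0:
            raise ValueError("accuracy_slope must be nonnegative")
        if self.theta_gain < 0:
            raise ValueError("theta_gain must be nonnegative")
        # intertrial stretches must exceed 6 respiratory periods even at the
        # short end of the period jitter (the study's inclusion criterion)
        if self.gap_breaths * (1.0 - self.period_jitter_frac) <= 6.0:
            raise ValueError(
                "gap_breaths too small: intertrial stretch must exceed "
                "6 respiratory periods under the worst-case jitter"
            )
        jitter_floor = (1.0 - self.period_jitter_frac) * self.breath_period_s
        if self.cue_lead_s >= jitter_floor:
            raise ValueError(
                "cue_lead_s must be shorter than the shortest breath period "
                "(phase steering windows may not overlap)"
            )
        if self.trial_post_s >= jitter_floor:
            raise ValueError(
                "trial_post_s must be shorter than the shortest breath period"
            )
        max_inhale = max(
            self.inhale_duration_anticipatory_s, self.inhale_duration_nonanticipatory_s
        ) * (1.0 + self.inhale_jitter_frac)
        if max_inhale >= 0.75 * jitter_floor:
            raise ValueError("inhale durations too long for the breath period")

    @classmethod
    def from_toml(cls, path: str | Path) -> "SynthConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "seed" not in data:
            raise ValueError("synthetic config must specify a seed")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SyntheticDataset:
    """A generated recording: neural trace, airflow, events, and ground truth.

    ``events`` lists every retained breath (subject, onset_s, condition,
    correct, inhale_peak, inhale_duration_s, onset_phase_rad, dmp_true);
    ``truth`` carries the config and per-trial realized quantities so that
    recovery tests can compare estimate against truth.
    """

    neural: np.ndarray
    sampling_rate_hz: float
    respiration: RespirationTrace
    events: pd.DataFrame
    truth: dict = field(default_factory=dict)


def expected_itpc_from_kappa(kappa) -> np.ndarray | float:
    """Population mean resultant length I1(kappa)/I0(kappa) of a von Mises sample.

    Calibration oracle for parameter-recovery tests: a large sample of
    phases drawn with concentration kappa has ITPC converging to this value.
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise ValueError("kappa must be nonnegative")
    out = np.where(k > 0, ive(1, k) / np.where(k > 0, ive(0, k), 1.0), 0.0)
    return float(out) if np.isscalar(kappa) or out.ndim == 0 else out


# exhale shape: -sin(pi*u) * exp(-2u) on u in (0, 1); its integral fixes the
# exhale amplitude that balances each breath's inhale area to zero
_EXHALE_UNIT_AREA = np.pi * (1.0 + np.exp(-2.0)) / (4.0 + np.pi**2)


def _plan_breaths(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the breath train: gap (intertrial) blocks around each trial breath."""
    # how many intertrial breaths survive the guard band, per the labeling
    # rule: the breaths immediately flanking each trial window are dropped
    trailing = cfg.gap_breaths
    est_kept = cfg.n_anticipatory * (cfg.gap_breaths - 2) + (trailing - 1) + 1
    deficit = cfg.n_nonanticipatory - est_kept
    if deficit > 0:
        trailing += deficit

    kinds = []
    for _ in range(cfg.n_anticipatory):
        kinds.extend([NONANTICIPATORY] * cfg.gap_breaths)
        kinds.append(ANTICIPATORY)
    kinds.extend([NONANTICIPATORY] * trailing)

    n = len(kinds)
    periods = cfg.breath_period_s * (
        1.0 + rng.uniform(-cfg.period_jitter_frac, cfg.period_jitter_frac, size=n)
    )
    is_ant = np.array([k == ANTICIPATORY for k in kinds])
    dur_mean = np.where(
        is_ant, cfg.inhale_duration_anticipatory_s, cfg.inhale_duration_nonanticipatory_s
    )
    peak_mean = np.where(
        is_ant, cfg.inhale_peak_anticipatory, cfg.inhale_peak_nonanticipatory
    )
    durations = dur_mean * (
        1.0 + rng.uniform(-cfg.inhale_jitter_frac, cfg.inhale_jitter_frac, size=n)
    )
    peaks = peak_mean * (
        1.0 + rng.uniform(-cfg.inhale_jitter_frac, cfg.inhale_jitter_frac, size=n)
    )
    pre_roll = 1.0
    onsets = pre_roll + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "period_s": periods,
            "inhale_duration_s": durations,
            "inhale_peak": peaks,
            "kind": kinds,
        }
    )


def _render_respiration(
    breaths: pd.DataFrame, n_samples: int, fs: float
) -> np.ndarray:
    """Sample the airflow waveform onto the recording grid."""
    resp = np.full(n_samples, -0.02, dtype=float)  # sub-zero resting baseline
    t = np.arange(n_samples) / fs
    for row in breaths.itertuples(index=False):
        i0 = int(np.ceil(row.onset_s * fs))
        i1 = min(int(np.ceil((row.onset_s + row.inhale_duration_s) * fs)), n_samples)
        i2 = min(int(np.ceil((row.onset_s + row.period_s) * fs)), n_samples)
        if i0 >= n_samples:
            break
        tt = t[i0:i1] - row.onset_s
        resp[i0:i1] = row.inhale_peak * np.sin(np.pi * tt / row.inhale_duration_s)
        # exhale amplitude chosen so each breath integrates to ~zero, keeping
        # the z-scored trace's zero-crossings at the constructed onsets
        exhale_len = row.period_s - row.inhale_duration_s
        inhale_area = row.inhale_peak * 2.0 * row.inhale_duration_s / np.pi
        c = inhale_area / (_EXHALE_UNIT_AREA * exhale_len)
        u = (t[i1:i2] - row.onset_s - row.inhale_duration_s) / exhale_len
        resp[i1:i2] = -c * np.sin(np.pi * u) * np.exp(-2.0 * u)
    return resp


def _delta_phase(
    t: np.ndarray,
    onsets: np.ndarray,
    targets: np.ndarray,
    cue_lead: float,
    freq: float,
    phi0: float,
) -> np.ndarray:
    """Continuous phase trajectory with pre-onset steering.

    The oscillator free-runs at ``freq``; over the ``cue_lead`` window
    before each onset its phase offset ramps linearly so that the phase at
    the onset equals the drawn target. The trajectory is continuous (pure
    frequency modulation), so the oscillation's amplitude is never
    disturbed. Steering windows must not overlap.

    Implemented as the cumulative sum of a per-sample offset derivative,
    which keeps the cost linear in the recording length.
    """
    omega = _TWO_PI * freq
    dt = t[1] - t[0] if t.size > 1 else 1.0
    fs = 1.0 / dt
    deriv = np.zeros(t.size)
    offset = 0.0  # accumulated phase offset relative to the free run
    for onset, target in zip(onsets, targets):
        free_at_onset = phi0 + omega * onset + offset
        jump = float(_wrap(target - free_at_onset))
        i_on = int(round(onset * fs))
        i_cue = max(0, int(round((onset - cue_lead) * fs)))
        if i_on > i_cue:
            deriv[i_cue:i_on] += jump / (i_on - i_cue)
        offset += jump
    offsets = np.concatenate([[0.0], np.cumsum(deriv[:-1])])
    return phi0 + omega * t + offsets


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a coupled neural + respiration + behavior dataset.

    Deterministic given ``config.seed``: the same configuration yields a
    bit-identical dataset.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz

    breaths = _plan_breaths(cfg, rng)
    required = float(breaths["onset_s"].iloc[-1] + breaths["period_s"].iloc[-1] + 4.0)
    if cfg.duration_s is None:
        duration = required
    elif cfg.duration_s < required:
        raise ValueError(
            f"duration_s={cfg.duration_s} cannot accommodate the requested events; "
            f"need at least {required:.1f} s"
        )
    else:
        duration = float(cfg.duration_s)
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs

    resp = _render_respiration(breaths, n_samples, fs)

    is_ant = (breaths["kind"] == ANTICIPATORY).to_numpy()
    ant_onsets = breaths.loc[is_ant, "onset_s"].to_numpy()

    # the respiration-coupled delta oscillator is steered toward a target
    # phase ahead of EVERY inhale, so both conditions share identical
    # frequency-modulation statistics (no spectral/power confound); only the
    # anticipatory targets are von Mises-concentrated, nonanticipatory
    # targets are arbitrary per breath
    n_breaths = len(breaths)
    if cfg.reset_kappa > 0:
        vm = rng.vonmises(cfg.reset_mean_phase_rad, cfg.reset_kappa, n_breaths)
    else:
        vm = rng.uniform(-np.pi, np.pi, n_breaths)
    uni = rng.uniform(-np.pi, np.pi, n_breaths)
    all_targets = np.where(is_ant, vm, uni)
    phi0 = rng.uniform(-np.pi, np.pi)
    phase = _delta_phase(
        t, breaths["onset_s"].to_numpy(), all_targets, cfg.cue_lead_s,
        cfg.delta_freq_hz, phi0,
    )
    neural = cfg.delta_amp * np.cos(phase)

    # realized delta phase at every breath onset (truth for recovery tests)
    onset_phase = _wrap(all_targets)  # exact by construction
    targets = all_targets[is_ant]

    # post-inhale theta bursts on every breath (inhalation drives piriform
    # theta); on anticipatory trials the amplitude is additionally coupled
    # to the alignment of the onset phase with the preferred phase,
    # emulating the anticipation-enhanced odor-evoked response
    align = np.cos(_wrap(all_targets - cfg.reset_mean_phase_rad))
    burst_amp = cfg.theta_base_amp * np.where(
        is_ant, np.maximum(0.0, 1.0 + cfg.theta_gain * align), 1.0
    )
    half = cfg.theta_burst_center_s + 5.0 * cfg.theta_burst_sigma_s
    for onset, amp in zip(breaths["onset_s"].to_numpy(), burst_amp):
        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.ceil((onset + half) * fs)), n_samples)
        tau = t[i0:i1] - onset
        env = np.exp(-0.5 * ((tau - cfg.theta_burst_center_s) / cfg.theta_burst_sigma_s) ** 2)
        carrier = np.cos(_TWO_PI * cfg.theta_freq_hz * tau + rng.uniform(0, _TWO_PI))
        neural[i0:i1] += amp * env * carrier

    # 1/f^alpha background
    if cfg.noise_std > 0:
        white = rng.standard_normal(n_samples)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-cfg.noise_exponent / 2.0)
        colored = np.fft.irfft(spec * shape, n=n_samples)
        colored *= cfg.noise_std / np.std(colored)
        neural = neural + colored

    # behavioral accuracy from the true DMP via a logistic link
    dmp_true = np.abs(_wrap(onset_phase - cfg.reset_mean_phase_rad))
    p_correct = expit(cfg.accuracy_intercept - cfg.accuracy_slope * dmp_true)
    correct_draw = rng.random(len(breaths)) < p_correct

    # optional coupling of sniff vigor to phase alignment (off by default)
    peaks = breaths["inhale_peak"].to_numpy().copy()
    if cfg.inhale_peak_dmp_coupling != 0.0:
        scale = 1.0 + cfg.inhale_peak_dmp_coupling * (0.5 - dmp_true / np.pi)
        peaks[is_ant] *= scale[is_ant]
        breaths = breaths.assign(inhale_peak=peaks)
        resp = _render_respiration(breaths, n_samples, fs)

    if cfg.hardware_highpass_hz > 0:
        from scipy.signal import butter, lfilter

        b, a = butter(1, cfg.hardware_highpass_hz, btype="highpass", fs=fs)
        resp = lfilter(b, a, resp)

    # label every breath with the same window/guard rule the respiration
    # module applies, so detected labels reproduce truth exactly
    windows = [(o - cfg.cue_lead_s, o + cfg.trial_post_s) for o in ant_onsets]
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    onsets_all = breaths["onset_s"].to_numpy()
    cond = np.full(len(breaths), "dropped", dtype=object)
    for i, o in enumerate(onsets_all):
        if np.any((o >= starts) & (o < ends)):
            cond[i] = ANTICIPATORY
        elif np.min(np.minimum(np.abs(o - starts), np.abs(o - ends))) > cfg.guard_s:
            cond[i] = NONANTICIPATORY

    keep = cond != "dropped"
    events = pd.DataFrame(
        {
            "subject": cfg.subject,
            "onset_s": onsets_all[keep],
            "condition": cond[keep],
            "correct": [
                bool(c) if k == ANTICIPATORY else None
                for c, k in zip(correct_draw[keep], cond[keep])
            ],
            "inhale_peak": peaks[keep],
            "inhale_duration_s": breaths["inhale_duration_s"].to_numpy()[keep],
            "onset_phase_rad": onset_phase[keep],
            "dmp_true": dmp_true[keep],
        }
    )
    n_ant = int((events["condition"] == ANTICIPATORY).sum())
    if n_ant != cfg.n_anticipatory:
        raise RuntimeError("internal packing error: anticipatory count mismatch")
    n_non = int((events["condition"] == NONANTICIPATORY).sum())
    if n_non < cfg.n_nonanticipatory:
        raise ValueError(
            f"infeasible packing: only {n_non} nonanticipatory breaths survive "
            f"the guard band but {cfg.n_nonanticipatory} were requested; "
            "increase gap_breaths"
        )

    truth = {
        "config": asdict(cfg),
        "trial_windows": windows,
        "anticipatory_onsets_s": ant_onsets,
        "anticipatory_onset_phase_rad": _wrap(targets),
        "n_dropped": int((~keep).sum()),
    }
    return SyntheticDataset(
        neural=neural,
        sampling_rate_hz=fs,
        respiration=RespirationTrace(resp, fs),
        events=events,
        truth=truth,
    )


def save_dataset(
    ds: SyntheticDataset, h5_path: str | Path, events_csv: str | Path | None = None
) -> None:
    """Write continuous traces (+ config) to HDF5 and events to CSV."""
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("neural", data=ds.neural)
        fh.create_dataset("respiration", data=ds.respiration.samples)
        fh.attrs["sampling_rate_hz"] = ds.sampling_rate_hz
        fh.attrs["config_json"] = json.dumps(ds.truth.get("config", {}))
        fh.create_dataset(
            "trial_windows", data=np.asarray(ds.truth.get("trial_windows", []))
        )
    if events_csv is not None:
        ds.events.to_csv(events_csv, index=False)


def load_dataset(
    h5_path: str | Path, events_csv: str | Path | None = None
) -> SyntheticDataset:
    """Round-trip counterpart of :func:`save_dataset`."""
    with h5py.File(h5_path, "r") as fh:
        neural = fh["neural"][:]
        resp = fh["respiration"][:]
        fs = float(fh.attrs["sampling_rate_hz"])
        config = json.loads(fh.attrs.get("config_json", "{}"))
        windows = [tuple(w) for w in fh["trial_windows"][:]] if "trial_windows" in fh else []
    events = pd.read_csv(events_csv) if events_csv is not None else pd.DataFrame()
    return SyntheticDataset(
        neural=neural,
        sampling_rate_hz=fs,
        respiration=RespirationTrace(resp, fs),
        events=events,
        truth={"config": config, "trial_windows": windows},
    )
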