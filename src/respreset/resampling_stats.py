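"""Resampling statistics: bootstraps, permutation nulls, and simple tests.

Implements the study's inferential machinery:

* percentage-based one-sided p-values from bootstrap difference
  distributions (the fraction of repetitions failing the hypothesized
  direction);
* the two DMP <-> accuracy bootstrap analyses (group by accuracy, compare
  DMP; group by DMP extremes, compare accuracy);
* surrogate-event permutation z-maps (random circular event shifts) and
  condition-label-shuffle z-maps, both FDR-corrected;
* Spearman/Pearson correlations, paired t tests, a 2x2 repeated-measures
  ANOVA, and the median-split inhale-peak comparison.

All resampling is driven by a numpy Generator and is bit-reproducible from
a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .phase_metrics import fdr_mask


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def percentage_p(diffs: np.ndarray, direction: str = "greater") -> float:
    """One-sided percentage-based p from a bootstrap difference distribution.

    p is the fraction of repetitions NOT satisfying the hypothesized
    direction; exact zeros count against the direction. 991 of 1000 values
    above zero gives p = 0.009.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("empty distribution")
    if direction == "greater":
        satisfied = diffs > 0
    elif direction == "less":
        satisfied = diffs < 0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(1.0 - satisfied.sum() / diffs.size)


@dataclass
class BootstrapResult:
    """A bootstrap difference distribution with its three p-values.

    ``p_percent`` is the exact fraction failing the direction (resolution
    1/n_boot; :meth:`p_percent_str` reports zero counts honestly as
    "< 1/n_boot"); ``p_normal`` converts mean/SD of the distribution to a
    one-sided normal p; ``p_sign`` is an exact binomial sign test on the
    signs of the differences.
    """

    diffs: np.ndarray
    n_boot: int
    direction: str
    p_percent: float
    p_normal: float
    p_sign: float
    seed: int | None = None

    def p_percent_str(self) -> str:
        if self.p_percent < 1.0 / self.n_boot:
            return f"< {1.0 / self.n_boot:g}"
        return f"{self.p_percent:g}"


def _finish_bootstrap(diffs, n_boot, direction, seed) -> BootstrapResult:
    p_pct = percentage_p(diffs, direction)
    sd = np.std(diffs, ddof=1)
    z = np.mean(diffs) / sd if sd > 0 else np.inf * np.sign(np.mean(diffs))
    p_norm = float(st.norm.sf(z)) if direction == "greater" else float(st.norm.cdf(z))
    signs = np.sign(diffs)
    n_pos = int((signs > 0).sum())
    n_nonzero = int((signs != 0).sum())
    if n_nonzero == 0:
        p_sign = 1.0
    else:
        alt = "greater" if direction == "greater" else "less"
        p_sign = float(st.binomtest(n_pos, n_nonzero, 0.5, alternative=alt).pvalue)
    return BootstrapResult(
        diffs=np.asarray(diffs), n_boot=n_boot, direction=direction,
        p_percent=p_pct, p_normal=p_norm, p_sign=p_sign, seed=seed,
    )


def bootstrap_dmp_by_accuracy(
    dmp_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    resample_size: int | None = None,
) -> BootstrapResult:
    """Bootstrap the DMP difference between incorrect and correct trials.

    Trials are grouped by accuracy; each repetition resamples each group
    with replacement (size = the group's own size unless ``resample_size``
    overrides) and takes mean(DMP incorrect) - mean(DMP correct), so a
    positive difference means correct trials were better aligned to the
    mean phase.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    tbl = dmp_table.dropna(subset=["correct"])
    correct = tbl.loc[tbl["correct"].astype(bool), "dmp"].to_numpy(dtype=float)
    incorrect = tbl.loc[~tbl["correct"].astype(bool), "dmp"].to_numpy(dtype=float)
    if correct.size == 0:
        raise ValueError("no correct trials")
    if incorrect.size == 0:
        raise ValueError("no incorrect trials")
    gen = _rng(seed, rng)
    n_c = resample_size or correct.size
    n_i = resample_size or incorrect.size
    mean_c = correct[gen.integers(0, correct.size, size=(n_boot, n_c))].mean(axis=1)
    mean_i = incorrect[gen.integers(0, incorrect.size, size=(n_boot, n_i))].mean(axis=1)
    return _finish_bootstrap(mean_i - mean_c, n_boot, "greater", seed)


def bootstrap_accuracy_by_dmp(
    dmp_table: pd.DataFrame,
    quantile: float = 0.20,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrap the accuracy difference between well- and poorly-aligned trials.

    Each repetition resamples all labeled trials with replacement, sorts by
    DMP, takes the smallest ``quantile`` fraction (well-aligned) and the
    largest (poorly aligned), and differences their percent-correct, so a
    positive value means aligned trials were more accurate.
    """
    tbl = dmp_table.dropna(subset=["correct"])
    d = tbl["dmp"].to_numpy(dtype=float)
    c = tbl["correct"].astype(bool).to_numpy()
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 labeled trials")
    k = int(np.floor(quantile * n))
    if k < 2:
        raise ValueError("quantile groups would hold fewer than 2 trials")
    gen = _rng(seed, rng)
    idx = gen.integers(0, n, size=(n_boot, n))
    order = np.argsort(d[idx], axis=1, kind="stable")
    resampled_correct = np.take_along_axis(c[idx], order, axis=1)
    acc_well = resampled_correct[:, :k].mean(axis=1)
    acc_poor = resampled_correct[:, -k:].mean(axis=1)
    return _finish_bootstrap(acc_well - acc_poor, n_boot, "greater", seed)


@dataclass
class SurrogateDistribution:
    """Observed statistic vs. a permutation null, summarized bin-wise.

    ``z`` is (observed - null mean)/null SD; ``p`` the two-sided normal
    p-value; ``fdr_mask`` the FDR-corrected significance mask. The null is
    summarized by its running mean/SD rather than stored wholesale.
    """

    observed: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_std: np.ndarray
    z: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    n_perm: int


def _zmap_from_null(observed, null_mean, null_sq_mean, n_perm, fdr_q):
    var = np.maximum(null_sq_mean - null_mean**2, 0.0) * n_perm / max(n_perm - 1, 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - null_mean) / sd, 0.0)
    p = 2.0 * st.norm.sf(np.abs(z))
    mask = fdr_mask(p, q=fdr_q)
    return SurrogateDistribution(observed, null_mean, sd, z, p, mask, n_perm)


def surrogate_event_zmap(
    power: np.ndarray,
    fs: float,
    events_s: np.ndarray,
    window: tuple[float, float],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_shift_s: float | None = None,
    fdr_q: float = 0.05,
) -> SurrogateDistribution:
    """Surrogate-event z-map for event-locked power.

    The observed map is the event-averaged power over ``window``. Each
    permutation shifts every event independently by a uniform random amount
    (circular over the recording, at least ``min_shift_s``, default one
    epoch length), destroying event-locking while preserving the marginal
    signal; the z-map standardizes the observed map against the resulting
    null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    power = np.atleast_2d(np.asarray(power, dtype=float))
    n = power.shape[-1]
    w0, w1 = window
    n_samp = int(round((w1 - w0) * fs))
    if min_shift_s is None:
        min_shift_s = w1 - w0
    min_shift = int(round(min_shift_s * fs))
    if n <= 2 * min_shift:
        raise ValueError("recording too short to admit the required shifts")
    starts = np.round((np.asarray(events_s, dtype=float) + w0) * fs).astype(int)
    if np.any(starts < 0) or np.any(starts + n_samp > n):
        raise ValueError("events with the window do not fit inside the recording")
    offs = np.arange(n_samp)

    observed = power[:, starts[:, None] + offs[None, :]].mean(axis=1)
    gen = _rng(seed, rng)
    null_mean = np.zeros_like(observed)
    null_sq = np.zeros_like(observed)
    for _ in range(n_perm):
        shifts = gen.integers(min_shift, n - min_shift, size=starts.size)
        s = (starts + shifts) % n
        surr = power[:, (s[:, None] + offs[None, :]) % n].mean(axis=1)
        null_mean += surr
        null_sq += surr**2
    null_mean /= n_perm
    null_sq /= n_perm
    return _zmap_from_null(observed, null_mean, null_sq, n_perm, fdr_q)


def label_shuffle_zmap(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    fdr_q: float = 0.05,
) -> SurrogateDistribution:
    """Condition-label-shuffle z-map for a power difference.

    The observed map is mean(A) - mean(B) over per-trial power epochs; the
    null relabels the pooled epochs preserving group sizes.
    """
    a = np.asarray(epochs_a, dtype=float)
    b = np.asarray(epochs_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("condition epochs live on different time/frequency grids")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 epochs per condition")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    n_a = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    total = pooled.sum(axis=0)
    n = pooled.shape[0]
    observed = a.mean(axis=0) - b.mean(axis=0)
    gen = _rng(seed, rng)
    null_mean = np.zeros_like(observed)
    null_sq = np.zeros_like(observed)
    flat = pooled.reshape(n, -1)
    for _ in range(n_perm):
        pick = gen.permutation(n)[:n_a]
        sum_a = flat[pick].sum(axis=0).reshape(observed.shape)
        diff = sum_a / n_a - (total - sum_a) / (n - n_a)
        null_mean += diff
        null_sq += diff**2
    null_mean /= n_perm
    null_sq /= n_perm
    return _zmap_from_null(observed, null_mean, null_sq, n_perm, fdr_q)


@dataclass
class CorrelationResult:
    spearman_r: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    n: int


def correlate(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman (average ranks) and Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    sr = st.spearmanr(x, y)
    pr = st.pearsonr(x, y)
    return CorrelationResult(
        float(sr.statistic), float(sr.pvalue), float(pr.statistic), float(pr.pvalue),
        int(x.size),
    )


def paired_tests(values_a: np.ndarray, values_b: np.ndarray):
    """Two-tailed paired t test; returns (t, df, p).

    Zero-variance differences (e.g. identical inputs) are rejected
    explicitly rather than returning an undefined statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = st.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


@dataclass
class RMAnovaResult:
    """2x2 within-subject ANOVA: F and p for both main effects and the interaction."""

    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_interaction: float
    p_interaction: float
    df: tuple[int, int]


def rm_anova_2x2(values: np.ndarray) -> RMAnovaResult:
    """Two-way repeated-measures ANOVA on a (subject, A-level, B-level) array.

    With two levels per factor each effect reduces to a one-sample t test
    on the per-subject contrast (F = t^2 with df = (1, n-1)); the full
    within-subject sums-of-squares decomposition gives the same values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape[1:] != (2, 2):
        raise ValueError("expected shape (n_subjects, 2, 2)")
    if np.any(~np.isfinite(v)):
        raise ValueError("missing cells in the repeated-measures design")
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    def contrast_f(d):
        sd = np.std(d, ddof=1)
        if sd == 0:
            return 0.0 if np.allclose(np.mean(d), 0) else np.inf
        t = np.mean(d) / (sd / np.sqrt(n))
        return float(t**2)

    d_a = v[:, 1, :].mean(axis=1) - v[:, 0, :].mean(axis=1)
    d_b = v[:, :, 1].mean(axis=1) - v[:, :, 0].mean(axis=1)
    d_ab = (v[:, 1, 1] - v[:, 1, 0]) - (v[:, 0, 1] - v[:, 0, 0])
    f_a, f_b, f_ab = contrast_f(d_a), contrast_f(d_b), contrast_f(d_ab)
    df = (1, n - 1)
    p = lambda f: float(st.f.sf(f, *df)) if np.isfinite(f) else 0.0
    return RMAnovaResult(f_a, p(f_a), f_b, p(f_b), f_ab, p(f_ab), df)


@dataclass
class MedianSplitResult:
    """Per-subject inhale peaks for well- vs poorly-aligned trials + group test."""

    per_subject: pd.DataFrame
    t: float
    df: int
    p: float
    skipped_subjects: list = field(default_factory=list)


def median_split_compare(
    dmp_table: pd.DataFrame, value_col: str = "inhale_peak"
) -> MedianSplitResult:
    """Median-split trials by DMP within subject and compare inhale peaks.

    For each subject the trials are split at the DMP median (with odd
    counts, the median trial is excluded); the group-level comparison is a
    paired t test of the per-subject mean peaks for small-DMP vs large-DMP
    halves. Subjects with fewer than 4 trials are skipped with a warning.
    """
    import warnings

    rows = []
    skipped = []
    for subject, grp in dmp_table.groupby("subject"):
        if len(grp) < 4:
            skipped.append(subject)
            warnings.warn(
                f"subject {subject!r} has fewer than 4 trials; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        g = grp.sort_values("dmp", kind="stable").reset_index(drop=True)
        m = len(g)
        half = m // 2
        low = g.iloc[:half]
        high = g.iloc[m - half :]  # odd counts: middle trial excluded
        rows.append(
            (subject, low[value_col].mean(), high[value_col].mean(), m)
        )
    per_subject = pd.DataFrame(
        rows, columns=["subject", "small_dmp_mean", "large_dmp_mean", "n_trials"]
    )
    if len(per_subject) < 3:
        raise ValueError("fewer than 3 subjects with enough trials")
    t, df, p = paired_tests(
        per_subject["small_dmp_mean"].to_numpy(),
        per_subject["large_dmp_mean"].to_numpy(),
    )
    return MedianSplitResult(per_subject, t, df, p, skipped)
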