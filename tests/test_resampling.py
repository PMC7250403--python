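"""Bootstraps, permutation z-maps, correlations, paired tests, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from respreset import resampling_stats as rs


class TestPercentageP:
    def test_half_positive(self):
        diffs = np.concatenate([np.ones(500), -np.ones(500)])
        assert rs.percentage_p(diffs) == pytest.approx(0.5)

    def test_zeros_count_against_direction(self):
        diffs = np.concatenate([np.ones(8), np.zeros(2)])
        assert rs.percentage_p(diffs) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.percentage_p(np.array([]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        hst.lists(
            hst.floats(-5, 5, allow_nan=False).filter(lambda v: v != 0.0),
            min_size=1,
            max_size=200,
        )
    )
    def test_directional_complementarity(self, diffs):
        d = np.asarray(diffs)
        p_g = rs.percentage_p(d, "greater")
        p_l = rs.percentage_p(-d, "less")
        assert p_g == pytest.approx(p_l, abs=1e-12)
        # with no exact zeros the satisfying counts are complementary
        assert rs.percentage_p(d, "greater") + rs.percentage_p(d, "less") == (
            pytest.approx(1.0 + (d == 0).mean() if (d == 0).any() else 1.0)
        )


class TestBootstrapDMPByAccuracy:
    def _table(self, dmp_correct, dmp_incorrect):
        return pd.DataFrame(
            {
                "dmp": np.concatenate([dmp_correct, dmp_incorrect]),
                "correct": [True] * len(dmp_correct) + [False] * len(dmp_incorrect),
            }
        )

    def test_full_separation(self):
        tbl = self._table(np.zeros(20), np.full(20, np.pi))
        res = rs.bootstrap_dmp_by_accuracy(tbl, n_boot=1000, seed=0)
        assert np.allclose(res.diffs, np.pi)
        assert res.p_percent == 0.0
        assert res.p_percent_str() == "< 0.001"

    def test_null_calibration(self, rng):
        # random labels on a common DMP pool: rejection rate at 0.05 is
        # 0.05 +- 0.02 over repeated runs
        hits = 0
        n_runs = 400
        for i in range(n_runs):
            d = rng.uniform(0, np.pi, 40)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            tbl = pd.DataFrame({"dmp": d, "correct": labels})
            res = rs.bootstrap_dmp_by_accuracy(tbl, n_boot=200, rng=rng)
            hits += res.p_percent < 0.05
        assert hits / n_runs == pytest.approx(0.05, abs=0.025)

    def test_seed_reproducible(self):
        tbl = self._table(np.linspace(0, 1, 15), np.linspace(1, 2, 9))
        a = rs.bootstrap_dmp_by_accuracy(tbl, n_boot=200, seed=3)
        b = rs.bootstrap_dmp_by_accuracy(tbl, n_boot=200, seed=3)
        assert np.array_equal(a.diffs, b.diffs)

    def test_empty_group_named(self):
        tbl = self._table(np.linspace(0, 1, 5), [])
        with pytest.raises(ValueError, match="incorrect"):
            rs.bootstrap_dmp_by_accuracy(tbl, seed=0)


class TestBootstrapAccuracyByDMP:
    def test_deterministic_rule_full_separation(self):
        n = 50
        dmp = np.linspace(0, np.pi, n)
        correct = dmp < np.median(dmp)
        tbl = pd.DataFrame({"dmp": dmp, "correct": correct})
        res = rs.bootstrap_accuracy_by_dmp(tbl, n_boot=500, seed=1)
        assert np.allclose(res.diffs, 1.0)

    def test_independence_gives_zero_mean(self, rng):
        means = []
        for i in range(300):
            tbl = pd.DataFrame(
                {
                    "dmp": rng.uniform(0, np.pi, 60),
                    "correct": rng.random(60) < 0.7,
                }
            )
            res = rs.bootstrap_accuracy_by_dmp(tbl, n_boot=50, rng=rng)
            means.append(res.diffs.mean())
        assert abs(np.mean(means)) < 0.02

    def test_too_few_trials_rejected(self):
        tbl = pd.DataFrame({"dmp": np.arange(8.0), "correct": [True] * 8})
        with pytest.raises(ValueError):
            rs.bootstrap_accuracy_by_dmp(tbl, seed=0)


class TestSurrogateEventZmap:
    def test_null_calibration(self, rng):
        power = rng.standard_normal((3, 60_000)) ** 2
        events = np.linspace(20.0, 90.0, 12)
        sd = rs.surrogate_event_zmap(
            power, 500.0, events, (-1.0, 1.0), n_perm=300, rng=rng
        )
        assert np.mean(np.abs(sd.z) > 1.96) == pytest.approx(0.05, abs=0.04)

    def test_event_locked_burst_detected(self, rng):
        fs = 200.0
        power = rng.standard_normal((1, int(200 * fs))) ** 2
        events = np.arange(20.0, 180.0, 10.0)
        for t in events:
            i = int(t * fs)
            power[0, i : i + int(0.5 * fs)] += 20.0
        sd = rs.surrogate_event_zmap(power, fs, events, (-1.0, 1.0), n_perm=200, seed=0)
        taxis = -1.0 + np.arange(sd.z.shape[-1]) / fs
        burst = (taxis >= 0.05) & (taxis < 0.45)
        assert np.all(sd.z[0, burst] > 3.0)
        assert sd.fdr_mask[0, burst].all()

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            rs.surrogate_event_zmap(
                rng.standard_normal((1, 10_000)), 500.0, [10.0], (-1.0, 1.0), n_perm=0
            )

    def test_seed_reproducible(self, rng):
        power = rng.standard_normal((2, 40_000)) ** 2
        a = rs.surrogate_event_zmap(power, 500.0, [30.0, 50.0], (-1.0, 1.0), n_perm=50, seed=5)
        b = rs.surrogate_event_zmap(power, 500.0, [30.0, 50.0], (-1.0, 1.0), n_perm=50, seed=5)
        assert np.array_equal(a.z, b.z)


class TestLabelShuffleZmap:
    def test_identical_trials_give_zero(self, rng):
        a = rng.standard_normal((10, 4, 20))
        sd = rs.label_shuffle_zmap(a, a.copy(), n_perm=100, seed=0)
        assert np.allclose(sd.observed, 0.0)
        # the null has nonzero spread, so z is only approximately zero
        assert np.all(np.abs(sd.z) < 0.5)
        assert not sd.fdr_mask.any()

    def test_constant_offset_detected(self, rng):
        a = rng.standard_normal((15, 3, 10))
        b = a + 3.0
        sd = rs.label_shuffle_zmap(a, b, n_perm=300, seed=1)
        assert sd.fdr_mask.all()
        assert np.all(sd.z < 0)  # A - B is negative everywhere

    def test_null_rejection_rate(self, rng):
        rejected = []
        for i in range(100):
            a = rng.standard_normal((8, 2, 10))
            b = rng.standard_normal((8, 2, 10))
            sd = rs.label_shuffle_zmap(a, b, n_perm=200, rng=rng)
            rejected.append(sd.fdr_mask.mean())
        assert np.mean(rejected) <= 0.05

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            rs.label_shuffle_zmap(
                rng.standard_normal((5, 3, 10)), rng.standard_normal((5, 3, 11))
            )


class TestCorrelate:
    def test_linear_relationship(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = rs.correlate(x, 2 * x + 1)
        assert res.spearman_r == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = rs.correlate(x, np.exp(x))
        assert res.spearman_r == pytest.approx(1.0)
        assert res.pearson_r < 1.0

    def test_hand_computed_rank_correlation(self):
        # ranks give d = (-1, 1, -1, 1), sum d^2 = 4, rho = 1 - 24/60 = 0.6
        res = rs.correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.spearman_r == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rs.correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPairedTests:
    def test_identical_inputs_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            rs.paired_tests(a, a)

    def test_hand_computed_t(self):
        a = np.array([2.0, 4.0, 6.0])
        t, df, p = rs.paired_tests(a, a - np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        t1, _, p1 = rs.paired_tests(a, b)
        t2, _, p2 = rs.paired_tests(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestRMAnova:
    def test_all_cells_equal(self):
        v = np.full((5, 2, 2), 3.0)
        res = rs.rm_anova_2x2(v)
        assert res.f_a == res.f_b == res.f_interaction == 0.0

    def test_pure_main_effect(self, rng):
        n = 8
        v = rng.standard_normal((n, 1, 1)) + np.zeros((n, 2, 2))
        v[:, 1, :] += 2.0  # main effect of A only
        v += 0.05 * rng.standard_normal((n, 2, 2))
        res = rs.rm_anova_2x2(v)
        assert res.f_a > 100
        assert res.f_interaction < 10

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 9
        v = rng.standard_normal((n, 2, 2))
        res = rs.rm_anova_2x2(v)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 4),
                "A": np.tile([0, 0, 1, 1], n),
                "B": np.tile([0, 1, 0, 1], n),
                "y": v.reshape(-1),
            }
        )
        ref = pingouin.rm_anova(
            data=df, dv="y", within=["A", "B"], subject="subject", detailed=True
        )
        f_ref = ref.set_index("Source")["F"]
        assert res.f_a == pytest.approx(float(f_ref["A"]), rel=1e-6)
        assert res.f_b == pytest.approx(float(f_ref["B"]), rel=1e-6)
        assert res.f_interaction == pytest.approx(float(f_ref["A * B"]), rel=1e-6)

    def test_subject_order_irrelevant(self, rng):
        v = rng.standard_normal((7, 2, 2))
        res1 = rs.rm_anova_2x2(v)
        res2 = rs.rm_anova_2x2(v[::-1])
        assert res1.f_interaction == pytest.approx(res2.f_interaction)

    def test_missing_cells_rejected(self):
        v = np.full((4, 2, 2), 1.0)
        v[0, 0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rs.rm_anova_2x2(v)


class TestMedianSplit:
    def _table(self, rng, n_subj=6, n_trials=20, coupled=False):
        rows = []
        for s in range(n_subj):
            d = rng.uniform(0, np.pi, n_trials)
            peaks = rng.uniform(0.8, 1.2, n_trials)
            if coupled:
                peaks = np.where(d < np.median(d), 2.0 * peaks, peaks)
            for di, pi_ in zip(d, peaks):
                rows.append((f"s{s}", di, pi_))
        return pd.DataFrame(rows, columns=["subject", "dmp", "inhale_peak"])

    def test_independent_peaks_nonsignificant(self, rng):
        sig = 0
        for i in range(20):
            res = rs.median_split_compare(self._table(rng))
            sig += res.p < 0.05
        assert sig <= 2  # mirrors a null outcome in >= 90% of runs

    def test_coupled_peaks_significant(self, rng):
        res = rs.median_split_compare(self._table(rng, coupled=True))
        assert res.p < 0.001
        assert (res.per_subject["small_dmp_mean"] > res.per_subject["large_dmp_mean"]).all()

    def test_small_subject_skipped(self, rng):
        tbl = self._table(rng)
        tbl = pd.concat(
            [tbl, pd.DataFrame(
                {"subject": ["tiny"] * 3, "dmp": [0.1, 0.2, 0.3], "inhale_peak": [1.0] * 3}
            )],
            ignore_index=True,
        )
        with pytest.warns(RuntimeWarning, match="tiny"):
            res = rs.median_split_compare(tbl)
        assert "tiny" in res.skipped_subjects
        assert "tiny" not in set(res.per_subject["subject"])
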