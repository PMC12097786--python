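"""Selectivity analyses: window tests, cluster scans, population nulls."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sstats

from subneuro.config import NeuronProfile, TaskConfig
from subneuro.errors import ValidationError
from subneuro.rates import RateMatrix
from subneuro.selectivity import (
    cluster_scan,
    covariate_control_scan,
    cue_selectivity,
    overlap_test,
    perception_selectivity,
    population_count_test,
    proportion_difference_test,
    sensory_selectivity,
    task_selectivity,
)


def _rm(rates, t0_ms=-300, alignment="stimulus"):
    rates = np.atleast_2d(np.asarray(rates, float))
    t = np.arange(t0_ms, t0_ms + rates.shape[1])
    return RateMatrix(alignment, t, rates, np.arange(rates.shape[0]))


class TestCueSelectivity:
    def test_all_ties_no_evidence(self):
        pre = np.full(25, 4.0)
        res = cue_selectivity(pre, pre)
        assert res.eligible and not res.flag and res.p == 1.0

    def test_18_of_20_decreases_exact_binomial(self):
        """18/20 sign-consistent decreases: p = 2*P(X>=18 | B(20, .5))."""
        pre = np.full(20, 10.0)
        post = np.concatenate([np.full(18, 8.0), np.full(2, 12.0)])
        res = cue_selectivity(pre, post)
        expected = 2 * sum(sstats.binom.pmf(k, 20, 0.5) for k in range(18, 21))
        assert res.p == pytest.approx(expected)
        assert res.p == pytest.approx(0.000402, abs=5e-6)
        assert res.flag and res.direction == "decrease"

    def test_under_20_trials_ineligible(self):
        res = cue_selectivity(np.ones(19), np.zeros(19))
        assert not res.eligible and "19" in res.reason

    def test_type_one_rate_calibrated(self, rng):
        """Null Poisson counts: flag rate stays near the exact-test level."""
        flags = 0
        for _ in range(400):
            pre = rng.poisson(5, 40).astype(float)
            post = rng.poisson(5, 40).astype(float)
            flags += cue_selectivity(pre, post).flag
        rate = flags / 400
        assert rate <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 400)


class TestTaskSelectivity:
    def test_identical_rates_p_one(self):
        x = np.linspace(5, 15, 30)
        res = task_selectivity(x, x)
        assert res.eligible and not res.flag and res.p == pytest.approx(1.0)

    def test_small_sample_matches_sign_flip_enumeration(self, rng):
        """8 paired trials: p equals the exhaustive 2^8 sign-flip oracle."""
        base = rng.normal(10, 2, 8)
        win = rng.normal(8, 2, 8)
        res = task_selectivity(base, win, min_trials=2)
        d = win - base
        obs = abs(d.mean())
        null = [
            abs(np.mean([s * v for s, v in zip(signs, d)]))
            for signs in product((1, -1), repeat=8)
        ]
        oracle = np.mean(np.array(null) >= obs - 1e-12)
        assert res.p == pytest.approx(oracle)

    def test_power_for_halved_rate(self, rng):
        """task gain 0.5 at 20 Hz baseline, 40 trials: reliably detected
        with direction decrease."""
        hits = 0
        for _ in range(30):
            base = rng.poisson(10, 40) / 0.5  # 500-ms baseline at 20 Hz
            win = rng.poisson(20, 40) / 2.0  # 2-s window at 10 Hz
            res = task_selectivity(base, win, n_perm=500, seed=rng)
            hits += res.flag and res.direction == "decrease"
        assert hits >= 29


class TestClusterScan:
    def test_identical_conditions_no_cluster(self, rng):
        a = rng.normal(10, 1, size=(30, 700))
        t = np.arange(-300, 400)
        assert cluster_scan(a, a.copy(), t, test="ranksum") is None

    def test_constructed_100ms_window_recovered(self, rng):
        """A deterministic 100-ms separation yields one cluster with bounds
        near the construction."""
        t = np.arange(-300, 400)
        a = rng.normal(10, 1, size=(30, 700))
        b = rng.normal(10, 1, size=(30, 700))
        a[:, (t >= 150) & (t < 250)] += 8.0
        c = cluster_scan(a, b, t, test="ranksum")
        assert c is not None
        assert abs(c.start_ms - 150) <= 10 and abs(c.end_ms - 250) <= 10
        assert c.sign == "A>B"

    def test_60ms_separation_fails_duration_rule(self, rng):
        t = np.arange(-300, 400)
        a = rng.normal(10, 1, size=(30, 700))
        b = rng.normal(10, 1, size=(30, 700))
        a[:, (t >= 150) & (t < 210)] += 8.0
        assert cluster_scan(a, b, t, test="ranksum") is None

    def test_exactly_80ms_fails_strict_rule(self):
        """A run of exactly 80 ms is not 'above 80 ms' and is discarded."""
        t = np.arange(0, 400)
        a = np.tile(np.zeros(400), (25, 1))
        a[:, 100:180] = 5.0  # 80 samples -> 80 ms run, deterministic
        baseline = np.zeros(25)
        assert cluster_scan(a, baseline, t, test="signrank") is None
        a[:, 100:181] = 5.0  # 81 ms
        c = cluster_scan(a, baseline, t, test="signrank")
        assert c is not None and c.length_ms == 81

    def test_longest_cluster_kept_earliest_on_tie(self):
        t = np.arange(0, 400)
        a = np.tile(np.zeros(400), (25, 1))
        a[:, 10:110] = 5.0
        a[:, 200:300] = -5.0
        c = cluster_scan(a, np.zeros(25), t, test="signrank")
        assert (c.start_ms, c.end_ms) == (10, 110)
        assert c.sign == "increase"


class TestSensorySelectivity:
    def test_pure_drift_fully_cancelled(self):
        """Deterministic cue-locked drift leaves zero residual, hence no
        flag, after catch correction."""
        from subneuro.rates import catch_drift_correct

        t = np.arange(-500, 3000) / 1000
        drift = 12.0 + 1.5 * t
        stim = RateMatrix("cue", np.arange(-500, 3000), np.tile(drift, (25, 1)), np.arange(25))
        catch = RateMatrix("cue", np.arange(-500, 3000), np.tile(drift, (6, 1)), np.arange(6))
        corrected = catch_drift_correct(stim, catch, np.linspace(0.85, 2.4, 25))
        res = sensory_selectivity(corrected)
        assert res.eligible and not res.flag

    def test_injected_suppression_recovered_via_full_path(self):
        """sensory gain 0.3 at 200 ms for 130 ms, recovered end to end with
        latency error within one kernel SD."""
        from subneuro.behavior import apply_qc
        from subneuro.pipeline import analyze_neuron, prepare_neuron
        from subneuro.synth import simulate_session

        profile = NeuronProfile(
            baseline_rate=25.0,
            sensory_gain=0.3,
            sensory_latency=0.2,
            sensory_duration=0.13,
        )
        task = TaskConfig(n_trials=60)
        sess = simulate_session([profile], seed=101, task=task)
        trials = apply_qc(sess.trials)
        prep = prepare_neuron(trials, sess.spike_trains[0], sess.artifact_epochs, task)
        res = analyze_neuron(prep, seed=0)["sensory"]
        assert res.flag and res.direction == "decrease"
        assert abs(res.cluster.start_ms - 200) <= 40

    def test_effect_outside_400ms_window_ignored(self, rng):
        t = np.arange(-300, 700)
        rates = rng.normal(0, 0.5, size=(30, 1000))
        rates[:, (t >= 500) & (t < 620)] += 10.0
        rm = RateMatrix("stimulus", t, rates, np.arange(30))
        res = sensory_selectivity(rm)
        assert res.eligible and not res.flag

    def test_trial_gate(self):
        rm = _rm(np.zeros((10, 700)))
        res = sensory_selectivity(rm)
        assert not res.eligible


class TestPerceptionSelectivity:
    def test_copied_matrices_no_cluster(self, rng):
        x = rng.normal(10, 1, size=(15, 700))
        res = perception_selectivity(_rm(x), _rm(x.copy()))
        assert res.eligible and not res.flag

    def test_injected_suppression_flagged_with_direction(self, rng):
        t = np.arange(-300, 400)
        hit = rng.normal(10, 1, size=(20, 700))
        miss = rng.normal(10, 1, size=(20, 700))
        hit[:, (t >= 150) & (t < 270)] -= 6.0
        res = perception_selectivity(_rm(hit), _rm(miss))
        assert res.flag and res.direction == "miss>hit"
        assert abs(res.cluster.start_ms - 150) <= 15

    def test_gates(self):
        big, small = np.zeros((15, 700)), np.zeros((9, 700))
        assert not perception_selectivity(_rm(small), _rm(big)).eligible
        assert not perception_selectivity(_rm(big), _rm(small)).eligible


class TestPopulationCount:
    def test_observed_zero_p_one(self):
        pre = np.full(25, 5.0)
        items = [(pre, pre)] * 4
        res = population_count_test(items, "cue", n_perm=200, seed=0)
        assert res.observed_count == 0 and res.p == 1.0

    def test_task_exact_matches_joint_enumeration_oracle(self, rng):
        """2 neurons x 4 trials: the exact Poisson-binomial p equals a brute
        force over all 2^8 joint sign assignments."""
        items = [
            (rng.normal(10, 1, 4), rng.normal(7, 1, 4)),
            (rng.normal(10, 1, 4), rng.normal(10, 1, 4)),
        ]
        res = population_count_test(items, "task", seed=0)
        assert res.exact

        def neuron_flag(d, signs):
            flipped = d * np.array(signs)
            obs = abs(flipped.mean())
            null = [
                abs(np.mean(d * np.array(signs2) * np.array(signs)))
                for signs2 in product((1, -1), repeat=len(d))
            ]
            # inner exact p of the flipped data against its own flip null
            return np.mean(np.array(null) >= obs - 1e-12) < 0.05

        diffs = [win - base for base, win in items]
        observed = sum(neuron_flag(d, (1,) * len(d)) for d in diffs)
        counts = []
        for s1 in product((1, -1), repeat=4):
            for s2 in product((1, -1), repeat=4):
                counts.append(neuron_flag(diffs[0], s1) + neuron_flag(diffs[1], s2))
        oracle_p = np.mean(np.array(counts) >= observed)
        assert res.observed_count == observed
        assert res.p == pytest.approx(oracle_p)

    def test_perception_exact_matches_label_enumeration_oracle(self, rng):
        """2 neurons, 3+3 trials, tiny scan: exact p equals brute force over
        all C(6,3)^2 joint label assignments."""
        t_cols, min_len = 24, 10
        items = []
        for shift in (4.0, 0.0):
            hit = rng.normal(0, 1, size=(3, t_cols)) + shift
            miss = rng.normal(0, 1, size=(3, t_cols))
            items.append((hit, miss))
        res = population_count_test(items, "perception", seed=0, min_len_ms=min_len)
        assert res.exact

        def flag(pooled, rows):
            a, b = pooled[list(rows)], pooled[[i for i in range(6) if i not in rows]]
            ps = np.array(
                [
                    sstats.mannwhitneyu(
                        a[:, j], b[:, j], alternative="two-sided",
                        method="asymptotic", use_continuity=False,
                    ).pvalue
                    for j in range(t_cols)
                ]
            )
            sig = ps < 0.05
            best = 0
            run = 0
            for s in sig:
                run = run + 1 if s else 0
                best = max(best, run)
            return best >= min_len + 1

        observed, qs = 0, []
        for hit, miss in items:
            pooled = np.vstack([hit, miss])
            flags = [flag(pooled, rows) for rows in combinations(range(6), 3)]
            observed += flags[0]
            qs.append(np.mean(flags))
        # joint p over the product space = tail of the Bernoulli convolution
        pmf = np.array([1.0])
        for q in qs:
            pmf = np.convolve(pmf, [1 - q, q])
        oracle_p = pmf[observed:].sum()
        assert res.observed_count == observed
        assert res.p == pytest.approx(oracle_p)

    def test_strong_cohort_small_p(self, rng):
        """10/12 neurons with a strong paired effect: population p at the
        Monte-Carlo floor."""
        items = []
        for i in range(12):
            base = rng.normal(10, 1, 30)
            win = base - (5.0 if i < 10 else 0.0) + rng.normal(0, 1, 30)
            items.append((base, win))
        res = population_count_test(items, "task", n_perm=500, seed=3)
        assert res.observed_count >= 10
        assert res.p == pytest.approx(1 / 501)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValidationError):
            population_count_test([(np.ones(5), np.ones(5))], "task")


class TestProportionAndOverlap:
    def test_proportion_enumeration_oracle(self):
        """6 neurons, 3 per region, flags 1,1,1,0,0,0: p matches the 20
        region assignments."""
        flags = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        regions = np.array(["STN"] * 3 + ["thalamus"] * 3)
        p = proportion_difference_test(flags, regions)
        diffs = []
        for idx in combinations(range(6), 3):
            a = np.zeros(6, bool)
            a[list(idx)] = True
            diffs.append(abs(flags[a].mean() - flags[~a].mean()))
        obs = abs(1.0 - 0.0)
        oracle = np.mean(np.array(diffs) >= obs - 1e-12)
        assert p == pytest.approx(oracle) == pytest.approx(2 / 20)

    def test_identical_proportions_p_one(self):
        flags = np.array([1, 0, 1, 0], dtype=bool)
        regions = np.array(["STN", "STN", "thalamus", "thalamus"])
        assert proportion_difference_test(flags, regions) == pytest.approx(1.0)

    def test_all_flagged_p_one(self):
        flags = np.ones(10, dtype=bool)
        regions = np.array(["STN"] * 5 + ["thalamus"] * 5)
        assert proportion_difference_test(flags, regions) == pytest.approx(1.0)

    def test_overlap_identical_flags_significant(self):
        flags = np.zeros(40, dtype=bool)
        flags[:4] = True
        assert overlap_test(flags, flags.copy()) <= 0.01

    def test_overlap_enumeration_oracle(self, rng):
        a = np.array([1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
        b = np.array([1, 0, 0, 1, 1, 0, 0, 0], dtype=bool)
        p = overlap_test(a, b)
        obs = np.sum(a & b)
        null = [
            np.sum(a[list(idx)]) for idx in combinations(range(8), int(b.sum()))
        ]
        oracle = np.mean(np.array(null) >= obs - 1e-12)
        assert p == pytest.approx(oracle)

    def test_disjoint_flags_large_p(self):
        a = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        b = np.array([0, 0, 1, 1, 0, 0, 0, 0], dtype=bool)
        assert overlap_test(a, b) > 0.5

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError):
            overlap_test(np.ones(4, bool), np.ones(5, bool))


class TestCovariateControl:
    def test_amplitude_independent_neuron_clean(self, rng):
        rates = rng.normal(10, 1, size=(44, 700))
        rm = _rm(rates)
        values = rng.uniform(0.5, 1.5, 44)
        res = covariate_control_scan(rm, values)
        assert res.eligible and not res.flag

    def test_amplitude_coding_neuron_flagged(self, rng):
        values = np.linspace(0.5, 1.5, 44)
        rates = rng.normal(0, 0.3, size=(44, 700)) + 8.0 * values[:, None]
        res = covariate_control_scan(_rm(rates), values)
        assert res.flag and res.direction == "high>low"

    def test_onset_ramp_confound_separated(self, rng):
        """An onset-hazard ramp is caught by the onset split but not by a
        hit/miss contrast with labels balanced over onsets."""
        onsets = np.linspace(0.8, 2.6, 40)
        rates = rng.normal(0, 0.4, size=(40, 700)) + 3.0 * onsets[:, None]
        rm = _rm(rates)
        assert covariate_control_scan(rm, onsets).flag
        labels = np.tile([True, False], 20)  # balanced across the ramp
        res = perception_selectivity(
            RateMatrix("stimulus", rm.time_ms, rates[labels], np.arange(20)),
            RateMatrix("stimulus", rm.time_ms, rates[~labels], np.arange(20)),
        )
        assert not res.flag

    def test_gate_on_half_sizes(self, rng):
        rm = _rm(rng.normal(0, 1, size=(30, 700)))
        res = covariate_control_scan(rm, rng.uniform(0, 1, 30))
        assert not res.eligible
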