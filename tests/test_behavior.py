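"""Outcome labeling, sliding hit-rate filter, eligibility, behavioral tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subneuro.behavior import (
    CR,
    FA,
    HIT,
    MISS,
    apply_qc,
    behavior_summary,
    covariate_permutation_test,
    filter_trials,
    group_rate_comparison,
    label_outcomes,
    session_eligibility,
    sliding_hit_rate,
)
from subneuro.errors import ValidationError
from conftest import make_trials


def _toy_table(stim_flags, reports):
    return pd.DataFrame(
        {
            "index": range(len(reports)),
            "cue_onset": np.arange(len(reports), dtype=float),
            "cue_offset": np.arange(len(reports)) + 0.3,
            "stim_onset": [i + 1.0 if s else np.nan for i, s in enumerate(stim_flags)],
            "respond_cue": np.arange(len(reports)) + 3.0,
            "report": reports,
        }
    )


class TestLabelOutcomes:
    def test_ten_trial_hand_count(self):
        """3 catch trials among 10; outcome counts match hand enumeration."""
        stim = [1, 1, 0, 1, 1, 0, 1, 1, 0, 1]
        reports = ["yes", "no", "yes", "no", "yes", "no", "yes", "no", "no", "yes"]
        out = label_outcomes(_toy_table(stim, reports))
        counts = out.outcome.value_counts()
        assert counts[HIT] == 4 and counts[MISS] == 3
        assert counts[FA] == 1 and counts[CR] == 2

    def test_missing_report_rejected(self):
        table = _toy_table([1, 1], ["yes", None])
        with pytest.raises(ValidationError):
            label_outcomes(table)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.sampled_from(["yes", "no"])),
            min_size=1,
            max_size=30,
        )
    )
    def test_partition_exhaustive_and_exclusive(self, rows):
        stim = [r[0] for r in rows]
        reports = [r[1] for r in rows]
        out = label_outcomes(_toy_table(stim, reports))
        assert out.outcome.isin([HIT, MISS, CR, FA]).all()
        for _, row in out.iterrows():
            present = np.isfinite(row.stim_onset)
            expected = {
                (True, "yes"): HIT,
                (True, "no"): MISS,
                (False, "yes"): FA,
                (False, "no"): CR,
            }[(present, row.report)]
            assert row.outcome == expected


def _mirror_oracle(x, window):
    """Independent sliding-mean oracle with explicit mirror construction."""
    half = (window - 1) // 2
    ext = list(x[1 : half + 1][::-1]) + list(x) + list(x[-half - 1 : -1][::-1])
    return np.array(
        [np.mean(ext[i : i + window]) for i in range(len(x))]
    )


class TestSlidingHitRate:
    def test_all_hits_constant_one(self):
        assert np.allclose(sliding_hit_rate(np.ones(20)), 1.0)

    def test_alternating_sequence_matches_mirror_oracle(self):
        x = np.tile([1, 0], 10)
        trace = sliding_hit_rate(x, 11)
        interior = trace[5:-5]
        assert set(np.round(interior * 11).astype(int)) <= {5, 6}
        np.testing.assert_allclose(trace, _mirror_oracle(x, 11))

    def test_window_one_is_identity(self):
        x = np.array([1, 0, 0, 1, 1])
        np.testing.assert_array_equal(sliding_hit_rate(x, 1), x.astype(float))

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, size=rng.integers(11, 60))
            np.testing.assert_allclose(sliding_hit_rate(x, 11), _mirror_oracle(x, 11))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValidationError):
            sliding_hit_rate(np.ones(5), 11)
        with pytest.raises(ValidationError):
            sliding_hit_rate(np.ones(20), 10)  # even window


class TestFilter:
    def test_boundaries_are_open(self):
        trace = np.array([0.25, 0.75, 6 / 11, 0.26, 0.74])
        mask = filter_trials(trace)
        np.testing.assert_array_equal(mask, [False, False, True, True, True])

    def test_all_miss_run_removed_flanks_kept(self):
        """A 15-trial all-miss run is excised; balanced flanks survive."""
        x = np.concatenate([np.tile([1, 0], 15), np.zeros(15), np.tile([0, 1], 15)])
        trace = sliding_hit_rate(x, 11)
        mask = filter_trials(trace)
        oracle = filter_trials(_mirror_oracle(x, 11))
        np.testing.assert_array_equal(mask, oracle)
        assert not mask[35:40].any()  # deep inside the miss run
        assert mask[:25].all() and mask[-25:].all()

    def test_filter_idempotent_on_fixed_trace(self):
        trace = np.linspace(0, 1, 50)
        mask = filter_trials(trace)
        np.testing.assert_array_equal(mask & filter_trials(trace), mask)


class TestEligibility:
    def test_boundary_cases(self):
        outcomes = np.array([HIT] * 10 + [MISS] * 10)
        assert session_eligibility(outcomes, np.ones(20, bool))
        outcomes = np.array([HIT] * 9 + [MISS] * 30)
        assert not session_eligibility(outcomes, np.ones(39, bool))

    def test_cohort_discard_matches_per_session_oracle(self):
        """Mixed-quality cohort: kept flags equal an independent per-session
        re-derivation from the raw outcome sequences."""
        from subneuro.config import ObserverModel
        from subneuro.pipeline import simulate_cohort

        sessions = simulate_cohort(n_sessions=12, seed=33, low_quality_fraction=0.5)
        for sess in sessions:
            qc = apply_qc(sess.trials)
            kept = behavior_summary(qc).kept_session
            stim = qc[qc.outcome.isin([HIT, MISS])]
            trace = _mirror_oracle((stim.outcome == HIT).to_numpy(), 11)
            keep = (trace > 0.25) & (trace < 0.75)
            n_hit = int(((stim.outcome == HIT).to_numpy() & keep).sum())
            n_miss = int(((stim.outcome == MISS).to_numpy() & keep).sum())
            assert kept == (n_hit >= 10 and n_miss >= 10)

    def test_stationary_observer_rarely_discarded(self):
        from subneuro.pipeline import simulate_cohort

        sessions = simulate_cohort(n_sessions=20, seed=8, low_quality_fraction=0.0)
        kept = [behavior_summary(apply_qc(s.trials)).kept_session for s in sessions]
        assert np.mean(kept) > 0.9


class TestCovariatePermutation:
    def test_identical_groups_p_near_one(self):
        res = covariate_permutation_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_two == pytest.approx(1.0)

    def test_small_groups_match_enumeration_oracle(self):
        """Groups of 4 and 3: p equals brute-force over all 35 assignments."""
        x = [0.3, 1.2, 0.8, 0.5]
        y = [1.0, 0.9, 1.4]
        res = covariate_permutation_test(x, y)
        pooled = np.array(x + y)
        obs = np.mean(x) - np.mean(y)
        diffs = []
        for idx in combinations(range(7), 4):
            sel = np.zeros(7, bool)
            sel[list(idx)] = True
            diffs.append(pooled[sel].mean() - pooled[~sel].mean())
        oracle = np.mean(np.abs(diffs) >= abs(obs) - 1e-12)
        assert res.method == "exact"
        assert res.p_two == pytest.approx(oracle)

    def test_separated_groups_extreme_p(self, rng):
        x = rng.normal(10, 1, 20)
        y = rng.normal(0, 1, 20)
        res = covariate_permutation_test(x, y, n_perm=1000, seed=1)
        assert res.p_two <= 0.002

    def test_p_bounded_below(self, rng):
        x = rng.normal(5, 1, 15)
        y = rng.normal(0, 1, 15)
        res = covariate_permutation_test(x, y, n_perm=200, seed=2)
        assert res.p_two >= 1 / 201

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            covariate_permutation_test([], [1.0])


class TestGroupComparison:
    def test_identical_groups(self):
        w, p = group_rate_comparison([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == pytest.approx(1.0)

    def test_separated_pairs_match_exact_enumeration(self):
        # complete separation with n=2,2: two-sided exact p = 2/C(4,2) = 1/3
        _, p = group_rate_comparison([0.1, 0.2], [0.8, 0.9])
        assert p == pytest.approx(1 / 3)

    def test_null_calibration_valid_p(self):
        """Under H0 the (discrete) p-values are valid: P(p <= a) <= a up to
        Monte-Carlo error, at every nominal level."""
        rng = np.random.default_rng(10)
        ps = np.array(
            [
                group_rate_comparison(rng.normal(0.5, 0.05, 8), rng.normal(0.5, 0.05, 9))[1]
                for _ in range(300)
            ]
        )
        for a in (0.01, 0.05, 0.1, 0.25, 0.5):
            mc = 2.58 * np.sqrt(a * (1 - a) / 300)
            assert np.mean(ps <= a) <= a + mc

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError):
            group_rate_comparison([0.1], [0.2, 0.3])
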