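"""Selectivity and movement scores, explained variance, onset lags."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from copingmanifold.session import IMMOBILITY, STRUGGLE
from copingmanifold.tuning import (classify_movement, classify_selectivity,
                                   ev_significance, movement_ev, movement_score,
                                   peth_lag, population_ev, score_session,
                                   ts_selectivity)


class TestTsSelectivity:
    def test_activity_only_during_suspension_scores_plus_one(self):
        assert ts_selectivity(np.zeros(50), np.r_[np.zeros(25), np.ones(25)]) == 1.0

    @pytest.mark.parametrize("base,ts,expected", [
        ([0, 0, 2, 2], [0, 2], 0.0),
        ([0, 0, 0, 4], [4, 4], 0.6),          # (1 - 0.25) / (1 + 0.25)
    ])
    def test_worked_examples(self, base, ts, expected):
        score = ts_selectivity(np.array(base, float), np.array(ts, float))
        assert score == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        """Score equals the definition computed step by step."""
        base, ts = rng.random(40), rng.random(25)
        both = np.concatenate([base, ts])
        scaled = (both - both.min()) / (both.max() - both.min())
        mb, mt = scaled[:40].mean(), scaled[40:].mean()
        assert ts_selectivity(base, ts) == pytest.approx((mt - mb) / (mt + mb))

    def test_antisymmetric_under_segment_swap(self, rng):
        base, ts = rng.random(30), rng.random(20)
        assert ts_selectivity(base, ts) == pytest.approx(-ts_selectivity(ts, base))

    def test_zero_denominator_flagged_not_zero(self):
        # transient mode with no transients anywhere
        score = ts_selectivity(np.zeros(10), np.zeros(10), mode="transient")
        assert np.isnan(score)

    def test_transient_mode_uses_rates(self):
        base = np.array([1, 0, 0, 0], float)   # rate 0.25
        ts = np.array([1, 1, 0, 0], float)     # rate 0.5
        assert ts_selectivity(base, ts, mode="transient") == pytest.approx(1 / 3)


class TestClassification:
    @pytest.mark.parametrize("score,expected", [
        (0.25, "TS"), (-0.2, "none"), (0.2, "none"), (0.0, "none"),
        (-0.21, "baseline"), (np.nan, "none")])
    def test_selectivity_boundaries_exclusive(self, score, expected):
        assert classify_selectivity(np.array(score)) == expected

    @pytest.mark.parametrize("score,expected", [
        (0.3, "struggle"), (-0.3, "immobility"), (0.15, "none"), (np.nan, "none")])
    def test_movement_classes(self, score, expected):
        assert classify_movement(np.array(score)) == expected


class TestMovementScore:
    def test_perfect_correlation(self, rng):
        speed = rng.random(100)
        assert movement_score(speed, speed) == pytest.approx(1.0)
        assert movement_score(speed, -speed) == pytest.approx(-1.0)

    def test_against_scipy_oracle(self):
        speed = np.array([0, 1, 2, 3], float)
        trace = np.array([1, 1, 2, 4], float)
        expected = pearsonr(speed, trace).statistic
        assert movement_score(speed, trace) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5 / np.sqrt(30))

    def test_invariant_to_positive_affine_transforms(self, rng):
        speed, trace = rng.random(80), rng.random(80)
        r = movement_score(speed, trace)
        assert movement_score(2 * speed + 1, trace) == pytest.approx(r)
        assert movement_score(speed, 0.5 * trace - 3) == pytest.approx(r)

    def test_constant_input_flagged(self):
        assert np.isnan(movement_score(np.ones(10), np.arange(10.0)))


class TestExplainedVariance:
    def test_noiseless_linear_relation_gives_unity(self, rng):
        speed = rng.random(1000)
        assert movement_ev(2 * speed + 1, speed) == pytest.approx(1.0, abs=1e-10)

    def test_independent_trace_near_zero(self, rng):
        assert movement_ev(rng.standard_normal(10000),
                           rng.standard_normal(10000)) <= 0.02

    def test_recovers_generator_oracle(self, rng):
        """A strongly speed-coupled trace: CV EV matches the noise-share
        prediction var(signal)/var(total) within 0.1."""
        speed = np.abs(rng.standard_normal(4000)).cumsum() % 7
        noise = rng.standard_normal(4000)
        trace = 2.0 * speed + noise
        oracle = np.var(2.0 * speed) / np.var(trace)
        assert movement_ev(trace, speed) == pytest.approx(oracle, abs=0.1)

    def test_significance_of_exact_relation(self, rng):
        speed = np.abs(np.sin(np.arange(4000) / 50)) + 0.1
        sig, real, surr = ev_significance(speed, speed, n_surrogates=50,
                                          shift_range_s=(20, 60), rng=rng)
        assert sig and real == pytest.approx(1.0, abs=1e-9)

    def test_significance_deterministic_under_seed(self, rng):
        speed = np.abs(rng.standard_normal(3000))
        trace = rng.standard_normal(3000)
        a = ev_significance(trace, speed, 50, (20, 60),
                            rng=np.random.default_rng(5))
        b = ev_significance(trace, speed, 50, (20, 60),
                            rng=np.random.default_rng(5))
        assert a[0] == b[0] and a[1] == b[1]
        np.testing.assert_array_equal(a[2], b[2])

    def test_shift_range_must_fit(self, rng):
        with pytest.raises(ValueError):
            ev_significance(rng.random(100), rng.random(100),
                            shift_range_s=(20, 120), rng=rng)

    def test_population_ev_target_among_predictors(self, rng):
        others = np.tile(rng.standard_normal(500), (8, 1))
        target = others[0] + 1e-6 * rng.standard_normal(500)
        ev = population_ev(target, others, n_predictors=5, rng=rng)
        assert ev > 0.999

    def test_population_ev_noise_floor(self, rng):
        others = rng.standard_normal((60, 4000))
        target = rng.standard_normal(4000)
        assert population_ev(target, others, n_predictors=50, rng=rng) <= 0.05

    def test_population_ev_needs_enough_neurons(self, rng):
        with pytest.raises(ValueError):
            population_ev(rng.random(100), rng.random((10, 100)),
                          n_predictors=50, rng=rng)


class TestPethLag:
    def _make(self, delay_frames, n=4000, rng=None):
        rng = rng or np.random.default_rng(2)
        speed = np.abs(np.convolve(rng.standard_normal(n), np.ones(20) / 20,
                                   mode="same")) + 0.05
        trace = np.roll(speed, delay_frames)
        coping = np.full(n, IMMOBILITY, dtype=np.int8)
        for s in range(200, n - 200, 400):
            coping[s:s + 200] = STRUGGLE
        return trace, coping, speed

    @pytest.mark.parametrize("delay", [0, 4])
    def test_lag_recovers_imposed_delay(self, delay):
        trace, coping, speed = self._make(delay)
        traces = np.vstack([trace, trace])
        res = peth_lag(traces, coping, speed, np.array(["struggle", "struggle"]))
        sub = res.table[res.table.coping_type == "struggle"]
        assert len(sub) == 2
        for lag in sub.lag_s:
            assert lag == pytest.approx(delay / 20.0, abs=0.05)  # one frame

    def test_single_neuron_is_degenerate(self):
        trace, coping, speed = self._make(0)
        res = peth_lag(trace[None, :], coping, speed, np.array(["struggle"]))
        row = res.table.iloc[0]
        assert row.degenerate and not row.significant and row.cls == "none"

    def test_no_valid_onsets_gives_empty_result(self):
        trace = np.random.default_rng(0).random(100)
        coping = np.full(100, STRUGGLE, dtype=np.int8)  # no onsets inside
        res = peth_lag(trace[None, :], coping, np.ones(100),
                       np.array(["struggle"]))
        assert len(res.table) == 0


class TestSessionRecovery:
    def test_movement_tuning_specific_to_suspension(self, default_session):
        """Speed coupling acts only under suspension: |movement score| is
        larger there than at baseline, and scores track the true coupling."""
        session, truth, _ = default_session
        table = score_session(session)
        ts_scores = table["movement_score_TS"].to_numpy()
        base_scores = table["movement_score_baseline"].to_numpy()
        assert np.nanmean(np.abs(ts_scores)) > np.nanmean(np.abs(base_scores))
        rho = spearmanr(truth.movement_beta, ts_scores).statistic
        assert rho >= 0.9

    def test_selectivity_class_agreement(self, default_session):
        session, truth, _ = default_session
        table = score_session(session)
        strong = truth.true_selectivity_class != "none"
        agree = np.mean(table["selectivity_class"].to_numpy()[strong]
                        == truth.true_selectivity_class[strong])
        assert agree >= 0.9
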