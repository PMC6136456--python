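"""Rate archetypes and inhomogeneous-Poisson sampling."""

import numpy as np
import pytest
from scipy import stats as sps

import rewardshift as rs
from rewardshift.behavior import PredictionState
from rewardshift.spikes import RateModel, session_rate_model
from rewardshift.task import Trial


def make_trial(v_num, drop_times, flavor="chocolate", omission=None,
               believed="chocolate", confidence=0.99):
    state = PredictionState()
    state.sides["left"].v_num = v_num
    state.sides["left"].believed_flavor = believed
    state.sides["left"].flavor_confidence = confidence
    trial = Trial(
        index=1, block_index=1, odor="forced_left", chosen_side="left",
        correct=True, t_trial_start=0.0, t_odor_on=0.5, t_odor_off=1.0,
        t_well_entry=2.0, drop_times=list(drop_times),
        omission_time=omission, lick_times=[], latency_ms=300.0,
        n_drops=len(drop_times), flavor=flavor, pred_state=state,
    )
    return trial, state


class TestRateProfile:
    def test_error_neuron_silent_for_fully_predicted_drop(self):
        gt = rs.NeuronGroundTruth("error", baseline_rate=5, gain=10,
                                  flavor_gain=0.0)
        trial, state = make_trial(v_num=1.0, drop_times=[2.5])
        t = np.linspace(2.5, 3.0, 50)
        assert np.allclose(rs.rate_profile(gt, trial, state, t), 5.0)

    def test_error_neuron_full_surprise_on_unexpected_second_drop(self):
        gt = rs.NeuronGroundTruth("error", baseline_rate=5, gain=10,
                                  flavor_gain=0.0)
        trial, state = make_trial(v_num=1.0, drop_times=[2.5, 3.0, 3.5])
        # second drop entirely unpredicted: rate = baseline + gain in window
        assert rs.rate_profile(gt, trial, state, 3.2) == pytest.approx(15.0)
        # first drop fully predicted
        assert rs.rate_profile(gt, trial, state, 2.7) == pytest.approx(5.0)

    def test_error_neuron_suppressed_at_surprising_omission(self):
        gt = rs.NeuronGroundTruth("error", baseline_rate=5, gain=10,
                                  flavor_gain=0.0)
        trial, state = make_trial(v_num=3.0, drop_times=[2.5], omission=3.0)
        assert rs.rate_profile(gt, trial, state, 3.2) == pytest.approx(0.0)
        # expected omission (v=1): no suppression
        trial2, state2 = make_trial(v_num=1.0, drop_times=[2.5], omission=3.0)
        assert rs.rate_profile(gt, trial2, state2, 3.2) == pytest.approx(5.0)

    def test_prediction_neuron_ramps_before_each_expected_drop(self):
        gt = rs.NeuronGroundTruth("prediction", baseline_rate=5, gain=10)
        trial, state = make_trial(v_num=3.0, drop_times=[2.5, 3.0, 3.5])
        for t_drop in trial.drop_times:
            before = rs.rate_profile(gt, trial, state, t_drop - 0.21)
            ramping = rs.rate_profile(gt, trial, state, t_drop - 0.10)
            peak = rs.rate_profile(gt, trial, state, t_drop + 0.10)
            after = rs.rate_profile(gt, trial, state, t_drop + 0.28)
            assert before == pytest.approx(5.0)
            assert 5.0 < ramping < peak
            assert peak == pytest.approx(15.0)
            assert after == pytest.approx(5.0)

    def test_prediction_neuron_post_drop_response_is_surprise_free(self):
        gt = rs.NeuronGroundTruth("prediction", baseline_rate=5, gain=10)
        surprised, _ = make_trial(v_num=1.0, drop_times=[2.5, 3.0, 3.5])
        expected, _ = make_trial(v_num=3.0, drop_times=[2.5, 3.0, 3.5])
        t = np.linspace(3.1, 3.29, 20)  # post-delivery window of drop 2
        r_s = rs.rate_profile(gt, surprised, surprised.pred_state, t)
        r_e = rs.rate_profile(gt, expected, expected.pred_state, t)
        assert np.allclose(r_s, r_e)

    def test_prediction_neuron_anticipates_omitted_drop(self):
        gt = rs.NeuronGroundTruth("prediction", baseline_rate=5, gain=10)
        trial, state = make_trial(v_num=3.0, drop_times=[2.5], omission=3.0)
        # expected second drop at 3.0: ramp present though nothing delivered
        assert rs.rate_profile(gt, trial, state, 2.95) > 5.0
        assert rs.rate_profile(gt, trial, state, 3.1) == pytest.approx(15.0)

    def test_error_neuron_has_no_pre_drop_ramp(self):
        gt = rs.NeuronGroundTruth("error", baseline_rate=5, gain=10)
        trial, state = make_trial(v_num=1.0, drop_times=[2.5, 3.0, 3.5],
                                  confidence=0.0, believed=None)
        for t_drop in trial.drop_times:
            t = np.linspace(t_drop - 0.2, t_drop + 0.09, 30)
            assert np.allclose(
                rs.rate_profile(gt, trial, state, t), 5.0
            )

    def test_flavor_selective_neuron_ignores_surprise(self):
        gt = rs.NeuronGroundTruth(
            "flavor_selective", baseline_rate=5, gain=10,
            preferred_flavor="chocolate",
        )
        pref_surprised, _ = make_trial(
            v_num=1.0, drop_times=[2.5], believed="vanilla"
        )
        pref_expected, _ = make_trial(v_num=1.0, drop_times=[2.5])
        r1 = rs.rate_profile(gt, pref_surprised, pref_surprised.pred_state, 2.7)
        r2 = rs.rate_profile(gt, pref_expected, pref_expected.pred_state, 2.7)
        assert r1 == r2 == pytest.approx(15.0)
        nonpref, _ = make_trial(v_num=1.0, drop_times=[2.5], flavor="vanilla")
        assert rs.rate_profile(
            gt, nonpref, nonpref.pred_state, 2.7
        ) == pytest.approx(5.0)


class TestSampleSpikes:
    def test_constant_rate_poisson_count(self):
        model = RateModel(10.0, [])
        counts = [
            len(rs.sample_spikes(model, (0.0, 100.0), seed))
            for seed in range(500)
        ]
        se = np.sqrt(1000 / 500)
        assert abs(np.mean(counts) - 1000) < 3 * se

    def test_zero_rate_gives_empty_train(self):
        model = RateModel(1e-12, [])
        assert len(rs.sample_spikes(model, (0.0, 100.0), 1)) == 0

    def test_ceiling_bounds_rate_everywhere(self):
        model = RateModel(5.0, [(1.0, 2.0, 0.0, 10.0), (2.0, 3.0, 10.0, 0.0)])
        t = np.linspace(0, 4, 1000)
        assert np.all(model.rate(t) <= model.ceiling() + 1e-9)

    def test_spike_times_sorted_and_inside_interval(self):
        model = RateModel(20.0, [(1.0, 2.0, 0.0, 30.0)])
        ts = rs.sample_spikes(model, (0.5, 5.0), 3)
        assert np.all(np.diff(ts) >= 0)
        assert ts.min() >= 0.5 and ts.max() < 5.0


class TestSimulatePopulation:
    def test_population_size_and_determinism(self, short_session):
        specs = [rs.NeuronGroundTruth("null") for _ in range(5)]
        a = rs.simulate_population(short_session, specs, 9)
        b = rs.simulate_population(short_session, specs, 9)
        assert len(a) == 5
        for x, y in zip(a, b):
            assert np.array_equal(x.timestamps, y.timestamps)

    def test_empty_spec_list(self, short_session):
        assert rs.simulate_population(short_session, [], 1) == []

    def test_ground_truth_attached(self, short_session):
        specs = [rs.NeuronGroundTruth("prediction")]
        (train,) = rs.simulate_population(short_session, specs, 2)
        assert train.ground_truth.archetype == "prediction"

    def test_time_rescaling_makes_intervals_exponential(self, short_session):
        """Transformed ISIs of simulated trains pass a KS test against the
        unit exponential for at least 95% of neurons (alpha = .01)."""
        specs = []
        for i in range(20):
            arch = ["prediction", "error", "flavor_selective", "null"][i % 4]
            specs.append(
                rs.NeuronGroundTruth(
                    arch,
                    preferred_flavor=(
                        "chocolate" if arch == "flavor_selective" else None
                    ),
                )
            )
        pop = rs.simulate_population(short_session, specs, 33)
        n_pass = 0
        for train in pop:
            model = session_rate_model(train.ground_truth, short_session)
            lam = np.array([model.cumulative(t) for t in train.timestamps])
            isi = np.diff(lam)
            p = sps.kstest(isi, "expon").pvalue
            n_pass += p > 0.01
        assert n_pass >= int(0.95 * len(pop))
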