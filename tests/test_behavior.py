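"""Delta-rule learner and behavioral simulation."""

import numpy as np
import pytest

import rewardshift as rs
from rewardshift.behavior import PredictionState


def fresh_state():
    s = PredictionState()
    s.sides["left"].v_num = 1.0
    s.sides["left"].believed_flavor = "chocolate"
    s.sides["left"].flavor_confidence = 0.9
    return s


class TestUpdatePrediction:
    def test_zero_learning_rate_leaves_state_unchanged(self):
        s = fresh_state()
        s2 = rs.update_prediction(s, "left", (3, "chocolate"), alpha=0.0)
        assert s2.sides["left"].v_num == s.sides["left"].v_num
        assert s2.sides["left"].flavor_confidence == pytest.approx(0.9)

    def test_full_learning_rate_jumps_to_outcome(self):
        s = fresh_state()
        s2 = rs.update_prediction(s, "left", (3, "chocolate"), alpha=1.0)
        assert s2.sides["left"].v_num == 3.0

    def test_delta_rule_recursion_hand_computed(self):
        # v=1, outcomes of 3 drops twice at alpha=0.3: 1.6 then 2.02
        s = fresh_state()
        s = rs.update_prediction(s, "left", (3, "chocolate"), alpha=0.3)
        assert s.sides["left"].v_num == pytest.approx(1.6)
        s = rs.update_prediction(s, "left", (3, "chocolate"), alpha=0.3)
        assert s.sides["left"].v_num == pytest.approx(2.02)

    def test_flavor_switch_resets_confidence(self):
        s = fresh_state()
        s2 = rs.update_prediction(s, "left", (1, "vanilla"), alpha=0.3)
        assert s2.sides["left"].believed_flavor == "vanilla"
        assert s2.sides["left"].flavor_confidence == pytest.approx(0.3)

    def test_matching_flavor_grows_confidence(self):
        s = fresh_state()
        s2 = rs.update_prediction(s, "left", (1, "chocolate"), alpha=0.3)
        assert s2.sides["left"].flavor_confidence == pytest.approx(
            0.9 + 0.3 * 0.1
        )

    def test_input_state_not_mutated(self):
        s = fresh_state()
        rs.update_prediction(s, "left", (3, "vanilla"), alpha=0.5)
        assert s.sides["left"].v_num == 1.0
        assert s.sides["left"].believed_flavor == "chocolate"


class TestSimulateBehavior:
    def test_same_seed_gives_identical_session(self, short_config):
        sched = rs.build_block_schedule(short_config, 4)
        p = rs.BehaviorParams()
        a = rs.simulate_behavior(sched, p, short_config, 7)
        b = rs.simulate_behavior(sched, p, short_config, 7)
        assert a.trials == b.trials
        assert a.attentive == b.attentive

    def test_correct_trials_obey_drop_timing(self, session):
        cfg = session.config
        for t in session.correct_trials():
            expected, omission = rs.drop_event_times(
                t.t_well_entry, t.n_drops, cfg
            )
            assert t.drop_times == expected
            assert t.omission_time == omission

    def test_error_trials_deliver_nothing(self, session):
        for t in session.trials:
            if not t.correct:
                assert t.drop_times == [] and t.omission_time is None
                assert t.lick_count == 0 and t.n_drops == 0

    def test_greedy_choice_limit_prefers_three_drop_side(self, short_config):
        sched = rs.build_block_schedule(short_config, 4)
        p = rs.BehaviorParams(softmax_temp=50.0)
        sess = rs.simulate_behavior(sched, p, short_config, 7)
        # once values converge (second half of block 1), greedy choices all
        # go to the 3-drop side
        b1 = sess.blocks[0]
        three = b1.side_with_drops(3)
        half = b1.n_trials // 2
        free_late = [
            t for t in sess.trials
            if t.block_index == 1 and t.index > half and t.odor == "free"
        ]
        assert free_late  # sanity
        assert all(t.chosen_side == three for t in free_late)

    def test_no_learning_means_flat_choice_across_number_shift(
        self, short_config
    ):
        p = rs.BehaviorParams(alpha_value=0.0, flavor_attention_prob=0.0)
        deltas = []
        for seed in range(40):
            sched = rs.build_block_schedule(short_config, seed)
            sess = rs.simulate_behavior(sched, p, short_config, 100 + seed)
            for shift, ttype in sess.transitions():
                if ttype != "number":
                    continue
                pre, post, ok = rs.choice_rate_around_transition(
                    sess, shift, n_window=15
                )
                if pre is not None and post is not None:
                    deltas.append(post - pre)
        # with alpha=0 values never separate, so choices hover near 1/2
        assert abs(np.mean(deltas)) < 0.1

    def test_number_shifts_move_choice_more_than_flavor_shifts(self, config):
        p = rs.BehaviorParams()
        num_d, fla_d = [], []
        for seed in range(25):
            sched = rs.build_block_schedule(config, seed)
            sess = rs.simulate_behavior(sched, p, config, 200 + seed)
            for shift, ttype in sess.transitions():
                pre, post, ok = rs.choice_rate_around_transition(sess, shift)
                if pre is None or post is None:
                    continue
                (num_d if ttype == "number" else fla_d).append(
                    abs(post - pre)
                )
        assert np.mean(num_d) > 5 * np.mean(fla_d)
        assert np.mean(num_d) > 0.3

    def test_timestamps_are_millisecond_exact(self, session):
        for t in session.trials[:50]:
            for x in (
                [t.t_trial_start, t.t_odor_on, t.t_odor_off, t.t_well_entry]
                + t.drop_times
                + t.lick_times
            ):
                assert x == pytest.approx(round(x * 1000) / 1000, abs=1e-9)
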