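"""Screening, difference scores, population tests, and the factorial
analysis of post-reward firing."""

import numpy as np
import pytest

import rewardshift as rs
from conftest import poisson_train
from rewardshift.stats import (
    DegenerateVarianceError,
    InsufficientDataError,
    anova_from_table,
)

import pandas as pd


class TestScreen:
    def test_elevated_reward_response_is_flagged(self, short_session):
        # prediction archetype fires above baseline after the first drop
        (train,) = rs.simulate_population(
            short_session, [rs.NeuronGroundTruth("prediction")], 5
        )
        flag, info = rs.screen_reward_responsive(train, short_session)
        assert flag and info["mean_diff"] > 0

    def test_identical_rates_not_flagged(self, short_session):
        # a 10 Hz metronome: every window whose span is a multiple of the
        # spacing holds the same rate, so epoch == baseline trial-by-trial
        spikes = np.arange(0.0, short_session.t_end, 0.1)
        flag, info = rs.screen_reward_responsive(spikes, short_session)
        assert not flag and info["p"] == 1.0

    def test_null_neurons_flagged_at_alpha_rate(self, session):
        n = 600
        n_sig = 0
        for seed in range(n):
            spikes = poisson_train(5.0, session.t_end, 1000 + seed)
            _, info = rs.screen_reward_responsive(spikes, session)
            n_sig += info["p"] < 0.05
        p_hat = n_sig / n
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(p_hat - 0.05) < 3 * se

    def test_insufficient_trials_raise(self, session):
        tiny = rs.Session(
            config=session.config, blocks=session.blocks,
            trials=session.trials[:1], t_end=session.t_end,
        )
        with pytest.raises(InsufficientDataError):
            rs.screen_reward_responsive([1.0, 2.0], tiny)


class TestScores:
    def test_identical_firing_early_and_late_scores_zero(self, short_session):
        # a metronome neuron: same rate in every epoch
        spikes = np.arange(0.0, short_session.t_end, 0.1)
        for shift, ttype in short_session.transitions():
            if ttype != "number":
                continue
            rec = rs.prediction_error_score(
                spikes, short_session, shift,
                rs.reward_response_epoch(("drop", 2)), side="3-drop",
            )
            assert rec is not None
            assert rec.score == pytest.approx(0.0, abs=1e-9)

    def test_hand_arithmetic_of_score(self, short_session):
        """Spike counts planted in the 200-ms epoch give the hand-computed
        early-minus-late mean rate difference."""
        shift = next(
            s for s, t in short_session.transitions() if t == "number"
        )
        new_block = short_session.block(shift + 1)
        phys = new_block.side_with_drops(3)
        trials = short_session.correct_trials(
            block_index=shift + 1, side=phys
        )
        early, late = trials[:5], trials[-5:]
        counts_early = [4, 2, 3, 1, 5]  # rates 20,10,15,5,25 -> mean 15 Hz
        counts_late = [1, 1, 0, 2, 0]  # rates 5,5,0,10,0 -> mean 4 Hz
        spikes = []
        for tr, c in list(zip(early, counts_early)) + list(
            zip(late, counts_late)
        ):
            t0 = tr.drop_times[1] + 0.1
            spikes.extend(t0 + 0.01 * k for k in range(c))
        rec = rs.prediction_error_score(
            np.sort(spikes), short_session, shift,
            rs.reward_response_epoch(("drop", 2)), side="3-drop",
        )
        assert rec.score == pytest.approx(15.0 - 4.0)

    def test_insufficient_trials_return_none(self, short_session):
        rec = rs.prediction_error_score(
            [], short_session, 1, rs.reward_response_epoch(("drop", 2)),
            side="3-drop", early_n=500,
        )
        assert rec is None


class TestPopulationTests:
    def test_all_zero_scores(self):
        r = rs.population_score_test([0.0, 0.0, 0.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_textbook_one_sample_t(self):
        # scores {1,2,3,4}: t = 2.5/(sd/sqrt(4)), sd = 1.290994
        r = rs.population_score_test([1.0, 2.0, 3.0, 4.0])
        sd = np.std([1, 2, 3, 4], ddof=1)
        assert r.t == pytest.approx(2.5 / (sd / 2.0))
        assert r.t == pytest.approx(3.8730, abs=1e-4)
        assert r.df == 3

    def test_single_score_rejected(self):
        with pytest.raises(InsufficientDataError):
            rs.population_score_test([1.0])

    def test_constant_nonzero_scores_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            rs.population_score_test([2.0, 2.0, 2.0])

    def test_identical_populations_compare_to_zero_t(self):
        a = [1.0, 2.0, 3.0]
        r = rs.compare_populations(a, list(a))
        assert r.t == pytest.approx(0.0)

    def test_compare_is_antisymmetric(self):
        a = [1.0, 2.0, 3.0, 2.5]
        b = [0.5, 0.2, 0.9, 1.4]
        r_ab = rs.compare_populations(a, b)
        r_ba = rs.compare_populations(b, a)
        assert r_ab.t == pytest.approx(-r_ba.t)
        assert r_ab.t > 0  # a has the larger mean


class TestFiringAnova:
    def test_balanced_design_matches_textbook_f(self):
        """Hand-built 2x2x2 design with a flavor effect: F from explicit
        between/within sums of squares equals the fitted ANOVA's F."""
        rng = np.random.default_rng(8)
        rows = []
        delta = 4.0
        for side in ("left", "right"):
            for number in (1, 3):
                for flavor in ("chocolate", "vanilla"):
                    for _ in range(2):  # 16 trials
                        mu = 10.0 + (delta if flavor == "chocolate" else 0.0)
                        rows.append(
                            {"side": side, "number": number,
                             "flavor": flavor,
                             "rate": mu + rng.normal(0, 1)}
                        )
        table = pd.DataFrame(rows)
        out = anova_from_table(table)

        # oracle: textbook balanced ANOVA arithmetic for the flavor effect
        y = table["rate"].to_numpy()
        groups = [
            table.loc[table["flavor"] == f, "rate"].to_numpy()
            for f in ("chocolate", "vanilla")
        ]
        grand = y.mean()
        ss_flavor = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        # residual: within-cell variation over the 8 cells
        ss_within = 0.0
        for _, cell in table.groupby(["side", "number", "flavor"]):
            ss_within += ((cell["rate"] - cell["rate"].mean()) ** 2).sum()
        f_oracle = (ss_flavor / 1) / (ss_within / (16 - 8))
        assert out["flavor"][0] == pytest.approx(f_oracle, rel=1e-6)
        assert out["flavor"][3] < 0.05

    def test_flavor_selective_neuron_shows_flavor_main_effect(
        self, short_session
    ):
        (train,) = rs.simulate_population(
            short_session,
            [rs.NeuronGroundTruth(
                "flavor_selective", preferred_flavor="vanilla"
            )],
            13,
        )
        out = rs.firing_anova(train, short_session)
        assert out["flavor"][3] < 0.05

    def test_null_neuron_effects_at_nominal_rate(self, short_session):
        n_rep = 120
        sig = {"side": 0, "number": 0, "flavor": 0}
        for seed in range(n_rep):
            spikes = poisson_train(5.0, short_session.t_end, 5000 + seed)
            out = rs.firing_anova(spikes, short_session)
            for k in sig:
                sig[k] += out[k][3] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        for k in ("side", "flavor"):
            assert abs(sig[k] / n_rep - 0.05) < 3.5 * se, k
        # the number factor inherits the side-dependent epoch duration, so
        # its null rate is moderately inflated; bounded, not nominal
        assert sig["number"] / n_rep < 0.15


class TestFlavorFollowup:
    def test_flavor_tracking_without_error_pattern(self, config):
        """Flavor-selective neurons change across flavor shifts (their
        preferred flavor arrives or leaves) but are stable within the new
        block."""
        sched = rs.build_block_schedule(config, 31)
        sess = rs.simulate_behavior(
            sched, rs.BehaviorParams(), config, 32
        )
        specs = [
            rs.NeuronGroundTruth(
                "flavor_selective",
                preferred_flavor=("chocolate" if i % 2 else "vanilla"),
            )
            for i in range(12)
        ]
        pop = rs.simulate_population(sess, specs, 33)
        res = rs.flavor_subpop_followup(pop, sess)
        assert res.n_neurons >= 10  # nearly all have a flavor main effect
        assert res.shift_test.p < 0.05 and res.shift_test.mean > 0
        assert res.block_test.p > 0.05

    def test_error_neurons_change_within_block(self, config):
        """An error archetype with flavor surprise decays over the new
        block, so its early-vs-late within-block change is positive."""
        sched = rs.build_block_schedule(config, 41)
        sess = rs.simulate_behavior(
            sched, rs.BehaviorParams(), config, 42
        )
        specs = [rs.NeuronGroundTruth("error") for _ in range(12)]
        pop = rs.simulate_population(sess, specs, 43)
        res = rs.flavor_subpop_followup(
            pop, sess, require_flavor_effect=False
        )
        assert res.block_test.p < 0.05 and res.block_test.mean > 0

    def test_null_neurons_calibrated_at_nominal_alpha(self, config):
        """Across replicate null cohorts both follow-up tests reject at
        roughly the nominal 5% rate, not systematically."""
        n_rep = 12
        rej_shift = rej_block = 0
        for r in range(n_rep):
            sched = rs.build_block_schedule(config, 51 + r)
            sess = rs.simulate_behavior(
                sched, rs.BehaviorParams(), config, 500 + r
            )
            specs = [rs.NeuronGroundTruth("null") for _ in range(10)]
            pop = rs.simulate_population(sess, specs, 53 + r)
            res = rs.flavor_subpop_followup(
                pop, sess, require_flavor_effect=False
            )
            rej_shift += res.shift_test.p < 0.05
            rej_block += res.block_test.p < 0.05
        # P(X >= 4 | n=12, p=.05) ~ 0.002
        assert rej_shift <= 3
        assert rej_block <= 3
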