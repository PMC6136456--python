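"""Simulate one session of the block-design reward task and summarize it.

Builds a five-block schedule (unsignaled number/flavor transitions), runs
the delta-rule behavioral learner over it, and prints the block structure
plus the free-choice rates around each transition: large swings at number
transitions, none at flavor transitions.
"""

import rewardshift as rs

config = rs.TaskConfig()
params = rs.BehaviorParams()

schedule = rs.build_block_schedule(config, rng_seed=1)
session = rs.simulate_behavior(schedule, params, config, rng_seed=2)

print(f"session: {len(session.trials)} trials, "
      f"flavor-attentive={session.attentive}")
print(f"{'block':>5} {'transition':>10} {'trials':>6}   left        right")
for b in session.blocks:
    left = "{}x {}".format(*b.contingency["left"])
    right = "{}x {}".format(*b.contingency["right"])
    print(f"{b.index:>5} {b.transition_type:>10} {b.n_trials:>6}   "
          f"{left:<11} {right}")

print("\nfree-choice rate toward the (new) 3-drop side, "
      "last/first 25 trials around each transition:")
for shift, ttype in session.transitions():
    pre, post, _ = rs.choice_rate_around_transition(session, shift)
    print(f"  shift {shift} ({ttype:>6}): {pre:.2f} -> {post:.2f}")

n_correct = sum(t.correct for t in session.trials)
print(f"\naccuracy: {n_correct}/{len(session.trials)} trials correct; "
      "number transitions move choices, flavor transitions do not.")
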