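"""Learn a dosing policy and score it against the exact oracle.

Trajectories are sampled from the enumerable discrete-severity MDP under
the clinician behavior policy; the actor-critic learns offline from those
logged transitions. Because the MDP is enumerable, the true expected
return of any policy is computable by dynamic programming, so we can
report how close the learned policy comes to the best single-threshold
policy — something impossible on real ICU data.
"""

import numpy as np

from corticorl import agent
from corticorl.mdp import Trajectory
from corticorl.synthetic_ehr import (SeverityMDP, SimConfig,
                                     best_threshold_policy)

config = SimConfig(seed=0)
mdp = SeverityMDP(config)
behavior = config.behavior_policy()

paths = mdp.sample_paths(behavior, 2000, np.random.default_rng(7))
trajectories = []
for i, p in enumerate(paths):
    rewards = np.zeros(p["length"])
    rewards[-1] = p["reward"]
    trajectories.append(Trajectory(str(i), p["states"], p["actions"],
                                   rewards, p["reward"] < 0, gamma=1.0))

model, log = agent.train(trajectories,
                         agent.TrainConfig(gamma=1.0, seed=3, epochs=300))


def greedy(severity, day=0):
    probs = model.policy_probs(np.array([[2 * severity - 1]]))[0]
    out = np.zeros(5)
    out[int(probs.argmax())] = 1.0
    return out


_, v_best, threshold, action = best_threshold_policy(config)
v_behavior = mdp.value(behavior)
v_agent = mdp.value(greedy)

print(f"epochs run:                  {len(log.td_loss)}")
print(f"clinician policy value:      {v_behavior:+.3f} "
      f"(expected mortality {100 * (1 - v_behavior) / 2:.1f}%)")
print(f"learned policy value:        {v_agent:+.3f} "
      f"(expected mortality {100 * (1 - v_agent) / 2:.1f}%)")
print(f"best threshold policy value: {v_best:+.3f} "
      f"(dose bin {action} when severity >= {threshold})")

# The learned policy should close most of the gap between the clinician
# behavior policy and the grid-searched optimum: treat with moderate doses
# at high severity, withhold at low severity.
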