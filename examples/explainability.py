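"""Which features drive the agent's and the clinicians' decisions?

Layer-wise relevance propagation decomposes the actor's chosen-action
logit onto the input features; a random-forest behavior clone predicts the
clinicians' logged actions and exposes its own feature importances. The
two rankings are compared with a Spearman rank correlation.
"""

import numpy as np

from corticorl import agent, explain
from corticorl.mdp import Trajectory

rng = np.random.default_rng(0)
n = 2000
severity = rng.uniform(-1, 1, n)      # drives the outcome
vasopressor = rng.uniform(-1, 1, n)   # drives the clinicians' choice only
noise = rng.uniform(-1, 1, n)

names = ["severity", "vasopressor", "noise"]
states = np.column_stack([severity, vasopressor, noise])
actions = (vasopressor > 0).astype(int)              # clinician habit
rewards = np.where((actions == 1) == (severity > 0), 1.0, -1.0)

trajectories = [Trajectory(str(i), states[i:i + 1], [actions[i]],
                           [rewards[i]], rewards[i] < 0, gamma=1.0)
                for i in range(n)]
model, _ = agent.train(trajectories, agent.TrainConfig(
    epochs=200, seed=0, lr_actor=5e-3, lr_critic=5e-3, gamma=1.0))

vectors = [explain.lrp_relevance(model, s, feature_names=names)
           for s in states[:300]]
agent_ranking = explain.aggregate_relevance(vectors)
clone = explain.fit_behavior_clone(states, actions, states, actions,
                                   explain.CloneConfig(n_estimators=200),
                                   feature_names=names)
comparison = explain.compare_rankings(agent_ranking, clone.importances)

print("agent ranking (mean |relevance|):")
print(agent_ranking.to_string(index=False))
print("\nclinician-clone ranking (forest importance):")
print(clone.importances.to_string(index=False))
print(f"\nclone AUROC: {clone.auroc:.3f}")
print(f"Spearman rank correlation: {comparison.spearman:+.2f}")

# The agent's top feature is the outcome-driving severity marker; the
# clone's is the vasopressor cue the clinicians key on — mirroring how a
# mortality-optimizing policy can diverge from prescribing habits.
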