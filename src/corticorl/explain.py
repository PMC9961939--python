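"""Explainability: relevance propagation for the agent, a random-forest
behavior clone for the clinicians, and ranking comparison.

Layer-wise relevance propagation decomposes the actor's chosen-action
logit onto the input features with the epsilon-stabilized rule

    R_j = sum_k  a_j w_jk / (z_k + eps * sign(z_k)) * R_k,
    z_k = sum_j a_j w_jk,

where a_j are the layer's (post-activation) inputs. Because the
denominator is the same sum being redistributed, the total relevance is
conserved at every layer when eps = 0 and no denominator vanishes, so the
input relevances sum exactly to the explained logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import label_binarize

from ._mlp import MLP
from .agent import ActorCriticModel, N_ACTIONS


@dataclass
class RelevanceVector:
    relevances: dict                # feature name -> relevance
    target_action: int
    target_logit: float
    state: np.ndarray

    @property
    def total(self) -> float:
        return float(sum(self.relevances.values()))


def lrp_relevance(model, state: np.ndarray, epsilon: float = 0.01,
                  action: int | None = None,
                  feature_names=None) -> RelevanceVector:
    """Relevance of each input feature for the actor's decision at ``state``.

    Explains the pre-softmax logit of ``action`` (default: the recommended
    argmax action). Accepts an :class:`ActorCriticModel` or a bare actor MLP.
    """
    if isinstance(model, ActorCriticModel):
        actor = model.actor
        feature_names = feature_names or model.feature_names
    elif isinstance(model, MLP):
        actor = model
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}; "
                        "expected ActorCriticModel or MLP")
    state = np.asarray(state, dtype=float).ravel()
    logits, activations = actor.forward(state)
    logits = logits[0]
    if action is None:
        action = int(np.argmax(logits))
    relevance = np.zeros(len(logits))
    relevance[action] = logits[action]
    for layer in range(actor.n_layers - 1, -1, -1):
        a = activations[layer][0]                     # inputs to this layer
        w = actor.weights[layer]
        z = a @ w                                     # bias excluded on purpose
        sign = np.where(z >= 0, 1.0, -1.0)
        denom = z + epsilon * sign
        share = np.divide(relevance, denom, out=np.zeros_like(denom),
                          where=denom != 0)
        relevance = a * (w @ share)
    names = list(feature_names) if feature_names else \
        [f"feature_{i}" for i in range(len(relevance))]
    if len(names) != len(relevance):
        raise ValueError("feature_names length does not match input width")
    return RelevanceVector(relevances=dict(zip(names, relevance.tolist())),
                           target_action=action,
                           target_logit=float(logits[action]), state=state)


def aggregate_relevance(relevance_vectors) -> pd.DataFrame:
    """Global feature ranking: mean absolute relevance across day-states,
    sorted descending; ties broken alphabetically."""
    vectors = list(relevance_vectors)
    if not vectors:
        raise ValueError("need at least one relevance vector")
    frame = pd.DataFrame([rv.relevances for rv in vectors]).abs()
    scores = frame.mean()
    out = pd.DataFrame({"feature": scores.index, "score": scores.to_numpy()})
    out = out.sort_values(["score", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Random-forest behavior clone
# ---------------------------------------------------------------------------

@dataclass
class CloneConfig:
    n_estimators: int = 500
    max_depth: int | None = None
    class_weight: str | None = "balanced"
    seed: int = 0


@dataclass
class BehaviorClone:
    """Supervised model of the clinicians' policy: predicts the logged
    action from the daily state."""

    forest: RandomForestClassifier
    classes: np.ndarray
    auroc: float                    # micro-average one-vs-rest, held-out
    importances: pd.DataFrame
    feature_names: list = field(default_factory=list)

    def predict_proba(self, states: np.ndarray) -> np.ndarray:
        """Probabilities over all 5 actions (zeros for unseen classes)."""
        raw = self.forest.predict_proba(np.atleast_2d(states))
        out = np.zeros((raw.shape[0], N_ACTIONS))
        out[:, self.classes.astype(int)] = raw
        return out


def fit_behavior_clone(train_states, train_actions, val_states, val_actions,
                       config: CloneConfig | None = None,
                       feature_names=None) -> BehaviorClone:
    """Fit the random-forest behavior clone and score it on held-out data
    with the micro-average one-vs-rest multiclass AUROC."""
    cfg = config or CloneConfig()
    X = np.atleast_2d(np.asarray(train_states, dtype=float))
    y = np.asarray(train_actions, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("behavior cloning requires at least two action classes")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
        class_weight=cfg.class_weight, random_state=cfg.seed, n_jobs=1)
    forest.fit(X, y)
    classes = forest.classes_

    Xv = np.atleast_2d(np.asarray(val_states, dtype=float))
    yv = np.asarray(val_actions, dtype=int)
    proba = forest.predict_proba(Xv)
    y_bin = label_binarize(yv, classes=classes)
    if y_bin.shape[1] == 1:     # binary case: label_binarize gives one column
        y_bin = np.hstack([1 - y_bin, y_bin])
    auroc = float(roc_auc_score(y_bin.ravel(), proba.ravel()))

    names = list(feature_names) if feature_names else \
        [f"feature_{i}" for i in range(X.shape[1])]
    imp = pd.DataFrame({"feature": names,
                        "importance": forest.feature_importances_})
    imp = imp.sort_values(["importance", "feature"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    imp["rank"] = np.arange(1, len(imp) + 1)
    return BehaviorClone(forest=forest, classes=classes, auroc=auroc,
                         importances=imp, feature_names=names)


@dataclass
class RankingComparison:
    table: pd.DataFrame
    spearman: float


def compare_rankings(agent_ranking: pd.DataFrame,
                     clone_ranking: pd.DataFrame) -> RankingComparison:
    """Join the agent's relevance ranking with the clone's importance
    ranking and compute the Spearman rank correlation over the shared
    feature universe (which must be identical)."""
    a = set(agent_ranking["feature"])
    b = set(clone_ranking["feature"])
    if a != b:
        raise ValueError(f"feature universes differ: only-agent="
                         f"{sorted(a - b)[:3]}, only-clone={sorted(b - a)[:3]}")
    merged = agent_ranking.rename(
        columns={"score": "agent_score", "rank": "agent_rank"}).merge(
        clone_ranking.rename(
            columns={"importance": "clone_importance", "rank": "clone_rank"}),
        on="feature")
    rho = spearmanr(merged["agent_rank"], merged["clone_rank"]).statistic
    return RankingComparison(table=merged, spearman=float(rho))
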