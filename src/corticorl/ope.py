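"""High-confidence off-policy evaluation of the learned dosing policy.

The learned (evaluation) policy cannot be judged by the rewards in the log,
which were earned under the clinicians' (behavior) policy. Importance
sampling reweights each logged trajectory by the truncated likelihood
ratio ``w = min(c, prod_t pi_e(a_t|s_t) / b(a_t|s_t))`` and a concentration
inequality turns the weighted returns into a 1-delta lower confidence
bound on the evaluation policy's expected return, compared against the
behavior policy's empirical average return.

Because terminal rewards are +/-1, any expected return J maps onto an
expected mortality (1 - J) / 2; the "normalized expected mortality" is
that quantity for the evaluation policy divided by the behavior policy's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent import ActorCriticModel, N_ACTIONS


@dataclass
class BehaviorPolicy:
    """Estimated clinician policy b(a|s) with a probability floor.

    The floor mixes the raw estimate with a uniform distribution,
    ``b' = (1 - 5 p_min) b + p_min``, guaranteeing every action (in
    particular the logged one) probability >= p_min so importance ratios
    stay bounded.
    """

    prob_fn: callable               # states (n, d) -> probabilities (n, 5)
    p_min: float
    provenance: str                 # "empirical" | "behavior_clone" | "exact"

    def __post_init__(self):
        if not 0 < self.p_min < 0.2:
            raise ValueError("p_min must lie in (0, 0.2); larger floors would "
                             "flatten the 5-way distribution")

    def probs(self, states: np.ndarray) -> np.ndarray:
        raw = np.asarray(self.prob_fn(np.atleast_2d(states)), dtype=float)
        floored = (1.0 - N_ACTIONS * self.p_min) * raw + self.p_min
        return floored / floored.sum(axis=1, keepdims=True)

    def prob_of(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        p = self.probs(states)
        return p[np.arange(len(p)), np.asarray(actions, dtype=int)]


def estimate_behavior_policy(trajectories, method: str = "behavior_clone",
                             clone=None, p_min: float = 0.01,
                             n_clusters: int = 50, seed: int = 0) -> BehaviorPolicy:
    """Estimate b(a|s) from training trajectories.

    ``behavior_clone`` uses a fitted multiclass classifier's predicted
    probabilities (see the explain module); ``empirical`` clusters states
    with k-means and uses per-cluster action frequencies. Both are floored
    at p_min and renormalized.
    """
    if method == "behavior_clone":
        if clone is None:
            raise ValueError("behavior_clone method requires a fitted clone")
        return BehaviorPolicy(prob_fn=clone.predict_proba, p_min=p_min,
                              provenance="behavior_clone")
    if method == "empirical":
        from sklearn.cluster import KMeans
        S = np.concatenate([tr.states for tr in trajectories])
        A = np.concatenate([tr.actions for tr in trajectories])
        km = KMeans(n_clusters=min(n_clusters, len(S)), random_state=seed,
                    n_init=10).fit(S)
        freq = np.zeros((km.n_clusters, N_ACTIONS))
        np.add.at(freq, (km.labels_, A), 1.0)
        freq /= np.maximum(freq.sum(axis=1, keepdims=True), 1.0)

        def prob_fn(states):
            return freq[km.predict(np.atleast_2d(states))]

        return BehaviorPolicy(prob_fn=prob_fn, p_min=p_min, provenance="empirical")
    raise ValueError(f"unknown behavior-policy method {method!r}")


def importance_weights(trajectories, pi_e_probs, b_probs, c: float = 100.0,
                       per_decision: bool = False) -> np.ndarray:
    """Truncated trajectory importance weights.

    ``pi_e_probs`` and ``b_probs`` are lists (one array per trajectory) of
    the probabilities each policy assigns to the logged actions. With
    ``per_decision=False`` (default) returns w = min(c, prod ratios) per
    trajectory; the per-decision variant returns the per-step cumulative
    ratio products truncated at c (list of arrays).
    """
    out = []
    for pe, pb in zip(pi_e_probs, b_probs):
        pe = np.asarray(pe, dtype=float)
        pb = np.asarray(pb, dtype=float)
        if np.any(pb <= 0):
            raise ValueError("behavior probability is zero on a logged action; "
                             "apply a probability floor")
        ratios = pe / pb
        if per_decision:
            out.append(np.minimum(np.cumprod(ratios), c))
        else:
            out.append(min(float(np.prod(ratios)), c))
    return out if per_decision else np.asarray(out)


def hcope_lower_bound(weighted_returns, delta: float = 0.05,
                      method: str = "concentration", seed: int = 0) -> float:
    """1-delta lower confidence bound on the expected weighted return.

    Methods: ``concentration`` (empirical-Bernstein on the truncated
    sample, using the sample range), ``t_test`` (one-sided Student-t), or
    ``bootstrap_bca``. Requires n >= 30 trajectories.
    """
    x = np.asarray(weighted_returns, dtype=float)
    n = len(x)
    if n < 30:
        raise ValueError("HCOPE bound requires at least 30 trajectories")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if method not in ("concentration", "t_test", "bootstrap_bca"):
        raise ValueError(f"unknown HCOPE method {method!r}")
    mean = float(x.mean())
    span = float(x.max() - x.min())
    if span == 0.0:
        return mean
    if method == "concentration":
        var = float(x.var(ddof=1))
        log_term = np.log(2.0 / delta)
        return mean - np.sqrt(2.0 * var * log_term / n) \
            - 7.0 * span * log_term / (3.0 * (n - 1))
    if method == "t_test":
        sd = float(x.std(ddof=1))
        return mean - stats.t.ppf(1.0 - delta, n - 1) * sd / np.sqrt(n)
    if method == "bootstrap_bca":
        res = stats.bootstrap((x,), np.mean, confidence_level=1.0 - 2.0 * delta,
                              method="BCa", n_resamples=2000,
                              random_state=np.random.default_rng(seed))
        return float(res.confidence_interval.low)
    raise ValueError(f"unknown HCOPE method {method!r}")


@dataclass
class OPEReport:
    weights: np.ndarray
    truncation: float
    estimate: float                     # importance-weighted J_e
    behavior_estimate: float            # empirical J_b
    lower_bound_95: float
    normalized_expected_mortality: float
    delta: float = 0.05
    method: str = "concentration"

    def to_dict(self) -> dict:
        return {"estimate": self.estimate,
                "behavior_estimate": self.behavior_estimate,
                "lower_bound_95": self.lower_bound_95,
                "normalized_expected_mortality": self.normalized_expected_mortality,
                "delta": self.delta, "method": self.method,
                "truncation": self.truncation,
                "n_trajectories": int(len(self.weights)),
                "mean_weight": float(np.mean(self.weights)),
                "outperforms_behavior": bool(self.lower_bound_95
                                             > self.behavior_estimate)}


def evaluate_policy(model: ActorCriticModel, trajectories,
                    behavior: BehaviorPolicy, c: float = 100.0,
                    delta: float = 0.05, method: str = "concentration",
                    seed: int = 0) -> OPEReport:
    """Full HCOPE comparison of the learned policy against the clinicians'.

    The pass criterion mirrored from the study design is
    ``lower_bound_95 > behavior_estimate``.
    """
    pi_e, b = [], []
    returns = []
    for tr in trajectories:
        probs = model.policy_probs(tr.states)
        pi_e.append(probs[np.arange(len(tr)), tr.actions])
        b.append(behavior.prob_of(tr.states, tr.actions))
        returns.append(tr.return_)
    returns = np.asarray(returns)
    w = importance_weights(trajectories, pi_e, b, c=c)
    weighted = w * returns
    j_e = float(weighted.mean())
    j_b = float(returns.mean())
    bound = hcope_lower_bound(weighted, delta=delta, method=method, seed=seed)
    mort_e = (1.0 - j_e) / 2.0
    mort_b = (1.0 - j_b) / 2.0
    nem = float(mort_e / mort_b) if mort_b > 0 else float("nan")
    return OPEReport(weights=w, truncation=c, estimate=j_e,
                     behavior_estimate=j_b, lower_bound_95=float(bound),
                     normalized_expected_mortality=nem, delta=delta,
                     method=method)


# ---------------------------------------------------------------------------
# Concordance-stratified outcomes and policy comparison curves
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceOutcome:
    """Day-state counts and mortality rates for concordant vs discordant
    decisions, overall and stratified. Mortality is attributed at the
    day-state level: every ICU day of a non-survivor counts as a death-day.
    Empty strata report NaN rates."""

    table: pd.DataFrame
    identical_policies: bool = False


def concordance_outcomes(model: ActorCriticModel, trajectories,
                         episodes=None) -> ConcordanceOutcome:
    shock_by_adm = {}
    if episodes is not None:
        shock_by_adm = {e.admission_id: e.septic_shock for e in episodes}
    rows = []
    for tr in trajectories:
        rec = model.policy_probs(tr.states).argmax(axis=1)
        for t in range(len(tr)):
            rows.append({"admission_id": tr.admission_id,
                         "concordant": bool(rec[t] == tr.actions[t]),
                         "agent_withheld": bool(rec[t] == 0),
                         "septic_shock": bool(shock_by_adm.get(tr.admission_id, False)),
                         "death_day": bool(tr.died_in_icu)})
    df = pd.DataFrame(rows)
    strata = {
        "overall": df,
        "agent_withheld": df[df["agent_withheld"]],
        "agent_prescribed": df[~df["agent_withheld"]],
        "septic_shock": df[df["septic_shock"]],
        "no_septic_shock": df[~df["septic_shock"]],
    }
    out = []
    for name, sub in strata.items():
        for conc in (True, False):
            cell = sub[sub["concordant"] == conc]
            out.append({
                "stratum": name,
                "concordant": conc,
                "n_day_states": int(len(cell)),
                "mortality_rate": float(cell["death_day"].mean()) if len(cell) else float("nan"),
            })
    table = pd.DataFrame(out)
    identical = bool(df["concordant"].all())
    return ConcordanceOutcome(table=table, identical_policies=identical)


def policy_comparison_curves(model: ActorCriticModel, trajectories) -> pd.DataFrame:
    """Per day-since-onset: % of admissions still in the ICU receiving any
    corticosteroid and the mean daily hydrocortisone-equivalent dose, for
    the clinician (logged) and agent policies. Doses use bin midpoints
    (50/150/250 mg, 350 mg for the open top bin)."""
    from .mdp import ACTION_BIN_MIDPOINTS_MG
    mid = np.asarray(ACTION_BIN_MIDPOINTS_MG)
    rows = []
    for tr in trajectories:
        rec = model.policy_probs(tr.states).argmax(axis=1)
        for t in range(len(tr)):
            rows.append((t, tr.actions[t], int(rec[t])))
    df = pd.DataFrame(rows, columns=["day", "clinician_action", "agent_action"])
    out = df.groupby("day").agg(
        n_admissions=("clinician_action", "size"),
        clinician_usage_pct=("clinician_action", lambda a: 100.0 * np.mean(np.asarray(a) > 0)),
        agent_usage_pct=("agent_action", lambda a: 100.0 * np.mean(np.asarray(a) > 0)),
        clinician_mean_dose_mg=("clinician_action", lambda a: float(mid[np.asarray(a)].mean())),
        agent_mean_dose_mg=("agent_action", lambda a: float(mid[np.asarray(a)].mean())),
    ).reset_index()
    return out
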