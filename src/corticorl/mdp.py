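"""Decision-process construction: dose conversion, action discretization,
reward assignment, and admission-level dataset splitting.

The action space is the daily cumulative systemic corticosteroid dose,
converted to hydrocortisone equivalents and binned into five actions:
none, 1-100 mg, 101-200 mg, 201-300 mg, and over 300 mg. Rewards are
terminal only: +1 for ICU survival, -1 for ICU death, so expected return J
maps to a normalized expected mortality (1 - J) / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_ACTIONS = 5

# relative glucocorticoid potency: mg hydrocortisone per mg of compound
STEROID_POTENCY_MG_HC = {
    "hydrocortisone": 1.0,
    "prednisolone": 4.0,
    "prednisone": 4.0,
    "methylprednisolone": 5.0,
    "dexamethasone": 26.7,
}

# bin edges in mg hydrocortisone equivalent; bins are (edge, next-edge],
# except bin 0 which is exactly dose 0
ACTION_BIN_EDGES = (0.0, 100.0, 200.0, 300.0)
ACTION_BIN_MIDPOINTS_MG = (0.0, 50.0, 150.0, 250.0, 350.0)
ACTION_LABELS = ("none", "1-100 mg", "101-200 mg", "201-300 mg", ">300 mg")


@dataclass(frozen=True)
class ActionBin:
    index: int
    hydrocortisone_range_mg: tuple
    label: str


ACTION_BINS = (
    ActionBin(0, (0.0, 0.0), ACTION_LABELS[0]),
    ActionBin(1, (0.0, 100.0), ACTION_LABELS[1]),
    ActionBin(2, (100.0, 200.0), ACTION_LABELS[2]),
    ActionBin(3, (200.0, 300.0), ACTION_LABELS[3]),
    ActionBin(4, (300.0, float("inf")), ACTION_LABELS[4]),
)


def hydrocortisone_equivalent(drug_name: str, dose_mg: float,
                              registry: dict | None = None) -> float:
    """Convert a glucocorticoid dose to mg of hydrocortisone equivalent."""
    registry = STEROID_POTENCY_MG_HC if registry is None else registry
    try:
        factor = registry[drug_name]
    except KeyError:
        raise KeyError(
            f"unknown corticosteroid {drug_name!r}; known compounds: "
            f"{sorted(registry)}") from None
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    return float(dose_mg) * factor


def discretize_action(daily_dose_mg: float) -> int:
    """Map a daily hydrocortisone-equivalent dose to its action index.

    0 -> 0; (0, 100] -> 1; (100, 200] -> 2; (200, 300] -> 3; (300, inf) -> 4.
    """
    d = float(daily_dose_mg)
    if d < 0 or not np.isfinite(d):
        raise ValueError(f"dose must be finite and non-negative, got {daily_dose_mg}")
    if d == 0:
        return 0
    for i, edge in enumerate(ACTION_BIN_EDGES[1:], start=1):
        if d <= edge:
            return i
    return 4


def daily_steroid_actions(events: pd.DataFrame, admissions: pd.DataFrame,
                          registry: dict | None = None) -> pd.DataFrame:
    """Daily hydrocortisone-equivalent totals and action bins per admission.

    Day windows are consecutive 24 h intervals from admission. Days without
    any steroid administration get dose 0 / action 0 (rows are emitted for
    every ICU day of every admission).
    """
    registry = STEROID_POTENCY_MG_HC if registry is None else registry
    adm = admissions.set_index("admission_id")
    steroids = events[events["variable_name"].isin(registry)].copy()
    if len(steroids):
        admitted = adm.loc[steroids["admission_id"], "admitted_at"].to_numpy()
        delta = steroids["timestamp"].to_numpy() - admitted
        steroids["day_index"] = (delta / np.timedelta64(1, "h") // 24).astype(int)
        steroids["equiv"] = [
            hydrocortisone_equivalent(n, v, registry)
            for n, v in zip(steroids["variable_name"], steroids["numeric_value"])
        ]
        totals = steroids.groupby(["admission_id", "day_index"])["equiv"].sum()
    else:
        totals = pd.Series(dtype=float)
    rows = []
    for adm_id, rec in adm.iterrows():
        los_h = (rec["discharged_at"] - rec["admitted_at"]) / pd.Timedelta(hours=1)
        n_days = max(1, int(np.ceil(los_h / 24.0 - 1e-9)))
        for day in range(n_days):
            dose = float(totals.get((adm_id, day), 0.0))
            rows.append((adm_id, day, dose, discretize_action(dose)))
    return pd.DataFrame(rows, columns=["admission_id", "day_index",
                                       "dose_equiv_mg", "action"])


@dataclass
class Trajectory:
    """Ordered (state, action, reward) sequence for one septic admission.

    ``states`` is a (T, d) array; rewards are all zero except the terminal
    one (+1 discharged alive, -1 died in ICU). ``return_`` is the
    gamma-discounted sum of rewards.
    """
    admission_id: str
    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    died_in_icu: bool
    gamma: float
    return_: float = field(init=False)

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.actions = np.asarray(self.actions, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=float)
        T = len(self.actions)
        if self.states.shape[0] != T or self.rewards.shape[0] != T:
            raise ValueError("states, actions and rewards must have equal length")
        self.return_ = float(sum(self.gamma ** t * r
                                 for t, r in enumerate(self.rewards)))

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def transitions(self):
        """Iterate (s, a, r, s_next or None)."""
        for t in range(len(self)):
            s_next = self.states[t + 1] if t + 1 < len(self) else None
            yield self.states[t], int(self.actions[t]), float(self.rewards[t]), s_next


def build_trajectories(states_df: pd.DataFrame, actions_df: pd.DataFrame,
                       admissions: pd.DataFrame, gamma: float = 0.99,
                       feature_names=None) -> list:
    """Assemble trajectories from the daily state matrix and daily actions.

    ``states_df`` must be indexed by (admission_id, day_index) with one
    column per feature; ``actions_df`` as produced by
    :func:`daily_steroid_actions`. Intermediate rewards are 0; terminal
    reward is +1 if discharged alive, -1 if died in ICU.
    """
    died = admissions.set_index("admission_id")["died_in_icu"]
    act = actions_df.set_index(["admission_id", "day_index"])["action"]
    feature_names = list(states_df.columns) if feature_names is None else feature_names
    trajectories = []
    for adm_id, grp in states_df.groupby(level=0, sort=True):
        grp = grp.sort_index(level=1)
        days = grp.index.get_level_values(1)
        if adm_id not in died.index or pd.isna(died.loc[adm_id]):
            raise ValueError(f"admission {adm_id} has no terminal disposition")
        actions = np.array([int(act.get((adm_id, d), 0)) for d in days])
        rewards = np.zeros(len(days))
        rewards[-1] = -1.0 if bool(died.loc[adm_id]) else 1.0
        trajectories.append(Trajectory(admission_id=str(adm_id),
                                       states=grp.to_numpy(dtype=float),
                                       actions=actions, rewards=rewards,
                                       died_in_icu=bool(died.loc[adm_id]),
                                       gamma=gamma))
    return trajectories


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

SPLIT_NAMES = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    assignment: dict          # admission_id -> split name
    fractions: tuple
    seed: int

    def ids(self, split: str) -> list:
        return sorted(k for k, v in self.assignment.items() if v == split)

    def sizes(self) -> dict:
        return {s: sum(1 for v in self.assignment.values() if v == s)
                for s in SPLIT_NAMES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.assignment.items()),
                            columns=["admission_id", "split"])


def largest_remainder_sizes(n: int, fractions) -> list:
    """Apportion n items to fractions by largest-remainder rounding."""
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - sizes[i],
                   reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_admissions(ids, fractions=(0.70, 0.20, 0.10), seed: int = 0) -> SplitAssignment:
    """Randomly partition admission ids into train/validation/test.

    Admission-level (all days of an admission share its split); sizes follow
    largest-remainder rounding of the fractions; deterministic given seed.
    """
    ids = list(ids)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != len(SPLIT_NAMES):
        raise ValueError("expected three fractions (train, validation, test)")
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(ids) < n_nonzero:
        raise ValueError("fewer admissions than nonzero split fractions")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate admission ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(ids))
    sizes = largest_remainder_sizes(len(ids), fractions)
    assignment = {}
    pos = 0
    for name, size in zip(SPLIT_NAMES, sizes):
        for adm_id in order[pos:pos + size]:
            assignment[str(adm_id)] = name
        pos += size
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions),
                           seed=seed)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_trajectories(path, trajectories) -> None:
    """One JSON object per line: ids, actions, rewards, flattened states."""
    path = Path(path)
    with path.open("w") as fh:
        for tr in trajectories:
            fh.write(json.dumps({
                "admission_id": tr.admission_id,
                "actions": tr.actions.tolist(),
                "rewards": tr.rewards.tolist(),
                "states": tr.states.tolist(),
                "died_in_icu": tr.died_in_icu,
                "gamma": tr.gamma,
            }) + "\n")


def read_trajectories(path) -> list:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            d = json.loads(line)
            out.append(Trajectory(admission_id=d["admission_id"],
                                  states=np.asarray(d["states"]),
                                  actions=np.asarray(d["actions"]),
                                  rewards=np.asarray(d["rewards"]),
                                  died_in_icu=d["died_in_icu"],
                                  gamma=d["gamma"]))
    return out
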