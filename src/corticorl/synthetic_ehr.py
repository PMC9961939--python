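"""Synthetic ICU cohort generator with known ground truth.

Emulates the structure of a high-resolution ICU database (admissions,
irregularly timestamped vitals/labs, drug administrations, cultures) so the
whole dosing-policy pipeline — sepsis cohorting, daily feature construction,
trajectory building, policy learning and off-policy evaluation — can be
exercised end-to-end without access to restricted patient data.

The generative model is deliberately simple and fully documented:

* Each admission carries a latent daily *severity* in [0, 1] following a
  mean-reverting random walk (autocorrelated, SOFA-like).
* A severity-monotone softmax *behavior policy* prescribes one of five
  daily corticosteroid dose bins (sicker patients receive more steroids).
* Treatment shifts next-day severity towards a pivot (moderate doses help
  at high severity, harm at low severity) and enters the terminal death
  log-odds directly (dose-dependent side effects).
* Stay length is geometric; on the discharge day the patient dies in ICU
  with probability ``sigmoid(intercept + severity_weight * s +
  treatment_effect[a])`` evaluated at that day's severity and action.

Because the death decision only involves the current day's severity and
action, the process is Markov: discretizing severity onto a finite grid
gives an enumerable MDP whose expected return under any policy can be
computed exactly by dynamic programming (`true_policy_value`) — the oracle
used to validate off-policy estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from ._mlp import softmax
from .mdp import STEROID_POTENCY_MG_HC

N_ACTIONS = 5

EVENT_COLUMNS = ["admission_id", "variable_name", "timestamp",
                 "numeric_value", "variable_class"]


class ConfigError(ValueError):
    """Invalid simulator configuration."""


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults define the package's reference scenario: ~23% ICU mortality,
    clinicians withholding steroids on roughly half of patient-days, and a
    non-trivial optimal policy (moderate doses beneficial only at high
    severity).
    """

    n_admissions: int = 200
    seed: int = 0
    # stay length: geometric number of ICU days, capped
    mean_los_days: float = 6.0
    max_los_days: int = 60
    # latent severity process (mean-reverting walk on [0, 1])
    severity_reversion: float = 0.15
    severity_attractor: float = 0.35
    severity_noise: float = 0.08
    init_severity_mean: float = 0.45
    init_severity_sd: float = 0.15
    init_severity_min: float = 0.25   # floor for infected admissions
    # behavior policy: softmax(intercepts + slopes * severity) over 5 bins
    behavior_intercepts: tuple = (2.5, 0.0, -0.5, -1.5, -2.2)
    behavior_slopes: tuple = (-2.0, 1.5, 3.0, 2.5, 2.0)
    # terminal outcome: log-odds of ICU death on the discharge day
    outcome_intercept: float = -3.0
    outcome_severity_weight: float = 4.0
    outcome_treatment_effects: tuple = (0.0, 0.10, 0.15, 0.45, 0.90)
    # treatment drift on next-day severity: -gain[a] * (s - pivot)
    treatment_drift_gain: tuple = (0.0, 0.25, 0.45, 0.35, 0.20)
    treatment_drift_pivot: float = 0.45
    # cohort composition
    infected_fraction: float = 0.85
    short_stay_fraction: float = 0.05   # stays under 24 h (excluded downstream)
    minor_fraction: float = 0.02        # age < 18 (excluded downstream)
    repeat_patient_fraction: float = 0.03
    # event emission (events/day per variable of each class)
    sampling_rates: dict = field(default_factory=lambda: {
        "vital": 8.0, "lab": 1.5, "drug_rate": 8.0, "ventilation": 4.0,
    })
    # probability that a variable is not sampled at all on a given day
    missingness_rates: dict = field(default_factory=lambda: {
        "vital": 0.02, "lab": 0.12, "drug_rate": 0.0, "ventilation": 0.0,
    })
    # discretization used by the enumerable-MDP oracle
    severity_grid_size: int = 21

    def __post_init__(self):
        if not isinstance(self.n_admissions, (int, np.integer)) or self.n_admissions < 0:
            raise ConfigError("n_admissions must be a non-negative integer")
        if self.mean_los_days < 1:
            raise ConfigError("mean_los_days must be >= 1")
        if self.max_los_days < 1:
            raise ConfigError("max_los_days must be >= 1")
        for name in ("severity_noise", "init_severity_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for d in (self.sampling_rates, self.missingness_rates):
            for k, v in d.items():
                if not np.isfinite(v) or v < 0:
                    raise ConfigError(f"rate {k}={v} must be finite and >= 0")
        for name in ("behavior_intercepts", "behavior_slopes",
                     "outcome_treatment_effects", "treatment_drift_gain"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (N_ACTIONS,) or not np.all(np.isfinite(vec)):
                raise ConfigError(f"{name} must be 5 finite numbers")
        for frac in ("infected_fraction", "short_stay_fraction",
                     "minor_fraction", "repeat_patient_fraction"):
            if not 0 <= getattr(self, frac) <= 1:
                raise ConfigError(f"{frac} must lie in [0, 1]")
        if self.severity_grid_size < 2:
            raise ConfigError("severity_grid_size must be >= 2")

    def behavior_policy(self):
        """The clinician behavior policy: (severity, day) -> 5 probabilities."""
        intercepts = np.asarray(self.behavior_intercepts, dtype=float)
        slopes = np.asarray(self.behavior_slopes, dtype=float)

        def policy(severity, day=0):
            return softmax(intercepts + slopes * float(severity))

        return policy


@dataclass
class AdmissionRecord:
    admission_id: str
    patient_id: str
    age_years: int
    sex: str
    admitted_at: datetime
    discharged_at: datetime
    died_in_icu: bool


# ---------------------------------------------------------------------------
# Severity -> observable mapping
# ---------------------------------------------------------------------------

# measurement panel: name -> (class, intercept, severity slope, noise sd, floor)
MEASUREMENT_MODELS = {
    "heart_rate":             ("vital", 65.0, 45.0, 8.0, 20.0),
    "mean_arterial_pressure": ("vital", 88.0, -35.0, 7.0, 20.0),
    "respiratory_rate":       ("vital", 14.0, 10.0, 3.0, 4.0),
    "temperature":            ("vital", 37.0, 1.5, 0.4, 32.0),
    "gcs":                    ("vital", 15.0, -11.0, 0.8, 3.0),
    "lactate":                ("lab", 0.8, 4.2, 0.5, 0.3),
    "creatinine":             ("lab", 0.7, 3.5, 0.35, 0.3),
    "platelets":              ("lab", 250.0, -220.0, 35.0, 5.0),
    "bilirubin":              ("lab", 0.5, 4.0, 0.6, 0.1),
    "leukocytes":             ("lab", 8.0, 14.0, 2.5, 0.5),
    "glucose":                ("lab", 6.5, 5.0, 1.2, 2.0),
    "sodium":                 ("lab", 137.0, 6.0, 3.0, 110.0),
    "pao2_fio2_ratio":        ("lab", 430.0, -320.0, 45.0, 40.0),
}

URINE_RATE_PER_DAY = 12.0          # hourly-ish urine output measurements
VENT_SEVERITY_THRESHOLD = 0.60     # ventilated days
VASOPRESSOR_SEVERITY_THRESHOLD = 0.50

STEROID_COMPOUNDS = ("hydrocortisone", "prednisolone",
                     "methylprednisolone", "dexamethasone")

# draw total daily hydrocortisone-equivalents strictly inside each bin so
# float round-trips through compound potencies cannot cross a bin edge
_BIN_DRAW_RANGES = {1: (5.0, 95.0), 2: (105.0, 195.0),
                    3: (205.0, 295.0), 4: (305.0, 500.0)}


def expected_sofa(severity: float) -> int:
    """Noise-free SOFA total implied by a latent severity value.

    Applies the standard Sepsis-3 subscore thresholds to the deterministic
    part of the measurement models; used only to define the generator's own
    ground-truth sepsis eligibility flag.
    """
    s = float(severity)
    total = 0
    pf = 430.0 - 320.0 * s
    vent = s > VENT_SEVERITY_THRESHOLD
    if pf < 100 and vent:
        total += 4
    elif pf < 200 and vent:
        total += 3
    elif pf < 300:
        total += 2
    elif pf < 400:
        total += 1
    plat = 250.0 - 220.0 * s
    total += 4 if plat < 20 else 3 if plat < 50 else 2 if plat < 100 else 1 if plat < 150 else 0
    bili = 0.5 + 4.0 * s
    total += 4 if bili >= 12 else 3 if bili >= 6 else 2 if bili >= 2 else 1 if bili >= 1.2 else 0
    norepi = max(0.0, 0.05 + 0.55 * (s - VASOPRESSOR_SEVERITY_THRESHOLD)) \
        if s > VASOPRESSOR_SEVERITY_THRESHOLD else 0.0
    map_ = 88.0 - 35.0 * s
    total += 4 if norepi > 0.1 else 3 if norepi > 0 else 1 if map_ < 70 else 0
    gcs = round(15.0 - 11.0 * s)
    total += 4 if gcs < 6 else 3 if gcs <= 9 else 2 if gcs <= 12 else 1 if gcs <= 14 else 0
    creat = 0.7 + 3.5 * s
    total += 4 if creat >= 5 else 3 if creat >= 3.5 else 2 if creat >= 2 else 1 if creat >= 1.2 else 0
    return total


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _simulate_severity_path(cfg: SimConfig, s0: float, n_days: int,
                            rng: np.random.Generator, policy):
    """Daily severity path and behavior actions; returns (severities, actions)."""
    gains = np.asarray(cfg.treatment_drift_gain)
    sev = np.empty(n_days)
    actions = np.empty(n_days, dtype=int)
    s = s0
    for t in range(n_days):
        sev[t] = s
        p = policy(s, t)
        actions[t] = rng.choice(N_ACTIONS, p=p)
        drift = -gains[actions[t]] * (s - cfg.treatment_drift_pivot)
        s = float(np.clip(
            s + cfg.severity_reversion * (cfg.severity_attractor - s)
            + drift + rng.normal(0.0, cfg.severity_noise), 0.0, 1.0))
    return sev, actions


def _death_probability(cfg: SimConfig, severity: float, action: int) -> float:
    tau = cfg.outcome_treatment_effects[action]
    return float(_sigmoid(cfg.outcome_intercept
                          + cfg.outcome_severity_weight * severity + tau))


def _emit_measurements(rows, cfg, adm_id, day, day_start, sev, hours_in_day, rng):
    for name, (vclass, b0, b1, noise, floor) in MEASUREMENT_MODELS.items():
        rate = cfg.sampling_rates.get(vclass, 0.0)
        if rate <= 0 or rng.random() < cfg.missingness_rates.get(vclass, 0.0):
            continue
        k = rng.poisson(rate)
        if k == 0:
            continue
        hours = rng.uniform(0.0, hours_in_day, size=k)
        values = np.maximum(floor, b0 + b1 * sev + rng.normal(0.0, noise, size=k))
        if name == "gcs":
            values = np.clip(np.round(values), 3, 15)
        for h, v in zip(hours, values):
            rows.append((adm_id, name, day_start + timedelta(hours=float(h)),
                         float(v), vclass))
    # urine output: quasi-hourly volumes summing to a severity-driven daily total
    k = rng.poisson(URINE_RATE_PER_DAY * hours_in_day / 24.0)
    if k:
        daily_total = max(50.0, 2000.0 - 1800.0 * sev + rng.normal(0.0, 150.0))
        vols = np.maximum(0.0, rng.normal(daily_total / max(k, 1), 15.0, size=k))
        for h, v in zip(rng.uniform(0.0, hours_in_day, size=k), vols):
            rows.append((adm_id, "urine_output", day_start + timedelta(hours=float(h)),
                         float(v), "vital"))
    if sev > VENT_SEVERITY_THRESHOLD:
        k = rng.poisson(cfg.sampling_rates.get("ventilation", 4.0))
        for h in rng.uniform(0.0, hours_in_day, size=k):
            rows.append((adm_id, "ventilated", day_start + timedelta(hours=float(h)),
                         1.0, "ventilation"))
    if sev > VASOPRESSOR_SEVERITY_THRESHOLD:
        k = rng.poisson(cfg.sampling_rates.get("drug_rate", 8.0))
        if k:
            base = 0.05 + 0.55 * (sev - VASOPRESSOR_SEVERITY_THRESHOLD)
            rates = np.maximum(0.01, base + rng.normal(0.0, 0.02, size=k))
            for h, v in zip(rng.uniform(0.0, hours_in_day, size=k), rates):
                rows.append((adm_id, "norepinephrine", day_start + timedelta(hours=float(h)),
                             float(v), "drug_rate"))


def _emit_steroids(rows, adm_id, compound, day_start, hours_in_day, action, rng):
    """Emit corticosteroid boluses whose hydrocortisone equivalent falls in
    the bin of ``action``; returns the exact equivalent total emitted."""
    if action == 0:
        return 0.0
    lo, hi = _BIN_DRAW_RANGES[action]
    total_equiv = rng.uniform(lo, hi)
    n_boluses = rng.integers(1, 3)
    parts = np.full(n_boluses, total_equiv / n_boluses)
    potency = STEROID_POTENCY_MG_HC[compound]
    for h, part in zip(sorted(rng.uniform(0.0, hours_in_day, size=n_boluses)), parts):
        rows.append((adm_id, compound, day_start + timedelta(hours=float(h)),
                     float(part / potency), "drug_bolus"))
    return float(total_equiv)


def generate_cohort(config: SimConfig):
    """Simulate a cohort; returns (admissions, events, ground_truth).

    * ``admissions``: list of :class:`AdmissionRecord`
    * ``events``: long-format DataFrame with columns
      (admission_id, variable_name, timestamp, numeric_value, variable_class)
    * ``ground_truth``: per-day DataFrame carrying the latent severity, the
      true behavior action, and admission-level oracle flags
      (infected, eligible_sepsis, died_in_icu) for test oracles.

    Deterministic given ``config`` (including its seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    policy = cfg.behavior_policy()
    base_date = datetime(2015, 1, 1)

    admissions: list[AdmissionRecord] = []
    event_rows: list[tuple] = []
    gt_rows: list[dict] = []
    n_patients = 0

    for i in range(cfg.n_admissions):
        adm_id = f"A{i:05d}"
        if n_patients and rng.random() < cfg.repeat_patient_fraction:
            patient_id = f"P{rng.integers(0, n_patients):05d}"
        else:
            patient_id = f"P{n_patients:05d}"
            n_patients += 1
        minor = rng.random() < cfg.minor_fraction
        age = int(rng.integers(1, 18)) if minor else int(rng.integers(18, 91))
        sex = "M" if rng.random() < 0.576 else "F"
        admitted_at = base_date + timedelta(hours=float(rng.uniform(0, 365 * 24)))

        infected = rng.random() < cfg.infected_fraction
        short_stay = rng.random() < cfg.short_stay_fraction
        if infected:
            s0 = float(np.clip(rng.normal(cfg.init_severity_mean, cfg.init_severity_sd),
                               cfg.init_severity_min, 0.95))
        else:
            s0 = float(np.clip(rng.normal(0.12, 0.08), 0.0, 0.40))

        if short_stay:
            los_hours = float(rng.uniform(6.0, 23.0))
            n_days = 1
        else:
            n_days = int(min(cfg.max_los_days, rng.geometric(1.0 / cfg.mean_los_days)))
            los_hours = n_days * 24.0 + float(rng.uniform(0.5, 6.0))
        discharged_at = admitted_at + timedelta(hours=los_hours)

        sev, actions = _simulate_severity_path(cfg, s0, n_days, rng, policy)
        died = rng.random() < _death_probability(cfg, sev[-1], actions[-1])
        admissions.append(AdmissionRecord(adm_id, patient_id, age, sex,
                                          admitted_at, discharged_at, died))

        compound = STEROID_COMPOUNDS[rng.integers(0, len(STEROID_COMPOUNDS))]
        # infection suspicion pair: culture + antibiotics within the window
        if infected:
            culture_h = float(rng.uniform(2.0, min(20.0, los_hours - 1.0)))
            event_rows.append((adm_id, "blood_culture",
                               admitted_at + timedelta(hours=culture_h), 1.0, "culture"))
            abx_first = max(0.0, culture_h + float(rng.uniform(-12.0, 48.0)))
            abx_first = min(abx_first, los_hours - 0.5)   # stays inside the stay
            for d in range(min(5, n_days)):
                h = abx_first + 24.0 * d
                if h < los_hours:
                    event_rows.append((adm_id, "antibiotic",
                                       admitted_at + timedelta(hours=h), 1000.0, "drug_bolus"))
        elif rng.random() < 0.3:   # prophylactic antibiotics, no culture
            event_rows.append((adm_id, "antibiotic",
                               admitted_at + timedelta(hours=float(rng.uniform(0, los_hours))),
                               1000.0, "drug_bolus"))

        esofa = [expected_sofa(s) for s in sev]
        rise = 0
        running_min = esofa[0]
        for v in esofa[1:]:
            rise = max(rise, v - running_min)
            running_min = min(running_min, v)
        eligible = bool(infected and age >= 18 and los_hours >= 24.0
                        and (esofa[0] >= 2 or rise >= 2))

        for t in range(n_days):
            day_start = admitted_at + timedelta(hours=24.0 * t)
            hours_in_day = min(24.0, los_hours - 24.0 * t)
            _emit_measurements(event_rows, cfg, adm_id, t, day_start,
                               sev[t], hours_in_day, rng)
            equiv = _emit_steroids(event_rows, adm_id, compound, day_start,
                                   hours_in_day, int(actions[t]), rng)
            gt_rows.append({
                "admission_id": adm_id, "day_index": t,
                "severity": float(sev[t]), "action": int(actions[t]),
                "steroid_equiv_mg": equiv, "infected": infected,
                "eligible_sepsis": eligible, "died_in_icu": died,
            })

    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    if len(events):
        events = events.sort_values(
            ["admission_id", "timestamp", "variable_name"], kind="stable"
        ).reset_index(drop=True)
    ground_truth = pd.DataFrame(
        gt_rows, columns=["admission_id", "day_index", "severity", "action",
                          "steroid_equiv_mg", "infected", "eligible_sepsis",
                          "died_in_icu"])
    return admissions, events, ground_truth


def admissions_frame(admissions) -> pd.DataFrame:
    df = pd.DataFrame([asdict(a) for a in admissions],
                      columns=["admission_id", "patient_id", "age_years", "sex",
                               "admitted_at", "discharged_at", "died_in_icu"])
    return df


def write_cohort(outdir, admissions, events, ground_truth) -> None:
    """Write admissions.csv / events.csv / ground_truth.csv (RFC-4180,
    ISO-8601 timestamps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adm = admissions_frame(admissions)
    for col in ("admitted_at", "discharged_at"):
        adm[col] = pd.to_datetime(adm[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    adm.to_csv(outdir / "admissions.csv", index=False)
    ev = events.copy()
    if len(ev):
        ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(outdir / "events.csv", index=False)
    ground_truth.to_csv(outdir / "ground_truth.csv", index=False)


def read_cohort(indir):
    """Read back the three delimited files written by :func:`write_cohort`."""
    indir = Path(indir)
    adm = pd.read_csv(indir / "admissions.csv",
                      parse_dates=["admitted_at", "discharged_at"])
    events = pd.read_csv(indir / "events.csv", parse_dates=["timestamp"])
    gt = pd.read_csv(indir / "ground_truth.csv")
    return adm, events, gt


# ---------------------------------------------------------------------------
# Enumerable discrete-severity MDP and exact policy value
# ---------------------------------------------------------------------------

class SeverityMDP:
    """Discrete-severity variant of the generator: severity snapped to a
    finite grid, transitions and terminal death probabilities enumerated,
    so any policy's expected return is computable exactly by backward
    induction (no sampling)."""

    def __init__(self, config: SimConfig):
        cfg = config
        self.config = cfg
        K = cfg.severity_grid_size
        self.grid = np.linspace(0.0, 1.0, K)
        self.discharge_prob = 1.0 / cfg.mean_los_days
        self.horizon = cfg.max_los_days
        gains = np.asarray(cfg.treatment_drift_gain)
        # per-action Gaussian step discretized by integrating over grid cells
        half = 0.5 * (self.grid[1] - self.grid[0])
        edges = np.concatenate(([-np.inf], self.grid[:-1] + half, [np.inf]))
        from scipy.stats import norm
        self.transition = np.empty((N_ACTIONS, K, K))
        for a in range(N_ACTIONS):
            mean_next = np.clip(
                self.grid + cfg.severity_reversion * (cfg.severity_attractor - self.grid)
                - gains[a] * (self.grid - cfg.treatment_drift_pivot), 0.0, 1.0)
            cdf = norm.cdf(edges[None, :], loc=mean_next[:, None],
                           scale=max(cfg.severity_noise, 1e-9))
            self.transition[a] = np.diff(cdf, axis=1)
        taus = np.asarray(cfg.outcome_treatment_effects)
        self.death_prob = _sigmoid(cfg.outcome_intercept
                                   + cfg.outcome_severity_weight * self.grid[:, None]
                                   + taus[None, :])               # (K, 5)
        init = norm.pdf(self.grid, loc=cfg.init_severity_mean,
                        scale=max(cfg.init_severity_sd, 1e-9))
        init = np.where(self.grid >= cfg.init_severity_min, init, 0.0)
        if init.sum() <= 0:
            raise ConfigError("initial severity distribution has no support on grid")
        self.initial = init / init.sum()

    def _policy_matrix(self, policy, day: int) -> np.ndarray:
        pi = np.array([np.asarray(policy(s, day), dtype=float) for s in self.grid])
        if pi.shape != (len(self.grid), N_ACTIONS):
            raise ValueError("policy must return 5 probabilities per state")
        if not np.all(np.isfinite(pi)) or np.any(pi < -1e-12):
            raise ValueError("policy returned non-finite or negative probabilities")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("policy probabilities must sum to 1")
        return np.clip(pi, 0.0, None)

    def value(self, policy, gamma: float = 1.0) -> float:
        """Exact expected return of ``policy`` (terminal reward +1 survive /
        -1 die, discounted by gamma per ICU day)."""
        K = len(self.grid)
        terminal = 1.0 - 2.0 * self.death_prob       # (K, 5) expected terminal reward
        V_next = np.zeros(K)
        for t in range(self.horizon - 1, -1, -1):
            q = 1.0 if t == self.horizon - 1 else self.discharge_prob
            pi = self._policy_matrix(policy, t)
            cont = np.stack([self.transition[a] @ V_next for a in range(N_ACTIONS)],
                            axis=1)                  # (K, 5)
            V_next = (pi * (q * terminal + (1.0 - q) * gamma * cont)).sum(axis=1)
        return float(self.initial @ V_next)

    def sample_paths(self, policy, n: int, rng, gamma: float = 1.0):
        """Sample ``n`` stays under ``policy``; vectorized across active stays.

        Returns a list of dicts with keys severities, states (2s-1 column
        vectors), actions, behavior_probs (prob of the taken action under
        ``policy``), reward (terminal +/-1), return_ (gamma-discounted).
        """
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        K = len(self.grid)
        state_idx = rng.choice(K, size=n, p=self.initial)
        active = np.arange(n)
        paths = [{"sev_idx": [], "actions": [], "probs": []} for _ in range(n)]
        rewards = np.zeros(n)
        lengths = np.zeros(n, dtype=int)
        trans_cum = np.cumsum(self.transition, axis=2)
        for t in range(self.horizon):
            if active.size == 0:
                break
            pi = self._policy_matrix(policy, t)       # (K, 5)
            pi_rows = pi[state_idx]
            u = rng.random(active.size)
            acts = (np.cumsum(pi_rows, axis=1) < u[:, None]).sum(axis=1)
            acts = np.minimum(acts, N_ACTIONS - 1)
            for j, tr in enumerate(active):
                paths[tr]["sev_idx"].append(state_idx[j])
                paths[tr]["actions"].append(int(acts[j]))
                paths[tr]["probs"].append(float(pi_rows[j, acts[j]]))
            q = 1.0 if t == self.horizon - 1 else self.discharge_prob
            discharge = rng.random(active.size) < q
            if discharge.any():
                idx = np.where(discharge)[0]
                p_die = self.death_prob[state_idx[idx], acts[idx]]
                dies = rng.random(idx.size) < p_die
                rewards[active[idx]] = np.where(dies, -1.0, 1.0)
                lengths[active[idx]] = t + 1
            stay = ~discharge
            if stay.any():
                rows = trans_cum[acts[stay], state_idx[stay]]
                u2 = rng.random(stay.sum())
                state_idx = (rows < u2[:, None]).sum(axis=1)
                state_idx = np.minimum(state_idx, K - 1)
                active = active[stay]
            else:
                active = active[:0]
        out = []
        for i, p in enumerate(paths):
            sev = self.grid[np.asarray(p["sev_idx"], dtype=int)]
            T = lengths[i]
            out.append({
                "severities": sev,
                "states": (2.0 * sev - 1.0)[:, None],
                "actions": np.asarray(p["actions"], dtype=int),
                "behavior_probs": np.asarray(p["probs"], dtype=float),
                "reward": float(rewards[i]),
                "return_": float(rewards[i]) * gamma ** max(T - 1, 0),
                "length": int(T),
            })
        return out


def true_policy_value(config: SimConfig, policy, gamma: float = 1.0) -> float:
    """Exact expected terminal return of ``policy`` on the discrete-severity
    variant of the generator, by exhaustive dynamic programming.

    ``policy`` maps (severity: float, day: int) to a 5-way probability
    vector. Raises ValueError on non-finite or invalid probabilities.
    """
    return SeverityMDP(config).value(policy, gamma=gamma)


def best_threshold_policy(config: SimConfig, gamma: float = 1.0,
                          thresholds=None):
    """Grid-search the best single-threshold policy ('give dose bin a when
    severity >= threshold, else withhold') on the enumerable MDP.

    Returns (policy, value, threshold, action).
    """
    mdp_ = SeverityMDP(config)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    best = (None, -np.inf, None, None)

    def make_policy(th, a):
        def policy(severity, day=0):
            p = np.zeros(N_ACTIONS)
            p[a if severity >= th else 0] = 1.0
            return p
        return policy

    for a in range(N_ACTIONS):
        for th in thresholds:
            pol = make_policy(th, a)
            v = mdp_.value(pol, gamma=gamma)
            if v > best[1]:
                best = (pol, v, float(th), int(a))
    return best
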