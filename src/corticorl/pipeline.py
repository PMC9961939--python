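"""End-to-end pipeline orchestration.

Stages (in order): simulate -> cohort -> features -> mdp -> train ->
evaluate -> explain -> report. Each stage reads the previous stage's
delimited-text artifacts from the run directory and writes its own, so any
suffix of the pipeline can be re-run; a missing upstream artifact raises an
error naming the stage that produces it. A ``run_report.json`` summarizes
the whole run and is validated against a versioned schema on write.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import agent, cohort, explain, features, mdp, ope, synthetic_ehr

logger = logging.getLogger("corticorl.pipeline")

STAGES = ("simulate", "cohort", "features", "mdp", "train", "evaluate",
          "explain", "report")

REPORT_SCHEMA_VERSION = 1


@dataclass
class CohortSettings:
    suspicion_hours_before: float = 24.0
    suspicion_hours_after: float = 72.0


@dataclass
class FeatureSettings:
    coverage_threshold: float = 0.02


@dataclass
class MdpSettings:
    gamma: float = 0.99
    fractions: tuple = (0.70, 0.20, 0.10)


@dataclass
class OpeSettings:
    truncation: float = 100.0
    delta: float = 0.05
    method: str = "concentration"
    p_min: float = 0.01
    split: str = "validation"


@dataclass
class ExplainSettings:
    epsilon: float = 0.01
    n_estimators: int = 500
    max_lrp_states: int = 500


@dataclass
class RunConfig:
    seed: int = 0
    simulate: synthetic_ehr.SimConfig = field(default_factory=synthetic_ehr.SimConfig)
    cohort: CohortSettings = field(default_factory=CohortSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    mdp: MdpSettings = field(default_factory=MdpSettings)
    train: agent.TrainConfig = field(default_factory=agent.TrainConfig)
    ope: OpeSettings = field(default_factory=OpeSettings)
    explain: ExplainSettings = field(default_factory=ExplainSettings)

    def __post_init__(self):
        # the global seed drives every stage's source of randomness
        self.simulate.seed = int(self.seed)
        self.train.seed = int(self.seed) + 1

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"simulate": synthetic_ehr.SimConfig, "cohort": CohortSettings,
                    "features": FeatureSettings, "mdp": MdpSettings,
                    "train": agent.TrainConfig, "ope": OpeSettings,
                    "explain": ExplainSettings}
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, klass in sections.items():
            section = data.get(name, {}) or {}
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in config section "
                                 f"{name!r}: {sorted(bad)}")
            if "fractions" in section:
                section["fractions"] = tuple(section["fractions"])
            kwargs[name] = klass(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class RunReport(BaseModel):
    """Versioned schema of run_report.json."""
    model_config = ConfigDict(extra="forbid")

    schema_version: int
    config_hash: str
    seed: int
    cohort_counts: dict
    table1: dict
    split_sizes: dict
    final_concordance: dict
    action_distribution: dict
    ope: dict
    top_features_agent: list
    top_features_clone: list


# artifact -> stage that produces it
_ARTIFACTS = {
    "admissions.csv": "simulate", "events.csv": "simulate",
    "ground_truth.csv": "simulate",
    "episodes.csv": "cohort", "sofa.csv": "cohort",
    "states.csv": "features", "observed_mask.csv": "features",
    "feature_spec.json": "features", "splits.csv": "features",
    "trajectories.jsonl": "mdp",
    "model.json": "train", "training_log.csv": "train",
    "ope_report.json": "evaluate", "concordance_outcomes.csv": "evaluate",
    "day_curves.csv": "evaluate",
    "rankings.csv": "explain", "clone_metrics.json": "explain",
}


class MissingArtifactError(FileNotFoundError):
    pass


def _require(outdir: Path, *names):
    missing = [name for name in names if not (outdir / name).exists()]
    if missing:
        # point at the most upstream stage that still needs to run
        first = min(missing, key=lambda n: STAGES.index(_ARTIFACTS[n]))
        raise MissingArtifactError(
            f"missing artifact {first!r}; run the "
            f"{_ARTIFACTS[first]!r} stage first")


def _read_episodes(outdir: Path):
    df = pd.read_csv(outdir / "episodes.csv")
    return [cohort.SepsisEpisode(
        admission_id=str(r.admission_id), onset_day=int(r.onset_day),
        included=bool(r.included), exclusion_reason=str(r.exclusion_reason),
        septic_shock=bool(r.septic_shock), last_day=int(r.last_day))
        for r in df.itertuples()]


def _read_states(outdir: Path):
    df = pd.read_csv(outdir / "states.csv")
    df["admission_id"] = df["admission_id"].astype(str)
    return df.set_index(["admission_id", "day_index"])


def _read_splits(outdir: Path) -> dict:
    df = pd.read_csv(outdir / "splits.csv")
    return dict(zip(df["admission_id"].astype(str), df["split"]))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path):
    admissions, events, gt = synthetic_ehr.generate_cohort(cfg.simulate)
    synthetic_ehr.write_cohort(outdir, admissions, events, gt)
    logger.info("simulate: %d admissions, %d events", len(admissions), len(events))


def stage_cohort(cfg: RunConfig, outdir: Path):
    _require(outdir, "admissions.csv", "events.csv")
    adm, events, _ = synthetic_ehr.read_cohort(outdir)
    sofa = cohort.compute_sofa_daily(events, adm)
    suspicions = cohort.detect_suspected_infection(
        events, hours_before=cfg.cohort.suspicion_hours_before,
        hours_after=cfg.cohort.suspicion_hours_after)
    episodes = cohort.identify_sepsis(sofa, suspicions, adm)
    cohort.flag_all_septic_shock(episodes, events)
    cohort.episodes_frame(episodes).to_csv(outdir / "episodes.csv", index=False)
    cohort.sofa_frame(sofa).to_csv(outdir / "sofa.csv", index=False)
    n_inc = sum(e.included for e in episodes)
    logger.info("cohort: %d/%d admissions included", n_inc, len(episodes))


def stage_features(cfg: RunConfig, outdir: Path):
    _require(outdir, "admissions.csv", "events.csv", "episodes.csv")
    adm, events, _ = synthetic_ehr.read_cohort(outdir)
    episodes = _read_episodes(outdir)
    included_ids = [e.admission_id for e in episodes if e.included]
    split = mdp.split_admissions(included_ids, cfg.mdp.fractions, seed=cfg.seed + 2)
    split.to_frame().to_csv(outdir / "splits.csv", index=False)
    pipe = features.FeaturePipeline(coverage_threshold=cfg.features.coverage_threshold)
    normalized, observed = pipe.fit_transform(events, episodes, adm,
                                              split.ids("train"))
    normalized.reset_index().to_csv(outdir / "states.csv", index=False)
    observed.reset_index().to_csv(outdir / "observed_mask.csv", index=False)
    pipe.save(outdir / "feature_spec.json")
    logger.info("features: %d day-states x %d features (%.1f%% imputed, "
                "dropped: %s)", len(normalized), normalized.shape[1],
                100 * pipe.imputed_fraction, pipe.dropped or "none")


def stage_mdp(cfg: RunConfig, outdir: Path):
    _require(outdir, "states.csv", "admissions.csv", "events.csv", "episodes.csv")
    adm, events, _ = synthetic_ehr.read_cohort(outdir)
    states = _read_states(outdir)
    episodes = {e.admission_id: e for e in _read_episodes(outdir)}
    actions = mdp.daily_steroid_actions(events, adm)
    # re-index clinician actions onto days-since-onset
    actions["day_index"] = actions.apply(
        lambda r: r.day_index - episodes[str(r.admission_id)].onset_day
        if str(r.admission_id) in episodes else -1, axis=1)
    actions = actions[actions["day_index"] >= 0]
    trajectories = mdp.build_trajectories(states, actions, adm,
                                          gamma=cfg.mdp.gamma)
    mdp.write_trajectories(outdir / "trajectories.jsonl", trajectories)
    logger.info("mdp: %d trajectories, %d transitions", len(trajectories),
                sum(len(t) for t in trajectories))


def _split_trajectories(outdir: Path):
    trajectories = mdp.read_trajectories(outdir / "trajectories.jsonl")
    split = _read_splits(outdir)
    by = {name: [t for t in trajectories if split.get(t.admission_id) == name]
          for name in mdp.SPLIT_NAMES}
    return trajectories, by


def stage_train(cfg: RunConfig, outdir: Path):
    _require(outdir, "trajectories.jsonl", "splits.csv", "states.csv")
    _, by = _split_trajectories(outdir)
    feature_names = list(_read_states(outdir).columns)
    model, log = agent.train(by["train"], cfg.train,
                             eval_trajectories=by["validation"] or None)
    model.feature_names = feature_names
    model.save(outdir / "model.json")
    log.to_frame().to_csv(outdir / "training_log.csv", index=False)
    logger.info("train: %d epochs, final relative error %.3f, "
                "train concordance %.1f%%", len(log.td_loss),
                log.relative_error[-1], 100 * log.concordance[-1])


def _fit_clone(cfg: RunConfig, outdir: Path):
    _, by = _split_trajectories(outdir)
    feature_names = list(_read_states(outdir).columns)
    Xt = np.concatenate([t.states for t in by["train"]])
    yt = np.concatenate([t.actions for t in by["train"]])
    Xv = np.concatenate([t.states for t in by["validation"]])
    yv = np.concatenate([t.actions for t in by["validation"]])
    clone_cfg = explain.CloneConfig(n_estimators=cfg.explain.n_estimators,
                                    seed=cfg.seed + 3)
    return explain.fit_behavior_clone(Xt, yt, Xv, yv, clone_cfg,
                                      feature_names=feature_names)


def stage_evaluate(cfg: RunConfig, outdir: Path):
    _require(outdir, "model.json", "trajectories.jsonl", "splits.csv",
             "episodes.csv")
    model = agent.ActorCriticModel.load(outdir / "model.json")
    _, by = _split_trajectories(outdir)
    episodes = _read_episodes(outdir)
    clone = _fit_clone(cfg, outdir)
    behavior = ope.estimate_behavior_policy(by["train"], clone=clone,
                                            p_min=cfg.ope.p_min)
    report = ope.evaluate_policy(model, by[cfg.ope.split], behavior,
                                 c=cfg.ope.truncation, delta=cfg.ope.delta,
                                 method=cfg.ope.method, seed=cfg.seed + 4)
    (outdir / "ope_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    outcome = ope.concordance_outcomes(model, by["test"], episodes)
    outcome.table.to_csv(outdir / "concordance_outcomes.csv", index=False)
    curves = ope.policy_comparison_curves(model, by["test"])
    curves.to_csv(outdir / "day_curves.csv", index=False)
    logger.info("evaluate: J_e=%.3f, J_b=%.3f, 95%% bound=%.3f",
                report.estimate, report.behavior_estimate, report.lower_bound_95)


def stage_explain(cfg: RunConfig, outdir: Path):
    _require(outdir, "model.json", "trajectories.jsonl", "splits.csv")
    model = agent.ActorCriticModel.load(outdir / "model.json")
    _, by = _split_trajectories(outdir)
    S = np.concatenate([t.states for t in by["train"]])
    rng = np.random.default_rng(cfg.seed + 5)
    if len(S) > cfg.explain.max_lrp_states:
        S = S[rng.choice(len(S), cfg.explain.max_lrp_states, replace=False)]
    vectors = [explain.lrp_relevance(model, s, epsilon=cfg.explain.epsilon)
               for s in S]
    agent_ranking = explain.aggregate_relevance(vectors)
    clone = _fit_clone(cfg, outdir)
    comparison = explain.compare_rankings(agent_ranking, clone.importances)
    comparison.table.to_csv(outdir / "rankings.csv", index=False)
    (outdir / "clone_metrics.json").write_text(json.dumps({
        "auroc_micro": clone.auroc,
        "spearman_rank_correlation": comparison.spearman,
        "n_classes": int(len(clone.classes)),
    }, indent=2))
    logger.info("explain: clone AUROC %.3f, rank correlation %.2f",
                clone.auroc, comparison.spearman)


def stage_report(cfg: RunConfig, outdir: Path):
    _require(outdir, "admissions.csv", "episodes.csv", "sofa.csv", "splits.csv",
             "training_log.csv", "ope_report.json", "rankings.csv")
    adm, _, _ = synthetic_ehr.read_cohort(outdir)
    episodes = pd.read_csv(outdir / "episodes.csv")
    sofa = pd.read_csv(outdir / "sofa.csv")
    splits = pd.read_csv(outdir / "splits.csv")
    tlog = pd.read_csv(outdir / "training_log.csv")
    ope_report = json.loads((outdir / "ope_report.json").read_text())
    rankings = pd.read_csv(outdir / "rankings.csv")

    included = episodes[episodes["included"]]
    merged = adm.merge(included, on="admission_id")
    table1 = _table1(merged, sofa)
    counts = {"n_admissions": int(len(adm)),
              "n_included": int(len(included)),
              "n_septic_shock": int(included["septic_shock"].sum()),
              "exclusions": episodes[~episodes["included"]]
              ["exclusion_reason"].value_counts().to_dict()}
    action_cols = [c for c in tlog.columns if c.startswith("action_")]
    final_counts = tlog[action_cols].iloc[-1]
    action_distribution = {
        "agent_withheld_fraction": float(final_counts.iloc[0] / final_counts.sum()),
        "agent_action_counts": final_counts.astype(int).tolist(),
    }
    final_concordance = {"train": float(tlog["concordance"].iloc[-1])}
    if "concordance_val" in tlog.columns:
        final_concordance["validation"] = float(tlog["concordance_val"].iloc[-1])
    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        config_hash=cfg.config_hash(),
        seed=int(cfg.seed),
        cohort_counts=counts,
        table1=table1,
        split_sizes=splits["split"].value_counts().to_dict(),
        final_concordance=final_concordance,
        action_distribution=action_distribution,
        ope=ope_report,
        top_features_agent=rankings.sort_values("agent_rank")
            ["feature"].head(20).tolist(),
        top_features_clone=rankings.sort_values("clone_rank")
            ["feature"].head(20).tolist(),
    )
    (outdir / "run_report.json").write_text(report.model_dump_json(indent=2))
    logger.info("report: written run_report.json")


def _table1(merged: pd.DataFrame, sofa: pd.DataFrame) -> dict:
    """Cohort summary by survival status: sex, age bands, SOFA medians,
    septic shock."""
    out = {}
    bands = [(18, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 200)]
    sofa_by = sofa.groupby("admission_id")["total"]
    sofa_max = sofa_by.max()
    onset = merged.set_index("admission_id")["onset_day"]
    sofa_onset = sofa.set_index(["admission_id", "day_index"])["total"]
    for label, sub in (("total", merged),
                       ("survivors", merged[~merged["died_in_icu"]]),
                       ("non_survivors", merged[merged["died_in_icu"]])):
        ids = sub["admission_id"]
        onset_scores = [sofa_onset.get((a, int(onset[a])), np.nan) for a in ids]
        entry = {
            "n": int(len(sub)),
            "male_n": int((sub["sex"] == "M").sum()),
            "age_bands": {f"{lo}-{hi if hi < 200 else 'plus'}":
                          int(((sub["age_years"] >= lo)
                               & (sub["age_years"] <= hi)).sum())
                          for lo, hi in bands},
            "sofa_max_median": float(sofa_max.reindex(ids).median()),
            "sofa_onset_median": float(np.nanmedian(onset_scores))
            if len(sub) else float("nan"),
            "septic_shock_n": int(sub["septic_shock"].sum()),
        }
        out[label] = entry
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate, "cohort": stage_cohort,
    "features": stage_features, "mdp": stage_mdp, "train": stage_train,
    "evaluate": stage_evaluate, "explain": stage_explain,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, outdir, stages=None) -> Path:
    """Execute the requested pipeline stages in canonical order.

    ``stages=None`` runs everything. Artifacts are written under
    ``outdir``; returns that path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; "
                         f"valid stages are {list(STAGES)}")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("corticorl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for stage in STAGES:
            if stage not in requested:
                continue
            t0 = time.time()
            _STAGE_FUNCS[stage](config, outdir)
            logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
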