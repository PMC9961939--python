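"""Run the whole pipeline end to end on a small synthetic cohort.

simulate -> cohort -> features -> mdp -> train -> evaluate -> explain ->
report. Artifacts (CSV/JSON) land in ./corticorl_demo; the run report
collects cohort counts, split sizes, concordance, the off-policy
evaluation and the top-ranked features. Equivalent shell command:

    corticorl --out corticorl_demo --seed 3
"""

import json

from corticorl.pipeline import RunConfig, run_pipeline

config = RunConfig.from_dict({
    "seed": 3,
    "simulate": {"n_admissions": 400},
    "train": {"epochs": 250},
    "explain": {"n_estimators": 200, "max_lrp_states": 200},
})
outdir = run_pipeline(config, "corticorl_demo")

report = json.loads((outdir / "run_report.json").read_text())
print(f"cohort: {report['cohort_counts']['n_included']} of "
      f"{report['cohort_counts']['n_admissions']} admissions included "
      f"({report['cohort_counts']['n_septic_shock']} septic shock)")
print(f"splits: {report['split_sizes']}")
print(f"final concordance: {report['final_concordance']}")
print(f"agent withheld steroids on "
      f"{100 * report['action_distribution']['agent_withheld_fraction']:.0f}% "
      f"of training day-states")
ope = report["ope"]
print(f"OPE: J_e={ope['estimate']:+.3f}, J_b={ope['behavior_estimate']:+.3f}, "
      f"95% bound={ope['lower_bound_95']:+.3f}")
print(f"top agent features: {report['top_features_agent'][:5]}")
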