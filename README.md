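# corticorl

Offline reinforcement learning for corticosteroid dosing in septic ICU
patients — a fully testable reconstruction of the treatment-policy
pipeline on synthetic electronic-health-record data with known ground
truth.

## The problem

Corticosteroids in sepsis help some patients and harm others, and decades
of trials disagree about who should get them. One way to study the
question without a new trial is offline reinforcement learning: treat
each ICU day as a decision point, learn from the dosing variation already
present in routine care, and ask which dosing policy would have minimized
mortality. Real ICU databases that support this are access-restricted, so
this package ships a synthetic EHR generator that emulates their
structure (admissions, irregular timestamped vitals and labs, drug
administrations, cultures) while exposing the latent state and true
outcome model — which means every stage of the pipeline can be validated
against an exact oracle instead of taken on faith.

## The model

Each septic admission becomes a trajectory of daily decisions:

* **State** `s_t`: all features observed in a 24 h window (aggregated,
  imputed, normalized to [−1, 1]), excluding mortality and the
  administered steroid dose.
* **Action** `a_t ∈ {0,…,4}`: the 24 h cumulative systemic corticosteroid
  dose in hydrocortisone equivalents, binned as none, 1–100, 101–200,
  201–300, and >300 mg.
* **Reward**: terminal only — +1 for ICU survival, −1 for ICU death — so
  an expected return J maps to an expected mortality (1 − J)/2.

A temporal-difference actor-critic (two separate networks) learns a
stochastic policy π<sub>θ</sub>(a|s) and a value V<sub>w</sub>(s) from the
logged transitions: the critic minimizes the squared TD error
δ = r + γV(s′) − V(s), and the actor ascends δ∇<sub>θ</sub>log π<sub>θ</sub>(a_t|s_t).
The learned policy is judged by high-confidence off-policy evaluation:
truncated trajectory importance weights
w(τ) = min(c, Π<sub>t</sub> π<sub>e</sub>(a_t|s_t)/b(a_t|s_t)) against the
clinician behavior policy b, with an empirical-Bernstein 95% lower
confidence bound on the weighted returns. Explainability comes from
layer-wise relevance propagation (ε-rule) on the actor and a
random-forest behavior clone of the clinicians.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

`examples/train_policy.py` trains the agent on 2000 synthetic admissions
logged under the clinician behavior policy and scores every policy with
the exact dynamic-programming oracle of the generator:

```
epochs run:                  300
clinician policy value:      +0.520 (expected mortality 24.0%)
learned policy value:        +0.549 (expected mortality 22.6%)
best threshold policy value: +0.580 (dose bin 2 when severity >= 0.5)
```

The learned policy closes most of the gap between routine clinician
behavior and the grid-searched optimum for this scenario — give a
moderate dose (101–200 mg hydrocortisone) at high severity, withhold
otherwise — and its expected mortality is correspondingly lower.

Other examples, one per capability:

| script | shows |
| --- | --- |
| `examples/simulate_cohort.py` | what the synthetic EHR tables contain |
| `examples/cohort_identification.py` | Sepsis-3 cohorting vs ground truth |
| `examples/train_policy.py` | policy learning vs the DP oracle |
| `examples/offpolicy_evaluation.py` | HCOPE bounds vs the DP oracle |
| `examples/explainability.py` | LRP vs behavior-clone feature rankings |
| `examples/full_pipeline.py` | the end-to-end pipeline and run report |

The pipeline is also a shell command:

```bash
corticorl --config examples/demo_config.yaml --out corticorl_demo
```

which writes every stage's artifact (admissions/events tables, episode
list, daily state matrix, trajectories, model checkpoint, OPE report,
feature rankings) plus a validated `run_report.json` to the output
directory.

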