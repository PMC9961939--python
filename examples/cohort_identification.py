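"""Identify septic admissions with the operationalized Sepsis-3 criteria.

Suspected infection (culture/antibiotic pair within -24 h/+72 h) combined
with new organ dysfunction (SOFA >= 2 at admission or a rise >= 2 above
the running minimum) defines inclusion; minors and stays under 24 h are
excluded. The check at the end compares the decisions against the
generator's own ground-truth eligibility flag.
"""

from collections import Counter

from corticorl.cohort import (compute_sofa_daily, detect_suspected_infection,
                              episodes_frame, flag_all_septic_shock,
                              identify_sepsis)
from corticorl.synthetic_ehr import SimConfig, admissions_frame, generate_cohort

admissions, events, ground_truth = generate_cohort(SimConfig(n_admissions=400,
                                                             seed=2))
adf = admissions_frame(admissions)

sofa = compute_sofa_daily(events, adf)
suspicions = detect_suspected_infection(events)
episodes = identify_sepsis(sofa, suspicions, adf)
flag_all_septic_shock(episodes, events)

table = episodes_frame(episodes)
included = table[table["included"]]
print(f"admissions screened:  {len(table)}")
print(f"sepsis cohort:        {len(included)}")
print("exclusions:           ",
      dict(Counter(table.loc[~table['included'], 'exclusion_reason'])))
print(f"septic shock:         {int(included['septic_shock'].sum())} "
      f"({100 * included['septic_shock'].mean():.1f}% of cohort)")

truth = ground_truth.groupby("admission_id")["eligible_sepsis"].first()
agree = (table.set_index("admission_id")["included"] == truth).mean()
print(f"agreement with generator ground truth: {100 * agree:.1f}%")
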