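"""Extract the 13 per-meal features and the postprandial event labels.

Every meal with enough surrounding CGM coverage becomes one instance: the
6-hour retrospective window yields glucose summaries and risk indices, the
meal itself contributes carbohydrates, hour and insulin bolus, and the
4-hour postprandial horizon is scanned for sustained hypo-/hyperglycemia.
"""

import numpy as np

from glycloop import SimScenario, generate_cohort, build_dataset
from glycloop.features import FEATURE_NAMES

records, _ = generate_cohort(SimScenario(n_patients=3, n_days=10, seed=2))
instances = build_dataset(records)

print(f"{len(instances)} meal instances from {len(records)} patients")
hypo = np.mean([i.label_hypo for i in instances])
hyper = np.mean([i.label_hyper for i in instances])
print(f"event prevalence: hypoglycemia {hypo:.1%}, hyperglycemia {hyper:.1%}\n")

inst = instances[0]
print(f"first instance (patient {inst.patient_id}, meal {inst.meal_time}):")
for name, value in zip(FEATURE_NAMES, inst.features.to_array()):
    print(f"  {name:16s} {value:9.2f}")
print(f"  labels: hypo={inst.label_hypo}  hyper={inst.label_hyper}")
print("\nLBGI/HBGI are Kovatchev risk indices (0 = no risk); the excursion "
      "is BG(meal) - BG(meal - 60 min) in mg/dL.")
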