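"""Walk through one prediction-gated bolus adjustment.

Scenario: glucose is 115 mg/dL and falling before a 60 g meal, and the
hypoglycemia system votes positive. The standard calculator would dose on
carbs plus a (negative) correction toward the 150 mg/dL target; the
adjustment shrinks the dose via the sigmoid factor, applies the alpha
uplift on the falling-trend branch, and subtracts the insulin still on
board.
"""

import numpy as np
import pandas as pd

from glycloop import TherapyParams
from glycloop.bolus import BolusConfig, recommend
from glycloop.core_io import BolusEvent, GlucoseTrace

therapy = TherapyParams(cr=9.0, cf=105.0, cgm_target=150.0)
meal_time = pd.Timestamp("2024-03-01 13:00")

# 6 h of CGM ending at the meal: stable at 130, drifting down to 115
values = np.concatenate([np.full(60, 130.0), np.linspace(130, 115, 12)])
pre = GlucoseTrace(start_time=meal_time - pd.Timedelta(minutes=355),
                   values=values, missing=np.zeros(72, bool))
prior = [BolusEvent(time=meal_time - pd.Timedelta(hours=3), units=4.0)]

rec = recommend(
    pre, meal_time, cho_announced=60.0, therapy=therapy,
    predictor=lambda v: (1, 0),        # S1 predicts hypoglycemia
    prior_boluses=prior, config=BolusConfig())

print(f"standard bolus (MIB)        {rec.mib:6.2f} U")
print(f"adjustment factor           {rec.adjustment_factor:+6.3f}")
print(f"modified bolus (B_mod)      {rec.b_mod:6.2f} U")
print(f"CGM trend                   {rec.trend_slope:+6.3f} mg/dL/min")
print(f"insulin on board            {rec.iob:6.2f} U")
print(f"branch                      {rec.branch.value}")
print(f"final bolus (B_final)       {rec.b_final:6.2f} U")
print("\nB_final = alpha * B_mod - IOB on this branch; the dose is cut "
      "relative to MIB because glucose sits below target and is falling "
      "while insulin from the previous meal is still active.")
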