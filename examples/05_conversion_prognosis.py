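"""Conversion-risk prognosis: risk panel, high/low groups, Cox regression.

Simulates baseline marker matrices for at-risk subjects whose conversion
hazard doubles-and-a-bit per SD of a latent risk score (HR 2.3), trains a
sparse risk panel on converter status, splits an independent validation
cohort into high/low risk, and compares their conversion hazards.
"""

import numpy as np
import pandas as pd

from bloodmark import prognosis
from bloodmark.synthetic import gen_conversion_cohort

train = gen_conversion_cohort(600, np.log(2.3), seed=0, n_markers=74,
                              n_informative=18, marker_loading=0.6)
valid = gen_conversion_cohort(329, np.log(2.3), seed=1, n_markers=74,
                              n_informative=18, marker_loading=0.6)

records = pd.DataFrame({"sample": np.arange(train.time.size),
                        "time": train.time, "event": train.event})
labels = prognosis.label_converters(records).to_numpy()
model = prognosis.build_risk_model(train.matrix, labels, train.marker_ids,
                                   seed=0)
groups = prognosis.assign_risk_groups(model, valid.matrix, valid.marker_ids)
result = prognosis.cox_univariate(groups, valid.time, valid.event)
summary = prognosis.nonconversion_summary(groups, valid.time, valid.event,
                                          horizon_days=300.0)

print(f"risk panel size      : {len(model.marker_ids)} markers")
print(f"validation groups    : {int(groups.sum())} high / "
      f"{int((~groups).sum())} low risk")
print(f"hazard ratio         : {result.hazard_ratio:.2f} "
      f"(p = {result.hr_p:.2e})")
for _, row in summary.iterrows():
    med = row["median_survival_days"]
    med = "not reached" if np.isnan(med) else f"{med:.0f} days"
    print(f"  {row['group']:>4}-risk: survival at 300 d = "
          f"{row['survival_at_horizon']:.2f}, median non-conversion {med}")
# HR > 1 with a small p means the frozen panel separates subjects whose
# conversion hazard is genuinely higher - the prognostic claim.
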