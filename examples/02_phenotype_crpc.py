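"""Detect castration-resistant disease from longitudinal PSA records.

Runs the phenotyping algorithm — medical/surgical castration intervals,
running PSA nadir, and the CRPC rule (doubling of nadir with the value
above 2 ng/ml, or an absolute rise of 5 ng/ml) — on a simulated registry,
then compares detected CRPC dates with the generator's ground truth.
"""

import pandas as pd

from crpc_kinetics import (AnalysisConfig, SimConfig, apply_inclusion,
                           generate_cohort)

cfg = SimConfig(n_patients=400, seed=11)
timelines, truth = generate_cohort(cfg)

result = apply_inclusion(timelines, AnalysisConfig())
print("consort-style tally:")
for reason, n in result.tally.items():
    print(f"  {reason:26s} {n}")

detected = pd.DataFrame(
    [{"patient_id": pid, "crpc_date": ev.crpc_date, "rule": ev.rule}
     for pid, ev in result.events.items()])
print("\ntriggering rule among detected events:")
print(detected["rule"].value_counts().to_string())

merged = detected.merge(truth[["patient_id", "true_crpc_date"]],
                        on="patient_id")
merged = merged[merged["true_crpc_date"].notna()]
lag = (merged["crpc_date"] - merged["true_crpc_date"]).dt.days
print(f"\ndetection lag vs noise-free truth (days): "
      f"median {lag.median():.0f}, IQR {lag.quantile(0.25):.0f}"
      f"-{lag.quantile(0.75):.0f}")
# The lag is dominated by the sampling interval: detection can only fire
# at a measured PSA, roughly one test after the curve crosses the rule.
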