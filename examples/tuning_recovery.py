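"""Simulate a binocular population and recover its tuning and mismatch.

Generates 40 orientation-tuned units with well-matched eyes (wild-type-like)
under the standard 12-direction × 6-SF × 5-repeat grating protocol, runs the
full receptive-field analysis, and compares the recovered binocular mismatch
ΔO with the generator's ground truth.
"""

import numpy as np

from binomatch import tuning
from binomatch.simulate import simulate_unit_population

pop = simulate_unit_population(40, "matched", seed=1)
metrics = tuning.analyze_units(pop.spikes, pop.trials, pop.protocol)
merged = metrics.merge(pop.truth, on="unit_id")
included = merged[merged["included"]]

err = np.minimum(
    (merged["contra_opref_deg"] - merged["opref_contra_deg"]) % 180,
    180 - (merged["contra_opref_deg"] - merged["opref_contra_deg"]) % 180,
)
print(f"units included (> 0.5 Hz peak rate): {included.shape[0]} / {len(merged)}")
print(f"median |OPref error| (contra eye):   {np.median(err):.2f} deg")
print(f"mean recovered ΔO:                   {included['delta_o_deg'].mean():.2f} deg")
print(f"mean true ΔO:                        {merged['delta_o_true_deg'].mean():.2f} deg")
print(f"mean OSI / DSI (contra):             "
      f"{included['contra_osi'].mean():.2f} / {included['contra_dsi'].mean():.2f}")
# A well-matched population keeps mean ΔO near a few degrees; a mismatched
# (knockout-like) population generated with mismatch_model="uniform" would
# push the recovered mean toward 45 deg.
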