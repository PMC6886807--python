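"""Score forecasts with range-conditioned MARD and Clarke error grid.

A model can look fine on overall MARD while failing in the rare but
clinically critical hypoglycemic range; conditioning the metric on the
ground truth's range exposes this.
"""

import numpy as np

from glycoregress import ega_report, mard_by_range

rng = np.random.default_rng(0)
actual = np.concatenate([
    rng.uniform(45, 69, 30),     # hypoglycemic ground truths
    rng.uniform(71, 179, 600),   # normal
    rng.uniform(181, 350, 300),  # hyperglycemic
])
# a biased model: accurate in range, drags lows up toward normal
predicted = np.where(actual < 70, actual + 25, actual * rng.normal(1.0, 0.08, len(actual)))
predicted = np.clip(predicted, 40, 400)

rep = mard_by_range(predicted, actual)
print(f"MARD_all  = {rep.mard_all:5.2f}%  (n={rep.n_all})")
print(f"MARD_<70  = {rep.mard_hypo:5.2f}%  (n={rep.n_hypo})   <- the bias lives here")
print(f"MARD_norm = {rep.mard_norm:5.2f}%  (n={rep.n_norm})")
print(f"MARD_>180 = {rep.mard_hyper:5.2f}%  (n={rep.n_hyper})")

ega = ega_report(predicted, actual)
print("\nClarke EGA zone frequencies (A benign ... E dangerous):")
for zone in "ABCDE":
    print(f"  zone {zone}: {ega.percentages[zone]:5.2f}%")
# The weighted identity n_all*MARD_all == sum_C n_C*MARD_C holds exactly,
# so the overall number is just the occupancy-weighted blend — which is why
# it hides the hypoglycemic failure.
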