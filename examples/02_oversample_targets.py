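"""Balance a windowed dataset with target-synthesizing SMOTE.

The key point: the regression target is interpolated with the SAME lambda
as the features, so every synthetic example is a plausible (window, future
value) pair and keeps its parents' glycemic class.
"""

from glycoregress import SimConfig, build_windows, simulate_patient, smote_regression

patient = simulate_patient(SimConfig(days=14), seed=7)
windows = build_windows(patient.train)
print("before:", windows.class_counts())

balanced = smote_regression(windows, k=5, seed=0)
print("after: ", balanced.class_counts())

prov = balanced.provenance[0]
parent_a, parent_b = prov.seed_index, prov.neighbor_index
print(f"\nfirst synthetic row (lambda = {prov.lam:.3f}):")
print(f"  parent targets : {balanced.y[parent_a]:.1f}, {balanced.y[parent_b]:.1f} mg/dl")
print(f"  synthetic target: {balanced.y[prov.row]:.1f} mg/dl "
      f"(pseudolabel {balanced.pseudolabel[prov.row]})")
# The synthetic target sits between its parents' targets at the recorded
# interpolation fraction; minority classes now match the majority count.
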