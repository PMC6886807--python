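"""Simulate one patient's CGM record and turn it into supervised examples.

Builds a two-week synthetic trace (5-min readings, gaps, normoglycemic
dominance), splits it chronologically, and windows the training part into
24-reading feature vectors with 30-min-ahead targets and glycemic
pseudolabels.
"""

from glycoregress import SimConfig, build_windows, range_occupancy, simulate_patient

patient = simulate_patient(SimConfig(days=14), seed=7, patient_id="demo")

hypo, norm, hyper = range_occupancy(patient.train)
print(f"training readings: {len(patient.train)} "
      f"({patient.train.n_gaps()} gaps in the trace)")
print(f"range occupancy:   {hypo:.1%} hypo / {norm:.1%} normal / {hyper:.1%} hyper")

windows = build_windows(patient.train)
print(f"windows:           {len(windows)} "
      f"(each = 24 consecutive readings + target 30 min after the window)")
print(f"class counts:      {windows.class_counts()}")
print()
print("First window, last 4 features then target/pseudolabel:")
print(f"  ...{windows.X[0, -4:].round(1)} -> bg_t+30 = {windows.y[0]:.1f} "
      f"({windows.pseudolabel[0]})")
# The class counts show the imbalance the oversamplers exist to fix: the
# hypoglycemic class is a few percent of the data at most.
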