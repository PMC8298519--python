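"""Smooth segments, remove expert-percentile outliers, extract the 37 features.

Prints the expert thresholds (1st/99th percentiles of per-segment max force,
min force and duration), the outlier fraction, and a few feature values for
one segment.
"""

from surgforce import (
    FeatureConfig,
    FilterSpec,
    extract_all,
    fit_expert_thresholds,
    flag_outliers,
    make_fixture,
    remove_outliers,
    smooth_table,
)

ds = make_fixture("tiny", seed=7)
smoothed = smooth_table(ds.table, FilterSpec(order=4, cutoff=2.0))

thr = fit_expert_thresholds(smoothed)
print(f"expert thresholds from {thr.n_expert_segments} segments:")
print(f"  max force  [{thr.max_force_p1:.3f}, {thr.max_force_p99:.3f}] N")
print(f"  duration   [{thr.duration_p1:.2f}, {thr.duration_p99:.2f}] s")

flags = flag_outliers(smoothed, thr)
print(f"flagged {int(flags['flagged'].sum())}/{len(flags)} segments as outliers")
clean = remove_outliers(smoothed, thr)

features = extract_all(clean, FeatureConfig())
row = features.iloc[0]
print(f"\nsegment {row['segment_id']} ({row['task']}, {row['experience']}):")
for name in ("duration", "mean", "range", "sd", "peak_count", "spectral_entropy", "trend"):
    print(f"  {name:>18} = {row[name]:.4f}")
print(f"feature table: {features.shape[0]} segments x {features.shape[1] - 5} features")
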