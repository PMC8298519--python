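"""Compare a surgeon to the expert baseline on the four dashboard gauges.

Gauges: task completion time, force range, force variability index
(mean-crossing rate) and force uncertainty index (spectral entropy).  Each
is reported as the surgeon's mean over the selected cases with a z-score
against the expert mean +/- SD.
"""

from surgforce import compute_baseline, extract_all, gauge_panel, make_fixture

features = extract_all(make_fixture("tiny", seed=7).table)

baseline = compute_baseline(features)
print(f"expert baseline from {baseline.n_expert_segments} segments:")
for metric, stats in baseline.metrics.items():
    print(f"  {metric:>18}: {stats['expert_mean']:.3f} +/- {stats['expert_sd']:.3f}")

panel = gauge_panel(features, "NOV01", None, baseline)
print(f"\ngauge panel for {panel.surgeon_id} ({panel.n_segments} segments, "
      f"cases {panel.case_range[0]}..{panel.case_range[-1]}):")
for metric, g in panel.metrics.items():
    print(f"  {metric:>18}: {g['surgeon_value']:.3f}  (z = {g['z_score']:+.2f})")
print("\npositive z = above the expert mean; variability/uncertainty above the "
      "expert level are the signature of a less economical force profile")
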