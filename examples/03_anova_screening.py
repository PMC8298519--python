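"""Screen features with two-way ANOVA (experience x task) and select a subset.

Each feature is tested for experience and task main effects (Type II sums
of squares, suited to unbalanced layouts) plus their interaction; the fixed
rule then drops the 12 uninformative features, keeping 25 for modelling.
"""

from surgforce import anova_screen, extract_all, make_fixture, posthoc_tasks, select_model_subset

features = extract_all(make_fixture("tiny", seed=7).table)

report = anova_screen(features)
top = report.rows.nsmallest(5, "p_experience")[["feature", "f_experience", "p_experience", "p_task"]]
print("features most sensitive to experience level:")
print(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

ph = posthoc_tasks(features, "range")
print(f"\nTukey HSD task contrasts for force range ({len(ph)} pairs), most separated:")
print(ph.nsmallest(3, "p_adjusted").to_string(index=False, float_format=lambda v: f"{v:.4g}"))

selected = select_model_subset(report, mode="fixed")
print(f"\nfixed model subset keeps {len(selected)} of 37 features")
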