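"""Train the skill classifier and the task recognizer on synthetic segments.

Skill: standardize -> PCA -> RBF-SVM on the 25-feature subset, grid-searched
by cross-validated accuracy.  Task: fixed-length resampled force profiles
into a single-layer LSTM with dropout, dense ReLU and softmax over the 5
task classes.  Both report held-out metrics.
"""

from surgforce import (
    SkillModelConfig,
    TaskModelConfig,
    default_study_spec,
    extract_all,
    generate,
    predict_task,
    train_skill_model,
    train_task_model,
    with_counts,
)

# 50 segments per (task, experience) cell = 500 segments
table = generate(with_counts(default_study_spec(), 50), seed=7).table
features = extract_all(table)

skill, _ = train_skill_model(features, SkillModelConfig(seed=0))
print("skill model (Expert vs Novice):")
print(f"  AUC {skill.auc:.3f}  train acc {skill.train_accuracy:.3f}  test acc {skill.test_accuracy:.3f}")
print(f"  sensitivity {skill.sensitivity:.3f}  specificity {skill.specificity:.3f}")
print(f"  best cost {skill.best_cost:.4g}, gamma {skill.best_gamma:.4g}, "
      f"{skill.n_components_used} principal components")

task, fitted = train_task_model(table, TaskModelConfig(epochs=60, n_repeats=2, seed=0))
print("\ntask recognizer (5 classes, held-out, mean (SD) over repeats):")
print(f"  loss {task.mean_loss:.3f} ({task.sd_loss:.3f})")
print(f"  accuracy {task.mean_accuracy:.3f} ({task.sd_accuracy:.3f})")
print(f"  MSE {task.mean_mse:.3f} ({task.sd_mse:.3f})")

pred = predict_task(fitted, table.segments[:3])
print("\nsample predictions:")
print(pred[["segment_id", "label"]].to_string(index=False))
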