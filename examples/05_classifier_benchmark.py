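"""Benchmark the four-learner harness on full six-curve feature vectors.

A separable synthetic cohort (class biomarker means 8 degC apart) is turned
into concatenated six-curve features and evaluated by stratified 5-fold
cross-validation with leakage-safe per-fold z-scoring. Accuracies are
reported as mean +/- 95% CI over folds, with pooled confusion rates.
"""

from tfdp import (
    ClassSpec,
    CohortConfig,
    assemble_features,
    confusion_rates,
    generate_cohort,
    run_cv,
)

cfg = CohortConfig(
    control=ClassSpec(64.0, 78.0, sd_t1m=0.5, sd_t2m=0.5, n=20),
    poag=ClassSpec(56.0, 70.0, sd_t1m=0.5, sd_t2m=0.5, n=20),
    seed=31,
)
dataset = generate_cohort(cfg)
X, y = assemble_features(dataset.runs, grid_step=1.0)
print(f"feature matrix: {X.shape[0]} samples x {X.shape[1]} features")

report = run_cv(X, y, seed=31)
print(f"\n{'algorithm':10s} {'accuracy %':>12s} {'sens %':>8s} {'FPR %':>7s}")
for algorithm, res in report.results.items():
    rates = confusion_rates(res)
    print(
        f"{algorithm:10s} {res.mean_accuracy_pct:6.1f} +/- {res.ci_halfwidth_pct:4.1f}"
        f" {rates.sensitivity_pct:8.1f} {rates.false_positive_rate_pct:7.1f}"
    )

print(
    "\nOn a cohort this well separated every learner should be near-perfect;"
    "\nthe harness exists to compare learners fairly (shared folds, per-fold"
    "\nscaling, fixed published hyperparameters) rather than to tune them."
)
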