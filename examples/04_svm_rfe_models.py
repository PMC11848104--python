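"""Train the 15 individual response models on a synthetic cohort.

A table-level cohort (60 lesions, 3 planted discriminative features at
effect size d = 2) is pushed through every timepoint mode x region series
configuration. Series with feature selection (D, E) should find the
planted features and score well; series restricted to uninformative
regions hover near chance.
"""

from gradiomics import CohortSpec, make_feature_cohort, run_all_individual_models

cohort = make_feature_cohort(CohortSpec(
    n_lesions=60, class_balance=0.5, seed=4,
    planted_features={"oct_RAS_GM_mean": 2.0, "oct_LPI_RD_std": 2.0, "core_GM_mean": 2.0},
))
reports = run_all_individual_models(cohort, folds=5, iters=10, seed=0)
print(f"{len(reports)} models evaluated\n")
print("model  AUC    F1     selected-from")
for name, rep in reports.items():
    pool = "fixed 9" if rep.selection is None else f"pool of {len(rep.selection.frequency)}"
    print(f"{name:5s}  {rep.metrics.mean('auc'):.3f}  {rep.metrics.mean('f1'):.3f}  {pool}")
print("\nThe planted signal lives in the first scan, so 1D/1E lead; delta mode")
print("(3x) inherits it with flipped sign (delta = mri2 - mri1). Second-MRI")
print("models exceed chance only through selection optimism: selection is")
print("non-nested here, mirroring the frequency-RFE procedure's known bias.")
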