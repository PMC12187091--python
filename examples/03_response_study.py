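"""End-to-end immunotherapy-response study on synthetic phantoms.

Simulate a cohort whose tumor texture depends on the response label, extract
radiomics, harmonize/normalize/prune/ANOVA-select, compare classifiers under
5-fold CV, and evaluate the Radscore on a held-out split.
"""

import warnings

warnings.filterwarnings("ignore")

from radpath.pipeline import RunConfig, run_response_study

cfg = RunConfig(
    n_patients=120,
    seed=42,
    texture_contrast=0.05,  # much milder planted effect than the study default
    algorithms=("random_forest", "logistic_regression", "svm"),
    bootstrap=200,
)
report = run_response_study(cfg)

print("CV leaderboard (training split):")
for row in report["leaderboard"]:
    print(f"  {row['algorithm']:22s} AUC {row['cv_auc_mean']:.3f} "
          f"+/- {row['cv_auc_sd']:.3f}")
print(f"selected features: {report['selected_features'][:3]} ...")
print(f"held-out AUC {report['test']['auc']:.3f} "
      f"(sens {report['test']['sensitivity']:.2f}, "
      f"spec {report['test']['specificity']:.2f}) at the "
      f"training-frozen Youden threshold {report['test']['threshold']:.3f}")
dl = report["delong_radiomic_vs_clinical"]
print(f"DeLong radiomic vs clinical: z = {dl['z']:.2f}, p = {dl['p']:.3g}")
# The planted texture contrast separates responders, so the radiomic model
# should clearly beat the (uninformative) clinical covariates.
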