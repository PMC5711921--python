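"""Train the two-stage network cascade (ANN I -> ANN II = DANN) and evaluate it.

ANN I regresses normalized spine BMD on the marker plus five examination
items.  For each participant the rest of the cohort is then ranked by
Euclidean distance and cut into m divisions; four derivative features (own
ANN I output, division mean output, division mean distance, division
osteoporosis proportion) feed ANN II.  The division size m and the division
index are picked on the verification split.
"""

from osteomir import MODEL_FEATURES, GeneratorConfig, generate_cohort, train_dann
from osteomir.evaluation import optimal_cutoff, roc, se_at_fixed_sp

cohort = generate_cohort(GeneratorConfig(), seed=1)
model, diag = train_dann(cohort, MODEL_FEATURES, seed=1)

print(f"ANN I : R_Tr = {diag.ann1_report.r_train:.3f}, "
      f"R_Te = {diag.ann1_report.r_test:.3f} "
      f"({diag.ann1_report.n_centers} centers)")
print(f"ANN II: R_Tr = {diag.ann2_report.r_train:.3f}, "
      f"R_Te = {diag.ann2_report.r_test:.3f}")
print(f"selected division size m = {model.m}, division index = {model.d_index}")
print(f"Spearman rho(DANN output, BMD) on the cohort = {diag.rho_full:.3f}")

scores = model.score_internal()
res = roc(scores, cohort.risk_labels(), orientation="low")
thr, se, sp = optimal_cutoff(res)
print(f"\nROC for osteoporosis detection (low score = at risk):")
print(f"  AUC = {res.auc:.3f}")
print(f"  Youden-optimal cut-off {thr:.2f}: SE = {se:.2f}, SP = {sp:.2f}")
print(f"  SE at SP >= 0.9: {se_at_fixed_sp(res, 0.9):.2f}")
print("\nSimilar R_Tr/R_Te indicate the networks generalize rather than "
      "memorize; the DANN rho exceeding the single-marker |rho| (~0.37) is "
      "the gain from integrating the examination items.")
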