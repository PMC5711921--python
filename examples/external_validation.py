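"""Score an independent external cohort with a trained DANN.

External participants are ranked against the stored training reference
(normalized features, first-stage outputs and osteoporosis labels of the
training cohort), so no retraining is needed.  The binary risk call uses the
published cut-off of 0.38 on the BMD-like score.
"""

from scipy import stats

from osteomir import (
    MODEL_FEATURES,
    GeneratorConfig,
    accuracy_at_threshold,
    delong_test,
    external_cohort_config,
    generate_cohort,
    train_dann,
)

train_cohort = generate_cohort(GeneratorConfig(), seed=1)
model, _ = train_dann(train_cohort, MODEL_FEATURES, seed=1)

external = generate_cohort(external_cohort_config(), seed=11)
scores = model.score_external(external)
labels = external.risk_labels()

rho, p = stats.spearmanr(scores, external.bmd)
acc = accuracy_at_threshold(scores, labels, 0.38, orientation="low")
print(f"external cohort: n = {len(external)}, "
      f"groups = {external.status_counts()}")
print(f"Spearman rho(score, BMD) = {rho:.3f} (p = {p:.3g})")
print(f"accuracy at cut-off 0.38: {acc:.1%} "
      f"({int(acc * len(external))}/{len(external)} correct)")

comp = delong_test(train_cohort.df["mir194"].to_numpy(),
                   model.score_internal(), train_cohort.risk_labels(),
                   orientation1="high", orientation2="low")
print(f"\npaired AUC comparison on the training cohort (DeLong):")
print(f"  marker alone AUC = {comp.auc1:.3f}, DANN AUC = {comp.auc2:.3f}, "
      f"p = {comp.p:.4f}")
print("\nA small DeLong p means the panel model's ROC improvement over the "
      "marker alone is unlikely to be chance on paired subjects.")
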