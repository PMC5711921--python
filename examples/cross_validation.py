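"""Leakage-safe 10-fold cross-validation of the whole DANN system.

Everything — normalization, ANN I, the (m, division) search, ANN II and the
derivative-feature reference — is refitted inside each training fold; each
participant is scored only by a model that never saw her fold.
"""

from osteomir import MODEL_FEATURES, GeneratorConfig, generate_cohort, kfold_cv
from osteomir.evaluation import se_at_fixed_sp

cohort = generate_cohort(GeneratorConfig(), seed=1)
cv = kfold_cv(cohort, MODEL_FEATURES, k=10, seed=1)

print(f"pooled out-of-fold scores for {len(cv.scores)} participants")
print(f"Spearman rho(score, BMD) = {cv.rho:.3f}")
print(f"AUC for osteoporosis detection = {cv.roc.auc:.3f}")
print(f"SE at SP >= 0.9 = {se_at_fixed_sp(cv.roc, 0.9):.2f}")
print(f"division sizes selected per fold: {cv.selected_m}")
print("\nOut-of-fold numbers are lower than full-cohort ones by design: they "
      "estimate how the system would score genuinely new participants.")
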