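"""Draw a synthetic cohort and screen for BMD-correlated examination items.

The cohort emulates a postmenopausal study population: one circulating
miRNA marker, 42 routine examination items, spine BMD and T-score.  The
screen keeps items with |Spearman rho| > 0.1 and p < 0.01 against BMD and
then checks candidate inputs for collinearity (|rho| > 0.3).
"""

from osteomir import (
    GeneratorConfig,
    collinearity,
    generate_cohort,
    screen_items,
    select_model_inputs,
)

cohort = generate_cohort(GeneratorConfig(), seed=1)
print(f"cohort: {len(cohort)} participants, groups = {cohort.status_counts()}")

records = screen_items(cohort)
flagged = [r for r in records if r.bmd_correlated]
print(f"\n{len(flagged)} items pass the screen (|rho| > 0.1 and p < 0.01):")
for r in sorted(flagged, key=lambda r: -abs(r.rho)):
    print(f"  {r.item:10s} rho = {r.rho:+.3f}  p = {r.p:.2e}  [{r.band}]")

matrix = collinearity(cohort)
print(f"\ncollinear pairs (|rho| > 0.3) among all items:")
for a, b in matrix.flagged_pairs():
    print(f"  {a} - {b}: |rho| = {matrix.value(a, b):.2f}")

inputs = select_model_inputs(records, matrix, mode="noncollinear", max_eis=5,
                             registry_order=cohort.item_names)
print(f"\nselected model inputs (marker first, collinearity pruned): {inputs}")
print("\nThe marker's negative rho means higher circulating expression goes "
      "with lower bone density; pruning keeps one member of each collinear "
      "pair so the model inputs are not redundant.")
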