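"""Generate a synthetic longitudinal cohort and preprocess it.

Builds a small cohort with three planted progression paces plus healthy
controls, then runs the imputation pipeline and prints the distributional
shift it introduced: near-zero values mean imputation barely distorted the
observed feature distributions.
"""

import numpy as np

from pdprog import (
    GeneratorConfig,
    fit_normalization,
    generate,
    imputation_shift,
    impute,
    normalize,
    score_matrix,
)

cfg = GeneratorConfig(
    n_per_subtype={"rapid": 15, "moderate": 15, "slow": 15, "HC": 15}, seed=42)
cohort, labels = generate(cfg)
n_cells = sum(len(p) for p in cohort.participants)
observed = sum(int(v.mask.sum()) for p in cohort.participants for v in p.visits)
total = sum(v.mask.size for p in cohort.participants for v in p.visits)
print(f"cohort: {len(cohort)} participants, {n_cells} visits, "
      f"{100 * (1 - observed / total):.1f}% missing cells")

imputed = impute(cohort)
shift = imputation_shift(cohort, imputed)
print(f"imputation shift |d mean| = {shift.mean_delta_mean:.4f}, "
      f"|d std| = {shift.mean_delta_std:.4f}, z-distance = {shift.mean_z_distance:.3f}")
print("  (averaged over features; small values = distributions preserved)")

normalized = normalize(imputed, fit_normalization(imputed))
one = imputed.participants[0]
scores = score_matrix(one, imputed.schema)
print(f"\nparticipant {one.participant_id} ({labels[one.participant_id].value}):")
for v, (u1, u2, u3) in zip(one.visit_indices(), scores):
    print(f"  visit {v:2d} (month {6 * v:2d}): "
          f"UPDRS I={u1:5.1f}  II={u2:5.1f}  III={u3:5.1f}")
print("rising part-III totals reflect the planted progression pace")
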