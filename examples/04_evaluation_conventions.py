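"""The report types and their aggregation conventions.

Shows, on toy numbers, how the summary-table and horizon-table conventions
differ, and how two models are compared with the paired Wilcoxon
signed-rank test.
"""

import numpy as np

from pdprog import classification_report, paired_wilcoxon, regression_report
from pdprog.evaluation import (
    classification_errors,
    horizon_report,
    macro_recall_from_accuracies,
    overall_mse_from,
    overall_rmse_from,
    quadratic_mean,
)

# summary-table conventions from per-class accuracies / per-score MSEs
acc = [78.87, 76.42, 71.43, 100.0]
print(f"per-class accuracies {acc}")
print(f"  macro recall (their unweighted mean) = "
      f"{macro_recall_from_accuracies(acc):.2f}")
mses = (9.15, 8.30, 41.39)
print(f"per-score MSEs {mses}")
print(f"  overall MSE  (mean of MSEs)        = {overall_mse_from(mses):.2f}")
print(f"  overall RMSE (mean of root-MSEs)   = {overall_rmse_from(mses):.2f}")
print(f"  quadratic mean of (3.20, 3.11, 6.85) = "
      f"{quadratic_mean((3.20, 3.11, 6.85)):.2f}  <- horizon-table pooling")

# full reports on simulated predictions
rng = np.random.default_rng(0)
truth = rng.integers(0, 4, 200)
pred = np.where(rng.random(200) < 0.85, truth, rng.integers(0, 4, 200))
r = classification_report(pred, truth)
print(f"\nsimulated classifier: overall accuracy {r.overall_accuracy:.1f}%, "
      f"macro F1 {r.macro_f1:.1f}%")

u = rng.random((200, 3)) * 40
rr = regression_report(u + rng.normal(0, 2, (200, 3)), u)
print(f"simulated regressor: overall RMSE {rr.overall_rmse:.2f}, "
      f"R^2 {rr.overall_r2:.2f}")

# paired model comparison: model A is genuinely a little better
probs_a = np.full((200, 4), 0.05)
probs_a[np.arange(200), truth] = 0.85
probs_b = np.full((200, 4), 0.10)
probs_b[np.arange(200), truth] = 0.70
jitter = rng.normal(0, 0.02, 200)
err_a = np.clip(classification_errors(probs_a, truth) + jitter, 0, 1)
err_b = np.clip(classification_errors(probs_b, truth) - jitter, 0, 1)
stat, p = paired_wilcoxon(err_a, err_b)
print(f"\nWilcoxon signed-rank A vs B: statistic={stat:.0f}, p={p:.2e}")
print("  (small p: the per-instance error distributions genuinely differ)")
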