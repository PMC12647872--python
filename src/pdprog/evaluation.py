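"""Evaluation reports with explicit aggregation conventions.

Two different "overall RMSE" conventions coexist in this problem's reporting
tradition and both are implemented explicitly, never inferred from context:

* summary tables: overall MSE = arithmetic mean of the three per-score MSEs
  and overall RMSE = arithmetic mean of the three per-score RMSEs;
* horizon tables: the overall column is the quadratic mean (root of the mean
  of squares) of the three per-score RMSE values.

Classification reports use per-class accuracy (= recall of the class),
pooled micro accuracy, and macro-averaged precision/recall/F1, all on the
percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortError


@dataclass
class ClassificationReport:
    per_class_accuracy: dict[str, float]  # percent; NaN if class absent
    overall_accuracy: float  # pooled micro accuracy, percent
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # (C, C) rows = truth, cols = prediction
    class_names: tuple[str, ...]


@dataclass
class RegressionReport:
    per_score_mse: tuple[float, float, float]
    overall_mse: float  # arithmetic mean of the three MSEs
    overall_rmse: float  # arithmetic mean of the three per-score RMSEs
    overall_r2: float  # pooled across the three scores


@dataclass
class HorizonReport:
    horizons: list[int]
    rmse_at: dict[int, tuple[float, float, float]]
    rmse_at_overall: dict[int, float]  # quadratic mean over scores
    mean_rmse_upto: dict[int, tuple[float, float, float]]
    mean_rmse_upto_overall: dict[int, float]


DEFAULT_CLASSES = ("rapid", "moderate", "slow", "HC")


def classification_report(predictions, truth,
                          class_names: tuple[str, ...] = DEFAULT_CLASSES
                          ) -> ClassificationReport:
    """Accuracy/precision/recall/F1 on the percent scale.

    A truth class absent from the data gets NaN per-class metrics and is
    excluded from the macro means (with a warning).
    """
    y_pred = np.asarray(predictions, dtype=int)
    y_true = np.asarray(truth, dtype=int)
    if y_pred.shape != y_true.shape:
        raise CohortError("predictions and truth must have equal length")
    c = len(class_names)
    conf = np.zeros((c, c), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    per_acc: dict[str, float] = {}
    precisions, recalls, f1s = [], [], []
    for j, name in enumerate(class_names):
        support = conf[j].sum()
        if support == 0:
            warnings.warn(f"class {name} absent from the data; excluded from macros")
            per_acc[name] = float("nan")
            continue
        recall = conf[j, j] / support
        pred_j = conf[:, j].sum()
        precision = conf[j, j] / pred_j if pred_j > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        per_acc[name] = 100.0 * recall
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
    return ClassificationReport(
        per_acc,
        100.0 * conf.trace() / conf.sum(),
        100.0 * float(np.mean(precisions)),
        100.0 * float(np.mean(recalls)),
        100.0 * float(np.mean(f1s)),
        conf, class_names,
    )


def macro_recall_from_accuracies(per_class_acc) -> float:
    """The summary-table identity: macro recall = unweighted mean of the
    per-class accuracies (percent in, percent out)."""
    return float(np.mean(np.asarray(per_class_acc, dtype=float)))


def regression_report(predicted, truth) -> RegressionReport:
    """Per-score MSE plus the summary-table aggregation conventions."""
    u_hat = np.asarray(predicted, dtype=float).reshape(-1, 3)
    u = np.asarray(truth, dtype=float).reshape(-1, 3)
    if u_hat.shape != u.shape or u.shape[0] == 0:
        raise CohortError("predicted/truth must be equal-length, non-empty triplets")
    mse = tuple(float(np.mean((u_hat[:, j] - u[:, j]) ** 2)) for j in range(3))
    ss_res = float(np.sum((u_hat - u) ** 2))
    ss_tot = float(np.sum((u - u.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return RegressionReport(
        mse,
        overall_mse=float(np.mean(mse)),
        overall_rmse=float(np.mean([np.sqrt(m) for m in mse])),
        overall_r2=r2,
    )


def overall_mse_from(per_score_mse) -> float:
    return float(np.mean(np.asarray(per_score_mse, dtype=float)))


def overall_rmse_from(per_score_mse) -> float:
    return float(np.mean(np.sqrt(np.asarray(per_score_mse, dtype=float))))


def quadratic_mean(values) -> float:
    """Root of the mean of squares — the horizon-table overall convention."""
    v = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean(v ** 2)))


def horizon_report(predictions_by_horizon: dict[int, np.ndarray],
                   truth_by_horizon: dict[int, np.ndarray]) -> HorizonReport:
    """Horizon-wise forecast errors.

    ``predictions_by_horizon[h]``: (N_h, 3) step-h predictions (from
    autoregressive decoding); truth analogous.  RMSE *at* h uses step-h
    predictions only; *mean up to* h pools steps 1..h; the overall column is
    the quadratic mean of the three per-score values.
    """
    horizons = sorted(predictions_by_horizon)
    if horizons != list(range(1, len(horizons) + 1)):
        raise CohortError(f"horizons must be contiguous from 1, got {horizons}")
    if sorted(truth_by_horizon) != horizons:
        raise CohortError("truth horizons must match prediction horizons")
    rmse_at, rmse_at_all = {}, {}
    upto, upto_all = {}, {}
    pooled_sq = [[] for _ in range(3)]
    for h in horizons:
        p = np.asarray(predictions_by_horizon[h], dtype=float).reshape(-1, 3)
        t = np.asarray(truth_by_horizon[h], dtype=float).reshape(-1, 3)
        if p.shape != t.shape:
            raise CohortError(f"horizon {h}: prediction/truth shape mismatch")
        sq = (p - t) ** 2
        vals = tuple(float(np.sqrt(np.mean(sq[:, j]))) for j in range(3))
        rmse_at[h] = vals
        rmse_at_all[h] = quadratic_mean(vals)
        for j in range(3):
            pooled_sq[j].append(sq[:, j])
        m = tuple(float(np.sqrt(np.mean(np.concatenate(pooled_sq[j]))))
                  for j in range(3))
        upto[h] = m
        upto_all[h] = quadratic_mean(m)
    return HorizonReport(horizons, rmse_at, rmse_at_all, upto, upto_all)


def mean_std_over_windows(metric_by_window: dict[int, float]) -> tuple[float, float]:
    """Summary-table "mean ± std over input lengths": the mean and population
    standard deviation of a metric across the per-window-size evaluations
    (W = 2..5)."""
    v = np.array(list(metric_by_window.values()), dtype=float)
    return float(v.mean()), float(v.std())


def paired_wilcoxon(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-instance errors.

    Classification errors are 1 - p(true class); regression errors the
    per-instance squared error summed over the three scores.  Zero
    differences are dropped (the standard convention); if every difference
    is zero the degenerate return is (0, 1).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise CohortError("paired error vectors must be 1-D and equal length")
    if a.size < 5:
        raise CohortError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def classification_errors(probabilities: np.ndarray, truth) -> np.ndarray:
    """Per-instance error 1 - p_true for Wilcoxon pairing."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=int)
    return 1.0 - p[np.arange(len(y)), y]


def regression_errors(predicted, truth) -> np.ndarray:
    """Per-instance squared error summed over the three scores."""
    u_hat = np.asarray(predicted, dtype=float).reshape(-1, 3)
    u = np.asarray(truth, dtype=float).reshape(-1, 3)
    return np.sum((u_hat - u) ** 2, axis=1)


@dataclass
class Strata:
    sex: np.ndarray  # "M"/"F" per instance
    age: np.ndarray  # years per instance


def stratified_report(class_predictions, class_truth, reg_predicted, reg_truth,
                      strata: Strata, age_cut: float = 60.0) -> dict[str, dict]:
    """Classification + regression reports within demographic subgroups
    (female, male, age < cut, age >= cut); empty subgroups are skipped with
    a warning."""
    sex = np.asarray(strata.sex)
    age = np.asarray(strata.age, dtype=float)
    groups = {
        "female": sex == "F",
        "male": sex == "M",
        f"age<{age_cut:g}": age < age_cut,
        f"age>={age_cut:g}": age >= age_cut,
    }
    out: dict[str, dict] = {}
    cp = np.asarray(class_predictions)
    ct = np.asarray(class_truth)
    rp = np.asarray(reg_predicted, dtype=float)
    rt = np.asarray(reg_truth, dtype=float)
    for name, sel in groups.items():
        if not sel.any():
            warnings.warn(f"subgroup {name} is empty; skipped")
            continue
        out[name] = {
            "n": int(sel.sum()),
            "classification": classification_report(cp[sel], ct[sel]),
            "regression": regression_report(rp[sel], rt[sel]),
        }
    return out


def export_embeddings(model, samples, path=None) -> list[dict]:
    """One row per window: id, window spec, the 16 DiSE values, predicted and
    true labels.  Deterministic in evaluation mode; optionally written as TSV
    for external UMAP/PCA/SHAP tooling."""
    from .nn import softmax as _softmax
    from .nn import Tensor  # noqa: F401  (re-exported for symmetry)

    model.eval()
    rows = []
    for s in samples:
        x = s.input_vectors[None]
        pad = np.zeros((1, x.shape[1]), dtype=bool)
        d = model.dise_encode(model.sive_encode(x), padding_mask=pad)
        logits = model.classify(d)
        pred = int(np.argmax(logits.data[0]))
        rows.append({
            "participant_id": s.participant_id,
            "window": ",".join(str(v) for v in s.input_visit_indices),
            "embedding": d.data[0].copy(),
            "predicted_class": pred,
            "true_class": s.label.class_index,
        })
    if path is not None:
        dim = len(rows[0]["embedding"]) if rows else 16
        with open(path, "w") as fh:
            cols = ["participant_id", "window",
                    *[f"dise_{i}" for i in range(dim)],
                    "predicted_class", "true_class"]
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(
                    [r["participant_id"], r["window"],
                     *[format(v, ".10g") for v in r["embedding"]],
                     str(r["predicted_class"]), str(r["true_class"])]) + "\n")
    return rows
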