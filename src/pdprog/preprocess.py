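"""Coverage filtering, imputation, normalization and imputation diagnostics.

The imputation scheme is the simplest one consistent with longitudinal
clinical scores: static features are carried as the participant's observed
constant; time-varying features are filled by an ordinary-least-squares line
over visit_index fitted per (participant, feature), evaluated at the missing
visits and clipped to the feature's declared range.  This preserves each
participant's own trend instead of borrowing strength across participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, CohortError, ParticipantTrajectory, VisitRecord


@dataclass(frozen=True)
class CoverageThresholds:
    """Minimum observation coverage for keeping features and participants.

    ``min_feature_coverage``: fraction of participants with at least one
    observation of the feature.  ``min_participant_coverage``: fraction of
    (remaining) schema features the participant has observed at least once.
    """

    min_feature_coverage: float = 0.0
    min_participant_coverage: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.min_feature_coverage, self.min_participant_coverage):
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"coverage threshold {v} outside [0, 1]")


@dataclass
class RemovalReport:
    removed_features: list[str] = field(default_factory=list)
    removed_participants: list[str] = field(default_factory=list)


def filter_by_coverage(
    cohort: Cohort, thresholds: CoverageThresholds
) -> tuple[Cohort, RemovalReport]:
    """Drop sparse features, then sparse participants, in a single pass.

    Feature coverage is computed on the input cohort; participant coverage on
    the reduced schema.  Removing every feature or participant is an error.
    """
    from .cohort import FeatureSchema

    n_p = len(cohort)
    if n_p == 0:
        return cohort, RemovalReport()
    n_f = len(cohort.schema)
    obs = np.zeros((n_p, n_f), dtype=bool)  # participant x feature: observed >=1 time
    for i, p in enumerate(cohort.participants):
        for v in p.visits:
            obs[i] |= v.mask

    feat_cov = obs.mean(axis=0)
    keep_f = feat_cov >= thresholds.min_feature_coverage
    report = RemovalReport(
        removed_features=[f.name for f, k in zip(cohort.schema.features, keep_f) if not k]
    )
    if not keep_f.any():
        raise CohortError(
            f"coverage thresholds remove all features (max coverage {feat_cov.max():.3f})"
        )
    part_cov = obs[:, keep_f].mean(axis=1)
    keep_p = part_cov >= thresholds.min_participant_coverage
    report.removed_participants = [
        p.participant_id for p, k in zip(cohort.participants, keep_p) if not k
    ]
    if not keep_p.any():
        raise CohortError(
            f"coverage thresholds remove all participants (max coverage {part_cov.max():.3f})"
        )

    new_schema = FeatureSchema([f for f, k in zip(cohort.schema.features, keep_f) if k])
    idx = np.flatnonzero(keep_f)
    new_parts = []
    for p, k in zip(cohort.participants, keep_p):
        if not k:
            continue
        visits = [VisitRecord(v.visit_index, v.values[idx], v.mask[idx]) for v in p.visits]
        new_parts.append(ParticipantTrajectory(p.participant_id, p.group, visits,
                                               sex=p.sex, age_at_baseline=p.age_at_baseline))
    return Cohort(new_schema, new_parts), report


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (intercept, slope) of y over x."""
    xm, ym = x.mean(), y.mean()
    den = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / den) if den > 0 else 0.0
    return ym - slope * xm, slope


def impute(cohort: Cohort) -> Cohort:
    """Fill every missing cell; never alter an observed one.

    Static features: the participant's observed constant (error if none —
    run coverage filtering first).  Time-varying features: per-(participant,
    feature) OLS line over visit_index, clipped to the feature's range; one
    observation falls back to constant extension; zero observations to the
    cohort median at that visit (then the global feature median).
    """
    schema = cohort.schema
    n_f = len(schema)
    lo = np.array([f.value_range[0] for f in schema.features])
    hi = np.array([f.value_range[1] for f in schema.features])
    static = np.array([f.kind == "static" for f in schema.features])
    binary = np.array([f.is_binary for f in schema.features])

    # cohort-level fallbacks: per-(visit, feature) medians and global medians
    per_visit: dict[int, list[np.ndarray]] = {}
    all_obs: list[tuple[np.ndarray, np.ndarray]] = []
    for p in cohort.participants:
        for v in p.visits:
            per_visit.setdefault(v.visit_index, []).append(
                np.where(v.mask, v.values, np.nan))
            all_obs.append((v.values, v.mask))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns are expected
        visit_median = {
            vi: np.nanmedian(np.stack(rows), axis=0) for vi, rows in per_visit.items()
        }
    stacked = np.stack([np.where(m, val, np.nan) for val, m in all_obs])
    with np.errstate(invalid="ignore"):
        global_median = np.nanmedian(stacked, axis=0)
    global_median = np.where(np.isnan(global_median), 0.0, global_median)

    new_parts = []
    for p in cohort.participants:
        vis_idx = np.array(p.visit_indices(), dtype=float)
        vals = np.stack([v.values for v in p.visits])  # (n_v, n_f)
        mask = np.stack([v.mask for v in p.visits])
        out = vals.copy()
        for j in range(n_f):
            col_mask = mask[:, j]
            if col_mask.all():
                continue
            obs_x, obs_y = vis_idx[col_mask], vals[col_mask, j]
            missing = ~col_mask
            if static[j]:
                if obs_y.size == 0:
                    raise CohortError(
                        f"{p.participant_id}: static feature "
                        f"{schema.features[j].name} has no observation — filter first")
                out[missing, j] = obs_y[0]
            elif obs_y.size >= 2:
                b0, b1 = _ols_line(obs_x, obs_y)
                pred = np.clip(b0 + b1 * vis_idx[missing], lo[j], hi[j])
                # binary flags take valid levels, not fractional line values
                out[missing, j] = np.round(pred) if binary[j] else pred
            elif obs_y.size == 1:
                out[missing, j] = np.clip(obs_y[0], lo[j], hi[j])
            else:
                for r in np.flatnonzero(missing):
                    med = visit_median.get(int(vis_idx[r]), global_median)[j]
                    val = global_median[j] if np.isnan(med) else med
                    out[r, j] = np.round(val) if binary[j] else val
        visits = [VisitRecord(int(vi), out[r], np.ones(n_f, dtype=bool))
                  for r, vi in enumerate(vis_idx)]
        new_parts.append(ParticipantTrajectory(p.participant_id, p.group, visits,
                                               sex=p.sex, age_at_baseline=p.age_at_baseline))
    return Cohort(schema, new_parts)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-feature min/max learned on a reference (training) cohort."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    binary: np.ndarray  # pass-through flags

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "binary": self.binary.astype(int).tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["feature_min"], dtype=float),
                   np.array(d["feature_max"], dtype=float),
                   np.array(d["binary"], dtype=bool))


def fit_normalization(cohort: Cohort) -> NormalizationStats:
    """Learn min-max statistics over all observed cells of the reference cohort."""
    n_f = len(cohort.schema)
    fmin = np.full(n_f, np.inf)
    fmax = np.full(n_f, -np.inf)
    for p in cohort.participants:
        for v in p.visits:
            fmin[v.mask] = np.minimum(fmin[v.mask], v.values[v.mask])
            fmax[v.mask] = np.maximum(fmax[v.mask], v.values[v.mask])
    unseen = ~np.isfinite(fmin)
    fmin[unseen], fmax[unseen] = 0.0, 1.0
    binary = np.array([f.is_binary for f in cohort.schema.features])
    return NormalizationStats(fmin, fmax, binary)


def _transform(cohort: Cohort, stats: NormalizationStats, inverse: bool) -> Cohort:
    span = stats.feature_max - stats.feature_min
    degenerate = span == 0
    span_safe = np.where(degenerate, 1.0, span)
    scale = ~stats.binary
    new_parts = []
    for p in cohort.participants:
        visits = []
        for v in p.visits:
            vals = v.values.copy()
            if inverse:
                vals[scale] = vals[scale] * span_safe[scale] + stats.feature_min[scale]
            else:
                vals[scale] = (vals[scale] - stats.feature_min[scale]) / span_safe[scale]
                vals[scale & degenerate] = 0.0
            visits.append(VisitRecord(v.visit_index, vals, v.mask.copy()))
        new_parts.append(ParticipantTrajectory(p.participant_id, p.group, visits,
                                               sex=p.sex, age_at_baseline=p.age_at_baseline))
    return Cohort(cohort.schema, new_parts)


def normalize(cohort: Cohort, stats: NormalizationStats) -> Cohort:
    """Min-max map continuous features to [0, 1] with reference stats.

    Binary features pass through; values outside the reference range are
    preserved (no clipping), so the inverse transform is exact.  A degenerate
    feature (min == max) maps to 0.
    """
    return _transform(cohort, stats, inverse=False)


def denormalize(cohort: Cohort, stats: NormalizationStats) -> Cohort:
    return _transform(cohort, stats, inverse=True)


# ---------------------------------------------------------------------------
# Imputation distributional-shift diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ShiftReport:
    """Per-feature and averaged |shift| of mean, std and z-score distance
    between the pre-imputation (observed-only) and post-imputation
    distributions.  ``skipped`` lists features with zero observed variance,
    for which the z-metric is undefined."""

    feature_names: list[str]
    delta_mean: np.ndarray
    delta_std: np.ndarray
    z_distance: np.ndarray  # nan where skipped
    skipped: list[str]

    @property
    def mean_delta_mean(self) -> float:
        return float(np.mean(self.delta_mean))

    @property
    def mean_delta_std(self) -> float:
        return float(np.mean(self.delta_std))

    @property
    def mean_z_distance(self) -> float:
        vals = self.z_distance[~np.isnan(self.z_distance)]
        return float(np.mean(vals)) if vals.size else float("nan")


def imputation_shift(before: Cohort, after: Cohort) -> ShiftReport:
    """Quantify how much imputation distorted each feature's distribution.

    Per feature: delta_mean = |mean(observed cells) - mean(all cells after)|,
    delta_std analogous; z-distance = mean over *imputed* cells of
    |value - mean_obs| / std_obs.  Headline numbers average over features.
    """
    if before.ids() != after.ids():
        raise CohortError("before/after cohorts must contain the same participants")
    if not after.fully_observed():
        raise CohortError("after-cohort must be fully observed")
    n_f = len(before.schema)
    obs_vals: list[list[float]] = [[] for _ in range(n_f)]
    all_vals: list[list[float]] = [[] for _ in range(n_f)]
    imp_vals: list[list[float]] = [[] for _ in range(n_f)]
    for pb, pa in zip(before.participants, after.participants):
        for vb, va in zip(pb.visits, pa.visits):
            for j in range(n_f):
                all_vals[j].append(va.values[j])
                if vb.mask[j]:
                    obs_vals[j].append(vb.values[j])
                else:
                    imp_vals[j].append(va.values[j])

    names = before.schema.names()
    dmean = np.zeros(n_f)
    dstd = np.zeros(n_f)
    zdist = np.full(n_f, np.nan)
    skipped = []
    for j in range(n_f):
        o = np.array(obs_vals[j]) if obs_vals[j] else np.array([0.0])
        a = np.array(all_vals[j])
        dmean[j] = abs(o.mean() - a.mean())
        dstd[j] = abs(o.std() - a.std())
        if imp_vals[j]:
            s = o.std()
            if s > 0:
                zdist[j] = float(np.mean(np.abs(np.array(imp_vals[j]) - o.mean()) / s))
            else:
                skipped.append(names[j])
        else:
            zdist[j] = 0.0
    return ShiftReport(names, dmean, dstd, zdist, skipped)
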