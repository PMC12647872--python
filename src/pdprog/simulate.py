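"""Synthetic longitudinal cohort generator.

Emulates the structural properties of PPMI-like Parkinson's cohorts that the
modelling pipeline exploits, without attempting to match real marginal
distributions:

* three planted PD progression paces (rapid / moderate / slow) plus healthy
  controls, realised as latent linear-in-visit MDS-UPDRS trajectories with
  subtype-specific intercepts and slopes;
* integer item features obtained by disaggregating each latent part total;
* auxiliary scales (Schwab & England ADL, MoCA, UPSIT, ESS) trending with
  the subtype; medication flags switching on over time for PD;
* visit-parity missingness: yearly visits (even indices on the 6-month grid)
  lose fewer cells than intermediate visits;
* variable follow-up length per participant.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    Cohort,
    CohortError,
    FeatureSchema,
    ParticipantTrajectory,
    SubtypeLabel,
    VisitRecord,
    default_schema,
)

PartParams = tuple[float, float]  # (mean, sd)


@dataclass(frozen=True)
class SubtypeProfile:
    """Latent trajectory parameters of one subtype.

    Baselines are in scale points, slopes in points per 6-month step.  The
    planted ground truth is the part-III slope ordering
    rapid > moderate > slow >= HC (~0); the default sds keep the +-3 sd
    slope ranges disjoint so the ordering is unambiguous.
    """

    label: SubtypeLabel
    baseline_mean: tuple[float, float, float]  # part I, II, III
    baseline_sd: tuple[float, float, float]
    slope_mean: tuple[float, float, float]  # points / 6 months
    slope_sd: tuple[float, float, float]
    se_adl_decline: float  # points / 6 months (positive = decline)
    moca_decline: float
    noise_sd: float  # within-visit score noise, points


def default_profiles(noise_sd: float = 1.5) -> dict[str, SubtypeProfile]:
    mk = SubtypeProfile
    return {
        "rapid": mk(SubtypeLabel("rapid"), (12.0, 13.0, 34.0), (1.2, 1.2, 2.0),
                    (0.9, 1.1, 2.5), (0.10, 0.12, 0.15), 2.5, 0.30, noise_sd),
        "moderate": mk(SubtypeLabel("moderate"), (7.0, 8.0, 22.0), (1.2, 1.2, 2.0),
                       (0.5, 0.6, 1.2), (0.08, 0.10, 0.15), 1.2, 0.15, noise_sd),
        "slow": mk(SubtypeLabel("slow"), (3.5, 4.0, 11.0), (1.2, 1.2, 2.0),
                   (0.2, 0.25, 0.4), (0.05, 0.06, 0.10), 0.5, 0.08, noise_sd),
        "HC": mk(SubtypeLabel("HC"), (2.0, 1.0, 1.5), (1.0, 0.8, 1.0),
                 (0.0, 0.0, 0.0), (0.01, 0.01, 0.02), 0.05, 0.02, noise_sd),
    }


@dataclass
class GeneratorConfig:
    """Cohort-level generation settings.

    Defaults mirror the subtype sizes of the study cohort (145 rapid,
    152 moderate, 94 slow, 188 HC), follow-up of 4-13 six-month visits, and
    lower missingness at yearly (even-index) visits than at intermediate
    (odd-index) ones.
    """

    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"rapid": 145, "moderate": 152, "slow": 94, "HC": 188}
    )
    visit_count_range: tuple[int, int] = (4, 13)
    missing_rate_even: float = 0.10
    missing_rate_odd: float = 0.25
    seed: int = 0
    profiles: dict[str, SubtypeProfile] | None = None
    schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        for r in (self.missing_rate_even, self.missing_rate_odd):
            if not 0.0 <= r <= 1.0:
                raise CohortError(f"missing rate {r} outside [0, 1]")
        lo, hi = self.visit_count_range
        if lo < 2 or hi < lo:
            raise CohortError("visit_count_range must satisfy 2 <= min <= max")
        for k, n in self.n_per_subtype.items():
            if k not in ("rapid", "moderate", "slow", "HC") or n < 0:
                raise CohortError(f"bad n_per_subtype entry {k}={n}")


def disaggregate_total(
    total: float, n_items: int, item_max: float, rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Split a total score into ``n_items`` non-negative integers <= item_max
    that sum exactly to round(total).

    Uses largest-remainder allocation over Dirichlet weights (drawn here
    unless supplied; the generator fixes them per participant so each
    patient's item profile is stable across visits), then repairs any
    per-item cap violation by shifting surplus to unsaturated items;
    feasibility (0 <= total <= n_items * item_max) guarantees termination.
    """
    t = int(round(total))
    if t < 0 or t > n_items * item_max:
        raise CohortError(f"total {total} infeasible for {n_items} items <= {item_max}")
    if weights is None:
        weights = rng.dirichlet(np.ones(n_items))
    raw = weights * t
    items = np.floor(raw).astype(int)
    remainder = t - items.sum()
    if remainder > 0:
        order = np.argsort(-(raw - items), kind="stable")
        items[order[:remainder]] += 1
    cap = int(item_max)
    surplus = items - cap
    excess = int(surplus[surplus > 0].sum())
    items = np.minimum(items, cap)
    while excess > 0:
        room = np.flatnonzero(items < cap)
        take = room[: excess] if excess <= room.size else room
        items[take] += 1
        excess -= take.size
    return items


def _clip(v: float, lo: float, hi: float) -> float:
    return float(min(max(v, lo), hi))


def generate(config: GeneratorConfig) -> tuple[Cohort, dict[str, SubtypeLabel]]:
    """Generate a synthetic cohort and its ground-truth subtype labels."""
    rng = np.random.default_rng(config.seed)
    schema = config.schema or default_schema()
    profiles = config.profiles or default_profiles()
    part_items = {
        "updrs1": (schema.updrs_item_index["updrs1"], 4.0),
        "updrs2": (schema.updrs_item_index["updrs2"], 4.0),
        "updrs3": (schema.updrs_item_index["updrs3"], 4.0),
    }
    pos = {f.name: i for i, f in enumerate(schema.features)}
    n_f = len(schema)

    participants: list[ParticipantTrajectory] = []
    labels: dict[str, SubtypeLabel] = {}
    counter = 0
    for sub in ("rapid", "moderate", "slow", "HC"):
        prof = profiles[sub]
        for _ in range(config.n_per_subtype.get(sub, 0)):
            pid = f"SYN{counter:05d}"
            counter += 1
            group = "HC" if sub == "HC" else "PD"
            n_visits = int(rng.integers(config.visit_count_range[0],
                                        config.visit_count_range[1] + 1))
            # truncated-normal draws (+-2.5 sd) keep the planted class regions
            # disjoint whenever the profile gaps exceed the truncation spans
            intercepts = np.array([
                _clip(rng.normal(m, s), m - 2.5 * s, m + 2.5 * s)
                for m, s in zip(prof.baseline_mean, prof.baseline_sd)
            ])
            slopes = np.array([
                _clip(rng.normal(m, s), m - 2.5 * s, m + 2.5 * s)
                for m, s in zip(prof.slope_mean, prof.slope_sd)
            ])
            # static demographics, sampled once
            age = float(np.clip(rng.normal(62.0, 9.0), 30.0, 90.0))
            sex = int(rng.random() < 0.65)  # 1 = F; cohorts skew female
            race = int(rng.integers(1, 7)) if rng.random() < 0.08 else 0
            edu = float(np.clip(rng.normal(15.0, 3.0), 0.0, 30.0))
            fam = int(rng.random() < (0.15 if group == "PD" else 0.08))
            se0 = 95.0 if group == "HC" else float(rng.normal(90.0, 4.0))
            moca0 = float(rng.normal(27.5, 1.2))
            upsit0 = rng.normal(8.0 if group == "HC" else 5.0, 0.6, size=4)
            ess0 = rng.normal(0.8, 0.15, size=8)
            # stable per-participant item profiles (which symptoms dominate)
            item_weights = {
                cat: rng.dirichlet(np.full(len(part_items[cat][0]), 25.0))
                for cat in ("updrs1", "updrs2", "updrs3")
            }
            moca_weights = rng.dirichlet(np.full(5, 25.0))
            levo_threshold = rng.normal(30.0, 3.0)
            da_threshold = rng.normal(24.0, 3.0)
            other_med = group == "PD" and rng.random() < 0.10
            n_aux = len(schema.by_category("other"))
            aux_base = rng.normal(3.0, 0.3, size=n_aux)
            # filler scales track overall severity, like most clinical scores
            aux_coef = rng.uniform(0.8, 1.2, size=n_aux)
            part3_slope = slopes[2]

            visits = []
            for vi in range(n_visits):
                values = np.zeros(n_f)
                values[pos["age_at_baseline"]] = age
                values[pos["sex"]] = sex
                values[pos["race"]] = race
                values[pos["education_years"]] = edu
                values[pos["family_history_pd"]] = fam
                for k, cat in enumerate(("updrs1", "updrs2", "updrs3")):
                    idx, item_max = part_items[cat]
                    latent = intercepts[k] + slopes[k] * vi + rng.normal(0, prof.noise_sd)
                    latent = _clip(latent, 0.0, len(idx) * item_max)
                    values[idx] = disaggregate_total(latent, len(idx), item_max, rng,
                                                     weights=item_weights[cat])
                se = _clip(se0 - prof.se_adl_decline * vi + rng.normal(0, prof.noise_sd),
                           0.0, 100.0)
                values[pos["se_adl"]] = round(se / 5.0) * 5.0  # scored in 5-point steps
                moca = _clip(moca0 - prof.moca_decline * vi
                             + rng.normal(0, 0.3 * prof.noise_sd), 0.0, 30.0)
                moca_i = round(moca)
                values[pos["moca_total"]] = moca_i
                dom = disaggregate_total(min(moca_i, 30), 5, 6.0, rng,
                                         weights=moca_weights)
                for j in range(5):
                    values[pos[f"moca_domain{j + 1}"]] = dom[j]
                for j in range(4):
                    drift = 0.15 * part3_slope * vi
                    values[pos[f"upsit_booklet{j + 1}"]] = round(
                        _clip(upsit0[j] - drift + rng.normal(0, 0.2 * prof.noise_sd),
                              0.0, 10.0))
                for j in range(8):
                    values[pos[f"ess_item{j + 1}"]] = round(
                        _clip(ess0[j] + 0.02 * part3_slope * vi
                              + rng.normal(0, 0.15 * prof.noise_sd), 0.0, 3.0))
                if group == "PD":
                    # medication onset tracks motor severity, then persists
                    sev_now = intercepts[2] + slopes[2] * vi
                    values[pos["med_levodopa"]] = float(sev_now >= levo_threshold)
                    values[pos["med_dopamine_agonist"]] = float(sev_now >= da_threshold)
                    values[pos["med_other_pd"]] = float(other_med)
                severity = (intercepts[2] + slopes[2] * vi) / 20.0
                for j in range(n_aux):
                    values[pos[f"aux_feature{j + 1:02d}"]] = _clip(
                        aux_base[j] + aux_coef[j] * severity
                        + rng.normal(0, 0.2 * max(prof.noise_sd, 0.25)),
                        0.0, 10.0)

                mask = np.ones(n_f, dtype=bool)
                rate = config.missing_rate_even if vi % 2 == 0 else config.missing_rate_odd
                if rate > 0:
                    tv = np.array([f.kind == "time_varying" for f in schema.features])
                    drop = (rng.random(n_f) < rate) & tv
                    mask[drop] = False
                if vi > 0:
                    # static features are recorded at baseline only
                    static = np.array([f.kind == "static" for f in schema.features])
                    mask[static] = False
                visits.append(VisitRecord(vi, values, mask))

            # guarantee >=1 observation per time-varying feature per participant
            obs_any = np.zeros(n_f, dtype=bool)
            for v in visits:
                obs_any |= v.mask
            for j in np.flatnonzero(~obs_any):
                v = visits[int(rng.integers(0, len(visits)))]
                v.mask[j] = True

            participants.append(
                ParticipantTrajectory(pid, group, visits,
                                      sex="F" if sex == 1 else "M",
                                      age_at_baseline=age)
            )
            labels[pid] = SubtypeLabel(sub)

    return Cohort(schema, participants), labels


def inject_outliers(
    cohort: Cohort, n: int, magnitude: float, seed: int
) -> tuple[Cohort, list[str]]:
    """Perturb ``n`` random PD trajectories with non-physiological jumps.

    Every observed time-varying cell of the chosen participants is shifted
    by ``magnitude`` feature-wise standard deviations (alternating sign per
    visit, so the jump cannot be mistaken for fast progression), clipped to
    the feature range.  Returns the modified cohort and the perturbed ids.
    """
    pd_ids = [p.participant_id for p in cohort.participants if p.group == "PD"]
    if n > len(pd_ids):
        raise CohortError(f"cannot inject {n} outliers into {len(pd_ids)} PD participants")
    if n == 0 or magnitude == 0:
        return cohort, []
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(pd_ids, size=n, replace=False).tolist())

    # feature-wise sd over all observed cells
    n_f = len(cohort.schema)
    sums = np.zeros(n_f)
    sqs = np.zeros(n_f)
    counts = np.zeros(n_f)
    for p in cohort.participants:
        for v in p.visits:
            sums[v.mask] += v.values[v.mask]
            sqs[v.mask] += v.values[v.mask] ** 2
            counts[v.mask] += 1
    mean = np.divide(sums, np.maximum(counts, 1))
    var = np.maximum(np.divide(sqs, np.maximum(counts, 1)) - mean ** 2, 0.0)
    sd = np.sqrt(var)
    sd[sd == 0] = 1.0
    tv = np.array([f.kind == "time_varying" for f in cohort.schema.features])
    lo = np.array([f.value_range[0] for f in cohort.schema.features])
    hi = np.array([f.value_range[1] for f in cohort.schema.features])

    out_participants = []
    for p in cohort.participants:
        if p.participant_id not in chosen:
            out_participants.append(p)
            continue
        new_visits = []
        for k, v in enumerate(p.visits):
            sign = 1.0 if k % 2 == 0 else -1.0
            vals = v.values.copy()
            bump = v.mask & tv
            vals[bump] = np.clip(vals[bump] + sign * magnitude * sd[bump],
                                 lo[bump], hi[bump])
            new_visits.append(VisitRecord(v.visit_index, vals, v.mask.copy()))
        out_participants.append(
            ParticipantTrajectory(p.participant_id, p.group, new_visits,
                                  sex=p.sex, age_at_baseline=p.age_at_baseline)
        )
    return Cohort(cohort.schema, out_participants), sorted(chosen)


def zero_noise_config(**overrides) -> GeneratorConfig:
    """Config with no within-visit noise and no missingness — the separable
    regime in which planted subtypes are exactly recoverable."""
    cfg = GeneratorConfig(
        missing_rate_even=0.0, missing_rate_odd=0.0,
        profiles=default_profiles(noise_sd=0.0),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
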