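"""Domain model for longitudinal clinical cohorts.

A cohort is a set of participants, each observed at visits on a fixed
6-month grid (visit 0 = baseline).  Every visit carries a numeric feature
vector of fixed width together with a boolean observation mask, so missing
data is explicit rather than encoded as sentinel values.  The canonical
on-disk interchange is a long-format CSV (one row per observed cell) which
natively encodes missingness.

The default feature schema models the 89 clinical features used in
longitudinal Parkinson's studies: demographics, patient history, the item
scores of MDS-UPDRS parts I-III, Schwab & England ADL, MoCA, UPSIT, ESS and
medication flags.  The published category sizes sum to 71, so the default
schema pads with configurable filler time-varying features to reach 89.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

FEATURE_CATEGORIES = (
    "demographics",
    "history",
    "updrs1",
    "updrs2",
    "updrs3",
    "se_adl",
    "moca",
    "upsit",
    "ess",
    "medication",
    "other",
)

#: Fixed class order matching the subtype logits [s_rapid, s_moderate, s_slow, s_HC].
SUBTYPE_ORDER = ("rapid", "moderate", "slow", "HC")

MAX_VISIT_INDEX = 12  # default grid: baseline + 12 six-month steps (6 years)


class CohortError(ValueError):
    """Raised for malformed cohort data or schema violations."""


@dataclass(frozen=True)
class SubtypeLabel:
    """Progression subtype with its fixed class index.

    The bijection value <-> class_index follows the logits order
    (rapid=0, moderate=1, slow=2, HC=3) and every label encode/decode in the
    package goes through this type.
    """

    value: str

    def __post_init__(self) -> None:
        if self.value not in SUBTYPE_ORDER:
            raise CohortError(f"unknown subtype {self.value!r}")

    @property
    def class_index(self) -> int:
        return SUBTYPE_ORDER.index(self.value)

    @classmethod
    def from_index(cls, idx: int) -> "SubtypeLabel":
        if not 0 <= idx < len(SUBTYPE_ORDER):
            raise CohortError(f"class index {idx} out of range")
        return cls(SUBTYPE_ORDER[idx])


@dataclass(frozen=True)
class ScoreTriplet:
    """MDS-UPDRS part I/II/III total scores u = [u_I, u_II, u_III]."""

    u_I: float
    u_II: float
    u_III: float

    def __post_init__(self) -> None:
        for name, v in (("u_I", self.u_I), ("u_II", self.u_II), ("u_III", self.u_III)):
            if v < 0:
                raise CohortError(f"{name} must be non-negative, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u_I, self.u_II, self.u_III], dtype=float)


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical feature: its category, time behaviour and value range."""

    name: str
    category: str
    kind: str  # "static" or "time_varying"
    value_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise CohortError(f"unknown category {self.category!r} for {self.name}")
        if self.kind not in ("static", "time_varying"):
            raise CohortError(f"kind must be static/time_varying, got {self.kind!r}")
        lo, hi = self.value_range
        if lo > hi:
            raise CohortError(f"value_range min > max for {self.name}")
        if self.category in ("demographics", "history") and self.kind != "static":
            raise CohortError(f"{self.category} feature {self.name} must be static")
        if self.category.startswith("updrs") and self.kind != "time_varying":
            raise CohortError(f"updrs feature {self.name} must be time_varying")

    @property
    def is_binary(self) -> bool:
        return self.value_range == (0.0, 1.0)


class FeatureSchema:
    """Ordered feature list plus the item-position index used to form totals."""

    def __init__(self, features: Sequence[FeatureSpec]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise CohortError("feature names must be unique")
        self.features: tuple[FeatureSpec, ...] = tuple(features)
        self._index = {f.name: i for i, f in enumerate(self.features)}
        self.updrs_item_index: dict[str, list[int]] = {
            cat: [i for i, f in enumerate(self.features) if f.category == cat]
            for cat in ("updrs1", "updrs2", "updrs3")
        }

    def __len__(self) -> int:
        return len(self.features)

    def position(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise CohortError(f"unknown feature {name!r}") from None

    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def by_category(self, category: str) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.category == category]

    # --- JSON serialization (bit-exact reload) -------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": f.name,
                "category": f.category,
                "kind": f.kind,
                "value_range": list(f.value_range),
            }
            for f in self.features
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                FeatureSpec(
                    d["name"], d["category"], d["kind"],
                    (float(d["value_range"][0]), float(d["value_range"][1])),
                )
                for d in payload
            ]
        )


def default_schema(n_filler: int = 18) -> FeatureSchema:
    """The 89-feature default schema.

    Category sizes: demographics 4, history 1, updrs1 13, updrs2 13,
    updrs3 18, se_adl 1, moca 6 (5 sub-domains + total), upsit 4, ess 8,
    medication 3 — 71 named features; ``n_filler`` additional time-varying
    features (default 18) complete the 89.
    """
    feats: list[FeatureSpec] = [
        FeatureSpec("age_at_baseline", "demographics", "static", (18.0, 100.0)),
        FeatureSpec("sex", "demographics", "static", (0.0, 1.0)),
        FeatureSpec("race", "demographics", "static", (0.0, 6.0)),
        FeatureSpec("education_years", "demographics", "static", (0.0, 30.0)),
        FeatureSpec("family_history_pd", "history", "static", (0.0, 1.0)),
    ]
    for part, n_items in (("updrs1", 13), ("updrs2", 13), ("updrs3", 18)):
        feats += [
            FeatureSpec(f"{part}_item{i + 1:02d}", part, "time_varying", (0.0, 4.0))
            for i in range(n_items)
        ]
    feats.append(FeatureSpec("se_adl", "se_adl", "time_varying", (0.0, 100.0)))
    feats += [
        FeatureSpec(f"moca_domain{i + 1}", "moca", "time_varying", (0.0, 6.0))
        for i in range(5)
    ]
    feats.append(FeatureSpec("moca_total", "moca", "time_varying", (0.0, 30.0)))
    feats += [
        FeatureSpec(f"upsit_booklet{i + 1}", "upsit", "time_varying", (0.0, 10.0))
        for i in range(4)
    ]
    feats += [
        FeatureSpec(f"ess_item{i + 1}", "ess", "time_varying", (0.0, 3.0))
        for i in range(8)
    ]
    for name in ("med_levodopa", "med_dopamine_agonist", "med_other_pd"):
        feats.append(FeatureSpec(name, "medication", "time_varying", (0.0, 1.0)))
    feats += [
        FeatureSpec(f"aux_feature{i + 1:02d}", "other", "time_varying", (0.0, 10.0))
        for i in range(n_filler)
    ]
    return FeatureSchema(feats)


@dataclass
class VisitRecord:
    """One visit: index on the 6-month grid, values and observation mask."""

    visit_index: int
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.visit_index < 0:
            raise CohortError("visit_index must be non-negative")
        if self.values.shape != self.mask.shape:
            raise CohortError("values and mask must have identical shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise CohortError("observed values must be finite")


@dataclass
class ParticipantTrajectory:
    """L_p = {x_BL, x_1, ..., x_n}: all visits of one participant."""

    participant_id: str
    group: str  # "PD" or "HC"
    visits: list[VisitRecord] = field(default_factory=list)
    sex: str = "unknown"  # "M", "F" or "unknown"
    age_at_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise CohortError(f"group must be PD or HC, got {self.group!r}")
        if not self.visits:
            raise CohortError(f"{self.participant_id}: at least one visit required")
        idx = [v.visit_index for v in self.visits]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise CohortError(f"{self.participant_id}: visit_index must strictly increase")

    def __len__(self) -> int:
        return len(self.visits)

    def visit_indices(self) -> list[int]:
        return [v.visit_index for v in self.visits]


@dataclass
class Cohort:
    """A schema plus its participants; the unit every pipeline stage consumes."""

    schema: FeatureSchema
    participants: list[ParticipantTrajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise CohortError("participant ids must be unique")
        n_f = len(self.schema)
        for p in self.participants:
            for v in p.visits:
                if v.values.shape[0] != n_f:
                    raise CohortError(
                        f"{p.participant_id} visit {v.visit_index}: vector length "
                        f"{v.values.shape[0]} != schema length {n_f}"
                    )

    def __len__(self) -> int:
        return len(self.participants)

    def ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def get(self, participant_id: str) -> ParticipantTrajectory:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise CohortError(f"unknown participant {participant_id!r}")

    def subset(self, keep_ids: Iterable[str]) -> "Cohort":
        keep = set(keep_ids)
        return Cohort(self.schema, [p for p in self.participants if p.participant_id in keep])

    def fully_observed(self) -> bool:
        return all(v.mask.all() for p in self.participants for v in p.visits)


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

CSV_HEADER = ["participant_id", "group", "visit_index", "feature", "value"]


def read_cohort(path: str | Path, schema: FeatureSchema) -> Cohort:
    """Read a long-format cohort CSV (one row per observed cell).

    Absent (participant, visit, feature) cells get mask=False.  Unknown
    feature names, duplicate cells and non-numeric values are rejected with
    the offending line number.
    """
    path = Path(path)
    n_f = len(schema)
    # participant -> (group, {visit_index -> (values, mask)})
    data: dict[str, tuple[str, dict[int, tuple[np.ndarray, np.ndarray]]]] = {}
    seen: set[tuple[str, int, str]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_HEADER:
            raise CohortError(f"{path}: expected header {CSV_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise CohortError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            pid, group, vi_s, feat, val_s = row
            pos = schema.position(feat)  # rejects unknown features
            try:
                vi = int(vi_s)
                val = float(val_s)
            except ValueError:
                raise CohortError(f"{path}:{lineno}: non-numeric visit_index or value") from None
            if vi < 0:
                raise CohortError(f"{path}:{lineno}: negative visit_index")
            key = (pid, vi, feat)
            if key in seen:
                raise CohortError(f"{path}:{lineno}: duplicate cell {key}")
            seen.add(key)
            if pid not in data:
                data[pid] = (group, {})
            stored_group, visits = data[pid]
            if group != stored_group:
                raise CohortError(f"{path}:{lineno}: inconsistent group for {pid}")
            if vi not in visits:
                visits[vi] = (np.zeros(n_f), np.zeros(n_f, dtype=bool))
            values, mask = visits[vi]
            values[pos] = val
            mask[pos] = True

    participants = []
    age_pos = schema._index.get("age_at_baseline")
    sex_pos = schema._index.get("sex")
    for pid, (group, visits) in data.items():
        recs = [VisitRecord(vi, *visits[vi]) for vi in sorted(visits)]
        sex, age = "unknown", None
        first = recs[0]
        if sex_pos is not None and first.mask[sex_pos]:
            sex = "F" if first.values[sex_pos] >= 0.5 else "M"
        if age_pos is not None and first.mask[age_pos]:
            age = float(first.values[age_pos])
        participants.append(
            ParticipantTrajectory(pid, group, recs, sex=sex, age_at_baseline=age)
        )
    return Cohort(schema, participants)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical long-format CSV: only observed cells, rows sorted
    by (participant_id, visit_index, feature position)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        names = cohort.schema.names()
        for p in sorted(cohort.participants, key=lambda q: q.participant_id):
            for v in p.visits:
                for pos in np.flatnonzero(v.mask):
                    writer.writerow(
                        [p.participant_id, p.group, v.visit_index, names[pos],
                         format(v.values[pos], "g")]
                    )


def total_scores(visit: VisitRecord, schema: FeatureSchema) -> ScoreTriplet:
    """Sum the MDS-UPDRS item features of one visit into u = [u_I, u_II, u_III].

    All item features must be observed (run imputation first otherwise).
    """
    totals = []
    for cat in ("updrs1", "updrs2", "updrs3"):
        pos = schema.updrs_item_index[cat]
        if not np.all(visit.mask[pos]):
            raise CohortError(
                f"visit {visit.visit_index}: unobserved {cat} items — impute the cohort first"
            )
        totals.append(float(np.sum(visit.values[pos])))
    return ScoreTriplet(*totals)


def score_matrix(trajectory: ParticipantTrajectory, schema: FeatureSchema) -> np.ndarray:
    """(n_visits, 3) array of part I/II/III totals for a fully observed trajectory."""
    return np.stack([total_scores(v, schema).as_array() for v in trajectory.visits])
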