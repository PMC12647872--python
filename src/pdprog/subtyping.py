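"""Progression-subtype extraction.

An LSTM autoencoder compresses each participant's variable-length visit
sequence into a single embedding (the encoder's final hidden state).  The
autoencoder consumes the time-varying clinical features only: static
demographics carry no progression information, and including them makes the
embedding — and hence the clusters — reflect demographic rather than
disease-course structure.  The reconstruction loss doubles as an outlier
gate: trajectories the autoencoder cannot reconstruct are atypical and
removed.  K-Means over the PD embeddings (standardized per coordinate, as
the latent dimensions carry arbitrary relative scales) then uncovers the
progression subtypes, which are named by ranking the clusters' mean
MDS-UPDRS part III slopes (fastest = rapid).  Healthy controls are excluded
from clustering and receive the fixed HC label; the fitted centroids
transfer labels to external cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .cohort import Cohort, CohortError, ParticipantTrajectory, SubtypeLabel, score_matrix
from .nn import LSTM, Adam, Linear, Module, Tensor, stack


def to_padded_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Stack a fully observed cohort into (N, T_max, F) values and (N, T_max)
    step masks (True = real visit)."""
    n = len(cohort)
    t_max = max(len(p) for p in cohort.participants)
    n_f = len(cohort.schema)
    x = np.zeros((n, t_max, n_f))
    m = np.zeros((n, t_max), dtype=bool)
    for i, p in enumerate(cohort.participants):
        for t, v in enumerate(p.visits):
            x[i, t] = v.values
            m[i, t] = True
    return x, m


@dataclass
class LSTMAutoencoderConfig:
    """Training settings for the trajectory autoencoder.

    ``hidden_dim`` is the embedding dimension (32), trained 70 epochs with
    Adam at 2e-3; one LSTM layer in encoder and decoder.
    """

    hidden_dim: int = 32
    epochs: int = 70
    learning_rate: float = 2e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.epochs < 1:
            raise CohortError("hidden_dim and epochs must be >= 1")


class TrajectoryAutoencoder(Module):
    """Seq2seq LSTM autoencoder: encode to the final hidden state, then
    decode by feeding the embedding at every output step.

    ``feature_idx`` records which schema positions the model consumes
    (the time-varying subset when trained through :func:`train_autoencoder`).
    """

    def __init__(self, n_features: int, hidden_dim: int, rng: np.random.Generator,
                 feature_idx: np.ndarray | None = None):
        super().__init__()
        self.encoder = LSTM(n_features, hidden_dim, rng)
        self.decoder = LSTM(hidden_dim, hidden_dim, rng)
        self.head = Linear(hidden_dim, n_features, rng)
        # forget-gate bias init of 1: states integrate the whole sequence
        # from the first epochs, which this short training budget needs
        for lstm in (self.encoder, self.decoder):
            lstm.b_ih.data[hidden_dim:2 * hidden_dim] = 1.0
        self.hidden_dim = hidden_dim
        self.n_features = n_features
        self.feature_idx = (np.arange(n_features) if feature_idx is None
                            else np.asarray(feature_idx))

    def encode(self, x: Tensor, mask: np.ndarray) -> Tensor:
        _, h = self.encoder(x, mask=mask)
        return h

    def reconstruct(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        h = self.encode(x, mask)  # (B, H)
        rep = stack([h] * T, axis=1)  # (B, T, H)
        outs, _ = self.decoder(rep, mask=mask)
        return self.head(stack(outs, axis=1))  # (B, T, F)


def visit_mean_squared_error(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Visit-averaged squared reconstruction error of one trajectory:
    (1/|L_p|) sum_i ||x_i - x_hat_i||^2."""
    x = np.atleast_2d(x)
    x_hat = np.atleast_2d(x_hat)
    if x.shape != x_hat.shape:
        raise CohortError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean(np.sum((x - x_hat) ** 2, axis=-1)))


def _batch_loss(model: TrajectoryAutoencoder, x: np.ndarray, m: np.ndarray) -> Tensor:
    """Batch mean of per-participant visit-averaged losses (padded steps and
    their reconstruction error excluded)."""
    xt = Tensor(x)
    x_hat = model.reconstruct(xt, m)
    resid = x_hat - xt
    sq = (resid * resid).sum(axis=-1)  # (B, T)
    w = m / m.sum(axis=1, keepdims=True)  # per-visit weights: 1/|L_p|
    return (sq * Tensor(w)).sum() * (1.0 / x.shape[0])


def time_varying_positions(schema) -> np.ndarray:
    return np.flatnonzero([f.kind == "time_varying" for f in schema.features])


def train_autoencoder(cohort: Cohort, config: LSTMAutoencoderConfig
                      ) -> TrajectoryAutoencoder:
    """Fit the autoencoder on an imputed, normalized cohort (PD and HC).

    Consumes the time-varying features of each visit and minimizes the batch
    mean of per-participant visit-averaged reconstruction losses with Adam;
    deterministic given ``config.seed``.
    """
    if len(cohort) == 0:
        raise CohortError("cannot train on an empty cohort")
    tv = time_varying_positions(cohort.schema)
    x, m = to_padded_arrays(cohort)
    x = x[:, :, tv]
    rng = np.random.default_rng(config.seed)
    model = TrajectoryAutoencoder(x.shape[2], config.hidden_dim, rng, feature_idx=tv)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = x.shape[0]
    order_rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        order = order_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, x[idx], m[idx])
            loss.backward()
            opt.step()
    model.eval()
    return model


def reconstruction_loss(model: TrajectoryAutoencoder,
                        trajectory: ParticipantTrajectory) -> float:
    """Visit-averaged squared reconstruction error of one trajectory."""
    x = np.stack([v.values for v in trajectory.visits])[None]
    if x.shape[2] < model.feature_idx.max() + 1:
        raise CohortError(
            f"trajectory width {x.shape[2]} incompatible with the trained model")
    x = x[:, :, model.feature_idx]
    if x.shape[2] != model.n_features:
        raise CohortError(
            f"trajectory has {x.shape[2]} model features, expected {model.n_features}")
    m = np.ones((1, x.shape[1]), dtype=bool)
    model.eval()
    x_hat = model.reconstruct(Tensor(x), m).data
    return visit_mean_squared_error(x[0], x_hat[0])


def cohort_losses(model: TrajectoryAutoencoder, cohort: Cohort) -> np.ndarray:
    model.eval()
    x, m = to_padded_arrays(cohort)
    x = x[:, :, model.feature_idx]
    x_hat = model.reconstruct(Tensor(x), m).data
    sq = np.sum((x - x_hat) ** 2, axis=-1)
    return np.array([sq[i, m[i]].mean() for i in range(len(cohort))])


@dataclass(frozen=True)
class OutlierPolicy:
    """How the loss cutoff L_max is set: an absolute value, or a quantile of
    the cohort's loss distribution (default: 99th percentile)."""

    absolute: float | None = None
    quantile: float | None = 0.99

    def l_max(self, losses: np.ndarray) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        if self.quantile is None:
            raise CohortError("policy needs an absolute value or a quantile")
        return float(np.quantile(losses, self.quantile))


def flag_outliers(model: TrajectoryAutoencoder, cohort: Cohort,
                  policy: OutlierPolicy = OutlierPolicy()
                  ) -> tuple[Cohort, list[str]]:
    """Remove participants whose reconstruction loss exceeds L_max."""
    losses = cohort_losses(model, cohort)
    l_max = policy.l_max(losses)
    flagged = [p.participant_id for p, l in zip(cohort.participants, losses) if l > l_max]
    if len(flagged) == len(cohort):
        raise CohortError("outlier policy would remove every participant")
    kept = cohort.subset(set(cohort.ids()) - set(flagged))
    return kept, flagged


def embed_participants(model: TrajectoryAutoencoder, cohort: Cohort) -> np.ndarray:
    """Per-participant embeddings (encoder final hidden state), cohort order."""
    model.eval()
    x, m = to_padded_arrays(cohort)
    x = x[:, :, model.feature_idx]
    return model.encode(Tensor(x), m).data.copy()


# ---------------------------------------------------------------------------
# K-Means subtyping
# ---------------------------------------------------------------------------

@dataclass
class ClusteringModel:
    """Fitted K-Means subtyping model.

    ``emb_mean``/``emb_scale`` record the per-coordinate standardization of
    the embedding space in which the centroids live; label transfer applies
    the same transform, so training and external cohorts are compared in one
    geometry.
    """

    k: int
    centroids: np.ndarray  # (k, hidden_dim), standardized coordinates
    emb_mean: np.ndarray
    emb_scale: np.ndarray
    subtype_map: dict[int, SubtypeLabel] = field(default_factory=dict)
    autoencoder: TrajectoryAutoencoder | None = None
    l_max: float | None = None

    def standardize(self, embeddings: np.ndarray) -> np.ndarray:
        return (np.asarray(embeddings, dtype=float) - self.emb_mean) / self.emb_scale

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "emb_mean": self.emb_mean.tolist(),
            "emb_scale": self.emb_scale.tolist(),
            "subtype_map": {str(c): lab.value for c, lab in self.subtype_map.items()},
            "l_max": self.l_max,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusteringModel":
        d = json.loads(Path(path).read_text())
        return cls(d["k"], np.array(d["centroids"]),
                   np.array(d["emb_mean"]), np.array(d["emb_scale"]),
                   {int(c): SubtypeLabel(v) for c, v in d["subtype_map"].items()},
                   l_max=d.get("l_max"))


@dataclass
class KSelectionReport:
    """Per-candidate-k model-selection criteria."""

    aic: dict[int, float]
    silhouette: dict[int, float]
    davies_bouldin: dict[int, float]


def _kmeans_aic(x: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    """AIC of K-Means read as an equal-weight spherical Gaussian mixture with
    a shared variance estimated from within-cluster dispersion; the parameter
    count is m = k*d + 1 (centroids plus the shared variance)."""
    n, d = x.shape
    k = centers.shape[0]
    sse = float(np.sum((x - centers[labels]) ** 2))
    sigma2 = max(sse / (n * d), 1e-12)
    log_l = -0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1) - n * np.log(k)
    m = k * d + 1
    return -2 * log_l + 2 * m


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-coordinate standardization with the scale floored at 20% of the
    largest coordinate sd, so near-constant latent dimensions are not
    amplified into pure noise."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    scale = np.maximum(sd, max(0.2 * sd.max(), 1e-12))
    return (x - mean) / scale, mean, scale


def evaluate_k(embeddings: np.ndarray, candidate_ks=(2, 3), seed: int = 0,
               standardize: bool = True) -> KSelectionReport:
    """Fit K-Means per candidate k and report AIC, silhouette and
    Davies-Bouldin (by default in standardized embedding coordinates, the
    same geometry the subtyping fit uses)."""
    x = np.asarray(embeddings, dtype=float)
    if x.shape[0] <= max(candidate_ks):
        raise CohortError("need more points than the largest candidate k")
    if standardize:
        x, _, _ = _standardize(x)
    aic, sil, db = {}, {}, {}
    for k in candidate_ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        aic[k] = _kmeans_aic(x, km.cluster_centers_, km.labels_)
        sil[k] = float(silhouette_score(x, km.labels_))
        db[k] = float(davies_bouldin_score(x, km.labels_))
    return KSelectionReport(aic, sil, db)


def fit_clusters(pd_embeddings: np.ndarray, k: int = 3, seed: int = 0,
                 standardize: bool = True) -> tuple[ClusteringModel, np.ndarray]:
    """K-Means (k-means++ init, 10 restarts, fixed seed) over PD embeddings,
    run in per-coordinate standardized space by default.

    Returns the model and the cluster assignment per embedding row.
    """
    x = np.asarray(pd_embeddings, dtype=float)
    if x.shape[0] < k:
        raise CohortError(f"{x.shape[0]} points cannot form {k} clusters")
    if standardize:
        xs, mean, scale = _standardize(x)
    else:
        xs = x
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(xs)
    return (ClusteringModel(k, km.cluster_centers_.copy(), mean, scale),
            km.labels_.copy())


def part3_slope(trajectory: ParticipantTrajectory, schema) -> float:
    """Per-participant OLS slope of the part-III total over visit_index."""
    scores = score_matrix(trajectory, schema)[:, 2]
    t = np.array(trajectory.visit_indices(), dtype=float)
    tm = t.mean()
    den = float(np.sum((t - tm) ** 2))
    return float(np.sum((t - tm) * (scores - scores.mean())) / den) if den > 0 else 0.0


def order_subtypes(model: ClusteringModel, pd_cohort: Cohort,
                   assignments: np.ndarray) -> dict[int, SubtypeLabel]:
    """Name the k=3 clusters by pace: highest mean part-III slope -> rapid,
    middle -> moderate, lowest -> slow.  Slope ties break on the mean final
    part-III total, then on cluster index (all deterministic).
    """
    if model.k != 3:
        raise CohortError("subtype ordering is defined for k = 3")
    schema = pd_cohort.schema
    slopes = np.array([part3_slope(p, schema) for p in pd_cohort.participants])
    finals = np.array([score_matrix(p, schema)[-1, 2] for p in pd_cohort.participants])
    keys = []
    for c in range(model.k):
        sel = assignments == c
        keys.append((float(slopes[sel].mean()) if sel.any() else 0.0,
                     float(finals[sel].mean()) if sel.any() else 0.0,
                     -c))
    ranked = sorted(range(model.k), key=lambda c: keys[c], reverse=True)
    names = ("rapid", "moderate", "slow")
    model.subtype_map = {c: SubtypeLabel(names[r]) for r, c in enumerate(ranked)}
    return model.subtype_map


def transfer_labels(model: ClusteringModel, embeddings: np.ndarray,
                    is_hc: np.ndarray | None = None) -> list[SubtypeLabel]:
    """Nearest-centroid (Euclidean) label transfer through subtype_map.

    Rows flagged in ``is_hc`` bypass clustering and receive HC.  Exact
    equidistance resolves to the lowest cluster index.
    """
    x = np.asarray(embeddings, dtype=float)
    if x.shape[1] != model.centroids.shape[1]:
        raise CohortError(
            f"embedding width {x.shape[1]} != centroid width {model.centroids.shape[1]}")
    if not model.subtype_map:
        raise CohortError("subtype_map not set — run order_subtypes first")
    x = model.standardize(x)
    d2 = ((x[:, None, :] - model.centroids[None]) ** 2).sum(axis=-1)
    nearest = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    labels = [model.subtype_map[int(c)] for c in nearest]
    if is_hc is not None:
        labels = [SubtypeLabel("HC") if h else lab for lab, h in zip(labels, is_hc)]
    return labels


def extract_subtypes(cohort: Cohort, raw_cohort: Cohort,
                     config: LSTMAutoencoderConfig = LSTMAutoencoderConfig(),
                     outlier_policy: OutlierPolicy | None = None,
                     k: int = 3) -> tuple[ClusteringModel, dict[str, SubtypeLabel]]:
    """Full unsupervised stage: autoencoder -> (optional outlier gate) ->
    K-Means on PD embeddings -> pace-ordered subtype labels; HCs labelled HC.

    ``cohort`` must be imputed and normalized (the autoencoder's input);
    ``raw_cohort`` provides unnormalized scores for pace ordering and must be
    imputed.  Returns the fitted clustering model and labels per participant.
    """
    model_ae = train_autoencoder(cohort, config)
    work = cohort
    if outlier_policy is not None:
        work, flagged = flag_outliers(model_ae, cohort, outlier_policy)
        raw_cohort = raw_cohort.subset(work.ids())
    pd_ids = [p.participant_id for p in work.participants if p.group == "PD"]
    pd_cohort = work.subset(pd_ids)
    emb = embed_participants(model_ae, pd_cohort)
    cmodel, assign = fit_clusters(emb, k=k, seed=config.seed)
    cmodel.autoencoder = model_ae
    order_subtypes(cmodel, raw_cohort.subset(pd_ids), assign)
    labels = {pid: cmodel.subtype_map[int(c)] for pid, c in zip(pd_cohort.ids(), assign)}
    for p in work.participants:
        if p.group == "HC":
            labels[p.participant_id] = SubtypeLabel("HC")
    return cmodel, labels
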