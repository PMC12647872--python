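"""Sliding-window sample construction, stratified splitting and the
three-phase training schedule.

Phase 1 pretrains the SiVE autoencoder on single visits; phase 2 trains the
shared encoder and subtype decoder on windows with the score branch frozen;
phase 3 trains with the joint objective, teacher forcing the score decoder
and keeping the upper branch frozen for the first ``e_thres`` warm-up
epochs.  Freezing is implemented by giving each (sub-)phase an optimizer
over exactly the unfrozen parameters, so frozen weights are bitwise
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, CohortError, ParticipantTrajectory, SubtypeLabel, score_matrix
from .model import (
    LossConfig,
    PDualNet,
    joint_loss,
    mds_mse,
    reconstruction_loss_total,
    weighted_cross_entropy,
)
from .nn import Adam, Tensor, softmax


@dataclass
class WindowSample:
    """One training/test instance: a W-visit input window, the raw score
    triplet at its last visit (the decoding start input), 1..H future
    triplet targets and the subtype label."""

    participant_id: str
    input_visit_indices: list[int]
    input_vectors: np.ndarray  # (W, N_f), normalized
    context_triplet: np.ndarray  # (3,), raw scale
    target_triplets: np.ndarray  # (h, 3), raw scale
    label: SubtypeLabel

    @property
    def window(self) -> int:
        return self.input_vectors.shape[0]

    @property
    def horizon(self) -> int:
        return self.target_triplets.shape[0]


def make_windows(trajectory: ParticipantTrajectory, label: SubtypeLabel,
                 schema, window: int, max_horizon: int | None = None,
                 input_trajectory: ParticipantTrajectory | None = None
                 ) -> list[WindowSample]:
    """Enumerate every (start, horizon) sample of one imputed trajectory.

    Targets immediately follow the window with no gaps.  With the horizon
    uncapped the count is N(p, W) = (n - W)(n - W + 1) / 2 for n visits.
    ``input_trajectory`` supplies the (normalized) input vectors when they
    differ from the raw trajectory that provides score targets; both must
    share the visit grid.  ``window >= n`` yields an empty list.
    """
    if window < 2:
        raise CohortError("window size must be >= 2")
    if max_horizon is not None and max_horizon < 1:
        raise CohortError("max_horizon must be >= 1")
    n = len(trajectory)
    if window >= n:
        return []
    scores = score_matrix(trajectory, schema)  # (n, 3) raw totals
    src = input_trajectory or trajectory
    if len(src) != n:
        raise CohortError("input_trajectory must share the visit grid")
    vectors = np.stack([v.values for v in src.visits])
    vidx = trajectory.visit_indices()
    samples = []
    for start in range(n - window):
        end = start + window  # first target position
        h_cap = n - end
        if max_horizon is not None:
            h_cap = min(h_cap, max_horizon)
        for h in range(1, h_cap + 1):
            samples.append(WindowSample(
                trajectory.participant_id,
                vidx[start:end],
                vectors[start:end],
                scores[end - 1].copy(),
                scores[end:end + h].copy(),
                label,
            ))
    return samples


def build_samples(raw_cohort: Cohort, labels: dict[str, SubtypeLabel],
                  windows=(2, 3, 4, 5), max_horizon: int | None = 5,
                  input_cohort: Cohort | None = None) -> list[WindowSample]:
    """All window samples of a cohort for every window size in ``windows``."""
    out: list[WindowSample] = []
    for p in raw_cohort.participants:
        src = input_cohort.get(p.participant_id) if input_cohort is not None else None
        for w in windows:
            out.extend(make_windows(p, labels[p.participant_id], raw_cohort.schema,
                                    w, max_horizon, input_trajectory=src))
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_cohort(labels: dict[str, SubtypeLabel], test_fraction: float = 0.25,
                 seed: int = 0) -> tuple[list[str], list[str]]:
    """Participant-level stratified train/test split.

    Per class the test count is round-half-up(test_fraction * class size);
    membership is a seeded shuffle within the class.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for pid in sorted(labels):
        by_class.setdefault(labels[pid].value, []).append(pid)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(by_class):
        ids = by_class[cls]
        if len(ids) < 2:
            raise CohortError(f"class {cls} has fewer than 2 members")
        n_test = _round_half_up(test_fraction * len(ids))
        order = rng.permutation(len(ids))
        test.extend(ids[i] for i in order[:n_test])
        train.extend(ids[i] for i in order[n_test:])
    return sorted(train), sorted(test)


def kfold(train_ids: list[str], labels: dict[str, SubtypeLabel], k: int = 5,
          seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Participant-level stratified k-fold partition of the training ids."""
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    by_class: dict[str, list[str]] = {}
    for pid in sorted(train_ids):
        by_class.setdefault(labels[pid].value, []).append(pid)
    for cls in sorted(by_class):
        ids = by_class[cls]
        if len(ids) < k:
            raise CohortError(f"class {cls} smaller than k = {k}")
        order = rng.permutation(len(ids))
        for j, i in enumerate(order):
            folds[j % k].append(ids[i])
    out = []
    for j in range(k):
        val = sorted(folds[j])
        fit = sorted(pid for jj in range(k) if jj != j for pid in folds[jj])
        out.append((fit, val))
    return out


def class_weights_from(labels: dict[str, SubtypeLabel],
                       ids: list[str] | None = None) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1."""
    use = ids if ids is not None else list(labels)
    counts = np.zeros(4)
    for pid in use:
        counts[labels[pid].class_index] += 1
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w / w.mean()


@dataclass
class PhaseSchedule:
    """Batch sizes, learning rates and epoch budgets of the three phases,
    plus the loss configuration (class weights, alphas, w1/w2, E_thres)."""

    batch_sizes: tuple[int, int, int] = (8, 64, 128)
    learning_rates: tuple[float, float, float] = (1e-3, 3e-4, 3e-4)
    epochs: tuple[int, int, int] = (100, 60, 100)
    loss: LossConfig = field(default_factory=LossConfig)
    max_samples_per_epoch: int | None = None  # subsample cap for phases 2/3


def _batches(n: int, batch_size: int, rng: np.random.Generator,
             cap: int | None = None):
    order = rng.permutation(n)
    if cap is not None:
        order = order[:cap]
    for start in range(0, len(order), batch_size):
        yield order[start:start + batch_size]


def _collate(samples: list[WindowSample], idx: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                        np.ndarray, np.ndarray]:
    """Pad a batch to its max window and horizon.

    Returns (x, pad_mask, y_class, context, targets, step_mask).
    """
    batch = [samples[i] for i in idx]
    B = len(batch)
    w_max = max(s.window for s in batch)
    h_max = max(s.horizon for s in batch)
    n_f = batch[0].input_vectors.shape[1]
    x = np.zeros((B, w_max, n_f))
    pad = np.ones((B, w_max), dtype=bool)
    ctx = np.zeros((B, 3))
    tgt = np.zeros((B, h_max, 3))
    smask = np.zeros((B, h_max), dtype=bool)
    y = np.zeros(B, dtype=int)
    for i, s in enumerate(batch):
        x[i, :s.window] = s.input_vectors
        pad[i, :s.window] = False
        ctx[i] = s.context_triplet
        tgt[i, :s.horizon] = s.target_triplets
        smask[i, :s.horizon] = True
        y[i] = s.label.class_index
    return x, pad, y, ctx, tgt, smask


def train(model: PDualNet, data, schedule: PhaseSchedule, phase: int,
          seed: int = 0) -> list[float]:
    """Run one training phase; returns the per-epoch mean loss trace.

    ``data`` is a visit matrix (N, N_f) for phase 1 and a list of
    WindowSample for phases 2 and 3.
    """
    if phase == 1:
        return _train_phase1(model, np.asarray(data, dtype=float), schedule, seed)
    if phase == 2:
        return _train_phase2(model, data, schedule, seed)
    if phase == 3:
        return _train_phase3(model, data, schedule, seed)
    raise CohortError(f"unknown phase {phase}")


def _train_phase1(model: PDualNet, visits: np.ndarray, schedule: PhaseSchedule,
                  seed: int) -> list[float]:
    model.train()
    opt = Adam(model.sive_encoder.parameters() + model.sive_decoder.parameters(),
               lr=schedule.learning_rates[0])
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(schedule.epochs[0]):
        losses = []
        for idx in _batches(len(visits), schedule.batch_sizes[0], rng):
            opt.zero_grad()
            x = visits[idx]
            x_hat = model.sive_reconstruct(model.sive_encode(x))
            loss = reconstruction_loss_total(x, x_hat, reduction="mean")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    model.eval()
    return trace


def _forward_classify(model: PDualNet, x: np.ndarray, pad: np.ndarray) -> Tensor:
    z = model.sive_encode(x)
    d = model.dise_encode(z, padding_mask=pad)
    return model.classify(d)


def _train_phase2(model: PDualNet, samples: list[WindowSample],
                  schedule: PhaseSchedule, seed: int) -> list[float]:
    model.train()
    opt = Adam(model.upper_branch_parameters(), lr=schedule.learning_rates[1])
    rng = np.random.default_rng(seed)
    w = schedule.loss.class_weights
    trace = []
    for _ in range(schedule.epochs[1]):
        losses = []
        for idx in _batches(len(samples), schedule.batch_sizes[1], rng,
                            schedule.max_samples_per_epoch):
            opt.zero_grad()
            x, pad, y, *_ = _collate(samples, idx)
            loss = weighted_cross_entropy(_forward_classify(model, x, pad), y, w)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    model.eval()
    return trace


def _train_phase3(model: PDualNet, samples: list[WindowSample],
                  schedule: PhaseSchedule, seed: int) -> list[float]:
    model.train()
    cfg = schedule.loss
    opt_warm = Adam(model.score_branch_parameters(), lr=schedule.learning_rates[2])
    opt_joint = Adam(model.upper_branch_parameters()
                     + model.score_branch_parameters()
                     + cfg.balance_parameters(), lr=schedule.learning_rates[2])
    rng = np.random.default_rng(seed)
    trace = []
    for epoch in range(schedule.epochs[2]):
        warm = epoch <= cfg.e_thres
        opt = opt_warm if warm else opt_joint
        losses = []
        for idx in _batches(len(samples), schedule.batch_sizes[2], rng,
                            schedule.max_samples_per_epoch):
            opt.zero_grad()
            if not warm:
                cfg.w1.grad = None
                cfg.w2.grad = None
            x, pad, y, ctx, tgt, smask = _collate(samples, idx)
            z = model.sive_encode(x)
            d = model.dise_encode(z, padding_mask=pad)
            h_max = tgt.shape[1]
            preds = model.decode_scores(d, ctx, h_max, "teacher_forced",
                                        teacher_targets=tgt)
            mse = mds_mse(tgt, preds, cfg.alphas, step_mask=smask)
            ce = weighted_cross_entropy(model.classify(d), y, cfg.class_weights)
            loss = joint_loss(mse, ce, epoch, cfg)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    model.eval()
    return trace


def train_all_phases(model: PDualNet, visit_matrix: np.ndarray,
                     samples: list[WindowSample], schedule: PhaseSchedule,
                     seed: int = 0) -> dict[str, list[float]]:
    """Run the full three-phase schedule and return the loss traces."""
    return {
        "phase1": train(model, visit_matrix, schedule, 1, seed),
        "phase2": train(model, samples, schedule, 2, seed + 1),
        "phase3": train(model, samples, schedule, 3, seed + 2),
    }


def predict(model: PDualNet, window_vectors: np.ndarray,
            context_triplet: np.ndarray, horizon: int
            ) -> tuple[np.ndarray, np.ndarray]:
    """Inference on one window: subtype probabilities and an autoregressive
    score forecast of length ``horizon``."""
    if horizon < 1:
        raise CohortError("horizon must be >= 1")
    model.eval()
    x = np.asarray(window_vectors, dtype=float)[None]
    pad = np.zeros((1, x.shape[1]), dtype=bool)
    z = model.sive_encode(x)
    d = model.dise_encode(z, padding_mask=pad)
    probs = softmax(model.classify(d), axis=-1).data[0]
    preds = model.decode_scores(
        d, np.asarray(context_triplet, dtype=float)[None], horizon,
        "autoregressive").data[0]
    return probs, preds


def predict_batch(model: PDualNet, samples: list[WindowSample], horizon: int | None = None,
                  mode: str = "autoregressive") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inference over samples sharing any window/horizon mix.

    Returns (class probabilities (N, 4), score predictions (N, h, 3)) where
    h = ``horizon`` or each sample's own horizon padded with NaN.
    """
    model.eval()
    probs = np.zeros((len(samples), 4))
    h_out = horizon or max(s.horizon for s in samples)
    preds = np.full((len(samples), h_out, 3), np.nan)
    # group by window length for batching
    by_w: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        by_w.setdefault(s.window, []).append(i)
    for w, idxs in by_w.items():
        x = np.stack([samples[i].input_vectors for i in idxs])
        pad = np.zeros((len(idxs), w), dtype=bool)
        ctx = np.stack([samples[i].context_triplet for i in idxs])
        z = model.sive_encode(x)
        d = model.dise_encode(z, padding_mask=pad)
        probs[idxs] = softmax(model.classify(d), axis=-1).data
        h = horizon or max(samples[i].horizon for i in idxs)
        out = model.decode_scores(d, ctx, h, mode).data
        for row, i in enumerate(idxs):
            hi = min(h, h_out)
            preds[i, :hi] = out[row, :hi]
    return probs, preds
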