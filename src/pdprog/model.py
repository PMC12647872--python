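"""The dual-task progression network.

Architecture (all widths from the deployed configuration):

* **SiVE autoencoder** — an MLP autoencoder (89 -> 128 -> 64 -> 32 -> 16 and
  mirror) over single-visit feature vectors.  After pretraining only the
  encoder survives, serving as the embedding module of the sequence model.
* **DiSE transformer encoder** — one single-head transformer encoder layer
  (width 16, feed-forward 32) over the window's SiVE embeddings with a
  learnable CLS token prepended and learned positional embeddings; the CLS
  output is the Disease-State Embedding d_p.
* **Subtype decoder** — MLP 16 -> 8 -> 4 emitting unnormalized logits
  [s_rapid, s_moderate, s_slow, s_HC].
* **Score decoder** — an autoregressive single-head transformer decoder
  layer cross-attending to d_p.  Previous MDS-UPDRS totals are quantized to
  integer levels (vocabulary 101, padding index 100), embedded per part,
  concatenated and projected to width 16; the output head 16 -> 16 -> 3
  regresses the next [u_I, u_II, u_III] on the raw score scale.

The quantized embedding path applies only to decoder *inputs*; regression
targets and head outputs stay continuous and unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    Dropout,
    Embedding,
    LearnedPositionalEmbedding,
    Linear,
    Module,
    ReLU,
    Sequential,
    Tensor,
    TransformerDecoderLayer,
    TransformerEncoderLayer,
    causal_mask,
    concat,
    log_softmax,
    mlp,
)


class ModelError(ValueError):
    pass


@dataclass
class PDualNetConfig:
    """Architecture hyperparameters; defaults are the deployed configuration
    (34,703 trainable parameters excluding the pretraining-only SiVE
    decoder)."""

    sive_dims: tuple[int, ...] = (89, 128, 64, 32, 16)
    sive_dropout: float = 0.3
    d_model: int = 16
    n_heads: int = 1
    ff_dim: int = 32
    dise_dropout: float = 0.2
    subtype_dims: tuple[int, ...] = (16, 8, 4)
    dec_ff_dim: int = 32
    dec_dropout: float = 0.1
    score_head_dims: tuple[int, ...] = (16, 16, 3)
    vocab_size: int = 101
    padding_idx: int = 100
    score_embed_dim: int = 16
    # learned positional embeddings: encoder covers CLS + the 13-visit grid;
    # decoder covers any context-plus-horizon span on that grid
    enc_max_len: int = 14
    dec_max_len: int = 24

    def validate(self) -> None:
        if self.sive_dims[-1] != self.d_model:
            raise ModelError("last SiVE dim must equal the transformer width")
        if self.score_embed_dim != self.d_model:
            raise ModelError("score embedding projection must match the transformer width")
        if self.subtype_dims[0] != self.d_model or self.subtype_dims[-1] != 4:
            raise ModelError("subtype decoder must map d_model -> ... -> 4")
        if self.score_head_dims[0] != self.d_model or self.score_head_dims[-1] != 3:
            raise ModelError("score head must map d_model -> ... -> 3")


@dataclass
class LossConfig:
    """Loss weighting: per-class weights w, per-score weights alpha, the
    joint-loss balance terms w1/w2 (optionally trainable) and the warm-up
    epoch threshold E_thres."""

    class_weights: np.ndarray = field(default_factory=lambda: np.ones(4))
    alphas: tuple[float, float, float] = (1.0, 1.0, 1.0)
    w1_init: float = 0.0
    w2_init: float = 0.0
    trainable_balance: bool = True
    e_thres: int = 20

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if np.any(self.class_weights <= 0):
            raise ModelError("class weights must be positive")
        if any(a < 0 for a in self.alphas):
            raise ModelError("alphas must be non-negative")
        if self.e_thres < 0:
            raise ModelError("e_thres must be >= 0")
        self.w1 = Tensor(np.array(self.w1_init), requires_grad=self.trainable_balance)
        self.w2 = Tensor(np.array(self.w2_init), requires_grad=self.trainable_balance)

    def balance_parameters(self) -> list[Tensor]:
        return [self.w1, self.w2] if self.trainable_balance else []


class PDualNet(Module):
    """Shared-encoder dual-task model; see the module docstring."""

    def __init__(self, config: PDualNetConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)

        dims = list(config.sive_dims)
        self.sive_encoder = mlp(dims, rng, dropout=config.sive_dropout)
        self.sive_decoder = mlp(dims[::-1], rng, dropout=config.sive_dropout)

        self.cls_token = Tensor(rng.normal(0.0, 0.02, config.d_model),
                                requires_grad=True)
        self.enc_pos = LearnedPositionalEmbedding(config.enc_max_len, config.d_model, rng)
        self.dise_encoder = TransformerEncoderLayer(
            config.d_model, config.n_heads, config.ff_dim, config.dise_dropout, rng)

        self.subtype_decoder = mlp(list(config.subtype_dims), rng)

        self.score_embeddings = [
            Embedding(config.vocab_size, config.score_embed_dim, rng,
                      padding_idx=config.padding_idx)
            for _ in range(3)
        ]
        self.score_proj = Linear(3 * config.score_embed_dim, config.d_model, rng)
        self.dec_pos = LearnedPositionalEmbedding(config.dec_max_len, config.d_model, rng)
        self.score_decoder = TransformerDecoderLayer(
            config.d_model, config.n_heads, config.dec_ff_dim, config.dec_dropout, rng)
        self.score_head = mlp(list(config.score_head_dims), rng,
                              dropout=config.dec_dropout)

    # -- component groups (for phased freezing and parameter audits) --------
    def component_parameters(self) -> dict[str, list[Tensor]]:
        groups = {
            "sive_encoder": self.sive_encoder.parameters(),
            "sive_decoder": self.sive_decoder.parameters(),
            "cls_token": [self.cls_token],
            "enc_positional": self.enc_pos.parameters(),
            "dise_encoder": self.dise_encoder.parameters(),
            "subtype_decoder": self.subtype_decoder.parameters(),
            "score_embeddings": [p for e in self.score_embeddings
                                 for p in e.parameters()],
            "score_projection": self.score_proj.parameters(),
            "dec_positional": self.dec_pos.parameters(),
            "score_transformer_decoder": self.score_decoder.parameters(),
            "score_head": self.score_head.parameters(),
        }
        return groups

    def upper_branch_parameters(self) -> list[Tensor]:
        """SiVE encoder + DiSE encoder (+CLS, positional) + subtype decoder."""
        g = self.component_parameters()
        return (g["sive_encoder"] + g["cls_token"] + g["enc_positional"]
                + g["dise_encoder"] + g["subtype_decoder"])

    def score_branch_parameters(self) -> list[Tensor]:
        g = self.component_parameters()
        return (g["score_embeddings"] + g["score_projection"] + g["dec_positional"]
                + g["score_transformer_decoder"] + g["score_head"])

    # -- forward pieces ------------------------------------------------------
    def sive_encode(self, x) -> Tensor:
        """Map visit vectors (..., N_f) to SiVE embeddings (..., 16)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.sive_dims[0]:
            raise ModelError(
                f"visit vector width {x.shape[-1]} != {self.config.sive_dims[0]}")
        return self.sive_encoder(x)

    def sive_reconstruct(self, z) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        if z.shape[-1] != self.config.d_model:
            raise ModelError(f"embedding width {z.shape[-1]} != {self.config.d_model}")
        return self.sive_decoder(z)

    def dise_encode(self, z_seq: Tensor,
                    padding_mask: np.ndarray | None = None) -> Tensor:
        """Disease-state embedding of a window of SiVE embeddings.

        ``z_seq``: (B, T, 16); ``padding_mask``: (B, T) with True marking
        padded (ignored) steps.  A CLS token is prepended, learned positional
        embeddings added, and the transformer encoder output at the CLS
        position returned: (B, 16).
        """
        if z_seq.ndim != 3 or z_seq.shape[1] < 1:
            raise ModelError("dise_encode expects a non-empty (B, T, D) sequence")
        B, T, D = z_seq.shape
        cls = self.cls_token.reshape(1, 1, D) * Tensor(np.ones((B, 1, 1)))
        seq = concat([cls, z_seq], axis=1)
        seq = self.enc_pos(seq)
        kpm = None
        if padding_mask is not None:
            kpm = np.concatenate(
                [np.zeros((B, 1), dtype=bool), padding_mask], axis=1)
        out = self.dise_encoder(seq, key_padding_mask=kpm)
        return out[:, 0, :]

    def classify(self, d_p: Tensor) -> Tensor:
        """Unnormalized subtype logits (no softmax; the loss expects logits)."""
        return self.subtype_decoder(d_p)

    def quantize_scores(self, u: np.ndarray) -> np.ndarray:
        """Round and clip raw totals to the embeddable levels 0..vocab-2.

        Applies only to the decoder input path; targets stay continuous.
        """
        return np.clip(np.round(np.asarray(u, dtype=float)), 0,
                       self.config.vocab_size - 2).astype(int)

    def embed_score_tokens(self, tokens: np.ndarray) -> Tensor:
        """(B, T, 3) integer score levels -> (B, T, 16) decoder inputs."""
        parts = [self.score_embeddings[j](tokens[:, :, j]) for j in range(3)]
        return self.score_proj(concat(parts, axis=-1))

    def decode_scores(self, d_p: Tensor, context: np.ndarray, horizon: int,
                      mode: str = "autoregressive",
                      teacher_targets: np.ndarray | None = None) -> Tensor:
        """Forecast ``horizon`` future score triplets.

        ``context``: (B, 3) raw last observed triplets (the decoding start
        input).  In teacher-forced mode ``teacher_targets`` (B, horizon, 3)
        supplies the ground-truth triplets whose first horizon-1 entries feed
        steps 2..horizon; autoregressive mode feeds back predictions.
        Returns (B, horizon, 3) raw-scale predictions.
        """
        if horizon < 1:
            raise ModelError("horizon must be >= 1")
        context = np.asarray(context, dtype=float)
        if context.ndim != 2 or context.shape[1] != 3:
            raise ModelError("context must be (B, 3) score triplets")
        B = context.shape[0]
        memory = d_p.reshape(B, 1, self.config.d_model)

        if mode == "teacher_forced":
            if horizon > 1:
                if teacher_targets is None:
                    raise ModelError("teacher_forced mode needs teacher_targets")
                teacher_targets = np.asarray(teacher_targets, dtype=float)
                inputs = np.concatenate(
                    [context[:, None, :], teacher_targets[:, :horizon - 1, :]], axis=1)
            else:
                inputs = context[:, None, :]
            tokens = self.quantize_scores(inputs)
            x = self.dec_pos(self.embed_score_tokens(tokens))
            out = self.score_decoder(x, memory, target_mask=causal_mask(horizon))
            return self.score_head(out)
        if mode == "autoregressive":
            preds: list[np.ndarray] = []
            inputs = context[:, None, :]
            for t in range(horizon):
                tokens = self.quantize_scores(inputs)
                x = self.dec_pos(self.embed_score_tokens(tokens))
                out = self.score_decoder(x, memory, target_mask=causal_mask(t + 1))
                y = self.score_head(out)
                preds.append(y.data[:, -1, :].copy())
                if t + 1 < horizon:
                    inputs = np.concatenate([inputs, preds[-1][:, None, :]], axis=1)
            return Tensor(np.stack(preds, axis=1))
        raise ModelError(f"unknown decoding mode {mode!r}")


def build_model(config: PDualNetConfig | None = None, seed: int = 0) -> PDualNet:
    """Construct the network with seeded initialization."""
    return PDualNet(config or PDualNetConfig(), seed=seed)


def parameter_count_table(model: PDualNet) -> dict[str, int]:
    """Per-component trainable-parameter counts.

    ``deployed_total`` excludes the SiVE decoder, which exists only for
    phase-1 pretraining; ``with_pretraining_decoder`` includes it.
    """
    table = {name: sum(p.data.size for p in params)
             for name, params in model.component_parameters().items()}
    total = sum(table.values())
    table["with_pretraining_decoder"] = total
    table["deployed_total"] = total - table["sive_decoder"]
    return table


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def reconstruction_loss_total(x, x_hat, reduction: str = "sum"):
    """Squared reconstruction error over a batch of visit vectors:
    sum_p sum_i ||x_i - x_hat_i||^2 (or the batch mean for optimizer
    scaling)."""
    xt = x if isinstance(x, Tensor) else Tensor(x)
    if xt.shape != x_hat.shape:
        raise ModelError(f"shape mismatch {xt.shape} vs {x_hat.shape}")
    resid = x_hat - xt
    sq = (resid * resid).sum()
    if reduction == "sum":
        return sq
    if reduction == "mean":
        n = int(np.prod(xt.shape[:-1])) or 1
        return sq * (1.0 / n)
    raise ModelError(f"unknown reduction {reduction!r}")


def weighted_cross_entropy(logits: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    """Class-weighted cross-entropy normalized by the summed sample weights:

        L = sum_n w_{y_n} * (-log softmax(s_n)[y_n]) / sum_n w_{y_n}

    Invariant to rescaling all weights by a positive constant.
    """
    y = np.asarray(y, dtype=int)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ModelError("class weights must be positive")
    B = y.shape[0]
    if logits.shape[0] != B:
        raise ModelError("batch size mismatch between logits and labels")
    ls = log_softmax(logits, axis=-1)
    nll = -ls[np.arange(B), y]
    sample_w = w[y]
    return (nll * Tensor(sample_w)).sum() / float(sample_w.sum())


def mds_mse(u_true: np.ndarray, u_pred: Tensor,
            alphas: tuple[float, float, float] = (1.0, 1.0, 1.0),
            step_mask: np.ndarray | None = None) -> Tensor:
    """alpha-weighted sum of per-part MSEs over all evaluated steps.

    ``u_true``/``u_pred``: (B, H, 3); ``step_mask`` (B, H) with True for
    steps that count (padded horizons excluded).
    """
    u_true = np.asarray(u_true, dtype=float)
    if tuple(u_pred.shape) != u_true.shape:
        raise ModelError(f"shape mismatch {u_pred.shape} vs {u_true.shape}")
    if step_mask is None:
        step_mask = np.ones(u_true.shape[:2], dtype=bool)
    n = max(int(step_mask.sum()), 1)
    w = (step_mask / n).astype(float)
    resid = u_pred - Tensor(u_true)
    sq = resid * resid  # (B, H, 3)
    total = None
    for j, a in enumerate(alphas):
        part = (sq[:, :, j] * Tensor(w)).sum() * a
        total = part if total is None else total + part
    return total


def joint_loss(mse, ce, epoch: int, cfg: LossConfig):
    """Eq.-style phased joint objective: plain regression loss during the
    warm-up epochs, then (e^{-w1}/2) L_MSE + (e^{-w2}/2) L_subtype with
    optionally trainable balance terms."""
    if epoch <= cfg.e_thres:
        return mse
    mse_t = mse if isinstance(mse, Tensor) else Tensor(mse)
    ce_t = ce if isinstance(ce, Tensor) else Tensor(ce)
    return ((-cfg.w1).exp() * 0.5) * mse_t + ((-cfg.w2).exp() * 0.5) * ce_t
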