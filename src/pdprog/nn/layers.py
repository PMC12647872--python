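"""Neural-network building blocks on top of the autodiff engine.

Conventions: batch-first shapes (B, T, D); attention masks are additive
float arrays (0 for allowed, -1e9 for blocked); padding masks are boolean
with True marking *padded* (ignored) positions.  Parameter counting follows
the usual transformer bookkeeping (packed QKV projection with bias, output
projection, two/three layer norms per encoder/decoder layer).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, softmax

NEG_INF = -1e9


class Module:
    """Base class: recursive parameter discovery plus train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        seen = set()
        for prefix, mod in self._named_modules(""):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    yield (f"{prefix}{k}", v)

    def _named_modules(self, prefix):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = state[k].copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-bound, bound, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator,
                 padding_idx: int | None = None):
        super().__init__()
        w = rng.normal(0.0, 0.1, (num_embeddings, dim))
        if padding_idx is not None:
            w[padding_idx] = 0.0
        self.weight = Tensor(w, requires_grad=True)
        self.padding_idx = padding_idx

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(indices, dtype=int))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by a module-owned seeded generator, so a full
    training run is reproducible given the model seed."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def mlp(dims: list[int], rng: np.random.Generator, dropout: float = 0.0,
        final_activation: bool = False) -> Sequential:
    """Fully connected stack ``dims[0] -> ... -> dims[-1]`` with ReLU between
    layers (and optionally after the last)."""
    layers: list[Module] = []
    for i in range(len(dims) - 1):
        layers.append(Linear(dims[i], dims[i + 1], rng))
        last = i == len(dims) - 2
        if not last or final_activation:
            layers.append(ReLU())
            if dropout > 0:
                layers.append(Dropout(dropout, rng))
    return Sequential(*layers)


class MultiheadAttention(Module):
    """Scaled dot-product attention with a packed QKV input projection."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.in_proj = Linear(dim, 3 * dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 attn_mask: np.ndarray | None = None,
                 key_padding_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = query.shape
        S = key.shape[1]
        H, hd = self.n_heads, self.dim // self.n_heads
        qkv_w = self.in_proj.weight
        qkv_b = self.in_proj.bias
        q = query @ qkv_w[:, :D] + qkv_b[:D]
        k = key @ qkv_w[:, D:2 * D] + qkv_b[D:2 * D]
        v = value @ qkv_w[:, 2 * D:] + qkv_b[2 * D:]

        def split(x, L):
            return x.reshape(B, L, H, hd).swapaxes(1, 2)  # (B, H, L, hd)

        q, k, v = split(q, T), split(k, S), split(v, S)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))  # (B,H,T,S)
        add = np.zeros((B, 1, T, S))
        if attn_mask is not None:
            add = add + attn_mask[None, None, :, :]
        if key_padding_mask is not None:
            add = add + np.where(key_padding_mask, NEG_INF, 0.0)[:, None, None, :]
        if attn_mask is not None or key_padding_mask is not None:
            scores = scores + Tensor(add)
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (B,H,T,hd)
        out = out.swapaxes(1, 2).reshape(B, T, D)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer (self-attention + feed-forward)."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiheadAttention(dim, n_heads, rng)
        self.linear1 = Linear(dim, ff_dim, rng)
        self.linear2 = Linear(ff_dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, x: Tensor,
                 key_padding_mask: np.ndarray | None = None) -> Tensor:
        a = self.self_attn(x, x, x, key_padding_mask=key_padding_mask)
        x = self.norm1(x + self.dropout(a))
        f = self.linear2(self.dropout(self.linear1(x).relu()))
        return self.norm2(x + self.dropout(f))


class TransformerDecoderLayer(Module):
    """Post-norm decoder layer: causal self-attention, cross-attention to the
    encoder memory, feed-forward."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiheadAttention(dim, n_heads, rng)
        self.cross_attn = MultiheadAttention(dim, n_heads, rng)
        self.linear1 = Linear(dim, ff_dim, rng)
        self.linear2 = Linear(ff_dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)
        self.dropout = Dropout(dropout, rng)

    def __call__(self, target: Tensor, memory: Tensor,
                 target_mask: np.ndarray | None = None,
                 target_padding_mask: np.ndarray | None = None,
                 memory_padding_mask: np.ndarray | None = None) -> Tensor:
        a = self.self_attn(target, target, target, attn_mask=target_mask,
                           key_padding_mask=target_padding_mask)
        x = self.norm1(target + self.dropout(a))
        c = self.cross_attn(x, memory, memory,
                            key_padding_mask=memory_padding_mask)
        x = self.norm2(x + self.dropout(c))
        f = self.linear2(self.dropout(self.linear1(x).relu()))
        return self.norm3(x + self.dropout(f))


class LearnedPositionalEmbedding(Module):
    """Learned additive positional embedding up to ``max_len`` positions."""

    def __init__(self, max_len: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, (max_len, dim)), requires_grad=True)
        self.max_len = max_len

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        return x + self.weight[:T]


class LSTM(Module):
    """Single-layer LSTM over padded batches.

    ``mask`` (B, T) marks real steps with True; the hidden/cell state is
    frozen through padded steps, so the returned final state equals the state
    at each sequence's last real step.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(hidden_dim)
        self.w_ih = Tensor(rng.uniform(-bound, bound, (input_dim, 4 * hidden_dim)),
                           requires_grad=True)
        self.w_hh = Tensor(rng.uniform(-bound, bound, (hidden_dim, 4 * hidden_dim)),
                           requires_grad=True)
        self.b_ih = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)
        self.b_hh = Tensor(np.zeros(4 * hidden_dim), requires_grad=True)
        self.hidden_dim = hidden_dim

    def _step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        return self._step_pre(x_t @ self.w_ih + self.b_ih, h, c)

    def _step_pre(self, xw_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        gates = xw_t + h @ self.w_hh + self.b_hh
        i = gates[:, :H].sigmoid()
        f = gates[:, H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 initial: tuple[Tensor, Tensor] | None = None
                 ) -> tuple[list[Tensor], Tensor]:
        B, T, _ = x.shape
        H = self.hidden_dim
        if initial is None:
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
        else:
            h, c = initial
        # input projection for every step in one matmul
        xw = x @ self.w_ih + self.b_ih  # (B, T, 4H)
        outputs: list[Tensor] = []
        for t in range(T):
            h_new, c_new = self._step_pre(xw[:, t, :], h, c)
            if mask is not None:
                m = Tensor(mask[:, t:t + 1].astype(float))
                h = h_new * m + h * (1.0 - m)
                c = c_new * m + c * (1.0 - m)
            else:
                h, c = h_new, c_new
            outputs.append(h)
        return outputs, h


def causal_mask(T: int) -> np.ndarray:
    """Additive (T, T) mask blocking attention to future positions."""
    return np.where(np.triu(np.ones((T, T)), k=1) > 0, NEG_INF, 0.0)


class Adam:
    """Adam optimizer over an explicit parameter list.

    Parameters outside the list are never touched, which is how branch
    freezing is implemented during phased training.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
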