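"""Neural building blocks for the graph age regressor.

Layers operate on dense, batched graph tensors: because every subject's
graph shares the same vertex set (one vertex per parcellation region),
vertex features are stacked as (batch, R, F), scalar edge features as
(batch, R, R), and the adjacency as a {0,1} mask of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "TransformerConv",
    "BrainAgeGNN",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
]

_ALLOWED_LAYERS = (1, 2, 3, 4)
_ALLOWED_HEADS = (1, 2, 4, 8)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the graph regressor.

    ``hidden_dim`` is the per-head attention width; heads are concatenated, so
    each convolution block emits ``n_heads * hidden_dim`` channels. The MLP
    head is fixed at one 32-unit hidden layer and a single output unit.
    """

    in_dim: int = 116
    hidden_dim: int = 32
    n_conv_layers: int = 2
    n_heads: int = 1
    leaky_slope: float = 0.01
    mlp_hidden: int = 32
    use_edge_features: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_conv_layers not in _ALLOWED_LAYERS:
            raise ValueError(f"n_conv_layers must be one of {_ALLOWED_LAYERS}")
        if self.n_heads not in _ALLOWED_HEADS:
            raise ValueError(f"n_heads must be one of {_ALLOWED_HEADS}")
        if self.in_dim < 1 or self.hidden_dim < 1:
            raise ValueError("dimensions must be positive")


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m._training = True

    def eval(self) -> None:
        for m in self.modules():
            m._training = False

    _training = True


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_uniform_init(rng, in_dim, (in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(_uniform_init(rng, in_dim, (out_dim,)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Per-vector normalization over the channel (last) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gain + self.bias


class BatchNorm1d(Module):
    """Batch normalization over axis 0 of a (batch, channels) tensor.

    Training mode uses batch statistics (differentiated through); inference
    mode uses running averages, so a trained model gives per-subject
    predictions that do not depend on who else is in the batch.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self._training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            normed = centered * (var + self.eps) ** -0.5
        else:
            normed = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return normed * self.gain + self.bias


class TransformerConv(Module):
    """Graph transformer convolution with scalar edge features.

    For vertex i and head h with neighbors j:

        q_i = W_q x_i,  k_ij = W_k x_j + w_e e_ij,  v_ij = W_v x_j + w_e e_ij
        alpha_ij = softmax_j( q_i . k_ij / sqrt(d) )
        out_i    = concat_h( sum_j alpha_ij v_ij ) + W_r x_i

    The edge map is shared between the key and value paths. Because e_ij is a
    scalar, the attention logits and the aggregated edge term factorize and
    the whole operator is evaluated densely over the (batch, R, R) adjacency
    mask; isolated vertices receive the skip term W_r x_i only.
    """

    def __init__(
        self,
        in_dim: int,
        head_dim: int,
        n_heads: int,
        rng: np.random.Generator,
        use_edge_features: bool = True,
    ):
        hd = n_heads * head_dim
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.use_edge_features = use_edge_features
        self.w_query = Tensor(_uniform_init(rng, in_dim, (in_dim, hd)), requires_grad=True)
        self.b_query = Tensor(_uniform_init(rng, in_dim, (hd,)), requires_grad=True)
        self.w_key = Tensor(_uniform_init(rng, in_dim, (in_dim, hd)), requires_grad=True)
        self.b_key = Tensor(_uniform_init(rng, in_dim, (hd,)), requires_grad=True)
        self.w_value = Tensor(_uniform_init(rng, in_dim, (in_dim, hd)), requires_grad=True)
        self.b_value = Tensor(_uniform_init(rng, in_dim, (hd,)), requires_grad=True)
        self.w_edge = Tensor(_uniform_init(rng, 1, (hd,)), requires_grad=True)
        self.b_edge = Tensor(_uniform_init(rng, 1, (hd,)), requires_grad=True)
        self.w_root = Tensor(_uniform_init(rng, in_dim, (in_dim, hd)), requires_grad=True)
        self.b_root = Tensor(_uniform_init(rng, in_dim, (hd,)), requires_grad=True)

    def _heads(self, t: Tensor, B: int, R: int) -> Tensor:
        # (B, R, H*d) -> (B, H, R, d)
        return t.reshape(B, R, self.n_heads, self.head_dim).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor, edge_feat: Tensor, mask: np.ndarray) -> Tensor:
        B, R, _ = x.shape
        H, d = self.n_heads, self.head_dim
        q = self._heads(x @ self.w_query + self.b_query, B, R)
        k = self._heads(x @ self.w_key + self.b_key, B, R)
        v = self._heads(x @ self.w_value + self.b_value, B, R)

        scale = 1.0 / np.sqrt(d)
        # logits: q_i . k_j  (+ scalar-edge contribution, factorized)
        scores = q @ k.transpose((0, 1, 3, 2))
        if self.use_edge_features:
            we = self.w_edge.reshape(1, H, 1, d)
            be = self.b_edge.reshape(1, H, 1, d)
            q_we = (q * we).sum(axis=-1, keepdims=True)  # (B,H,R,1)
            q_be = (q * be).sum(axis=-1, keepdims=True)
            e4 = edge_feat.reshape(B, 1, R, R)
            scores = scores + e4 * q_we + q_be
        scores = scores * scale

        neg = np.where(mask[:, None, :, :] > 0, 0.0, -1e30)
        alpha = (scores + Tensor(neg)).softmax()
        # zero out isolated rows (their softmax is uniform over -1e30 logits)
        alpha = alpha * Tensor(mask[:, None, :, :].astype(float))

        out = alpha @ v
        if self.use_edge_features:
            a_e = (alpha * e4).sum(axis=-1, keepdims=True)  # (B,H,R,1)
            a_1 = alpha.sum(axis=-1, keepdims=True)
            out = out + a_e * we + a_1 * be
        out = out.transpose((0, 2, 1, 3)).reshape(B, R, H * d)
        return out + (x @ self.w_root + self.b_root)

    def attention(self, x: Tensor, edge_feat: Tensor, mask: np.ndarray) -> np.ndarray:
        """Return the (B, H, R, R) attention coefficients (no gradient)."""
        B, R, _ = x.shape
        H, d = self.n_heads, self.head_dim
        q = self._heads(x @ self.w_query + self.b_query, B, R).data
        k = self._heads(x @ self.w_key + self.b_key, B, R).data
        scores = q @ np.swapaxes(k, -1, -2)
        if self.use_edge_features:
            we = self.w_edge.data.reshape(1, H, 1, d)
            be = self.b_edge.data.reshape(1, H, 1, d)
            scores = scores + edge_feat.data.reshape(B, 1, R, R) * (q * we).sum(
                -1, keepdims=True
            ) + (q * be).sum(-1, keepdims=True)
        scores = scores / np.sqrt(d)
        scores = scores + np.where(mask[:, None, :, :] > 0, 0.0, -1e30)
        shifted = scores - scores.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        alpha = e / e.sum(axis=-1, keepdims=True)
        return alpha * (mask[:, None, :, :] > 0)


class BrainAgeGNN(Module):
    """Transformer-convolution graph regressor for chronological age.

    ``n_conv_layers`` blocks of (attention aggregation -> LayerNorm ->
    LeakyReLU), a channelwise mean readout over vertices, then a two-layer
    MLP head (Linear -> ReLU -> BatchNorm -> Linear) with one output unit.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        # non-trained output affine (target standardization); training sets
        # these to the training-fold age mean/SD so the head works on an
        # O(1) scale instead of crawling tens of years at Adam's step size
        self.out_loc = 0.0
        self.out_scale = 1.0
        rng = np.random.default_rng(config.seed)
        hd = config.n_heads * config.hidden_dim
        convs, norms = [], []
        in_dim = config.in_dim
        for _ in range(config.n_conv_layers):
            convs.append(
                TransformerConv(
                    in_dim,
                    config.hidden_dim,
                    config.n_heads,
                    rng,
                    use_edge_features=config.use_edge_features,
                )
            )
            norms.append(LayerNorm(hd))
            in_dim = hd
        self.convs = convs
        self.norms = norms
        self.fc1 = Linear(hd, config.mlp_hidden, rng)
        self.bn = BatchNorm1d(config.mlp_hidden)
        self.fc2 = Linear(config.mlp_hidden, 1, rng)

    def forward(self, x: Tensor, edge_feat: Tensor, mask: np.ndarray) -> Tensor:
        """Predict ages for a batch of graphs; returns a (batch,) tensor."""
        h = x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h, edge_feat, mask)
            h = norm(h)
            h = h.leaky_relu(self.config.leaky_slope)
        pooled = h.mean(axis=1)  # mean readout over vertices
        z = self.fc1(pooled).relu()
        z = self.bn(z)
        out = self.fc2(z) * self.out_scale + self.out_loc
        return out.reshape(x.shape[0])

    def __call__(self, x, edge_feat, mask):
        return self.forward(x, edge_feat, mask)

    def predict(self, x: np.ndarray, edge_feat: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Inference-mode prediction from raw arrays."""
        self.eval()
        out = self.forward(Tensor(x), Tensor(edge_feat), mask)
        return out.data.copy()

    # -- serialization --------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"params": [p.data.tolist() for p in self.parameters()]}
        state["running"] = {
            "mean": self.bn.running_mean.tolist(),
            "var": self.bn.running_var.tolist(),
        }
        state["out_affine"] = [self.out_loc, self.out_scale]
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(params) != len(state["params"]):
            raise ValueError("checkpoint parameter count mismatch")
        for p, data in zip(params, state["params"]):
            arr = np.asarray(data, dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = arr
        self.bn.running_mean = np.asarray(state["running"]["mean"])
        self.bn.running_var = np.asarray(state["running"]["var"])
        self.out_loc, self.out_scale = state.get("out_affine", [0.0, 1.0])


def save_checkpoint(model: BrainAgeGNN, path) -> None:
    payload = {
        "format_version": 1,
        "config": asdict(model.config),
        "state": model.state_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> BrainAgeGNN:
    with open(path) as fh:
        payload = json.load(fh)
    model = BrainAgeGNN(ModelConfig(**payload["config"]))
    model.load_state_dict(payload["state"])
    return model


class Adam:
    """Adam with L2 weight decay added to the gradient (decoupled off)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
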