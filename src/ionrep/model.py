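"""Twin-branch contrastive model: encoder f, projector g, predictor q.

Both augmented views of an ion image pass through a shared convolutional
encoder producing a 512-d representation r, a 3-layer MLP projector giving
h, and a 2-layer bottleneck predictor giving p.  Training minimizes the
symmetric negative cosine similarity

    L = 1/2 D(p1, stopgrad(h2)) + 1/2 D(p2, stopgrad(h1)),
    D(a, b) = -(a . b) / (||a|| ||b||),

where the stop-gradient on the projector targets prevents the collapsed
solution without requiring negative pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import (
    BatchNorm1d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    ResidualBlock,
    Sequential,
)
from .msi_data import IonImage

__all__ = [
    "ModelConfig",
    "TwinModel",
    "build_model",
    "encode",
    "negative_cosine",
    "simsiam_loss",
    "pad_to_multiple",
    "save_checkpoint",
    "load_checkpoint",
]

_PAD_MULTIPLE = 32
_MIN_SIDE = 8


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``repr_dim`` is the encoder output width (512); the projector has
    ``proj_layers`` (3) fully connected layers of width ``proj_hidden``, the
    predictor ``pred_layers`` (2) layers through a ``pred_hidden`` (128)
    bottleneck.  All weights are initialized N(0, ``init_std``);
    ``pretrained_backbone`` loads encoder weights from a checkpoint path
    instead, when one is available.
    """

    repr_dim: int = 512
    proj_hidden: int = 512
    proj_layers: int = 3
    pred_hidden: int = 128
    pred_layers: int = 2
    pretrained_backbone: bool = False
    init_std: float = 0.02
    input_channels: int = 3

    def __post_init__(self) -> None:
        if self.repr_dim % 8 != 0:
            raise ValueError("repr_dim must be divisible by 8 (stage widths double 3x)")
        if self.proj_layers < 1 or self.pred_layers < 1:
            raise ValueError("layer counts must be >= 1")


def pad_to_multiple(x: np.ndarray, multiple: int = _PAD_MULTIPLE) -> np.ndarray:
    """Reflect-pad the trailing two axes up to the next multiple of ``multiple``."""
    h, w = x.shape[-2], x.shape[-1]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return x
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="reflect")


class Encoder(Module):
    """Compact residual CNN: stem (stride-2 conv + max pool) and four
    residual stages of widths d/8, d/4, d/2, d, global-average-pooled to a
    d-dimensional representation (d = ``repr_dim``).  The last block omits
    its output rectifier so the pooled representation is sign-symmetric
    rather than confined to the positive orthant, and a final batch norm
    equalizes per-dimension feature scales — the usual choices for features
    consumed by cosine/Euclidean similarity."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        base = cfg.repr_dim // 8
        std = cfg.init_std
        self.net = Sequential(
            Conv2d(cfg.input_channels, base, 3, stride=2, rng=rng, init_std=std),
            BatchNorm2d(base),
            ReLU(),
            MaxPool2d(),
            ResidualBlock(base, base, 1, rng=rng, init_std=std),
            ResidualBlock(base, 2 * base, 2, rng=rng, init_std=std),
            ResidualBlock(2 * base, 4 * base, 2, rng=rng, init_std=std),
            ResidualBlock(4 * base, 8 * base, 2, rng=rng, init_std=std, final_relu=False),
            GlobalAvgPool(),
            BatchNorm1d(cfg.repr_dim),
        )

    def forward(self, x, train=True):
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)

    def params(self):
        return self.net.params()

    def buffers(self):
        return self.net.buffers()


class _MLPHead(Module):
    """Stack of FC layers with batch norm + ReLU between them; the final
    layer is linear (no rectifier), optionally followed by an output batch
    norm — the twin-network ancestor normalizes the projector output to keep
    its scale in check and ward off collapse."""

    def __init__(self, dims: list[int], rng: np.random.Generator, init_std: float,
                 output_bn: bool = False):
        layers: list[Module] = []
        n_fc = len(dims) - 1
        for i in range(n_fc):
            layers.append(Linear(dims[i], dims[i + 1], rng=rng, init_std=init_std))
            if i < n_fc - 1:
                layers.append(BatchNorm1d(dims[i + 1]))
                layers.append(ReLU())
            elif output_bn:
                layers.append(BatchNorm1d(dims[i + 1]))
        self.net = Sequential(*layers)
        self.n_fc_layers = n_fc

    def forward(self, x, train=True):
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)

    def params(self):
        return self.net.params()

    def buffers(self):
        return self.net.buffers()


class TwinModel:
    """Shared-weight encoder/projector/predictor triple."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        d = cfg.repr_dim
        proj_dims = [d] + [cfg.proj_hidden] * (cfg.proj_layers - 1) + [d]
        self.projector = _MLPHead(proj_dims, rng, cfg.init_std, output_bn=True)
        pred_dims = [d] + [cfg.pred_hidden] * (cfg.pred_layers - 1) + [d]
        self.predictor = _MLPHead(pred_dims, rng, cfg.init_std)

    # -- parameter bookkeeping ------------------------------------------------
    def params(self):
        return self.encoder.params() + self.projector.params() + self.predictor.params()

    def buffers(self):
        return self.encoder.buffers() + self.projector.buffers() + self.predictor.buffers()

    # -- inference ------------------------------------------------------------
    def encode_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Encode a (B, C, H, W) batch to (B, repr_dim) representations."""
        if x.shape[-1] < _MIN_SIDE or x.shape[-2] < _MIN_SIDE:
            raise ValueError(
                f"input images must be at least {_MIN_SIDE}x{_MIN_SIDE} pixels, "
                f"got {x.shape[-2]}x{x.shape[-1]}"
            )
        return self.encoder.forward(pad_to_multiple(x), train)

    def project(self, r: np.ndarray, train: bool = False) -> np.ndarray:
        if not np.all(np.isfinite(r)):
            raise ValueError("projector input must be finite")
        return self.projector.forward(r, train)

    def predict_head(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        if not np.all(np.isfinite(h)):
            raise ValueError("predictor input must be finite")
        return self.predictor.forward(h, train)


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> TwinModel:
    return TwinModel(cfg or ModelConfig(), seed=seed)


def encode(image: IonImage, model: TwinModel) -> np.ndarray:
    """Encode one normalized ion image to its ``repr_dim`` representation.

    The single channel is replicated to the backbone's expected channel
    count and the image reflect-padded to a multiple of 32 per side.
    """
    if not image.normalized:
        raise ValueError("encode expects a normalized ion image")
    x = image.pixels[None, None, :, :]
    x = np.repeat(x, model.config.input_channels, axis=1)
    return model.encode_batch(x, train=False)[0]


# ---------------------------------------------------------------------------
# loss


def _neg_cos_rows(a: np.ndarray, b: np.ndarray, eps: float = 0.0):
    """Row-wise negative cosine value and its gradient with respect to ``a``.

    Returns (mean value, dvalue/da).  ``b`` is treated as a constant
    (stop-gradient semantics live here).
    """
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    if eps == 0.0 and (np.any(na == 0) or np.any(nb == 0)):
        branch = "first" if np.any(na == 0) else "second"
        raise ValueError(f"negative cosine undefined: {branch} argument has zero norm")
    na = na + eps
    nb = nb + eps
    dot = np.sum(a * b, axis=-1, keepdims=True)
    cos = dot / (na * nb)
    n = a.shape[0] if a.ndim > 1 else 1
    grad = -(b / (na * nb) - cos * a / na**2) / n
    return float(np.mean(-cos)), grad


def negative_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """-(a . b)/(||a|| ||b||), in [-1, 1]; batched inputs are averaged row-wise."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    value, _ = _neg_cos_rows(a, b)
    return value


def simsiam_loss(p1: np.ndarray, h1: np.ndarray, p2: np.ndarray, h2: np.ndarray) -> float:
    """Symmetric stop-gradient loss value (the h arguments receive no gradient)."""
    value, _, _ = simsiam_loss_and_grads(p1, h1, p2, h2)
    return value


def simsiam_loss_and_grads(p1, h1, p2, h2, eps: float = 0.0):
    """Loss plus gradients with respect to p1 and p2 only.

    The projector outputs h1/h2 enter solely as stop-gradient targets, so
    their gradients are identically zero and are not returned.
    """
    arrs = [np.atleast_2d(np.asarray(v, dtype=np.float64)) for v in (p1, h1, p2, h2)]
    p1, h1, p2, h2 = arrs
    if not (p1.shape == h1.shape == p2.shape == h2.shape):
        raise ValueError("all four vectors must share one shape")
    v1, dp1 = _neg_cos_rows(p1, h2, eps)
    v2, dp2 = _neg_cos_rows(p2, h1, eps)
    return 0.5 * v1 + 0.5 * v2, 0.5 * dp1, 0.5 * dp2


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TwinModel, path) -> None:
    """Serialize parameters, batch-norm statistics and config to one file."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    np.savez(path, **arrays)


def load_checkpoint(path) -> TwinModel:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(str(data["config_json"])))
        model = TwinModel(cfg, seed=0)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"b{i}"]
    return model
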