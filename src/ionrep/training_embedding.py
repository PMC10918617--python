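"""Self-supervised training loop and the 20-d embedding stage.

Training: every epoch, each ion image of the cube is augmented into two
views; both views of a batch are concatenated and pushed through the shared
encoder/projector/predictor; Adam (lr 3e-4, beta1 0.5, beta2 0.99) descends
the symmetric stop-gradient loss.  After training, the encoder output for
each channel (no augmentation, evaluation mode) is reduced with UMAP to 20
dimensions and min-max scaled per dimension — the retrieval substrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import Adam
from .augmentation import AugmentationConfig, _augment_array
from .model import (
    ModelConfig,
    TwinModel,
    pad_to_multiple,
    simsiam_loss_and_grads,
    _neg_cos_rows,
)
from .msi_data import IonImageCube

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "RepresentationMatrix",
    "EmbeddingMatrix",
    "train",
    "represent",
    "reduce",
    "representation_dispersion",
    "write_embeddings",
    "read_embeddings",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``iterations`` counts epochs over the ion-image set.  ``batch_size`` is
    the number of ion images per step (each contributes two views).
    """

    learning_rate: float = 3e-4
    beta1: float = 0.5
    beta2: float = 0.99
    iterations: int = 100
    batch_size: int = 64
    seed: int = 0
    mode: str = "COL"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.mode not in ("COL", "ISO"):
            raise ValueError("mode must be 'COL' or 'ISO'")


@dataclass
class TrainResult:
    model: TwinModel
    loss_trace: np.ndarray  # per-epoch mean loss


@dataclass
class RepresentationMatrix:
    """H x repr_dim encoder outputs, one row per ion image."""

    values: np.ndarray
    mz_values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        if self.values.shape[0] != len(self.mz_values):
            raise ValueError("row count must equal the number of m/z values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representations must be finite")


@dataclass
class EmbeddingMatrix:
    """H x out_dim UMAP embeddings, min-max scaled to [0, 1] per column."""

    values: np.ndarray
    mz_values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        if self.values.shape[0] != len(self.mz_values):
            raise ValueError("row count must equal the number of m/z values")


def _as_batch(images: np.ndarray, channels: int) -> np.ndarray:
    """(B, H, W) single-channel stack -> padded (B, C, H', W') batch."""
    x = pad_to_multiple(images)[:, None, :, :]
    return np.repeat(x, channels, axis=1)


def train(
    cube: IonImageCube,
    aug: AugmentationConfig | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    ablation: str | None = None,
) -> TrainResult:
    """Train the twin model on every channel of a normalized cube.

    ``ablation='no_stop_gradient'`` trains on the raw symmetric cosine of
    the two projections, bypassing predictor and stop-gradient — the
    negative control that exhibits representational collapse.
    """
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    aug = aug or AugmentationConfig(mode=train_cfg.mode)
    if aug.mode != train_cfg.mode:
        raise ValueError(
            f"augmentation mode {aug.mode!r} does not match training mode {train_cfg.mode!r}"
        )
    if ablation not in (None, "no_stop_gradient"):
        raise ValueError(f"unknown ablation {ablation!r}")
    if not cube.normalized:
        raise ValueError("train expects a preprocessed cube; run preprocess_cube first")
    H = cube.n_channels
    if H < 2:
        raise ValueError(
            "training needs at least 2 ion images (batch normalization requires batch >= 2)"
        )

    ss = np.random.SeedSequence(train_cfg.seed)
    init_seed, aug_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    model = TwinModel(model_cfg, seed=init_seed)
    rng = np.random.default_rng(aug_seed)

    opt = Adam(
        model.params(),
        lr=train_cfg.learning_rate,
        beta1=train_cfg.beta1,
        beta2=train_cfg.beta2,
    )
    images = np.ascontiguousarray(cube.intensities.transpose(2, 0, 1))
    trace = np.empty(train_cfg.iterations)
    for epoch in range(train_cfg.iterations):
        order = rng.permutation(H)
        batch_losses = []
        for start in range(0, H, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            v1 = np.stack([_augment_array(images[i], aug, rng) for i in idx])
            v2 = np.stack([_augment_array(images[i], aug, rng) for i in idx])
            x = _as_batch(np.concatenate([v1, v2]), model_cfg.input_channels)

            opt.zero_grad()
            r = model.encoder.forward(x, train=True)
            h = model.projector.forward(r, train=True)
            B = len(idx)
            if ablation == "no_stop_gradient":
                h1, h2 = h[:B], h[B:]
                loss, dh1 = _neg_cos_rows(h1, h2, eps=1e-12)
                _, dh2 = _neg_cos_rows(h2, h1, eps=1e-12)
                dh = np.concatenate([dh1, dh2])
            else:
                p = model.predictor.forward(h, train=True)
                loss, dp1, dp2 = simsiam_loss_and_grads(
                    p[:B], h[:B], p[B:], h[B:], eps=1e-12
                )
                dh = model.predictor.backward(np.concatenate([dp1, dp2]))
            dr = model.projector.backward(dh)
            model.encoder.backward(dr)
            opt.step()
            batch_losses.append(loss)
        trace[epoch] = float(np.mean(batch_losses))
        if not np.isfinite(trace[epoch]):
            raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, train_cfg.iterations, trace[epoch])
    return TrainResult(model=model, loss_trace=trace)


def represent(cube: IonImageCube, model: TwinModel, batch_size: int = 32) -> RepresentationMatrix:
    """Encode every channel in evaluation mode (no augmentation)."""
    if not cube.normalized:
        raise ValueError("represent expects a preprocessed cube")
    images = np.ascontiguousarray(cube.intensities.transpose(2, 0, 1))
    rows = []
    for start in range(0, len(images), batch_size):
        x = _as_batch(images[start : start + batch_size], model.config.input_channels)
        rows.append(model.encode_batch(x, train=False))
    return RepresentationMatrix(values=np.concatenate(rows), mz_values=cube.mz_values.copy())


def minmax_columns(values: np.ndarray) -> np.ndarray:
    """Min-max scale each column to [0, 1]; constant columns map to zeros."""
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    return (values - lo) / span


def reduce(
    reps: RepresentationMatrix,
    out_dim: int = 20,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> EmbeddingMatrix:
    """UMAP the H x 512 representations to H x ``out_dim``, min-max scaled.

    Euclidean metric; the seed fixes the embedding exactly.
    """
    import umap

    H = reps.values.shape[0]
    if H < out_dim + 2:
        raise ValueError(f"need at least {out_dim + 2} ions to embed into {out_dim} dimensions")
    reducer = umap.UMAP(
        n_components=out_dim,
        n_neighbors=min(n_neighbors, H - 1),
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
    )
    emb = np.asarray(reducer.fit_transform(reps.values), dtype=np.float64)
    return EmbeddingMatrix(values=minmax_columns(emb), mz_values=reps.mz_values.copy())


def representation_dispersion(values: np.ndarray) -> float:
    """Collapse monitor: the standard deviation across images of the
    L2-normalized representation vectors, i.e. the square root of the trace
    of their covariance (the RMS distance from the mean normalized vector).

    Spread-out representations on the unit sphere sit near 1; the collapsed
    solution, where the encoder maps every image to one point, gives 0.
    """
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    z = values / norms
    return float(np.sqrt(np.sum(z.var(axis=0))))


def write_embeddings(emb: EmbeddingMatrix, path) -> None:
    """Write embeddings as CSV with columns mz, e1..eD."""
    cols = {"mz": emb.mz_values}
    for j in range(emb.values.shape[1]):
        cols[f"e{j + 1}"] = emb.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_embeddings(path) -> EmbeddingMatrix:
    df = pd.read_csv(path)
    ecols = [c for c in df.columns if c.startswith("e")]
    return EmbeddingMatrix(values=df[ecols].to_numpy(), mz_values=df["mz"].to_numpy())
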