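"""Comparison methods operating on flattened ion images.

Two families: similarity-measure (SIM) baselines — pairwise Euclidean,
cosine, Pearson correlation, through-origin R^2 and SSIM matrices over the
channels — and dimensionality-reduction (DR) baselines — PCA, t-SNE and
UMAP embeddings of the flattened channels, min-max scaled per dimension so
they drop into the same retrieval machinery as the learned embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.metrics import structural_similarity

from .msi_data import IonImageCube
from .retrieval import _pcc, _r2_through_origin
from .training_embedding import EmbeddingMatrix, minmax_columns

__all__ = ["SimilarityMatrix", "sim_matrix", "dr_embed"]

_METRICS = ("euclidean", "cosine", "pcc", "r2", "ssim")


@dataclass
class SimilarityMatrix:
    """H x H pairwise metric over channels.

    Symmetric for euclidean/cosine/pcc/ssim (R^2 through the origin is
    directional: rows index the query, columns the candidate).  Diagonal is
    the metric's self-similarity: 0 for euclidean, 1 otherwise.
    """

    values: np.ndarray
    metric: str


def sim_matrix(cube: IonImageCube, metric: str) -> SimilarityMatrix:
    """Pairwise similarity of all channels under one SIM metric.

    Vector metrics use on-mask pixels only; SSIM is windowed over the full
    2-D images (standard 7x7 uniform window, data range 1) and needs a
    normalized cube.  Constant channels give NaN entries for pcc/r2.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if not cube.normalized:
        raise ValueError("sim_matrix expects a preprocessed ([0, 1]) cube")
    H = cube.n_channels
    mask = cube.pixel_mask
    flat = np.stack([cube.intensities[:, :, h][mask].ravel() for h in range(H)])

    if metric == "euclidean":
        values = cdist(flat, flat, metric="euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(flat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        z = flat / norms
        values = np.clip(z @ z.T, -1.0, 1.0)
    elif metric == "pcc":
        values = np.empty((H, H))
        for i in range(H):
            values[i, i] = 1.0 if flat[i].std() > 0 else np.nan
            for j in range(i + 1, H):
                values[i, j] = values[j, i] = _pcc(flat[i], flat[j])
    elif metric == "r2":
        values = np.empty((H, H))
        for i in range(H):
            for j in range(H):
                values[i, j] = (
                    1.0
                    if i == j and flat[i].std() > 0
                    else _r2_through_origin(flat[i], flat[j])
                )
    else:  # ssim
        values = np.empty((H, H))
        for i in range(H):
            values[i, i] = 1.0
            for j in range(i + 1, H):
                values[i, j] = values[j, i] = structural_similarity(
                    cube.intensities[:, :, i], cube.intensities[:, :, j], data_range=1.0
                )
    return SimilarityMatrix(values=values, metric=metric)


def dr_embed(
    cube: IonImageCube, method: str, out_dim: int = 20, seed: int = 0
) -> EmbeddingMatrix:
    """Reduce flattened channels with PCA, t-SNE or UMAP.

    t-SNE is run at 2 output dimensions (exact t-SNE beyond 3 is
    nonstandard) and zero-padded to the common ``out_dim`` container.
    All embeddings are min-max scaled per dimension.
    """
    if not cube.normalized:
        raise ValueError("dr_embed expects a preprocessed cube")
    H = cube.n_channels
    if H <= out_dim and method != "tsne":
        raise ValueError(f"{method} needs more than {out_dim} channels, got {H}")
    mask = cube.pixel_mask
    flat = np.stack([cube.intensities[:, :, h][mask].ravel() for h in range(H)])

    if method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=out_dim, random_state=seed).fit_transform(flat)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (H - 1) / 3.0)
        low = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(flat)
        emb = np.zeros((H, out_dim))
        emb[:, :2] = low
    elif method == "umap":
        import umap

        emb = umap.UMAP(
            n_components=out_dim,
            n_neighbors=min(15, H - 1),
            min_dist=0.1,
            metric="euclidean",
            random_state=seed,
        ).fit_transform(flat)
    else:
        raise ValueError("method must be 'pca', 'tsne' or 'umap'")
    return EmbeddingMatrix(
        values=minmax_columns(np.asarray(emb, dtype=np.float64)),
        mz_values=cube.mz_values.copy(),
    )
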