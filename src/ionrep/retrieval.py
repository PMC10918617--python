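"""Downstream tasks on the 20-d ion embeddings.

* colocalization: rank all other ions by Euclidean distance to a query;
* isotope discovery: gate candidate pairs by neutron-mass m/z offsets,
  then call pairs whose embedding distance falls under a threshold;
* benchmarking: leave-one-out linear probe accuracy over labelled ion
  image categories, and per-pair PCC / R^2 baselines for isotope calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression

from .msi_data import IonImageCube
from .training_embedding import EmbeddingMatrix

__all__ = [
    "NEUTRON_MASS",
    "RankedResult",
    "IsotopePairing",
    "rank_colocalized",
    "find_isotopes",
    "linear_probe_loo",
    "baseline_isotope_scores",
]

#: mass difference between successive isotopologue peaks (Da per neutron)
NEUTRON_MASS = 1.00336


@dataclass
class RankedResult:
    query_index: int
    candidate_indices: np.ndarray
    distances: np.ndarray


@dataclass
class IsotopePairing:
    mono_index: int
    iso_index: int
    k: int
    delta_mz: float
    distance: float


def rank_colocalized(embeddings: EmbeddingMatrix, query: int, top_k: int) -> RankedResult:
    """Rank candidate ions by ascending Euclidean distance to the query.

    Ties are broken by ascending m/z; the query itself is excluded.
    """
    E = embeddings.values
    H = E.shape[0]
    if not 0 <= query < H:
        raise IndexError(f"query index {query} out of range [0, {H})")
    if not 1 <= top_k < H:
        raise ValueError(f"top_k must lie in [1, {H})")
    d = np.linalg.norm(E - E[query], axis=1)
    others = np.array([i for i in range(H) if i != query])
    order = np.lexsort((embeddings.mz_values[others], d[others]))
    chosen = others[order][:top_k]
    return RankedResult(
        query_index=query, candidate_indices=chosen, distances=d[chosen]
    )


def isotope_candidates(
    mz_values: np.ndarray, mz_tolerance: float = 0.02, k_max: int = 3
) -> list[tuple[int, int, int]]:
    """Enumerate (mono, iso, k) triples with |mz[iso]-mz[mono]-k*1.00336| <= tol.

    When several k fit, the one with the smallest residual is kept.
    """
    if mz_tolerance <= 0 or k_max < 1:
        raise ValueError("mz_tolerance must be positive and k_max >= 1")
    mz = np.asarray(mz_values, dtype=np.float64)
    out = []
    H = len(mz)
    for m in range(H):
        for j in range(m + 1, H):
            delta = mz[j] - mz[m]
            if delta > k_max * NEUTRON_MASS + mz_tolerance:
                break
            resid = np.abs(delta - np.arange(1, k_max + 1) * NEUTRON_MASS)
            k_best = int(np.argmin(resid)) + 1
            if resid[k_best - 1] <= mz_tolerance:
                out.append((m, j, k_best))
    return out


def find_isotopes(
    embeddings: EmbeddingMatrix,
    mz_tolerance: float = 0.02,
    k_max: int = 3,
    distance_threshold: float | None = None,
) -> list[IsotopePairing]:
    """Identify monoisotope-isotope pairs.

    Candidates must sit at a neutron-mass multiple (k <= ``k_max``, within
    ``mz_tolerance`` Da).  Among candidates, pairs with embedding distance
    at or below the threshold are emitted, each putative isotope assigned to
    its closest monoisotope.  When no threshold is given, half the median
    all-pairs embedding distance is used — a data-adaptive gate separating
    the tight isotope mode from the bulk of unrelated pairs.
    """
    E = embeddings.values
    cands = isotope_candidates(embeddings.mz_values, mz_tolerance, k_max)
    if not cands:
        return []
    if distance_threshold is None:
        all_d = cdist(E, E)
        iu = np.triu_indices(E.shape[0], k=1)
        distance_threshold = 0.5 * float(np.median(all_d[iu]))
    elif distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")

    best: dict[int, IsotopePairing] = {}
    for m, j, k in cands:
        d = float(np.linalg.norm(E[m] - E[j]))
        if d > distance_threshold:
            continue
        delta = float(embeddings.mz_values[j] - embeddings.mz_values[m])
        pair = IsotopePairing(mono_index=m, iso_index=j, k=k, delta_mz=delta, distance=d)
        if j not in best or d < best[j].distance:
            best[j] = pair
    return sorted(best.values(), key=lambda p: (p.mono_index, p.iso_index))


def linear_probe_loo(features: np.ndarray, labels) -> float:
    """Leave-one-out accuracy of a multinomial logistic probe.

    For every image, the linear classifier (fixed, untuned regularization)
    is fit on all other images and predicts the held-out label; returns the
    fraction of correct predictions.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("linear probe needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members for leave-one-out")
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = LogisticRegression(max_iter=5000)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def _pcc(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _r2_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares fit of candidate y on query x through the origin.

    1 - SS_res/SS_tot with yhat = a*x, a = sum(xy)/sum(x^2); can be negative
    when the proportional fit explains less than the mean does.
    """
    sstot = np.sum((y - y.mean()) ** 2)
    sxx = np.sum(x * x)
    if sstot == 0 or sxx == 0:
        return np.nan
    a = np.sum(x * y) / sxx
    ssres = np.sum((y - a * x) ** 2)
    return float(1.0 - ssres / sstot)


def baseline_isotope_scores(
    cube: IonImageCube,
    pairs: list[tuple[int, int]],
    method: str = "PCC",
) -> list[float]:
    """Per-pair spatial-similarity scores used as isotope-call baselines.

    PCC is the Pearson correlation between the two channels' on-mask pixel
    vectors; R2 the through-origin coefficient of determination of the
    candidate on the query.  Constant channels yield NaN (no call).
    Conventional call thresholds are PCC >= 0.5 and R2 >= 0.
    """
    if method not in ("PCC", "R2"):
        raise ValueError("method must be 'PCC' or 'R2'")
    mask = cube.pixel_mask
    out = []
    for m, j in pairs:
        x = cube.intensities[:, :, m][mask].ravel()
        y = cube.intensities[:, :, j][mask].ravel()
        out.append(_pcc(x, y) if method == "PCC" else _r2_through_origin(x, y))
    return out
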