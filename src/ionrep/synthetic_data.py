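"""Phantom MSI cube generator with known ground truth.

Emulates the low-SNR data model the augmentation stack assumes: ions in
the same colocalization group share one smooth spatial template (an
anatomical region stand-in) but differ the way real co-distributed ions
do — per-ion abundance, a per-ion contrast warp (template**gamma), a
diffuse matrix-background haze, ion-counting (Poisson) noise at few counts
per pixel, and heavy per-ion missingness.  Isotope pairs share their
monoisotope's full value map, dimmed by a scale s, with extra
intensity-dependent missingness and an m/z offset of k neutron masses.
Everything is seeded and bit-reproducible, so retrieval, probing and
isotope discovery can be scored against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .msi_data import IonImageCube
from .retrieval import NEUTRON_MASS

__all__ = ["PhantomSpec", "generate"]

_MZ_LO, _MZ_HI = 100.0, 2000.0  # synthetic acquisition range, Da


@dataclass
class PhantomSpec:
    """Phantom study conditions.

    Defaults model low-SNR MSI: per-pixel ion counts peak around
    ``count_scale`` (single digits to low tens in MALDI practice);
    ``missing_fraction`` is the mean per-ion missing-value proportion (real
    MSI ions commonly lose half or more of their pixels, the hardest ones
    70-90%), with each ion drawing its own fraction from a +-
    ``missing_spread`` band; ``gamma_range`` warps each member's contrast
    (template**gamma); ``haze_max`` bounds the diffuse matrix-background
    haze added per ion; ``speckle_max`` bounds the log-amplitude of the
    smooth multiplicative speckle field modelling matrix-crystallization
    heterogeneity.  Total channels
    H = n_groups * ions_per_group + n_background + 2 * isotope_pairs.
    """

    grid: tuple = (64, 64)
    n_groups: int = 5
    ions_per_group: int = 10
    n_background: int = 0
    shape_kinds: tuple = ("disk", "annulus", "stripe", "blob-union")
    count_scale: float = 8.0
    missing_fraction: float = 0.5
    missing_spread: float = 0.25
    gamma_range: tuple = (0.6, 1.67)
    haze_max: float = 0.5
    speckle_max: float = 0.5
    isotope_pairs: int = 0
    isotope_scales: tuple = (0.2, 0.6)
    iso_missing_max: float = 0.5
    gain_range: tuple = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 16:
            raise ValueError("grid must be at least 16 x 16 to hold the shape templates")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_groups < 0 or self.ions_per_group < 0 or self.n_background < 0:
            raise ValueError("counts must be non-negative")
        if self.isotope_pairs < 0:
            raise ValueError("isotope_pairs must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.n_groups * self.ions_per_group + self.n_background + 2 * self.isotope_pairs


def _binary_shape(kind: str, M: int, N: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:M, 0:N]
    s = min(M, N)

    def disk(cx, cy, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    if kind == "disk":
        return disk(rng.uniform(0.25, 0.75) * N, rng.uniform(0.25, 0.75) * M,
                    rng.uniform(0.15, 0.3) * s)
    if kind == "annulus":
        cx = rng.uniform(0.3, 0.7) * N
        cy = rng.uniform(0.3, 0.7) * M
        r_out = rng.uniform(0.2, 0.35) * s
        r_in = rng.uniform(0.5, 0.75) * r_out
        return disk(cx, cy, r_out) & ~disk(cx, cy, r_in)
    if kind == "stripe":
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(0.3, 0.7) * N
        cy = rng.uniform(0.3, 0.7) * M
        width = rng.uniform(0.08, 0.18) * s
        return np.abs((xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)) <= width
    if kind == "blob-union":
        out = np.zeros((M, N), dtype=bool)
        for _ in range(rng.integers(2, 5)):
            out |= disk(rng.uniform(0.2, 0.8) * N, rng.uniform(0.2, 0.8) * M,
                        rng.uniform(0.08, 0.18) * s)
        return out
    raise ValueError(f"unknown shape kind {kind!r}")


def _template(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    M, N = spec.grid
    mask = _binary_shape(rng.choice(spec.shape_kinds), M, N, rng)
    t = ndimage.gaussian_filter(mask.astype(float), sigma=min(M, N) / 24.0)
    m = t.max()
    return t / m if m > 0 else t


def _distinct_template(spec, rng, existing, max_corr=0.5, tries=50) -> np.ndarray:
    # groups stand for distinct regions; reject templates that nearly
    # coincide with an already drawn one
    for _ in range(tries):
        t = _template(spec, rng)
        if t.max() == 0:
            continue
        if all(np.corrcoef(t.ravel(), e.ravel())[0, 1] < max_corr for e in existing):
            return t
    return t  # fall back to the last draw rather than fail


def _haze(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Diffuse matrix-background field: smooth random haze scaled to max 1."""
    M, N = spec.grid
    field = ndimage.gaussian_filter(rng.random((M, N)), sigma=min(M, N) / 8.0)
    field -= field.min()
    m = field.max()
    return field / m if m > 0 else field


def _speckle(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field (mean 1) for matrix-crystallization
    heterogeneity: exp of a correlated Gaussian field."""
    M, N = spec.grid
    z = ndimage.gaussian_filter(rng.standard_normal((M, N)), sigma=min(M, N) / 8.0)
    s = z.std()
    if s > 0:
        z /= s
    sig = rng.uniform(0.0, spec.speckle_max)
    return np.exp(sig * z - 0.5 * sig * sig)


def _ion_value_map(template: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-ion expected-intensity map: gain * (template**gamma + haze) * speckle."""
    gain = rng.uniform(*spec.gain_range)
    gamma = rng.uniform(*spec.gamma_range)
    b = rng.uniform(0.0, spec.haze_max)
    return gain * (template**gamma + b * _haze(spec, rng)) * _speckle(spec, rng)


def _corrupt(values: np.ndarray, spec: PhantomSpec, rng: np.random.Generator,
             missing_fraction: float | None = None) -> np.ndarray:
    counts = rng.poisson(spec.count_scale * values).astype(np.float64)
    if missing_fraction is None:
        frac = rng.uniform(spec.missing_fraction - spec.missing_spread,
                           spec.missing_fraction + spec.missing_spread)
        frac = min(max(frac, 0.0), 0.9)
    else:
        frac = missing_fraction
    nz = np.flatnonzero(counts)
    n_drop = int(np.floor(frac * nz.size))
    if n_drop:
        counts.flat[rng.choice(nz, size=n_drop, replace=False)] = 0.0
    return counts


def _intensity_missing(counts: np.ndarray, max_fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    out = counts.copy()
    m = out.max()
    if m == 0 or max_fraction <= 0:
        return out
    p = max_fraction * (1.0 - out / m)
    out[(out != 0) & (rng.random(out.shape) < p)] = 0.0
    return out


def generate(spec: PhantomSpec):
    """Generate a phantom cube plus ground truth.

    Returns ``(cube, group_labels, isotope_truth)``: the raw-intensity
    :class:`IonImageCube` (channels sorted by m/z), an integer label per
    channel (group index; -1 for background and isotope channels), and the
    list of true (monoisotope, isotope) channel-index pairs.
    """
    rng = np.random.default_rng(spec.seed)
    M, N = spec.grid
    H = spec.n_channels

    templates: list[np.ndarray] = []
    channels: list[np.ndarray] = []
    labels: list[int] = []
    iso_mark: list[tuple[int, int, int] | None] = []  # (pair id, role, k)

    for g in range(spec.n_groups):
        t = _distinct_template(spec, rng, templates)
        templates.append(t)
        for _ in range(spec.ions_per_group):
            channels.append(_corrupt(_ion_value_map(t, spec, rng), spec, rng))
            labels.append(g)
            iso_mark.append(None)

    for _ in range(spec.n_background):
        t = _template(spec, rng)
        channels.append(_corrupt(_ion_value_map(t, spec, rng), spec, rng))
        labels.append(-1)
        iso_mark.append(None)

    s_lo = spec.isotope_scales[0]
    for pair in range(spec.isotope_pairs):
        t = _distinct_template(spec, rng, templates)
        templates.append(t)
        k = int(rng.choice([1, 2, 3], p=[0.6, 0.25, 0.15]))
        # the isotope is the same molecule: it shares the monoisotope's full
        # value map, dimmed by s, and only the counting noise is independent
        v = _ion_value_map(t, spec, rng)
        mono = _corrupt(v, spec, rng)
        s = rng.uniform(*spec.isotope_scales)
        iso = _corrupt(s * v, spec, rng)
        extra = spec.iso_missing_max * (1.0 - s) / (1.0 - s_lo if s_lo < 1 else 1.0)
        iso = _intensity_missing(iso, min(max(extra, 0.0), 0.99), rng)
        channels.append(mono)
        labels.append(-1)
        iso_mark.append((pair, 0, k))
        channels.append(iso)
        labels.append(-1)
        iso_mark.append((pair, 1, k))

    # m/z assignment: free channels uniform on the acquisition range,
    # isotope channels offset by k neutron masses (plus sub-tolerance jitter)
    mz = np.empty(H)
    for idx, mark in enumerate(iso_mark):
        if mark is None:
            mz[idx] = rng.uniform(_MZ_LO, _MZ_HI)
        elif mark[1] == 0:
            mz[idx] = rng.uniform(_MZ_LO, _MZ_HI - 4.0)
        else:
            k = mark[2]
            mz[idx] = mz[idx - 1] + k * NEUTRON_MASS + rng.uniform(-0.005, 0.005)

    # enforce a strictly increasing axis after sorting: nudge collisions
    for _ in range(100):
        order = np.argsort(mz)
        gaps_ok = np.all(np.diff(mz[order]) > 1e-4)
        if gaps_ok:
            break
        tight = np.where(np.diff(mz[order]) <= 1e-4)[0]
        for t_idx in tight:
            offender = order[t_idx + 1]
            if iso_mark[offender] is None:
                mz[offender] = rng.uniform(_MZ_LO, _MZ_HI)

    order = np.argsort(mz)
    inverse = np.empty(H, dtype=int)
    inverse[order] = np.arange(H)

    cube = IonImageCube(
        intensities=np.stack([channels[i] for i in order], axis=2),
        mz_values=mz[order],
        pixel_mask=np.ones((M, N), dtype=bool),
    )
    group_labels = np.array([labels[i] for i in order])
    pair_members: dict[int, dict[int, int]] = {}
    for idx, mark in enumerate(iso_mark):
        if mark is not None:
            pair_members.setdefault(mark[0], {})[mark[1]] = int(inverse[idx])
    isotope_truth = [
        (pair_members[p][0], pair_members[p][1]) for p in sorted(pair_members)
    ]
    return cube, group_labels, isotope_truth
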