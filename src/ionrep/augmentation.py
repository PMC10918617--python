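"""MSI-specific stochastic augmentation of ion images.

Contrastive training needs two corrupted "views" of each ion image that
differ the way real re-acquisitions would.  The operator stack models MSI
physics: photometric jitter and smoothing (detector gain / spatial spread),
Poisson resampling (ion counting statistics), uniform random dropout
(missing values), and, for the isotope mode, a global intensity scale plus
intensity-dependent dropout (isotopologues are dimmer copies of the
monoisotope with more missing pixels).

Two compositions exist:

* COL mode: jitter -> filter -> Poisson noise -> random missing.
* ISO mode: the COL stack, then a global scale s and intensity-dependent
  missing whose strength grows as s shrinks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import ndimage

from .msi_data import IonImage

__all__ = [
    "AugmentationConfig",
    "color_jitter",
    "smooth_filter",
    "poisson_noise",
    "random_missing",
    "intensity_dependent_missing",
    "make_views",
]


def _check_range(name: str, pair, lo_ok: float = -np.inf, hi_ok: float = np.inf) -> tuple:
    lo, hi = float(pair[0]), float(pair[1])
    if not (lo_ok <= lo <= hi <= hi_ok):
        raise ValueError(f"{name} must be an ordered pair within [{lo_ok}, {hi_ok}], got {pair}")
    return (lo, hi)


@dataclass
class AugmentationConfig:
    """Parameters of the view-generating transformation.

    All ranges are (lo, hi) pairs sampled uniformly per view.  ``mode`` picks
    the operator composition; ``rng_seed`` makes view pairs reproducible when
    no external generator is supplied.
    """

    mode: str = "COL"
    jitter_brightness: tuple = (0.8, 1.2)
    jitter_contrast: tuple = (0.8, 1.2)
    filter_sigma: tuple = (0.0, 1.5)
    poisson_scale: float = 50.0
    missing_fraction: tuple = (0.0, 0.3)
    iso_scale: tuple = (0.1, 1.0)
    iso_missing_max: float = 0.5
    filter_kind: str = "gaussian"
    drop_low_intensity: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("COL", "ISO"):
            raise ValueError(f"mode must be 'COL' or 'ISO', got {self.mode!r}")
        self.jitter_brightness = _check_range("jitter_brightness", self.jitter_brightness, 0.0)
        self.jitter_contrast = _check_range("jitter_contrast", self.jitter_contrast, 0.0)
        self.filter_sigma = _check_range("filter_sigma", self.filter_sigma, 0.0)
        if self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be positive")
        self.missing_fraction = _check_range("missing_fraction", self.missing_fraction, 0.0)
        if self.missing_fraction[1] >= 1.0:
            raise ValueError("missing_fraction must stay below 1")
        self.iso_scale = _check_range("iso_scale", self.iso_scale, 0.0)
        if not 0.0 <= self.iso_missing_max < 1.0:
            raise ValueError("iso_missing_max must lie in [0, 1)")
        if self.filter_kind not in ("gaussian", "median"):
            raise ValueError("filter_kind must be 'gaussian' or 'median'")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("jitter_brightness", "jitter_contrast", "filter_sigma",
                  "missing_fraction", "iso_scale"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


# ---------------------------------------------------------------------------
# array-level operators (hot path used by the trainer)


def _jitter(x: np.ndarray, brightness: float, contrast: float) -> np.ndarray:
    m = x.mean()
    y = np.clip(contrast * (x - m) + m, 0.0, 1.0)
    return np.clip(brightness * y, 0.0, 1.0)


def _filter(x: np.ndarray, sigma: float, kind: str = "gaussian") -> np.ndarray:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return x.copy()
    if kind == "gaussian":
        return ndimage.gaussian_filter(x, sigma=sigma, mode="reflect")
    # median alternative: sigma is mapped to an odd window of comparable extent
    size = max(3, int(2 * round(sigma) + 1))
    return ndimage.median_filter(x, size=size, mode="reflect")


def _poisson(x: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale <= 0:
        raise ValueError("poisson scale must be positive")
    k = rng.poisson(scale * x)
    return np.clip(k / scale, 0.0, 1.0)


def _random_missing(x: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    if not 0.0 <= fraction < 1.0:
        raise ValueError("missing fraction must lie in [0, 1)")
    y = x.copy()
    nz = np.flatnonzero(y)
    n_drop = int(np.floor(fraction * nz.size))
    if n_drop:
        drop = rng.choice(nz, size=n_drop, replace=False)
        y.flat[drop] = 0.0
    return y


def _intensity_missing(
    x: np.ndarray, max_fraction: float, rng: np.random.Generator, drop_low: bool = True
) -> np.ndarray:
    if not 0.0 <= max_fraction < 1.0:
        raise ValueError("max_fraction must lie in [0, 1)")
    y = x.copy()
    nz = y != 0
    # dim pixels vanish preferentially (drop_low); the flipped direction is
    # available for the alternative reading of intensity-dependent dropout
    p = max_fraction * (1.0 - y) if drop_low else max_fraction * y
    drop = nz & (rng.random(y.shape) < p)
    y[drop] = 0.0
    return y


def _augment_array(x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    b = rng.uniform(*cfg.jitter_brightness)
    c = rng.uniform(*cfg.jitter_contrast)
    sigma = rng.uniform(*cfg.filter_sigma)
    frac = rng.uniform(*cfg.missing_fraction)
    y = _jitter(x, b, c)
    y = _filter(y, sigma, cfg.filter_kind)
    y = _poisson(y, cfg.poisson_scale, rng)
    y = _random_missing(y, frac, rng)
    if cfg.mode == "ISO":
        s = rng.uniform(*cfg.iso_scale)
        y = y * s
        lo = cfg.iso_scale[0]
        denom = 1.0 - lo if lo < 1.0 else 1.0
        mf = cfg.iso_missing_max * (1.0 - s) / denom
        mf = min(max(mf, 0.0), np.nextafter(1.0, 0.0))
        y = _intensity_missing(y, mf, rng, cfg.drop_low_intensity)
    return np.clip(y, 0.0, 1.0)


# ---------------------------------------------------------------------------
# IonImage-level operators


def _require_normalized(image: IonImage, op: str) -> None:
    if not image.normalized:
        raise ValueError(f"{op} expects a normalized ([0, 1]) ion image")


def color_jitter(image: IonImage, brightness: float, contrast: float,
                 rng: np.random.Generator | None = None) -> IonImage:
    """Photometric jitter: contrast about the image mean, then brightness.

    y = clip(brightness * clip(contrast * (x - mean(x)) + mean(x))) in [0, 1].
    """
    _require_normalized(image, "color_jitter")
    if brightness < 0 or contrast < 0:
        raise ValueError("brightness and contrast factors must be non-negative")
    return replace(image, pixels=_jitter(image.pixels, brightness, contrast))


def smooth_filter(image: IonImage, sigma: float, kind: str = "gaussian") -> IonImage:
    """Gaussian blur (std ``sigma`` pixels, reflective boundary); sigma 0 is identity."""
    return replace(image, pixels=_filter(image.pixels, sigma, kind))


def poisson_noise(image: IonImage, scale: float, rng: np.random.Generator) -> IonImage:
    """Scaled-count shot noise: x -> k/scale with k ~ Poisson(scale * x).

    Unbiased before clipping (E[out] = in), with variance x/scale, mirroring
    ion-counting statistics at a mean peak count of ``scale``.
    """
    _require_normalized(image, "poisson_noise")
    return replace(image, pixels=_poisson(image.pixels, scale, rng))


def random_missing(image: IonImage, fraction: float, rng: np.random.Generator) -> IonImage:
    """Zero exactly floor(fraction * n_nonzero) nonzero pixels, chosen uniformly."""
    return replace(image, pixels=_random_missing(image.pixels, fraction, rng))


def intensity_dependent_missing(
    image: IonImage, max_fraction: float, rng: np.random.Generator, drop_low: bool = True
) -> IonImage:
    """Drop each nonzero pixel i independently with p_i = max_fraction * (1 - x_i).

    Low-intensity pixels vanish preferentially, as in real MS missingness;
    ``drop_low=False`` flips the direction (p_i proportional to x_i).
    """
    _require_normalized(image, "intensity_dependent_missing")
    return replace(
        image, pixels=_intensity_missing(image.pixels, max_fraction, rng, drop_low)
    )


def make_views(
    image: IonImage, config: AugmentationConfig, rng: np.random.Generator | None = None
) -> tuple[IonImage, IonImage]:
    """Generate two independently augmented views of one ion image.

    COL composes jitter -> filter -> Poisson -> random missing; ISO appends a
    global scale s ~ U(iso_scale) and intensity-dependent missing with
    max_fraction = iso_missing_max * (1 - s) / (1 - iso_scale_lo), so dimmer
    views lose proportionally more pixels.  With the same generator state the
    view pair is reproducible.
    """
    _require_normalized(image, "make_views")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    v1 = _augment_array(image.pixels, config, rng)
    v2 = _augment_array(image.pixels, config, rng)
    return (replace(image, pixels=v1), replace(image, pixels=v2))
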