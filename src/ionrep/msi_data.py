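"""MSI datacube container and preprocessing.

Mass spectrometry imaging produces one 2-D intensity map ("ion image") per
m/z channel.  This module holds the dense M x N x H datacube, reads it from
imzML or a single-file dense array store, and applies the two preprocessing
steps every downstream stage assumes: hotspot truncation (extreme high
intensities clipped to a per-image threshold) and per-image min-max
normalization to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "IonImage",
    "IonImageCube",
    "load_cube",
    "save_cube",
    "remove_hotspots",
    "normalize_image",
    "preprocess_cube",
]


@dataclass
class IonImage:
    """A single ion image: one m/z channel of the datacube.

    Parameters
    ----------
    pixels : ndarray of shape (M, N)
        Intensities; arbitrary units before normalization, [0, 1] after.
    mz : float
        The channel's m/z value in Da.
    normalized : bool
        True once min-max scaled to [0, 1].
    """

    pixels: np.ndarray
    mz: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("IonImage.pixels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class IonImageCube:
    """Dense MSI datacube of shape (M, N, H) plus per-channel m/z values.

    ``pixel_mask`` marks acquired (on-tissue) pixels; positions absent from
    the source file are zero-filled and masked out.
    """

    intensities: np.ndarray
    mz_values: np.ndarray
    pixel_mask: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have shape (M, N, H)")
        if self.mz_values.ndim != 1 or len(self.mz_values) != self.intensities.shape[2]:
            raise ValueError("mz_values length must equal the number of channels H")
        if np.any(np.diff(self.mz_values) <= 0):
            raise ValueError("mz_values must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_mask is None:
            self.pixel_mask = np.ones(self.intensities.shape[:2], dtype=bool)
        else:
            self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
            if self.pixel_mask.shape != self.intensities.shape[:2]:
                raise ValueError("pixel_mask shape must be (M, N)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    def channel(self, h: int) -> IonImage:
        """Return channel ``h`` as an :class:`IonImage` (a view is copied)."""
        if not 0 <= h < self.n_channels:
            raise IndexError(f"channel {h} out of range [0, {self.n_channels})")
        return IonImage(
            pixels=self.intensities[:, :, h].copy(),
            mz=float(self.mz_values[h]),
            normalized=self.normalized,
        )


def save_cube(cube: IonImageCube, path) -> None:
    """Write a cube to the single-file dense container (NumPy ``.npz``)."""
    np.savez(
        path,
        intensities=cube.intensities,
        mz_values=cube.mz_values,
        pixel_mask=cube.pixel_mask,
        normalized=np.array(cube.normalized),
    )


def _load_dense(path) -> IonImageCube:
    with np.load(path) as data:
        try:
            return IonImageCube(
                intensities=data["intensities"],
                mz_values=data["mz_values"],
                pixel_mask=data["pixel_mask"],
                normalized=bool(data["normalized"]),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"dense container {path} is missing record {exc}") from exc


def _load_imzml(path, bin_width: float) -> IonImageCube:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse imzML file {path}: {exc}") from exc

    coords = np.asarray(parser.coordinates)  # (n_spectra, 3), 1-based x, y, z
    xs, ys = coords[:, 0], coords[:, 1]
    n_rows = int(ys.max())
    n_cols = int(xs.max())

    spectra = [parser.getspectrum(i) for i in range(len(parser.coordinates))]
    lengths = {len(mzs) for mzs, _ in spectra}
    continuous = len(lengths) == 1 and all(
        np.array_equal(np.asarray(spectra[0][0]), np.asarray(mzs)) for mzs, _ in spectra
    )

    if continuous:
        mz_axis = np.asarray(spectra[0][0], dtype=np.float64)
        if np.any(np.diff(mz_axis) <= 0):
            raise ValueError(f"imzML file {path} has a non-monotone m/z axis")
        H = len(mz_axis)
        cube = np.zeros((n_rows, n_cols, H))
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        for (x, y, _z), (mzs, ints) in zip(parser.coordinates, spectra):
            cube[y - 1, x - 1, :] = np.asarray(ints, dtype=np.float64)
            mask[y - 1, x - 1] = True
        return IonImageCube(intensities=cube, mz_values=mz_axis, pixel_mask=mask)

    # processed dialect: bin every peak onto a uniform axis of the given width
    if bin_width <= 0:
        raise ValueError("bin_width must be positive for processed imzML")
    bins: dict[int, int] = {}
    for mzs, _ints in spectra:
        for b in np.rint(np.asarray(mzs, dtype=np.float64) / bin_width).astype(np.int64):
            bins.setdefault(int(b), 0)
    bin_ids = np.array(sorted(bins), dtype=np.int64)
    index = {int(b): i for i, b in enumerate(bin_ids)}
    mz_axis = bin_ids * bin_width
    H = len(mz_axis)
    cube = np.zeros((n_rows, n_cols, H))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for (x, y, _z), (mzs, ints) in zip(parser.coordinates, spectra):
        mask[y - 1, x - 1] = True
        b = np.rint(np.asarray(mzs, dtype=np.float64) / bin_width).astype(np.int64)
        for bi, vi in zip(b, np.asarray(ints, dtype=np.float64)):
            cube[y - 1, x - 1, index[int(bi)]] += vi
    return IonImageCube(intensities=cube, mz_values=mz_axis, pixel_mask=mask)


def load_cube(path, format: str = "imzml", bin_width: float = 0.01) -> IonImageCube:
    """Load an MSI datacube.

    Parameters
    ----------
    path : path-like
        Input file (``.imzML`` with its ``.ibd``, or an ``.npz`` dense store).
    format : {"imzml", "dense-array"}
        Input format.  imzML may be continuous (all spectra share one m/z
        axis) or processed; processed spectra are binned onto a uniform axis
        of width ``bin_width`` Da (peaks landing in the same bin are summed).
    """
    if format == "imzml":
        return _load_imzml(path, bin_width)
    if format == "dense-array":
        return _load_dense(path)
    raise ValueError(f"unknown format {format!r}; expected 'imzml' or 'dense-array'")


def _hotspot_threshold(values: np.ndarray, quantile_mode: str) -> float:
    if quantile_mode == "fraction-of-max":
        return 0.99 * float(values.max())
    if quantile_mode == "percentile":
        return float(np.percentile(values, 99))
    raise ValueError(
        f"unknown quantile_mode {quantile_mode!r}; expected 'fraction-of-max' or 'percentile'"
    )


def remove_hotspots(
    image: IonImage,
    quantile_mode: str = "fraction-of-max",
    mask: np.ndarray | None = None,
) -> IonImage:
    """Truncate hotspots: pixels above the threshold are clipped to it.

    Under ``fraction-of-max`` the threshold is 0.99 x the per-image maximum;
    under ``percentile`` it is the 99th percentile of the considered pixels.
    All-zero images are returned unchanged.  Idempotent.
    """
    if image.normalized:
        raise ValueError("remove_hotspots expects an un-normalized image")
    x = image.pixels
    considered = x if mask is None else x[mask]
    if considered.size == 0 or considered.max() == 0:
        return replace(image, pixels=x.copy())
    t = _hotspot_threshold(considered, quantile_mode)
    return replace(image, pixels=np.minimum(x, t))


def normalize_image(image: IonImage, mask: np.ndarray | None = None) -> IonImage:
    """Min-max scale an ion image to [0, 1]: (x - min) / (max - min).

    Min and max are taken over acquired pixels when a mask is given;
    off-mask pixels are set to zero.  A constant image maps to all zeros
    (with a warning) so blank channels do not abort batch preprocessing.
    """
    x = image.pixels
    if not np.any(np.isfinite(x)):
        raise ValueError("normalize_image requires at least one finite pixel")
    considered = x if mask is None else x[mask]
    lo = float(considered.min())
    hi = float(considered.max())
    if hi == lo:
        warnings.warn(
            f"constant ion image (m/z {image.mz:g}) normalized to all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
        out = np.clip(out, 0.0, 1.0)
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return replace(image, pixels=out, normalized=True)


def preprocess_cube(cube: IonImageCube, quantile_mode: str = "fraction-of-max") -> IonImageCube:
    """Hotspot-truncate and min-max normalize every channel independently."""
    if cube.normalized:
        return cube
    out = np.empty_like(cube.intensities)
    mask = cube.pixel_mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for h in range(cube.n_channels):
            img = cube.channel(h)
            img = remove_hotspots(img, quantile_mode=quantile_mode, mask=mask)
            img = normalize_image(img, mask=mask)
            out[:, :, h] = img.pixels
    return IonImageCube(
        intensities=out,
        mz_values=cube.mz_values.copy(),
        pixel_mask=mask.copy(),
        normalized=True,
    )
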