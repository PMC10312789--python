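"""Synthetic XLFM image formation.

A Fourier light-field microscope (XLFM) places a lenslet array in a Fourier
plane so that each lenslet images the sample from a slightly different angle;
a single camera exposure therefore contains one sub-image ("view") per
lenslet.  The forward model is linear: each depth plane of the sample volume
is convolved with that depth's 2D PSF and the contributions are summed.
Depth information is encoded as a per-lens, depth-dependent parallax shift of
the lenslet spots.

This module provides the simulator side of that model (lenslet PSF synthesis
and forward projection), plus the measurement-side preparation used to build
flow conditions: detecting lens centers from the PSF and cropping per-lens
views out of the raw image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from numpy.fft import irfft2, rfft2
from skimage.feature import peak_local_max

from .errors import DetectionError, GeometryError, InputError, ShapeError

__all__ = [
    "Volume",
    "LFImage",
    "PSFStack",
    "LensLayout",
    "ViewStack",
    "synthesize_psf",
    "forward_project",
    "back_project",
    "detect_lens_centers",
    "crop_views",
    "embed_lateral",
    "crop_lateral",
    "desk_layout",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_nonneg_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    if np.any(a < 0):
        raise InputError(f"{name} contains negative values")


@dataclass
class Volume:
    """Non-negative 3D intensity grid with axes (depth, height, width)."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)  # (dz, dy, dx), metadata only

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ShapeError(f"Volume must be 3D, got shape {self.data.shape}")
        _check_nonneg_finite(self.data, "Volume")

    @property
    def depth(self) -> int:
        return self.data.shape[0]


@dataclass
class LFImage:
    """A single raw light-field camera image (2D, non-negative)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(f"LFImage must be 2D, got shape {self.data.shape}")
        _check_nonneg_finite(self.data, "LFImage")


@dataclass
class PSFStack:
    """One 2D PSF plane per depth; defines the linear forward operator."""

    planes: np.ndarray

    def __post_init__(self):
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ShapeError(f"PSFStack must be 3D, got shape {self.planes.shape}")
        _check_nonneg_finite(self.planes, "PSFStack")

    @property
    def depth(self) -> int:
        return self.planes.shape[0]

    @property
    def image_shape(self) -> tuple:
        return self.planes.shape[1:]


@dataclass
class LensLayout:
    """Ordered lens centers (row, col) and the square view crop size."""

    centers: list
    crop_size: int

    def __post_init__(self):
        self.centers = [(int(r), int(c)) for r, c in self.centers]
        self.crop_size = int(self.crop_size)
        if len(self.centers) < 1:
            raise GeometryError("LensLayout needs at least one center")
        if self.crop_size < 1:
            raise GeometryError("crop_size must be >= 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"centers": [list(c) for c in self.centers],
                       "crop_size": self.crop_size}, fh)

    @classmethod
    def from_json(cls, path) -> "LensLayout":
        with open(path) as fh:
            d = json.load(fh)
        return cls(centers=[tuple(c) for c in d["centers"]], crop_size=d["crop_size"])


@dataclass
class ViewStack:
    """Per-lens crops stacked along the first axis: (n_views, crop, crop)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"ViewStack must be 3D, got shape {self.data.shape}")
        _check_nonneg_finite(self.data, "ViewStack")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# PSF synthesis
# ---------------------------------------------------------------------------


def synthesize_psf(layout: LensLayout, depth_count: int, spot_sigma: float,
                   parallax_per_depth: float, image_shape: tuple) -> PSFStack:
    """Build a lenslet PSF stack of Gaussian spots with depth parallax.

    Each lens contributes one Gaussian spot of width ``spot_sigma`` (pixels)
    per depth plane.  The spot for lens k at depth z is displaced from the
    lens center along the direction (lens center - image center) by
    ``parallax_per_depth * (z - z_central)`` pixels, with
    ``z_central = (depth_count - 1) / 2`` — each lens acts as a camera with a
    distinct viewing angle.  Every plane is normalized to unit sum.
    """
    if depth_count < 1:
        raise GeometryError("depth_count must be >= 1")
    if spot_sigma <= 0:
        raise GeometryError("spot_sigma must be > 0")
    h, w = int(image_shape[0]), int(image_shape[1])
    for r, c in layout.centers:
        if not (0 <= r < h and 0 <= c < w):
            raise GeometryError(f"lens center {(r, c)} outside image shape {(h, w)}")

    z_central = (depth_count - 1) / 2.0
    img_center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    planes = np.zeros((depth_count, h, w))
    for z in range(depth_count):
        shift_mag = parallax_per_depth * (z - z_central)
        for r, c in layout.centers:
            d = np.array([r, c], dtype=float) - img_center
            norm = np.hypot(*d)
            u = d / norm if norm > 0 else np.zeros(2)
            pr, pc = np.array([r, c], dtype=float) + shift_mag * u
            planes[z] += np.exp(-((rows - pr) ** 2 + (cols - pc) ** 2)
                                / (2.0 * spot_sigma**2))
        s = planes[z].sum()
        if s <= 0:
            raise GeometryError(f"PSF plane {z} has zero energy (spots off image)")
        planes[z] /= s
    return PSFStack(planes)


# ---------------------------------------------------------------------------
# forward / adjoint projection
# ---------------------------------------------------------------------------
#
# Same-size linear 2D convolution per depth via zero-padded FFTs.  The kernel
# origin is fixed at pixel (H//2, W//2) of each PSF plane, so a unit voxel at
# the lateral center reproduces the PSF plane exactly.  The adjoint is the
# matching correlation; the pair passes an exact dot-product test.


def _operator_spectra(psf: PSFStack) -> np.ndarray:
    d, h, w = psf.planes.shape
    kp = np.zeros((d, 2 * h, 2 * w))
    kp[:, :h, :w] = psf.planes
    kp = np.roll(kp, (-(h // 2), -(w // 2)), axis=(1, 2))
    return rfft2(kp, axes=(1, 2))


def _check_compat(vol_shape: tuple, psf: PSFStack) -> None:
    if vol_shape[0] != psf.depth:
        raise ShapeError(
            f"volume depth {vol_shape[0]} != PSF depth {psf.depth}")
    if vol_shape[1:] != psf.image_shape:
        raise ShapeError(
            f"volume lateral shape {vol_shape[1:]} != PSF plane shape "
            f"{psf.image_shape}; embed the volume first (embed_lateral)")


def forward_project(volume: Volume, psf: PSFStack) -> LFImage:
    """Project a volume to a light-field image: sum_z conv2d(V[z], PSF[z])."""
    _check_compat(volume.data.shape, psf)
    d, h, w = volume.data.shape
    spectra = _operator_spectra(psf)
    vf = rfft2(volume.data, s=(2 * h, 2 * w), axes=(1, 2))
    full = irfft2(vf * spectra, s=(2 * h, 2 * w), axes=(1, 2))
    out = full[:, :h, :w].sum(axis=0)
    return LFImage(np.maximum(out, 0.0))


def back_project(image, psf: PSFStack) -> np.ndarray:
    """Adjoint of :func:`forward_project` (correlation per depth).

    Accepts an :class:`LFImage` or a plain 2D array (the adjoint is applied
    to ratio images inside Richardson–Lucy, which need not be non-negative).
    Returns a raw ndarray of shape (depth, H, W).
    """
    img = image.data if isinstance(image, LFImage) else np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError(f"image must be 2D, got {img.shape}")
    if img.shape != psf.image_shape:
        raise ShapeError(f"image shape {img.shape} != PSF plane shape {psf.image_shape}")
    h, w = img.shape
    spectra = _operator_spectra(psf)
    uf = rfft2(img, s=(2 * h, 2 * w))
    full = irfft2(uf[None] * np.conj(spectra), s=(2 * h, 2 * w), axes=(1, 2))
    return full[:, :h, :w]


def embed_lateral(volume: Volume, image_shape: tuple) -> Volume:
    """Zero-pad a volume laterally to the (centered) camera field of view."""
    d, h, w = volume.data.shape
    hh, ww = image_shape
    if h > hh or w > ww:
        raise ShapeError("volume larger than target lateral shape")
    out = np.zeros((d, hh, ww))
    r0, c0 = (hh - h) // 2, (ww - w) // 2
    out[:, r0:r0 + h, c0:c0 + w] = volume.data
    return Volume(out, voxel_size=volume.voxel_size)


def crop_lateral(volume: Volume, lateral_shape: tuple) -> Volume:
    """Inverse of :func:`embed_lateral`: take the centered lateral window."""
    d, h, w = volume.data.shape
    hh, ww = lateral_shape
    if hh > h or ww > w:
        raise ShapeError("crop larger than volume")
    r0, c0 = (h - hh) // 2, (w - ww) // 2
    return Volume(volume.data[:, r0:r0 + hh, c0:c0 + ww], voxel_size=volume.voxel_size)


# ---------------------------------------------------------------------------
# lens detection and view cropping
# ---------------------------------------------------------------------------


def detect_lens_centers(psf: PSFStack, expected_count: int,
                        min_separation: float) -> LensLayout:
    """Find lens centers as the strongest local maxima of the central plane.

    Returns the ``expected_count`` highest peaks of the central depth plane
    that are pairwise separated by at least ``min_separation`` pixels
    (Euclidean).  Ordering is deterministic: descending peak value with a
    row-major tie-break.
    """
    if psf.depth < 1:
        raise ShapeError("empty PSF stack")
    if expected_count < 1:
        raise DetectionError("expected_count must be >= 1")
    plane = psf.planes[(psf.depth - 1) // 2]
    if plane.max() == plane.min():
        raise DetectionError("central PSF plane is flat: found 0 peaks, "
                             f"expected {expected_count}")
    cand = peak_local_max(plane, min_distance=1, exclude_border=False)
    order = np.lexsort((cand[:, 1], cand[:, 0], -plane[cand[:, 0], cand[:, 1]]))
    cand = cand[order]
    chosen: list = []
    for r, c in cand:
        if all(np.hypot(r - cr, c - cc) >= min_separation for cr, cc in chosen):
            chosen.append((int(r), int(c)))
        if len(chosen) == expected_count:
            break
    if len(chosen) < expected_count:
        raise DetectionError(
            f"found {len(chosen)} qualifying peaks, expected {expected_count}")
    # crop_size is unknown at detection time; default to the pitch estimate
    pitch = int(round(min_separation)) if len(chosen) > 1 else plane.shape[0]
    return LensLayout(centers=chosen, crop_size=max(pitch, 1))


def crop_views(image: LFImage, layout: LensLayout) -> ViewStack:
    """Cut a crop_size x crop_size window around each lens center.

    The window is centered so that the lens center lands at index
    ``crop_size // 2`` of each view; pixels falling outside the image are
    zero-filled.  Stacking order follows the layout order.
    """
    if len(layout.centers) < 1:
        raise GeometryError("empty lens layout")
    cs = layout.crop_size
    half = cs // 2
    padded = np.pad(image.data, cs)
    views = np.empty((len(layout.centers), cs, cs))
    for k, (r, c) in enumerate(layout.centers):
        r0 = r - half + cs
        c0 = c - half + cs
        views[k] = padded[r0:r0 + cs, c0:c0 + cs]
    return ViewStack(views)


def desk_layout(image_size: int = 96, grid: int = 3, crop_size: int = 32) -> LensLayout:
    """The desk-scale default geometry: a grid x grid lenslet array."""
    pitch = image_size // grid
    offs = [pitch // 2 + i * pitch for i in range(grid)]
    centers = [(r, c) for r in offs for c in offs]
    return LensLayout(centers=centers, crop_size=crop_size)


# ---------------------------------------------------------------------------
# TIFF I/O (page axis = depth / view)
# ---------------------------------------------------------------------------


def write_tiff(path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_volume(path) -> Volume:
    return Volume(tifffile.imread(path))


def read_image(path) -> LFImage:
    return LFImage(tifffile.imread(path))


def read_psf(path) -> PSFStack:
    return PSFStack(tifffile.imread(path))
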