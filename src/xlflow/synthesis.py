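"""Seeded synthetic data standing in for light-field calcium-imaging studies.

The in-distribution family emulates an immobilized animal expressing a
nuclear-localized calcium indicator after background removal: a handful of
compact blob "neurons" at fixed positions, whose brightness follows a
calcium-like time course (sparse Bernoulli onsets convolved with an
exponential decay, floored at a small fraction of a unit transient — the
baseline-subtracted activity returns to exactly zero between events).
Volumes are otherwise exactly zero, matching the sparsity of
background-removed recordings.

Two out-of-distribution families mirror the reference protocol: bead
phantoms (isolated point sources at dilution-series densities) and
"non-sparse" frames (an in-distribution scene plus a smooth autofluorescence
background covering most of the volume, emulating unprocessed raw data).
All randomness is owned by a single seed per generator call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DataError, ShapeError
from .model import ConditionSet
from .optics import (LensLayout, LFImage, PSFStack, ViewStack, Volume, crop_views,
                     embed_lateral, forward_project)

__all__ = [
    "SyntheticScene",
    "DatasetBundle",
    "generate_scene",
    "render_dataset",
    "generate_ood",
    "conditions_with_prior",
    "nonzero_fraction",
]

# Amplitudes below this fraction of a unit transient are treated as baseline.
AMPLITUDE_FLOOR = 0.05
# Blob support is truncated at this many sigmas (compact support).
BLOB_TRUNCATION = 2.5


@dataclass
class SyntheticScene:
    """Fixed neuron positions with per-neuron amplitude time series."""

    positions: np.ndarray      # (K, 3) integer voxel coordinates (z, y, x)
    amplitudes: np.ndarray     # (K, T) non-negative
    sigma: float               # blob width in voxels
    shape: tuple               # (D, H, W)
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def frames(self) -> int:
        return self.amplitudes.shape[1]


@dataclass
class DatasetBundle:
    """Per-frame ground truth, measurement, and conditions, plus the split."""

    volumes: list              # Volume, model scale (D, H, W)
    images: list               # LFImage, camera scale
    conditions: list           # ConditionSet (shared prior)
    prior: Volume              # mean of the training-split volumes
    split: dict                # {"train": [...], "val": [...], "test": [...]}
    layout: LensLayout

    def pairs(self, part: str):
        return [(self.volumes[i], self.conditions[i]) for i in self.split[part]]

    def frames(self, part: str):
        return [i for i in self.split[part]]


def generate_scene(n_neurons: int = 6, shape: tuple = (16, 32, 32),
                   frames: int = 36, event_rate: float = 0.1,
                   decay: float = 3.0, sigma: float = 1.2,
                   seed: int = 0) -> SyntheticScene:
    """Place neurons and synthesize calcium-like amplitude series.

    Positions are uniform over the volume (one-voxel margin) with pairwise
    separation >= 2*sigma; amplitudes are Bernoulli(event_rate) onset
    indicators convolved with exp(-t/decay) and floored at
    ``AMPLITUDE_FLOOR``.  Fully reproducible from the seed.
    """
    if min(n_neurons, frames) < 1 or min(shape) < 1:
        raise DataError("all counts must be positive")
    rng = np.random.default_rng(seed)
    d, h, w = shape
    min_sep = 2.0 * sigma
    positions = []
    tries = 0
    while len(positions) < n_neurons:
        tries += 1
        if tries > 1000 * n_neurons:
            raise DataError(
                f"could not place {n_neurons} neurons at separation "
                f"{min_sep:.2f} in shape {shape}")
        p = np.array([rng.integers(1, d - 1), rng.integers(1, h - 1),
                      rng.integers(1, w - 1)])
        if all(np.linalg.norm(p - q) >= min_sep for q in positions):
            positions.append(p)
    onsets = (rng.random((n_neurons, frames)) < event_rate).astype(float)
    t = np.arange(frames, dtype=float)
    kernel = np.zeros(frames)
    kernel[0] = 1.0
    if decay > 0:
        kernel = np.exp(-t / decay)
    amplitudes = np.stack([np.convolve(o, kernel)[:frames] for o in onsets])
    amplitudes[amplitudes < AMPLITUDE_FLOOR] = 0.0
    return SyntheticScene(positions=np.array(positions, dtype=int),
                          amplitudes=amplitudes, sigma=float(sigma),
                          shape=tuple(shape), seed=int(seed))


def _blob_kernel(sigma: float):
    """Offsets and weights of a truncated isotropic Gaussian blob."""
    r = int(np.ceil(BLOB_TRUNCATION * sigma))
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    rr2 = zz**2 + yy**2 + xx**2
    weights = np.exp(-rr2 / (2.0 * sigma**2))
    weights[rr2 > (BLOB_TRUNCATION * sigma) ** 2] = 0.0
    return ax, weights


def _paste_blob(volume: np.ndarray, pos, amplitude: float, ax, weights) -> None:
    d, h, w = volume.shape
    r = len(ax) // 2
    z0, y0, x0 = (int(pos[0]) - r, int(pos[1]) - r, int(pos[2]) - r)
    zs = slice(max(z0, 0), min(z0 + len(ax), d))
    ys = slice(max(y0, 0), min(y0 + len(ax), h))
    xs = slice(max(x0, 0), min(x0 + len(ax), w))
    kz = slice(zs.start - z0, zs.stop - z0)
    ky = slice(ys.start - y0, ys.stop - y0)
    kx = slice(xs.start - x0, xs.stop - x0)
    volume[zs, ys, xs] += amplitude * weights[kz, ky, kx]


def scene_volume(scene: SyntheticScene, frame: int) -> Volume:
    """Render one ground-truth frame: sum of amplitude-weighted blobs."""
    v = np.zeros(scene.shape)
    ax, weights = _blob_kernel(scene.sigma)
    for k in range(scene.n_neurons):
        amp = scene.amplitudes[k, frame]
        if amp > 0:
            _paste_blob(v, scene.positions[k], amp, ax, weights)
    return Volume(v)


def _bundle_from_volumes(volumes, psf: PSFStack, layout: LensLayout,
                         noise: str, noise_scale: float, seed: int,
                         n_train: int) -> DatasetBundle:
    rng = np.random.default_rng(seed)
    images, views_list = [], []
    for vol in volumes:
        img = forward_project(embed_lateral(vol, psf.image_shape), psf)
        if noise == "poisson":
            counts = rng.poisson(img.data * noise_scale)
            img = LFImage(counts / noise_scale)
        elif noise != "none":
            raise ValueError(f"unknown noise model '{noise}'")
        images.append(img)
        views_list.append(crop_views(img, layout))
    n = len(volumes)
    n_train = min(n_train, n)
    rest = list(range(n_train, n))
    split = {"train": list(range(n_train)),
             "val": rest[: len(rest) // 2],
             "test": rest[len(rest) // 2:]}
    if split["train"]:
        prior = Volume(np.mean([volumes[i].data for i in split["train"]], axis=0))
    else:
        prior = Volume(np.zeros_like(volumes[0].data))
    conds = [ConditionSet(views=v, prior=prior) for v in views_list]
    return DatasetBundle(volumes=list(volumes), images=images, conditions=conds,
                         prior=prior, split=split, layout=layout)


def render_dataset(scene: SyntheticScene, psf: PSFStack, layout: LensLayout,
                   noise: str = "none", noise_scale: float = 1000.0,
                   n_train: int = 10) -> DatasetBundle:
    """Render a scene through the optics into a ready-to-train bundle.

    The first ``n_train`` frames form the training split (the reference
    protocol trains on 10 image-volume pairs); the remainder is halved into
    validation and test.  The prior is the voxelwise mean of the training
    volumes and is shared by every frame's condition set.
    """
    if psf.depth != scene.shape[0]:
        raise ShapeError(f"PSF depth {psf.depth} != scene depth {scene.shape[0]}")
    volumes = [scene_volume(scene, t) for t in range(scene.frames)]
    return _bundle_from_volumes(volumes, psf, layout, noise, noise_scale,
                                scene.seed + 101, n_train)


def generate_ood(kind: str, psf: PSFStack, layout: LensLayout,
                 shape: tuple = (16, 32, 32), n_frames: int = 10,
                 density=1e-3, bead_sigma: float = 0.7,
                 background_strength: float = 0.3, seed: int = 0,
                 n_train: int = 10) -> DatasetBundle:
    """Generate an out-of-distribution family rendered through the same optics.

    kind='beads': isolated point-like sources; per-frame counts are
    Poisson(density * n_voxels).  ``density`` may be a scalar or a sequence
    cycled across frames (a dilution series spanning orders of magnitude).
    kind='non_sparse': an in-distribution-like scene plus a smooth
    low-frequency background occupying well over half the voxels.
    """
    rng = np.random.default_rng(seed)
    d, h, w = shape
    if kind == "beads":
        densities = np.atleast_1d(np.asarray(density, dtype=float))
        ax, weights = _blob_kernel(bead_sigma)
        volumes = []
        for t in range(n_frames):
            v = np.zeros(shape)
            dens = densities[t % len(densities)]
            count = rng.poisson(dens * v.size)
            for _ in range(count):
                pos = (rng.integers(0, d), rng.integers(0, h), rng.integers(0, w))
                _paste_blob(v, pos, float(rng.uniform(0.5, 1.5)), ax, weights)
            volumes.append(Volume(v))
    elif kind == "non_sparse":
        scene = generate_scene(shape=shape, frames=n_frames,
                               seed=int(rng.integers(2**31)))
        volumes = []
        for t in range(n_frames):
            base = scene_volume(scene, t).data
            bg = gaussian_filter(rng.random(shape), sigma=4.0)
            bg = np.maximum(bg - np.quantile(bg, 0.3), 0.0)
            peak = max(base.max(), 1.0)
            bg *= background_strength * peak / max(bg.max(), 1e-12)
            volumes.append(Volume(base + bg))
    else:
        raise ValueError(f"unknown OOD kind '{kind}'")
    return _bundle_from_volumes(volumes, psf, layout, "none", 1.0,
                                seed + 202, n_train)


def conditions_with_prior(bundle: DatasetBundle, prior: Volume):
    """Condition sets of a bundle rebuilt around a model's training prior.

    Used when scoring novel data against an already-trained model: the
    views come from the novel images, but the structural prior is the one
    the model was trained with.
    """
    return [ConditionSet(views=c.views, prior=prior) for c in bundle.conditions]


def nonzero_fraction(volume: Volume, rel_threshold: float = 1e-3) -> float:
    """Fraction of voxels above ``rel_threshold`` of the volume maximum."""
    v = volume.data
    m = v.max()
    if m <= 0:
        return 0.0
    return float(np.mean(v > rel_threshold * m))
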