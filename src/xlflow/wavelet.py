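"""Orthonormal Haar transform along the axial (depth) dimension only.

The hierarchical model halves volumes axially while keeping full lateral
resolution.  For consecutive depth slices (a, b) the transform emits an
approximation slice (a + b)/sqrt(2) and a detail slice (a - b)/sqrt(2).
With the 1/sqrt(2) normalization the transform is orthonormal: it conserves
energy (Parseval) and its Jacobian determinant is exactly 1, so it adds
nothing to the model log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError

__all__ = [
    "HaarPair",
    "haar_axial_forward",
    "haar_axial_inverse",
    "haar_pyramid",
    "validate_pyramid_depth",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class HaarPair:
    """Axial approximation (depth D/2) and congruent detail coefficients."""

    approximation: np.ndarray
    details: np.ndarray

    def __post_init__(self):
        self.approximation = np.asarray(self.approximation, dtype=np.float64)
        self.details = np.asarray(self.details, dtype=np.float64)
        if self.approximation.shape != self.details.shape:
            raise ShapeError(
                f"approximation shape {self.approximation.shape} != "
                f"details shape {self.details.shape}")


def haar_axial_forward(volume: np.ndarray) -> HaarPair:
    """One axial Haar analysis step; requires an even number of depth slices."""
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise ShapeError(f"expected a 3D grid, got shape {v.shape}")
    if v.shape[0] % 2 != 0:
        raise ShapeError(f"depth {v.shape[0]} is odd; no implicit padding")
    a = v[0::2]
    b = v[1::2]
    return HaarPair((a + b) / _SQRT2, (a - b) / _SQRT2)


def haar_axial_inverse(pair: HaarPair) -> np.ndarray:
    """Exact inverse: interleave (A+D)/sqrt(2) and (A-D)/sqrt(2) axially."""
    a = (pair.approximation + pair.details) / _SQRT2
    b = (pair.approximation - pair.details) / _SQRT2
    d, h, w = a.shape
    out = np.empty((2 * d, h, w))
    out[0::2] = a
    out[1::2] = b
    return out


def validate_pyramid_depth(depth: int, n_levels: int) -> None:
    """An n-level pyramid repeatedly halves the depth: 2**n must divide it."""
    if depth % (2 ** n_levels) != 0:
        raise ShapeError(
            f"depth {depth} not divisible by 2**{n_levels}; cannot build "
            f"a {n_levels}-level pyramid")


def haar_pyramid(volume: np.ndarray, n_levels: int):
    """Repeated axial analysis on the approximation.

    Returns ``(approximations, details)`` where ``approximations[i]`` is the
    volume downsampled i times (``approximations[0]`` is the input) and
    ``details[i]`` the detail coefficients produced at level i, so the input
    is recovered by folding ``details`` back in reverse order.
    """
    v = np.asarray(volume, dtype=np.float64)
    validate_pyramid_depth(v.shape[0], n_levels)
    approximations = [v]
    details = []
    for _ in range(n_levels):
        pair = haar_axial_forward(approximations[-1])
        approximations.append(pair.approximation)
        details.append(pair.details)
    return approximations, details
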