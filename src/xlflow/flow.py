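"""Conditional normalizing-flow core.

The flow maps detail coefficients x to a latent z that is standard normal
under the model, conditioned on features c derived from the measurement.
Exact likelihoods follow from the change of variables
``p_X(x|c) = p_Z(f(x,c)) * |det J|``.

Blocks are conditional affine transforms (CAT): elementwise
``y = s(c) * x + t(c)`` where scale and translation are produced by a small
convolutional subnet of the condition only, so the Jacobian is diagonal and
``log|det J| = sum log s(c)``.  Invertibility of the scale is guaranteed by a
soft-clamped exponential ``s = exp(clamp * tanh(raw / clamp))``, bounding s
in [e^-clamp, e^clamp].  Fixed seeded channel permutations separate the
blocks; they are volume-preserving (log-det 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Conv2d, Tensor, concat, gather_channels
from .errors import ShapeError

__all__ = [
    "LatentCode",
    "CATBlock",
    "ConditionalFlow",
    "cat_block",
    "flow_apply",
    "nll",
    "normalized_nll",
    "sample_latent",
    "LOG_2PI",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LatentCode:
    """Latent grid plus the accumulated log|det J| of the map producing it."""

    z: np.ndarray
    log_det: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if not np.all(np.isfinite(self.z)) or not np.isfinite(self.log_det):
            raise ShapeError("LatentCode must be finite")


class CATBlock:
    """One conditional affine transform block.

    The subnet is two same-padding convolutions (condition channels ->
    ``hidden`` -> 2 * x_channels) with a leaky-ReLU between; its output is
    split channelwise into a raw scale and a conditional mean m.  The block
    applies ``y = s(c) * (x - m(c))``, i.e. translation ``t = -s * m``: the
    modal (z = 0) inverse is ``m(c)`` independent of the scale, which keeps
    likelihood sharpening from dragging the spatial prediction.  The final
    layer is zero-initialized so a fresh block is the identity map.
    """

    def __init__(self, x_channels: int, cond_channels: int, hidden: int = 14,
                 kernel: int = 3, clamp: float = 2.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.x_channels = x_channels
        self.clamp = float(clamp)
        self.conv1 = Conv2d(cond_channels, hidden, kernel, rng)
        self.conv2 = Conv2d(hidden, 2 * x_channels, kernel, rng, zero_init=True)

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def affine(self, feat: Tensor):
        """Compute (s, t, log_s) from condition features (N, Cc, H, W)."""
        h = self.conv1(feat).leaky_relu()
        raw = self.conv2(h)
        if not np.all(np.isfinite(raw.data)):
            raise FloatingPointError("CAT subnet produced non-finite output")
        nc = self.x_channels
        raw_s = gather_channels(raw, np.arange(nc))
        m = gather_channels(raw, np.arange(nc, 2 * nc))
        log_s = (raw_s * (1.0 / self.clamp)).tanh() * self.clamp
        s = log_s.exp()
        return s, (-1.0) * s * m, log_s


class ConditionalFlow:
    """A chain of CAT blocks with fixed seeded channel permutations between."""

    def __init__(self, x_channels: int, cond_channels: int, n_blocks: int = 6,
                 hidden: int = 14, kernel: int = 3, clamp: float = 2.0,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.x_channels = x_channels
        self.blocks = [CATBlock(x_channels, cond_channels, hidden, kernel, clamp, rng)
                       for _ in range(n_blocks)]
        self.perms = [rng.permutation(x_channels) for _ in range(n_blocks - 1)]
        self.inv_perms = [np.argsort(p) for p in self.perms]

    def parameters(self):
        out = []
        for b in self.blocks:
            out.extend(b.parameters())
        return out

    def affine_params(self, feat: Tensor):
        """Per-block (s, t, log_s); shared by both directions of a pass."""
        return [b.affine(feat) for b in self.blocks]

    def forward_t(self, x: Tensor, params):
        """x -> z, accumulating per-sample log-det (shape (N,))."""
        log_det = None
        for k, (s, t, log_s) in enumerate(params):
            if k > 0:
                x = gather_channels(x, self.perms[k - 1])
            x = s * x + t
            ld = log_s.sum(axis=(1, 2, 3))
            log_det = ld if log_det is None else log_det + ld
        return x, log_det

    def inverse_t(self, z: Tensor, params):
        """z -> x, the exact reverse composition; log-det is negated."""
        log_det = None
        for k in reversed(range(len(self.blocks))):
            s, t, log_s = params[k]
            z = (z - t) / s
            if k > 0:
                z = gather_channels(z, self.inv_perms[k - 1])
            ld = log_s.sum(axis=(1, 2, 3))
            log_det = ld if log_det is None else log_det + ld
        return z, (-1.0) * log_det


# ---------------------------------------------------------------------------
# array-facing operations (single sample)
# ---------------------------------------------------------------------------


def _as_batch(a: np.ndarray) -> Tensor:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 3:
        raise ShapeError(f"expected (C, H, W) grid, got shape {a.shape}")
    return Tensor(a[None])


def cat_block(block: CATBlock, x: np.ndarray, cond_features: np.ndarray,
              direction: str = "forward"):
    """Apply one CAT block to a (C, H, W) grid. Returns (grid, log_det)."""
    with _nn.no_grad():
        s, t, log_s = block.affine(_as_batch(cond_features))
        xb = _as_batch(x)
        if direction == "forward":
            y = s * xb + t
            ld = float(log_s.data.sum())
        elif direction == "inverse":
            y = (xb - t) / s
            ld = -float(log_s.data.sum())
        else:
            raise ValueError(f"unknown direction '{direction}'")
    return y.data[0], ld


def flow_apply(flow: ConditionalFlow, data: np.ndarray, cond_features: np.ndarray,
               direction: str = "forward"):
    """Apply the composed flow to a (C, H, W) grid.

    Forward returns a :class:`LatentCode`; inverse returns the data grid.
    """
    with _nn.no_grad():
        params = flow.affine_params(_as_batch(cond_features))
        if direction == "forward":
            z, ld = flow.forward_t(_as_batch(data), params)
            return LatentCode(z=z.data[0], log_det=float(ld.data[0]))
        if direction == "inverse":
            x, _ = flow.inverse_t(_as_batch(data), params)
            return x.data[0]
    raise ValueError(f"unknown direction '{direction}'")


# ---------------------------------------------------------------------------
# likelihood and sampling
# ---------------------------------------------------------------------------


def nll(code: LatentCode, rho: float = 0.0, param_sq_norm: float = 0.0) -> float:
    """Training-form negative log-likelihood of one sample.

    ``||z||^2 / 2 - log|det J| + rho * ||Theta||^2`` — the additive-constant
    form minimized during training.
    """
    return float(0.5 * np.sum(code.z**2) - code.log_det + rho * param_sq_norm)


def normalized_nll(code: LatentCode) -> float:
    """Per-element NLL including the Gaussian constant.

    ``(||z||^2/2 - log|det J|) / numel + log(2 pi)/2`` — comparable across
    levels and volume sizes, the quantity thresholded for OOD detection.
    """
    n = code.z.size
    return float((0.5 * np.sum(code.z**2) - code.log_det) / n + 0.5 * LOG_2PI)


def sample_latent(shape, temperature: float, seed: int | None = None) -> np.ndarray:
    """Draw z = T * eps with eps ~ N(0, 1) under a seeded generator.

    T = 0 returns exact zeros without consuming randomness (the modal
    sample); identical (seed, shape, T) yield identical draws.
    """
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0, got {temperature}")
    if temperature == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    return temperature * rng.standard_normal(shape)
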