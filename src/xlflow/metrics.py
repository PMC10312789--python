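"""Reconstruction-quality metrics: PSNR, masked MAPE, neuron-trace PCC.

Three complementary views of quality for sparse neural-activity volumes:
overall fidelity (PSNR against the reference peak), on-support relative
error (MAPE over the jointly non-zero voxels — the volumes are mostly
zeros, so an unmasked mean would be dominated by background), and temporal
faithfulness (Pearson correlation of per-neuron activity traces, with
neuron positions always taken from the reference so every method is
measured at the same sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .errors import ShapeError
from .optics import Volume

__all__ = [
    "NeuronTrace",
    "psnr",
    "mape_masked",
    "extract_traces",
    "trace_pcc",
]

PSNR_CAP_DB = 100.0


@dataclass
class NeuronTrace:
    """A neuron site (z, y, x) and its activity time series."""

    position: tuple
    activity: np.ndarray


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def psnr(reference, estimate) -> float:
    """Peak signal-to-noise ratio in dB, peak = max of the reference.

    ``10 log10(peak^2 / MSE)``, capped at 100 dB (returned exactly for a
    perfect match).
    """
    ref, est = _as_array(reference), _as_array(estimate)
    if ref.shape != est.shape:
        raise ShapeError(f"shape mismatch {ref.shape} vs {est.shape}")
    if not np.any(ref):
        raise ValueError("all-zero reference has no peak")
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(ref.max() ** 2 / mse), PSNR_CAP_DB))


def mape_masked(reference, estimate, eps_rel: float = 1e-6) -> float:
    """Mean absolute percentage error over the jointly non-zero voxels.

    The mask is the intersection of the non-zero supports of reference and
    estimate, so the measure reads as the mean relative error on the signal
    both volumes agree exists; voxels the estimate misses entirely are left
    to PSNR.  The denominator is guarded by ``eps_rel`` times the reference
    maximum.  Returns a fraction (0.1011 means 10.11%); an empty mask gives 0.
    """
    ref, est = _as_array(reference), _as_array(estimate)
    if ref.shape != est.shape:
        raise ShapeError(f"shape mismatch {ref.shape} vs {est.shape}")
    mask = (ref != 0) & (est != 0)
    if not np.any(mask):
        return 0.0
    eps = eps_rel * np.abs(ref).max()
    denom = np.maximum(np.abs(ref[mask]), eps)
    return float(np.mean(np.abs(ref[mask] - est[mask]) / denom))


def _box_mean(stack: np.ndarray, pos, radius: int) -> np.ndarray:
    d, h, w = stack.shape[1:]
    z, y, x = (int(p) for p in pos)
    zs = slice(max(z - radius, 0), min(z + radius + 1, d))
    ys = slice(max(y - radius, 0), min(y + radius + 1, h))
    xs = slice(max(x - radius, 0), min(x + radius + 1, w))
    return stack[:, zs, ys, xs].mean(axis=(1, 2, 3))


def extract_traces(volumes, n_neurons: int, radius: int = 2):
    """Locate active neurons and read out their activity over time.

    Neuron sites are the ``n_neurons`` strongest local maxima of the
    per-voxel temporal variance, greedily accepted in deterministic order
    (descending variance, row-major tie-break) subject to pairwise Euclidean
    separation > ``radius``.  Activity is the mean intensity in a
    ``radius``-box around the site per frame.  Returns fewer traces (with a
    warning) if the variance volume does not support the request.
    """
    stack = np.stack([_as_array(v) for v in volumes])
    if stack.shape[0] < 1:
        raise ValueError("empty sequence")
    var = stack.var(axis=0)
    if not np.any(var > 0):
        if n_neurons > 0:
            warnings.warn("variance volume is zero: found 0 of "
                          f"{n_neurons} requested neurons")
        return []
    cand = peak_local_max(var, min_distance=1, exclude_border=False)
    vals = var[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -vals))
    chosen = []
    for p in cand[order]:
        if all(np.linalg.norm(p - np.array(q)) > radius for q in chosen):
            chosen.append(tuple(int(c) for c in p))
        if len(chosen) == n_neurons:
            break
    if len(chosen) < n_neurons:
        warnings.warn(f"found {len(chosen)} of {n_neurons} requested neurons")
    return [NeuronTrace(position=p, activity=_box_mean(stack, p, radius))
            for p in chosen]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; zero-variance traces contribute 0 by convention."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(np.sum(a**2)), np.sqrt(np.sum(b**2))
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def trace_pcc(ref_traces, est_volumes, radius: int = 2) -> float:
    """Mean Pearson correlation of reference traces vs the estimate sequence.

    For each reference neuron the estimate's activity is sampled at the same
    position (same box radius) and correlated against the reference trace.
    """
    stack = np.stack([_as_array(v) for v in est_volumes])
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames for a correlation")
    rs = []
    for tr in ref_traces:
        est_activity = _box_mean(stack, tr.position, radius)
        rs.append(_pearson(np.asarray(tr.activity, dtype=float), est_activity))
    return float(np.mean(rs)) if rs else 0.0
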