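"""The conditional wavelet-flow hierarchy.

A full-resolution volume V0 is decomposed by repeated axial Haar steps into
approximations V1..Vn and detail grids D0..D(n-1).  Each level i owns a
conditional normalizing flow modelling p(Di | Omega_i(C)), where the
condition set C is the stack of per-lens views of the raw light-field image
plus a structural prior volume (mean of the training volumes), and Omega_i
is a small convolutional conditioning network trained jointly with the
level's flow.  The lowest resolution Vn is regressed deterministically from
C by an encoder-decoder (the LR-NN), replacing an unconditional base flow.

The model factorizes the likelihood as
``log p(V0) = log p(Vn) + sum_i log p(Di | Omega_i(C))``
so each level trains independently.  Reconstruction runs the hierarchy in
reverse: predict Vn from C, then for each level sample a latent (scaled by
the temperature; zero temperature gives the deterministic modal volume),
invert the flow into detail coefficients, and Haar-upsample.

Per-level training minimizes the exact-likelihood loss plus a spatial
anchor: ``NLL(f(Di, Omega_i(C)))`` plus ``alpha * ||Vi - Vi_tilde||^2``
where ``Vi_tilde`` is the level's own reconstruction from z = 0.  The
spatial term keeps generated volumes geometrically faithful rather than
merely distribution-matched.  Depth slices are carried in the channel
dimension throughout, so all convolutions are 2D and lateral resolution is
never reduced by the pyramid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from ._nn import Adam, Conv2d, Tensor, avg_pool2d, concat, upsample_nearest2d
from .errors import ConfigError, DataError, ShapeError
from .flow import ConditionalFlow, LatentCode, LOG_2PI, normalized_nll, sample_latent
from .optics import ViewStack, Volume
from .wavelet import HaarPair, haar_axial_forward, haar_axial_inverse, haar_pyramid, \
    validate_pyramid_depth

__all__ = [
    "ConditionSet",
    "CWFAConfig",
    "TrainConfig",
    "CWFLevel",
    "CWFAModel",
    "build_model",
    "condition_features",
    "train_level",
    "train_lr_nn",
    "reconstruct",
    "log_likelihood",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)


@dataclass
class ConditionSet:
    """The flow conditions C: per-lens view stack + structural prior volume."""

    views: ViewStack
    prior: Volume


@dataclass
class CWFAConfig:
    """Architecture hyperparameters (desk-scale defaults).

    depth/lateral: full-resolution volume shape (depth, lateral, lateral);
    n_views must match the lens layout; n_levels wavelet-flow levels each
    with blocks_per_level CAT blocks of hidden_channels-wide subnets.
    """

    depth: int = 16
    lateral: int = 32
    n_views: int = 9
    n_levels: int = 2
    blocks_per_level: int = 6
    hidden_channels: int = 14
    cond_channels: int = 14
    kernel: int = 3
    clamp: float = 2.0
    lr_nn_width: int = 24
    seed: int = 0

    def detail_channels(self, level: int) -> int:
        return self.depth // (2 ** (level + 1))


@dataclass
class TrainConfig:
    """Optimization settings for per-level training.

    alpha weights the spatial (volume-anchoring) term relative to the NLL;
    rho is the Gaussian parameter-posterior strength, implemented as
    decoupled weight decay.  Each level trains in two phases: a spatial-only
    warm-up (``warmup_epochs`` at ``learning_rate``) that fits the modal
    detail prediction, then the full joint objective (``epochs_per_level``
    at ``joint_learning_rate``, default learning_rate / 3).  One epoch is
    one full-batch gradient step.

    noise_std is seeded dequantization noise added (on the normalized
    detail scale) to the likelihood term's input only: with a handful of
    noiseless training volumes the flow would otherwise sharpen its scales
    without bound on memorized residuals, and held-out likelihoods would
    be badly miscalibrated.  The noise caps attainable sharpness at
    ~1/noise_std, exactly as a real sensor's noise floor would.

    When validation pairs are supplied to the training functions, the
    warm-up phase keeps the parameters with the best validation spatial
    error, checked every ``val_check_every`` epochs (the LR-NN likewise
    keeps its best-validation-MSE parameters).  Model selection on a
    held-out split; the test split is never touched during training.
    """

    alpha: float = 0.48
    rho: float = 1e-4
    epochs_per_level: int = 200
    warmup_epochs: int = 600
    epochs_lr_nn: int = 400
    learning_rate: float = 3e-3
    joint_learning_rate: float | None = None
    noise_std: float = 0.1
    val_check_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.rho < 0:
            raise ConfigError("alpha and rho must be >= 0")
        if self.joint_learning_rate is None:
            self.joint_learning_rate = self.learning_rate / 3.0


class OmegaNet:
    """Conditioning network: (views + reduced prior) -> feature grid.

    A small encoder-decoder with a skip connection: the pooled path widens
    the receptive field enough to gather the parallax-shifted evidence each
    lens contributes, which a plain two-convolution stack cannot reach.
    """

    def __init__(self, in_channels: int, hidden: int, out_channels: int,
                 kernel: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, hidden, kernel, rng)
        self.down = Conv2d(hidden, 2 * hidden, kernel, rng)
        self.conv2 = Conv2d(3 * hidden, out_channels, kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h1 = self.conv1(x).leaky_relu()
        h2 = self.down(avg_pool2d(h1)).leaky_relu()
        up = upsample_nearest2d(h2)
        return self.conv2(concat([up, h1], axis=1))

    def parameters(self):
        return (self.conv1.parameters() + self.down.parameters()
                + self.conv2.parameters())


class LRNN:
    """Small encoder-decoder with a skip connection: C -> Vn."""

    def __init__(self, in_channels: int, width: int, out_channels: int,
                 kernel: int, rng: np.random.Generator):
        self.enc1 = Conv2d(in_channels, width, kernel, rng)
        self.enc2 = Conv2d(width, 2 * width, kernel, rng)
        self.dec1 = Conv2d(3 * width, width, kernel, rng)
        self.dec2 = Conv2d(width, out_channels, kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h1 = self.enc1(x).leaky_relu()
        h2 = self.enc2(avg_pool2d(h1)).leaky_relu()
        up = upsample_nearest2d(h2)
        h3 = self.dec1(concat([up, h1], axis=1)).leaky_relu()
        return self.dec2(h3)

    def parameters(self):
        return (self.enc1.parameters() + self.enc2.parameters()
                + self.dec1.parameters() + self.dec2.parameters())


@dataclass
class CWFLevel:
    index: int
    flow: ConditionalFlow
    omega: OmegaNet

    def parameters(self):
        return self.flow.parameters() + self.omega.parameters()


class CWFAModel:
    def __init__(self, config: CWFAConfig, levels, lr_nn: LRNN):
        self.config = config
        self.levels = levels
        self.lr_nn = lr_nn
        # per-level detail normalization, set from the training data the
        # first time a level trains (0 = unset; intensities then pass
        # through unscaled).  Part of the checkpoint: likelihoods are only
        # comparable under a fixed normalization.
        self.data_scales = np.zeros(config.n_levels)

    def level_scale(self, level: int) -> float:
        s = float(self.data_scales[level])
        return s if s > 0 else 1.0

    # -- parameters --------------------------------------------------------
    def level_parameters(self, i: int):
        return self.levels[i].parameters()

    def parameters(self):
        out = []
        for lv in self.levels:
            out.extend(lv.parameters())
        out.extend(self.lr_nn.parameters())
        return out

    def parameter_counts(self) -> dict:
        counts = {}
        for lv in self.levels:
            counts[f"level{lv.index}_flow"] = sum(p.size for p in lv.flow.parameters())
            counts[f"level{lv.index}_omega"] = sum(p.size for p in lv.omega.parameters())
        counts["lr_nn"] = sum(p.size for p in self.lr_nn.parameters())
        counts["total"] = sum(counts.values())
        return counts

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for lv in self.levels:
            for k, b in enumerate(lv.flow.blocks):
                pre = f"level{lv.index}.block{k}"
                state[f"{pre}.conv1.w"] = b.conv1.w.data
                state[f"{pre}.conv1.b"] = b.conv1.b.data
                state[f"{pre}.conv2.w"] = b.conv2.w.data
                state[f"{pre}.conv2.b"] = b.conv2.b.data
            for name, layer in (("conv1", lv.omega.conv1), ("down", lv.omega.down),
                                ("conv2", lv.omega.conv2)):
                state[f"level{lv.index}.omega.{name}.w"] = layer.w.data
                state[f"level{lv.index}.omega.{name}.b"] = layer.b.data
        for name in ("enc1", "enc2", "dec1", "dec2"):
            layer = getattr(self.lr_nn, name)
            state[f"lr_nn.{name}.w"] = layer.w.data
            state[f"lr_nn.{name}.b"] = layer.b.data
        state["data_scales"] = self.data_scales
        return state

    def load_state_dict(self, state: dict) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ConfigError("checkpoint keys do not match the architecture")
        for lv in self.levels:
            for k, b in enumerate(lv.flow.blocks):
                pre = f"level{lv.index}.block{k}"
                b.conv1.w.data = np.array(state[f"{pre}.conv1.w"], dtype=np.float64)
                b.conv1.b.data = np.array(state[f"{pre}.conv1.b"], dtype=np.float64)
                b.conv2.w.data = np.array(state[f"{pre}.conv2.w"], dtype=np.float64)
                b.conv2.b.data = np.array(state[f"{pre}.conv2.b"], dtype=np.float64)
            for name, layer in (("conv1", lv.omega.conv1), ("down", lv.omega.down),
                                ("conv2", lv.omega.conv2)):
                layer.w.data = np.array(state[f"level{lv.index}.omega.{name}.w"], dtype=np.float64)
                layer.b.data = np.array(state[f"level{lv.index}.omega.{name}.b"], dtype=np.float64)
        for name in ("enc1", "enc2", "dec1", "dec2"):
            layer = getattr(self.lr_nn, name)
            layer.w.data = np.array(state[f"lr_nn.{name}.w"], dtype=np.float64)
            layer.b.data = np.array(state[f"lr_nn.{name}.b"], dtype=np.float64)
        self.data_scales = np.array(state["data_scales"], dtype=np.float64)

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "parameters.npz", **self.state_dict())
        manifest = {"config": asdict(self.config),
                    "parameter_counts": self.parameter_counts(),
                    "format": "xlflow-checkpoint-v1"}
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "CWFAModel":
        from pathlib import Path

        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        model = build_model(CWFAConfig(**manifest["config"]))
        with np.load(directory / "parameters.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def build_model(config: CWFAConfig) -> CWFAModel:
    """Deterministically construct a model from its configuration."""
    try:
        validate_pyramid_depth(config.depth, config.n_levels)
    except ShapeError as exc:
        raise ConfigError(str(exc)) from exc
    if config.lateral % 2 != 0:
        raise ConfigError("lateral size must be even (LR-NN pools once)")
    rng = np.random.default_rng(config.seed)
    levels = []
    for i in range(config.n_levels):
        d_i = config.detail_channels(i)
        flow = ConditionalFlow(
            x_channels=d_i, cond_channels=config.cond_channels,
            n_blocks=config.blocks_per_level, hidden=config.hidden_channels,
            kernel=config.kernel, clamp=config.clamp,
            seed=int(rng.integers(2**31)))
        omega = OmegaNet(
            in_channels=config.n_views + 2 * d_i, hidden=config.hidden_channels,
            out_channels=config.cond_channels, kernel=config.kernel, rng=rng)
        levels.append(CWFLevel(index=i, flow=flow, omega=omega))
    lr_nn = LRNN(in_channels=config.n_views + config.depth,
                 width=config.lr_nn_width,
                 out_channels=config.depth // 2**config.n_levels,
                 kernel=config.kernel, rng=rng)
    return CWFAModel(config, levels, lr_nn)


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------


def _validate_cond(model: CWFAModel, cond: ConditionSet) -> None:
    cfg = model.config
    if cond.views.n_views != cfg.n_views:
        raise ConfigError(f"expected {cfg.n_views} views, got {cond.views.n_views}")
    if cond.views.data.shape[1:] != (cfg.lateral, cfg.lateral):
        raise ConfigError(f"views must be {cfg.lateral}x{cfg.lateral}, "
                          f"got {cond.views.data.shape[1:]}")
    if cond.prior.data.shape != (cfg.depth, cfg.lateral, cfg.lateral):
        raise ConfigError(f"prior shape {cond.prior.data.shape} != "
                          f"{(cfg.depth, cfg.lateral, cfg.lateral)}")


def _reduce_prior(prior: np.ndarray, times: int) -> np.ndarray:
    """Repeated Haar approximations bring the prior to a level's scale."""
    red = prior
    for _ in range(times):
        red = haar_axial_forward(red).approximation
    return red


def _prior_pathway(prior: np.ndarray, level: int) -> tuple:
    """The prior at level scale: its approximation and its detail template.

    Both grids live at the level's detail shape (depth / 2**(level+1)).
    The prior's own Haar details are the structural template the flow
    modulates — axial derivatives of the static anatomy — so they are
    offered to Omega alongside the approximation.
    """
    red = _reduce_prior(prior, level)
    pair = haar_axial_forward(red)
    return pair.approximation, pair.details


def _omega_input(model: CWFAModel, conds, level: int) -> np.ndarray:
    """Stack (views, prior approximation, prior details) channelwise."""
    batch = []
    for cond in conds:
        _validate_cond(model, cond)
        approx, det = _prior_pathway(cond.prior.data, level)
        batch.append(np.concatenate([cond.views.data, approx, det], axis=0))
    return np.stack(batch)


def _lr_input(model: CWFAModel, conds) -> np.ndarray:
    batch = []
    for cond in conds:
        _validate_cond(model, cond)
        batch.append(np.concatenate([cond.views.data, cond.prior.data], axis=0))
    return np.stack(batch)


def condition_features(model: CWFAModel, cond: ConditionSet, level: int) -> np.ndarray:
    """Omega_i feature grid for one condition set (channels, H, W)."""
    if not (0 <= level < len(model.levels)):
        raise ConfigError(f"level {level} out of range")
    with _nn.no_grad():
        feat = model.levels[level].omega(Tensor(_omega_input(model, [cond], level)))
    return feat.data[0]


def _haar_inverse_t(approx: Tensor, details: Tensor) -> Tensor:
    """Differentiable axial Haar synthesis with depth in the channel axis."""
    a = (approx + details) * _INV_SQRT2
    b = (approx - details) * _INV_SQRT2
    n, d, h, w = a.shape
    a5 = a.reshape(n, d, 1, h, w)
    b5 = b.reshape(n, d, 1, h, w)
    return concat([a5, b5], axis=2).reshape(n, 2 * d, h, w)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _pyramid_batches(model: CWFAModel, pairs, level: int):
    """Stacked (D_i, V_i, V_{i+1}) arrays from the Haar pyramids of V0."""
    cfg = model.config
    d_list, vi_list, vip1_list = [], [], []
    for vol, _ in pairs:
        if vol.data.shape != (cfg.depth, cfg.lateral, cfg.lateral):
            raise ShapeError(f"volume shape {vol.data.shape} != "
                             f"{(cfg.depth, cfg.lateral, cfg.lateral)}")
        approx, details = haar_pyramid(vol.data, level + 1)
        d_list.append(details[level])
        vi_list.append(approx[level])
        vip1_list.append(approx[level + 1])
    return np.stack(d_list), np.stack(vi_list), np.stack(vip1_list)


def train_level(model: CWFAModel, level: int, pairs, cfg: TrainConfig,
                val_pairs=None) -> dict:
    """Train level ``level``'s flow and Omega network on (V0, C) pairs.

    Full-batch optimization (deterministic for fixed seed and data); only
    the given level's parameters are updated.  Detail coefficients are
    normalized by the level's data scale (training-set RMS, stored on the
    model and accounted for exactly in the likelihood); the spatial term is
    evaluated on the same normalized intensity scale, where the loss weight
    alpha is meaningful.  Training runs a spatial-only warm-up followed by
    the joint NLL + alpha * spatial objective; if ``val_pairs`` are given,
    the warm-up restores the parameters with the lowest validation spatial
    error.  Returns a history dict with per-epoch per-element NLL, spatial
    MSE, and the combined loss.
    """
    if not pairs:
        raise DataError("empty training dataset")
    lv = model.levels[level]
    x_np, vi_np, vip1_np = _pyramid_batches(model, pairs, level)
    if not model.data_scales[level] > 0:
        model.data_scales[level] = float(np.sqrt(np.mean(x_np**2))) or 1.0
    sigma = model.level_scale(level)
    inp_np = _omega_input(model, [c for _, c in pairs], level)
    n, numel = x_np.shape[0], x_np[0].size
    x_t = Tensor(x_np / sigma)
    vi_t = Tensor(vi_np / sigma)
    vip1_t = Tensor(vip1_np / sigma)
    inp_t = Tensor(inp_np)
    zeros_t = Tensor(np.zeros_like(x_np))
    noise_rng = np.random.default_rng(cfg.seed + 7919 * (level + 1))
    history = {"nll": [], "spatial": [], "loss": []}

    if val_pairs:
        xv_np, viv_np, vip1v_np = _pyramid_batches(model, val_pairs, level)
        inp_v = Tensor(_omega_input(model, [c for _, c in val_pairs], level))
        viv_t = Tensor(viv_np / sigma)
        vip1v_t = Tensor(vip1v_np / sigma)
        zeros_v = Tensor(np.zeros_like(xv_np))

    def nll_of(params):
        x_in = x_t
        if cfg.noise_std > 0:
            x_in = x_t + Tensor(cfg.noise_std
                                * noise_rng.standard_normal(x_np.shape))
        z, log_det = lv.flow.forward_t(x_in, params)
        return ((z * z).sum() * 0.5 - log_det.sum()) * (1.0 / (n * numel)) \
            + 0.5 * LOG_2PI + np.log(sigma)

    def spatial_of(params, vi, vip1, zeros):
        d_tilde, _ = lv.flow.inverse_t(zeros, params)
        v_tilde = _haar_inverse_t(vip1, d_tilde)
        return ((vi - v_tilde) * (vi - v_tilde)).mean()

    def val_spatial():
        with _nn.no_grad():
            params = lv.flow.affine_params(lv.omega(inp_v))
            return float(spatial_of(params, viv_t, vip1v_t, zeros_v).data)

    def snapshot():
        return [p.data.copy() for p in lv.parameters()]

    phases = [(cfg.warmup_epochs, cfg.learning_rate, False),
              (cfg.epochs_per_level, cfg.joint_learning_rate, True)]
    for epochs, lr, joint in phases:
        opt = Adam(lv.parameters(), lr=lr, weight_decay=cfg.rho)
        track_val = bool(val_pairs) and not joint and cfg.val_check_every > 0
        best, best_params = np.inf, None
        for epoch in range(epochs):
            feat = lv.omega(inp_t)
            params = lv.flow.affine_params(feat)
            spatial = spatial_of(params, vi_t, vip1_t, zeros_t)
            if joint:
                nll_term = nll_of(params)
                loss = nll_term + cfg.alpha * spatial
            else:
                loss = spatial
                with _nn.no_grad():
                    nll_term = nll_of(params)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history["nll"].append(float(nll_term.data))
            history["spatial"].append(float(spatial.data))
            history["loss"].append(float(nll_term.data)
                                   + cfg.alpha * float(spatial.data))
            if track_val and (epoch + 1) % cfg.val_check_every == 0:
                vm = val_spatial()
                if vm < best:
                    best, best_params = vm, snapshot()
        if best_params is not None:
            for p, d in zip(lv.parameters(), best_params):
                p.data = d
    return history


def train_lr_nn(model: CWFAModel, pairs, cfg: TrainConfig, val_pairs=None) -> dict:
    """Supervised regression of the LR-NN onto the lowest-resolution volumes.

    With ``val_pairs``, keeps the parameters with the best validation MSE
    (checked every ``cfg.val_check_every`` epochs).
    """
    if not pairs:
        raise DataError("empty training dataset")
    cfgm = model.config

    def batch(prs):
        targets = [haar_pyramid(vol.data, cfgm.n_levels)[0][-1] for vol, _ in prs]
        return (Tensor(_lr_input(model, [c for _, c in prs])),
                Tensor(np.stack(targets)))

    inp_t, y_t = batch(pairs)
    if val_pairs:
        inp_v, y_v = batch(val_pairs)
    opt = Adam(model.lr_nn.parameters(), lr=cfg.learning_rate, weight_decay=cfg.rho)
    history = {"mse": []}
    best, best_params = np.inf, None
    for epoch in range(cfg.epochs_lr_nn):
        pred = model.lr_nn(inp_t)
        loss = ((pred - y_t) * (pred - y_t)).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        history["mse"].append(float(loss.data))
        if val_pairs and cfg.val_check_every > 0 \
                and (epoch + 1) % cfg.val_check_every == 0:
            with _nn.no_grad():
                pv = model.lr_nn(inp_v)
                vm = float(((pv - y_v) * (pv - y_v)).mean().data)
            if vm < best:
                best = vm
                best_params = [p.data.copy() for p in model.lr_nn.parameters()]
    if best_params is not None:
        for p, d in zip(model.lr_nn.parameters(), best_params):
            p.data = d
    return history


def train(model: CWFAModel, pairs, cfg: TrainConfig, val_pairs=None) -> dict:
    """Train the LR-NN and every level (each independently)."""
    histories = {"lr_nn": train_lr_nn(model, pairs, cfg, val_pairs)}
    for i in range(len(model.levels)):
        histories[f"level{i}"] = train_level(model, i, pairs, cfg, val_pairs)
    return histories


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def reconstruct(model: CWFAModel, cond: ConditionSet, temperature: float = 0.0,
                seed: int | None = None, zero_details: bool = False):
    """Run the hierarchy in reverse to reconstruct a volume from conditions.

    Returns ``(volume, info)`` where info carries the intermediate volumes
    per level and the latent draws used.  Temperature 0 draws no randomness
    and is fully deterministic; ``zero_details=True`` skips the flows
    entirely (the LR-only baseline, upsampled with zero detail).
    """
    cfg = model.config
    _validate_cond(model, cond)
    with _nn.no_grad():
        v = model.lr_nn(Tensor(_lr_input(model, [cond]))).data[0]
        info = {"v_tilde": {cfg.n_levels: v}, "z": {}}
        for i in reversed(range(cfg.n_levels)):
            lv = model.levels[i]
            d_i = cfg.detail_channels(i)
            shape = (d_i, cfg.lateral, cfg.lateral)
            if zero_details:
                d_tilde = np.zeros(shape)
                info["z"][i] = None
            else:
                lseed = None if seed is None else seed + i
                z = sample_latent(shape, temperature, lseed)
                feat = lv.omega(Tensor(_omega_input(model, [cond], i)))
                params = lv.flow.affine_params(feat)
                d_tilde = model.level_scale(i) \
                    * lv.flow.inverse_t(Tensor(z[None]), params)[0].data[0]
                info["z"][i] = z
            v = haar_axial_inverse(HaarPair(v, d_tilde))
            info["v_tilde"][i] = v
    return Volume(np.maximum(v, 0.0)), info


def log_likelihood(model: CWFAModel, volume: Volume, cond: ConditionSet) -> dict:
    """Exact per-level log-likelihood of a volume under the model.

    Returns per-level latent codes, per-level log p(Di | Omega_i(C)), their
    sum, and the LR-NN's negative-MSE surrogate for log p(Vn).  The
    deterministic LR-NN defines no density, so its surrogate is reported
    separately and the flow-level sum is what OOD monitoring uses.
    """
    cfg = model.config
    _validate_cond(model, cond)
    if volume.data.shape != (cfg.depth, cfg.lateral, cfg.lateral):
        raise ShapeError(f"volume shape {volume.data.shape} != "
                         f"{(cfg.depth, cfg.lateral, cfg.lateral)}")
    approx, details = haar_pyramid(volume.data, cfg.n_levels)
    codes, log_probs, norm_nlls = [], [], []
    with _nn.no_grad():
        for i, lv in enumerate(model.levels):
            sigma = model.level_scale(i)
            feat = lv.omega(Tensor(_omega_input(model, [cond], i)))
            params = lv.flow.affine_params(feat)
            z, ld = lv.flow.forward_t(Tensor(details[i][None] / sigma), params)
            n = details[i].size
            # normalization contributes -n*log(sigma) to log|det J|
            code = LatentCode(z=z.data[0],
                              log_det=float(ld.data[0]) - n * np.log(sigma))
            codes.append(code)
            log_probs.append(float(-0.5 * np.sum(code.z**2) + code.log_det
                                   - 0.5 * n * LOG_2PI))
            norm_nlls.append(normalized_nll(code))
        vn_pred = model.lr_nn(Tensor(_lr_input(model, [cond]))).data[0]
    lr_surrogate = float(-np.mean((vn_pred - approx[-1]) ** 2))
    return {
        "codes": codes,
        "per_level_log_prob": log_probs,
        "flow_log_prob": float(sum(log_probs)),
        "per_level_nll": norm_nlls,
        "lr_nn_surrogate": lr_surrogate,
        "total_log_prob": float(sum(log_probs)) + lr_surrogate,
    }
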