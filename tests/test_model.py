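"""Hierarchy construction, per-level training contracts, reconstruction."""

import hashlib

import numpy as np
import pytest

import xlflow.model as model_mod
from xlflow._nn import Tensor
from xlflow.errors import ConfigError, DataError
from xlflow.model import (ConditionSet, CWFAConfig, TrainConfig, build_model,
                          condition_features, log_likelihood, reconstruct,
                          train_level, train_lr_nn)
from xlflow.optics import ViewStack, Volume
from xlflow.wavelet import haar_axial_forward, haar_pyramid


def _tiny_config(**kw):
    base = dict(depth=8, lateral=8, n_views=4, n_levels=2, blocks_per_level=2,
                hidden_channels=6, cond_channels=5, lr_nn_width=6, seed=0)
    base.update(kw)
    return CWFAConfig(**base)


def _cond(cfg, rng, scale=1.0):
    views = ViewStack(scale * rng.random((cfg.n_views, cfg.lateral, cfg.lateral)))
    prior = Volume(scale * rng.random((cfg.depth, cfg.lateral, cfg.lateral)))
    return ConditionSet(views=views, prior=prior)


def _pair(cfg, rng, scale=1.0):
    vol = Volume(scale * rng.random((cfg.depth, cfg.lateral, cfg.lateral)))
    return vol, _cond(cfg, rng, scale)


def _checksum(state):
    h = hashlib.sha256()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k]).tobytes())
    return h.hexdigest()


class TestBuildModel:
    def test_single_level_depth_two(self):
        cfg = _tiny_config(depth=2, n_levels=1)
        m = build_model(cfg)
        assert len(m.levels) == 1
        assert cfg.detail_channels(0) == 1  # LR output depth 1

    def test_desk_shape_chain(self):
        cfg = CWFAConfig()  # depth 16, n=2
        assert cfg.detail_channels(0) == 8
        assert cfg.detail_channels(1) == 4
        m = build_model(cfg)
        assert m.lr_nn.dec2.w.data.shape[0] == 4  # V_2 depth

    def test_indivisible_depth_rejected(self):
        with pytest.raises(ConfigError):
            build_model(_tiny_config(depth=12, n_levels=3))

    def test_identical_seed_identical_parameters(self):
        a = build_model(_tiny_config(seed=5))
        b = build_model(_tiny_config(seed=5))
        assert _checksum(a.state_dict()) == _checksum(b.state_dict())
        c = build_model(_tiny_config(seed=6))
        assert _checksum(c.state_dict()) != _checksum(a.state_dict())

    def test_parameter_counts_reported(self):
        counts = build_model(_tiny_config()).parameter_counts()
        assert counts["total"] == sum(v for k, v in counts.items() if k != "total")
        assert all(v > 0 for v in counts.values())


class TestConditionFeatures:
    def test_zero_conditions_give_finite_features(self):
        cfg = _tiny_config()
        m = build_model(cfg)
        cond = ConditionSet(
            views=ViewStack(np.zeros((cfg.n_views, cfg.lateral, cfg.lateral))),
            prior=Volume(np.zeros((cfg.depth, cfg.lateral, cfg.lateral))))
        for lv in range(cfg.n_levels):
            feat = condition_features(m, cond, lv)
            assert np.all(np.isfinite(feat))

    def test_prior_pathway_matches_repeated_haar(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        cond = _cond(cfg, rng)
        for lv in range(cfg.n_levels):
            red_lv = cond.prior.data
            for _ in range(lv):
                red_lv = haar_axial_forward(red_lv).approximation
            pair = haar_axial_forward(red_lv)
            d_i = cfg.detail_channels(lv)
            inp = model_mod._omega_input(m, [cond], lv)[0]
            assert np.allclose(inp[cfg.n_views:cfg.n_views + d_i],
                               pair.approximation)
            assert np.allclose(inp[cfg.n_views + d_i:], pair.details)

    def test_view_perturbation_changes_features(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        cond = _cond(cfg, rng)
        base = condition_features(m, cond, 0)
        views2 = cond.views.data.copy()
        views2[1, 3, 3] += 1e-3
        cond2 = ConditionSet(views=ViewStack(views2), prior=cond.prior)
        pert = condition_features(m, cond2, 0)
        sens = np.abs(pert - base).max() / 1e-3
        assert sens > 1e-4  # finite-difference sensitivity is non-zero

    def test_bad_level_rejected(self, rng):
        cfg = _tiny_config()
        with pytest.raises(ConfigError):
            condition_features(build_model(cfg), _cond(cfg, rng), 7)


class TestTrainLevel:
    def test_overfit_single_sample_nll_decreases(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        pairs = [_pair(cfg, rng)]
        hist = train_level(m, 0, pairs, TrainConfig(
            alpha=0.0, epochs_per_level=10, learning_rate=1e-2))
        assert hist["nll"][-1] < hist["nll"][0]

    def test_zero_learning_rate_constant_loss(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        hist = train_level(m, 0, [_pair(cfg, rng)], TrainConfig(
            epochs_per_level=4, learning_rate=0.0, rho=0.0, noise_std=0.0))
        assert len(set(hist["loss"])) == 1

    def test_identical_seed_identical_loss_curve(self, rng):
        cfg = _tiny_config()
        pairs = [_pair(cfg, rng) for _ in range(2)]
        h1 = train_level(build_model(cfg), 0, pairs,
                         TrainConfig(epochs_per_level=5))
        h2 = train_level(build_model(cfg), 0, pairs,
                         TrainConfig(epochs_per_level=5))
        assert h1["loss"] == h2["loss"]

    def test_only_target_level_parameters_move(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        before = {k: v.copy() for k, v in m.state_dict().items()}
        train_level(m, 1, [_pair(cfg, rng)], TrainConfig(epochs_per_level=3))
        after = m.state_dict()
        for key in before:
            if key.startswith("level1"):
                continue
            if key == "data_scales":
                assert before[key][0] == after[key][0]  # level 0 untouched
                continue
            assert np.array_equal(before[key], after[key]), key
        assert any(not np.array_equal(before[k], after[k])
                   for k in before if k.startswith("level1"))

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train_level(build_model(_tiny_config()), 0, [], TrainConfig())


class TestTrainLRNN:
    def test_overfit_one_pair_reduces_mse_tenfold(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        hist = train_lr_nn(m, [_pair(cfg, rng)], TrainConfig(
            epochs_lr_nn=200, learning_rate=1e-2))
        assert hist["mse"][-1] <= hist["mse"][0] / 10

    def test_zero_targets_shrink_output(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        vol = Volume(np.zeros((cfg.depth, cfg.lateral, cfg.lateral)))
        pairs = [(vol, _cond(cfg, rng))]
        inp = Tensor(model_mod._lr_input(m, [pairs[0][1]]))
        import xlflow._nn as _nn

        with _nn.no_grad():
            before = float(np.sum(m.lr_nn(inp).data ** 2))
        train_lr_nn(m, pairs, TrainConfig(epochs_lr_nn=100, learning_rate=1e-2))
        with _nn.no_grad():
            after = float(np.sum(m.lr_nn(inp).data ** 2))
        assert after < before

    def test_zero_learning_rate_leaves_parameters(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        before = _checksum(m.state_dict())
        train_lr_nn(m, [_pair(cfg, rng)], TrainConfig(
            epochs_lr_nn=3, learning_rate=0.0, rho=0.0))
        assert _checksum(m.state_dict()) == before


class TestReconstruct:
    def test_zero_temperature_bitwise_deterministic(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        cond = _cond(cfg, rng)
        v1, _ = reconstruct(m, cond, temperature=0.0)
        v2, _ = reconstruct(m, cond, temperature=0.0)
        assert np.array_equal(v1.data, v2.data)

    def test_haar_oracle_with_identity_flows_and_true_latents(self, rng, monkeypatch):
        # with identity flows, injecting the true detail coefficients as
        # latents must reproduce V0 exactly through the Haar chain
        cfg = _tiny_config()
        m = build_model(cfg)  # fresh blocks are identity maps
        vol, cond = _pair(cfg, rng)
        approx, details = haar_pyramid(vol.data, cfg.n_levels)

        class _TrueVn:
            def __call__(self, x):
                return Tensor(approx[-1][None])

        monkeypatch.setattr(m, "lr_nn", _TrueVn())
        # identity flow: inverse(z) applies only the inverse permutations,
        # so pre-permute the true details to cancel them exactly
        def fake_sample(shape, temperature, seed=None):
            lv = next(l for l in m.levels
                      if (cfg.detail_channels(l.index),) == (shape[0],))
            d = details[lv.index]
            for p in lv.flow.perms:
                d = d[p]
            return d

        monkeypatch.setattr(model_mod, "sample_latent", fake_sample)
        rec, _ = reconstruct(m, cond, temperature=1.0, seed=0)
        assert np.abs(rec.data - vol.data).max() < 1e-6

    def test_zero_details_baseline_duplicates_slices(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        rec, info = reconstruct(m, _cond(cfg, rng), zero_details=True)
        v1 = info["v_tilde"][0]
        assert np.allclose(v1[0::2], v1[1::2])

    def test_likelihood_factorization_is_exact_sum(self, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        vol, cond = _pair(cfg, rng)
        ll = log_likelihood(m, vol, cond)
        assert ll["flow_log_prob"] == sum(ll["per_level_log_prob"])
        assert ll["total_log_prob"] == ll["flow_log_prob"] + ll["lr_nn_surrogate"]

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = _tiny_config()
        m = build_model(cfg)
        train_lr_nn(m, [_pair(cfg, rng)], TrainConfig(epochs_lr_nn=2))
        m.save(tmp_path / "ckpt")
        m2 = model_mod.CWFAModel.load(tmp_path / "ckpt")
        assert _checksum(m.state_dict()) == _checksum(m2.state_dict())
        cond = _cond(cfg, rng)
        va, _ = reconstruct(m, cond)
        vb, _ = reconstruct(m2, cond)
        assert np.array_equal(va.data, vb.data)
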