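"""Threshold calibration against brute-force oracles; classification rules."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlflow.errors import DataError
from xlflow.flow import LOG_2PI
from xlflow.model import CWFAConfig, TrainConfig, build_model
from xlflow.ood import (LikelihoodReport, classify, finetune, likelihood_of,
                        select_threshold)
from xlflow.optics import ViewStack, Volume
from xlflow.wavelet import haar_pyramid


def _brute_force_best(scores_in, scores_out, candidates):
    """Exhaustive F1 evaluation over candidate cut points."""
    best = (-1.0, None)
    for thr in candidates:
        tp = sum(s > thr for s in scores_out)
        fp = sum(s > thr for s in scores_in)
        fn = sum(s <= thr for s in scores_out)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best[0]:
            best = (f1, thr)
    return best


def _mann_whitney_auc(scores_in, scores_out):
    u = 0.0
    for o in scores_out:
        for i in scores_in:
            u += 1.0 if o > i else (0.5 if o == i else 0.0)
    return u / (len(scores_in) * len(scores_out))


class TestSelectThreshold:
    def test_perfect_separation(self):
        thr, f1, auc = select_threshold([-2.0, -1.5, -0.5], [1.5, 2.0, 3.0])
        assert auc == 1.0
        assert f1 == 1.0
        assert -0.5 <= thr < 1.5

    def test_identical_distributions_auc_half(self):
        scores = [0.1, 0.5, 0.9, 1.3]
        _, _, auc = select_threshold(scores, list(scores))
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self):
        s_in, s_out = [1.0, 2.0, 3.0], [2.5, 3.5, 4.0]
        thr, f1, auc = select_threshold(s_in, s_out, n_grid=1000)
        candidates = np.linspace(min(s_in), max(s_out), 1000)
        bf_f1, _ = _brute_force_best(s_in, s_out, candidates)
        assert f1 == pytest.approx(bf_f1)
        assert auc == pytest.approx(_mann_whitney_auc(s_in, s_out))
        # the returned threshold achieves the optimum it reports
        tp = sum(s > thr for s in s_out)
        fp = sum(s > thr for s in s_in)
        fn = sum(s <= thr for s in s_out)
        assert 2 * tp / (2 * tp + fp + fn) == pytest.approx(f1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=8),
           st.lists(st.integers(-5, 5), min_size=1, max_size=8))
    def test_auc_equals_mann_whitney_identity(self, s_in, s_out):
        _, _, auc = select_threshold(s_in, s_out)
        assert auc == pytest.approx(_mann_whitney_auc(s_in, s_out))

    def test_empty_lists_rejected(self):
        with pytest.raises(DataError):
            select_threshold([], [1.0])
        with pytest.raises(DataError):
            select_threshold([1.0], [])


class TestClassify:
    def _report(self, score):
        return LikelihoodReport(per_level_nll=[0.0, score], total_nll=score)

    def test_boundary_is_in_distribution(self):
        assert classify(self._report(1.0), threshold=1.0, level=1).is_ood is False

    def test_epsilon_above_is_ood(self):
        assert classify(self._report(1.0 + 1e-12), 1.0, level=1).is_ood is True

    def test_monotone_in_score(self):
        decisions = [classify(self._report(s), 0.5, level=1).is_ood
                     for s in np.linspace(-1, 2, 13)]
        assert decisions == sorted(decisions)

    def test_batch_matches_elementwise(self):
        scores = [0.1, 0.6, 0.4, 0.9]
        batch = [classify(self._report(s), 0.5, level=1) for s in scores]
        assert [d.is_ood for d in batch] == [s > 0.5 for s in scores]

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            classify(self._report(0.0), 0.0, level=5)


class TestLikelihoodOf:
    def _setup(self, rng):
        cfg = CWFAConfig(depth=8, lateral=8, n_views=4, n_levels=2,
                         blocks_per_level=2, hidden_channels=6,
                         cond_channels=5, lr_nn_width=6, seed=0)
        model = build_model(cfg)
        vol = Volume(rng.random((8, 8, 8)))
        from xlflow.model import ConditionSet

        cond = ConditionSet(views=ViewStack(rng.random((4, 8, 8))),
                            prior=Volume(rng.random((8, 8, 8))))
        return cfg, model, vol, cond

    def test_deterministic(self, rng):
        _, model, vol, cond = self._setup(rng)
        r1 = likelihood_of(model, vol, cond)
        r2 = likelihood_of(model, vol, cond)
        assert r1.per_level_nll == r2.per_level_nll

    def test_identity_flow_closed_form(self, rng):
        # fresh blocks are identity: level NLL is 0.5*mean(D^2) + log(2pi)/2
        cfg, model, vol, cond = self._setup(rng)
        _, details = haar_pyramid(vol.data, cfg.n_levels)
        report = likelihood_of(model, vol, cond)
        for i, d in enumerate(details):
            expected = 0.5 * np.mean(d**2) + 0.5 * LOG_2PI
            assert report.per_level_nll[i] == pytest.approx(expected, rel=1e-12)

    def test_total_is_sum(self, rng):
        _, model, vol, cond = self._setup(rng)
        report = likelihood_of(model, vol, cond)
        assert report.total_nll == pytest.approx(sum(report.per_level_nll))


class TestFinetune:
    def _pairs(self, rng, n=2):
        from xlflow.model import ConditionSet

        cfg = CWFAConfig(depth=8, lateral=8, n_views=4, n_levels=2,
                         blocks_per_level=2, hidden_channels=6,
                         cond_channels=5, lr_nn_width=6, seed=0)
        pairs = []
        for _ in range(n):
            vol = Volume(rng.random((8, 8, 8)))
            cond = ConditionSet(views=ViewStack(rng.random((4, 8, 8))),
                                prior=Volume(rng.random((8, 8, 8))))
            pairs.append((vol, cond))
        return cfg, pairs

    def _checksum(self, model):
        h = hashlib.sha256()
        state = model.state_dict()
        for k in sorted(state):
            h.update(np.ascontiguousarray(state[k]).tobytes())
        return h.hexdigest()

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        cfg, pairs = self._pairs(rng)
        model = build_model(cfg)
        before = self._checksum(model)
        finetune(model, pairs, strategy="replace",
                 cfg=TrainConfig(epochs_per_level=0, epochs_lr_nn=0))
        assert self._checksum(model) == before

    def test_append_requires_old_pairs(self, rng):
        cfg, pairs = self._pairs(rng)
        with pytest.raises(ValueError):
            finetune(build_model(cfg), pairs, strategy="append", old_pairs=None)

    def test_empty_new_pairs_rejected(self, rng):
        cfg, _ = self._pairs(rng)
        with pytest.raises(DataError):
            finetune(build_model(cfg), [], strategy="replace")

    def test_unknown_strategy_rejected(self, rng):
        cfg, pairs = self._pairs(rng)
        with pytest.raises(ValueError):
            finetune(build_model(cfg), pairs, strategy="blend")

    def test_finetuning_reduces_nll_on_new_family(self, rng):
        cfg, pairs = self._pairs(rng, n=3)
        model = build_model(cfg)
        before = np.mean([likelihood_of(model, v, c).per_level_nll[1]
                          for v, c in pairs])
        finetune(model, pairs, strategy="replace",
                 cfg=TrainConfig(epochs_per_level=30, epochs_lr_nn=0))
        after = np.mean([likelihood_of(model, v, c).per_level_nll[1]
                         for v, c in pairs])
        assert after < before
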