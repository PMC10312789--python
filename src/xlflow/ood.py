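"""Likelihood-based out-of-distribution detection and adaptation.

A trained conditional wavelet-flow assigns every volume an exact per-level
negative log-likelihood (per element, so thresholds are comparable across
levels and volume sizes).  Novel samples whose NLL at a monitored level
exceeds a calibrated threshold are flagged as out-of-distribution; the
threshold is picked on held-in/held-out score populations by maximizing F1
over a linear grid, with the threshold-free ROC AUC reported alongside.
Once flagged, the model can be adapted by fine-tuning either on the new
data alone ("replace") or on the union of old and new pairs ("append").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DataError
from .model import (CWFAModel, ConditionSet, TrainConfig, log_likelihood,
                    train_level, train_lr_nn)
from .optics import Volume

__all__ = [
    "LikelihoodReport",
    "OODDecision",
    "DEFAULT_MONITOR_LEVEL",
    "likelihood_of",
    "select_threshold",
    "classify",
    "finetune",
]

# The second-finest flow level separated best in the reference experiments.
DEFAULT_MONITOR_LEVEL = 1


@dataclass
class LikelihoodReport:
    """Per-level normalized NLLs of one sample and their sum."""

    per_level_nll: list
    total_nll: float
    sample_id: str | None = None

    def __post_init__(self):
        if not all(np.isfinite(self.per_level_nll)) or not np.isfinite(self.total_nll):
            raise ValueError("LikelihoodReport must be finite")


@dataclass
class OODDecision:
    level_used: int
    threshold: float
    score: float
    is_ood: bool


def likelihood_of(model: CWFAModel, volume: Volume, cond: ConditionSet,
                  sample_id: str | None = None) -> LikelihoodReport:
    """Exact per-level NLL of a full-resolution volume under the model.

    Runs the Haar pyramid on the volume, pushes each detail grid through its
    level's flow in the forward direction, and reports the normalized
    per-element NLL per level.  Deterministic.
    """
    ll = log_likelihood(model, volume, cond)
    nlls = [float(v) for v in ll["per_level_nll"]]
    return LikelihoodReport(per_level_nll=nlls, total_nll=float(sum(nlls)),
                            sample_id=sample_id)


def select_threshold(scores_in, scores_out, n_grid: int = 1000):
    """Calibrate an OOD threshold from in/out score populations.

    Returns ``(threshold, f1, auc)``: AUC is threshold-free over the score
    ranking (OOD positive, higher NLL more positive); the threshold is the
    F1-maximizing value among ``n_grid`` linearly spaced candidates over the
    pooled score range (ties resolved to the lowest threshold).  A sample is
    called OOD when its score is strictly above the threshold.
    """
    scores_in = np.asarray(list(scores_in), dtype=float)
    scores_out = np.asarray(list(scores_out), dtype=float)
    if scores_in.size == 0 or scores_out.size == 0:
        raise DataError("both score lists must be non-empty")
    pooled = np.concatenate([scores_in, scores_out])
    labels = np.concatenate([np.zeros(scores_in.size), np.ones(scores_out.size)])
    auc = float(roc_auc_score(labels, pooled))
    candidates = np.linspace(pooled.min(), pooled.max(), n_grid)
    best_thr, best_f1 = candidates[0], -1.0
    for thr in candidates:
        tp = float(np.sum(scores_out > thr))
        fp = float(np.sum(scores_in > thr))
        fn = float(np.sum(scores_out <= thr))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr, best_f1, auc


def classify(report: LikelihoodReport, threshold: float,
             level: int = DEFAULT_MONITOR_LEVEL) -> OODDecision:
    """Pure threshold rule: OOD iff the monitored level's NLL > threshold."""
    if not (0 <= level < len(report.per_level_nll)):
        raise ValueError(f"level {level} out of range "
                         f"(report has {len(report.per_level_nll)} levels)")
    score = float(report.per_level_nll[level])
    return OODDecision(level_used=level, threshold=float(threshold),
                       score=score, is_ood=bool(score > threshold))


def finetune(model: CWFAModel, new_pairs, strategy: str = "replace",
             old_pairs=None, cfg: TrainConfig | None = None) -> CWFAModel:
    """Adapt a trained model to a newly detected sample family.

    strategy='replace' fine-tunes every level (and the LR-NN) on the new
    pairs only; strategy='append' fine-tunes on old + new, preserving the
    original family.  Both resume from the model's current parameters.
    """
    if not new_pairs:
        raise DataError("new_pairs must be non-empty")
    # resume near an optimum: short warm-up, gentler rate
    cfg = cfg or TrainConfig(epochs_per_level=60, epochs_lr_nn=60,
                             warmup_epochs=30, learning_rate=1e-3)
    if strategy == "replace":
        data = list(new_pairs)
    elif strategy == "append":
        if not old_pairs:
            raise ValueError("strategy='append' requires old_pairs")
        data = list(old_pairs) + list(new_pairs)
    else:
        raise ValueError(f"unknown strategy '{strategy}'")
    if cfg.epochs_lr_nn > 0:
        train_lr_nn(model, data, cfg)
    if cfg.epochs_per_level > 0:
        for i in range(len(model.levels)):
            train_level(model, i, data, cfg)
    return model
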