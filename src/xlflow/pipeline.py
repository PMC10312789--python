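"""End-to-end desk-scale study: simulate, train, evaluate, monitor, adapt.

This module wires the pieces into the reference workflow at a CPU-tractable
scale (16x32x32 volumes, a 3x3 lenslet array on a 96x96 camera, 2 wavelet
levels, 10 training pairs) so a complete study — data synthesis, training,
reconstruction quality against baselines, OOD calibration, and fine-tuning
adaptation — runs in minutes on one core.  Every stage is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import extract_traces, mape_masked, psnr, trace_pcc
from .model import (CWFAConfig, CWFAModel, TrainConfig, build_model, reconstruct,
                    train)
from .ood import (DEFAULT_MONITOR_LEVEL, likelihood_of, select_threshold)
from .optics import LensLayout, PSFStack, Volume, desk_layout, synthesize_psf
from .synthesis import (DatasetBundle, conditions_with_prior, generate_ood,
                        generate_scene, render_dataset)

__all__ = [
    "DeskStudy",
    "desk_geometry",
    "run_desk_study",
    "evaluate_reconstruction",
    "ood_study",
    "finetune_study",
]

# Desk-scale geometry constants
IMAGE_SIZE = 96
GRID = 3
CROP = 32
DEPTH = 16
SPOT_SIGMA = 1.5
PARALLAX = 1.0


def desk_geometry():
    """The default simulated microscope: layout and PSF stack."""
    layout = desk_layout(IMAGE_SIZE, GRID, CROP)
    psf = synthesize_psf(layout, DEPTH, SPOT_SIGMA, PARALLAX,
                         (IMAGE_SIZE, IMAGE_SIZE))
    return layout, psf


@dataclass
class DeskStudy:
    layout: LensLayout
    psf: PSFStack
    bundle: DatasetBundle
    model: CWFAModel
    histories: dict
    seed: int


def run_desk_study(seed: int = 0, train_cfg: TrainConfig | None = None,
                   model_cfg: CWFAConfig | None = None,
                   frames: int = 36) -> DeskStudy:
    """Simulate a dataset and train the full hierarchy on its 10-pair split."""
    layout, psf = desk_geometry()
    scene = generate_scene(shape=(DEPTH, CROP, CROP), frames=frames, seed=seed)
    bundle = render_dataset(scene, psf, layout)
    model_cfg = model_cfg or CWFAConfig(seed=seed + 1)
    train_cfg = train_cfg or TrainConfig(seed=seed + 2)
    model = build_model(model_cfg)
    histories = train(model, bundle.pairs("train"), train_cfg,
                      val_pairs=bundle.pairs("val"))
    return DeskStudy(layout=layout, psf=psf, bundle=bundle, model=model,
                     histories=histories, seed=seed)


def evaluate_reconstruction(model: CWFAModel, bundle: DatasetBundle,
                            part: str = "test", temperature: float = 0.0,
                            seed: int | None = None) -> dict:
    """Reconstruction quality on a split, with the two reference baselines.

    Reports the mean PSNR and masked MAPE of the model's reconstructions,
    of the structural prior alone, and of the LR-only pipeline (zero detail
    coefficients), plus the mean neuron-trace PCC of the reconstructed
    sequence against the ground-truth sequence.
    """
    idx = bundle.split[part]
    recons, psnrs, mapes, psnr_prior, psnr_lr = [], [], [], [], []
    for i in idx:
        gt = bundle.volumes[i]
        rec, _ = reconstruct(model, bundle.conditions[i],
                             temperature=temperature, seed=seed)
        lr_only, _ = reconstruct(model, bundle.conditions[i], zero_details=True)
        recons.append(rec)
        psnrs.append(psnr(gt, rec))
        mapes.append(mape_masked(gt, rec))
        psnr_prior.append(psnr(gt, bundle.prior))
        psnr_lr.append(psnr(gt, Volume(np.maximum(lr_only.data, 0.0))))
    gt_seq = [bundle.volumes[i] for i in idx]
    traces = extract_traces(gt_seq, n_neurons=6)
    pcc = trace_pcc(traces, recons) if len(idx) >= 2 and traces else float("nan")
    return {
        "frames": list(idx),
        "psnr_db": float(np.mean(psnrs)),
        "mape": float(np.mean(mapes)),
        "prior_psnr_db": float(np.mean(psnr_prior)),
        "lr_only_psnr_db": float(np.mean(psnr_lr)),
        "trace_pcc": pcc,
        "per_frame_psnr_db": [float(p) for p in psnrs],
        "per_frame_mape": [float(m) for m in mapes],
    }


def _scores(model: CWFAModel, volumes, conds, level: int):
    return [likelihood_of(model, v, c).per_level_nll[level]
            for v, c in zip(volumes, conds)]


def ood_study(study: DeskStudy, seed: int = 0,
              level: int = DEFAULT_MONITOR_LEVEL, n_frames: int = 10) -> dict:
    """Score in-distribution frames against bead and non-sparse phantoms.

    In-distribution scores pool the training and held-out frames (the
    calibration population mixes both, as in the reference workflow); OOD
    scores come from bead phantoms at a three-decade dilution series and
    from non-sparse frames, all conditioned on the model's training prior.
    """
    model, bundle = study.model, study.bundle
    beads = generate_ood("beads", study.psf, study.layout,
                         shape=(DEPTH, CROP, CROP), n_frames=n_frames,
                         density=[1e-4, 1e-3, 1e-2], seed=seed + 11)
    nonsparse = generate_ood("non_sparse", study.psf, study.layout,
                             shape=(DEPTH, CROP, CROP), n_frames=n_frames,
                             seed=seed + 12)
    n_levels = len(model.levels)
    per_level = {}
    for lv in range(n_levels):
        idx_in = bundle.split["train"] + bundle.split["val"] + bundle.split["test"]
        s_in = _scores(model, [bundle.volumes[i] for i in idx_in],
                       [bundle.conditions[i] for i in idx_in], lv)
        s_beads = _scores(model, beads.volumes,
                          conditions_with_prior(beads, bundle.prior), lv)
        s_ns = _scores(model, nonsparse.volumes,
                       conditions_with_prior(nonsparse, bundle.prior), lv)
        per_level[lv] = {"in": s_in, "beads": s_beads, "non_sparse": s_ns}
    s = per_level[level]
    threshold, f1, auc = select_threshold(s["in"], s["beads"] + s["non_sparse"])
    return {
        "level": level,
        "per_level_scores": per_level,
        "threshold": float(threshold),
        "f1": float(f1),
        "auc": float(auc),
        "beads_bundle": beads,
        "non_sparse_bundle": nonsparse,
    }


def finetune_study(study: DeskStudy, seed: int = 0,
                   level: int = DEFAULT_MONITOR_LEVEL,
                   epochs: int = 60) -> dict:
    """Adaptation to a shifted family (a new specimen) by both strategies.

    Simulates a genetically identical but different individual (same
    statistics, new neuron positions), measures its monitored-level NLL and
    reconstruction PSNR before adaptation, then fine-tunes a copy of the
    model per strategy and re-measures.  'replace' trains on the new 10
    pairs only; 'append' on old+new and additionally reports how well the
    original family is preserved.
    """
    from .ood import finetune

    base_state = study.model.state_dict()
    shifted_scene = generate_scene(shape=(DEPTH, CROP, CROP), frames=20,
                                   seed=seed + 21)
    shifted = render_dataset(shifted_scene, study.psf, study.layout)
    cfg = TrainConfig(epochs_per_level=epochs, epochs_lr_nn=epochs,
                      warmup_epochs=epochs // 2, learning_rate=1e-3,
                      seed=seed + 22)

    def measure(model):
        nll = float(np.mean(_scores(model, shifted.volumes, shifted.conditions,
                                    level)))
        rec = evaluate_reconstruction(model, shifted, part="test")
        orig = evaluate_reconstruction(model, study.bundle, part="test")
        return nll, rec["psnr_db"], orig["psnr_db"]

    pre_nll, pre_psnr, pre_orig_psnr = measure(study.model)
    out = {"pre": {"nll": pre_nll, "psnr_db": pre_psnr,
                   "orig_psnr_db": pre_orig_psnr}}
    for strategy in ("replace", "append"):
        model = build_model(study.model.config)
        model.load_state_dict(base_state)
        finetune(model, shifted.pairs("train"), strategy=strategy,
                 old_pairs=study.bundle.pairs("train"), cfg=cfg)
        nll, psnr_db, orig_psnr = measure(model)
        out[strategy] = {"nll": nll, "psnr_db": psnr_db,
                         "orig_psnr_db": orig_psnr}
    study.model.load_state_dict(base_state)
    return out
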