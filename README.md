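# xlflow

Conditional wavelet-flow 3D reconstruction for Fourier light-field
microscopy (XLFM), with exact-likelihood out-of-distribution monitoring.

## The problem

An XLFM records a full 3D fluorescent volume in a single camera exposure:
a lenslet array in a Fourier plane forms one perspective view per lens on
one image.  Recovering the volume is an inverse problem traditionally
solved by Richardson–Lucy (RL) deconvolution — accurate but minutes per
frame, which forfeits the microscope's speed advantage for live imaging of
neural activity.  Plain neural-network reconstructors are fast but give no
warning when a sample falls outside what they were trained on, which makes
them risky for biomedical use.

`xlflow` implements a hierarchy of conditional normalizing flows that
reconstructs sparse activity volumes from a single light-field image and,
because the flow's likelihood is exact, can *monitor its own competence*:
samples whose negative log-likelihood exceeds a calibrated threshold are
flagged as out-of-distribution, after which the model can be fine-tuned on
the new sample family in minutes.  The package is aimed at computational
imaging and systems-neuroscience researchers who want the whole workflow —
simulator, RL gold standard, flow training, quality metrics, OOD
calibration, adaptation — runnable and testable at desk scale on a laptop
CPU.

## The model

Volumes are halved axially by an orthonormal Haar transform, level by
level: `V_i -> (V_{i+1}, D_i)` with approximation `(a+b)/√2` and detail
`(a−b)/√2` for adjacent slices.  The likelihood factorizes exactly,

    log p(V0) = log p(Vn) + Σ_i log p(D_i | Ω_i(C)),

so every level trains independently.  Conditions `C` are (1) per-lens
crops of the raw XLFM image and (2) a structural prior volume, the mean of
the training volumes.  Each level's flow is a chain of conditional affine
transform (CAT) blocks `y = s(c) ⊙ (x − m(c))` with soft-clamped scales,
separated by fixed channel permutations — exactly invertible, with
`log|det J| = Σ log s`.  The lowest resolution `V_n` is regressed by a
small deterministic encoder-decoder (LR-NN).  Reconstruction runs the
hierarchy in reverse from a temperature-scaled latent; temperature 0 gives
the deterministic modal volume, which is also the best one here.
Training minimizes the exact NLL plus `α·‖V_i − Ṽ_i‖²` (α = 0.48), the
spatial anchor that keeps generated volumes geometrically faithful.

See `docs/methods.md` for assumptions, parameters, and numerical choices.

## Worked example

```python
import numpy as np
from xlflow import (desk_geometry, generate_scene, render_dataset,
                    build_model, CWFAConfig, TrainConfig, train,
                    reconstruct, psnr, mape_masked, likelihood_of)
from xlflow.pipeline import run_desk_study, evaluate_reconstruction

study = run_desk_study(seed=1)        # simulate + train (~10 min on 1 CPU)
ev = evaluate_reconstruction(study.model, study.bundle, part="test")
print(f"reconstruction PSNR {ev['psnr_db']:.2f} dB "
      f"(prior {ev['prior_psnr_db']:.2f}, LR-only {ev['lr_only_psnr_db']:.2f})")
print(f"masked MAPE {ev['mape']:.3f}   trace PCC {ev['trace_pcc']:.3f}")
```

prints (seed 1):

```
reconstruction PSNR 33.84 dB (prior 29.99, LR-only 31.36)
masked MAPE 0.505   trace PCC 0.968
```

The trained hierarchy reconstructs held-out frames ~3.9 dB above the
structural prior and ~2.5 dB above the LR-only baseline (zero detail
coefficients), i.e. the flow levels contribute real axial detail; the
masked MAPE is the mean relative intensity error on the jointly non-zero
voxels, and the trace PCC says per-neuron activity time courses are
recovered almost perfectly.  Scoring a bead phantom through
`likelihood_of` returns per-level NLLs orders of magnitude above the
in-distribution range — the basis of the OOD monitor.

The same workflow is scriptable from the shell:

```bash
xlflow simulate dataset --out data/
xlflow train --data data/ --out model/
xlflow reconstruct --model model/ --image data/images/frame0012.tif \
    --psf data/psf.tif --prior data/prior.tif --layout data/layout.json \
    --temperature 0 --out rec.tif
xlflow metrics --ref data/volumes/frame0012.tif --est rec.tif --out m.json
```

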