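# recistnet

A 3D densely-connected convolutional network with embedded-Gaussian
non-local self-attention for predicting immunotherapy treatment response
from CT lesion volumes fused with clinical/hemato-chemical data — plus the
surrounding pipeline: RECIST 1.1 lesion handling, 16×64×64 VOI extraction,
patient-disjoint cross-validated training, and Grad-CAM saliency. A
synthetic CT-lesion cohort generator stands in for clinical data, so the
whole pipeline is runnable and testable end to end.

The network and its training loop are implemented in pure numpy (layers
with explicit forward/backward passes and an Adam optimizer), so no deep
learning framework is required.

## Layout

| Module | Contents |
| --- | --- |
| `recistnet.synthetic_cohort` | Ellipsoid lesion phantoms in CT-like volumes, class-correlated clinical vectors, cohort generation with exact class counts and patient-disjoint splits |
| `recistnet.preprocessing` | ROI → 16×64×64 VOI extraction (bi-cubic resize, zero-padded invisible slices), clinical encoding/z-scoring |
| `recistnet.recist` | RECIST 1.1 target-lesion selection (LD ≥ 20 mm), CR/PR/SD/PD categorisation, C1/C2 binary mapping |
| `recistnet.network` | `ArchitectureSpec`, separable 3D convolutions, dense blocks, transition layers, non-local blocks, the full fusion classifier |
| `recistnet.training` | NLL loss + L2, rotation/translation augmentation, patient-disjoint stratified k-fold CV, accuracy/sensitivity/specificity/F1 |
| `recistnet.saliency` | Grad-CAM for the 3D backbone, PNG overlays |
| `recistnet.pipeline`, `recistnet.cli` | Reproducible end-to-end runs, YAML config, checkpoints, manifest |
| `recistnet.nn` | The numpy layer/optimizer substrate |

The default `ArchitectureSpec` follows the published layer plan exactly:
3×3×3 stem → 32 channels; six dense blocks of [6, 8, 8, 8, 8, 6] separable
layers (growth 16) preceded by [0, 1, 2, 3, 4, 5] non-local blocks, each
followed by a 1×1×1-conv + 2×2×2-maxpool transition; flattened 736-long
visual embedding; concatenation with the 15-element clinical vector (751);
FC stack 375/187/93/46/46/46 → 2 with softmax. `ArchitectureSpec.small()`
is a reduced-width variant of the same grammar for CPU-scale training.

## CLI

```bash
recistnet describe                         # per-layer shape table of the full model
recistnet synth --seed 1 --out-dir data/   # synthetic cohort (NIfTI + cohort.csv)
recistnet preprocess --cohort-dir data/ --out-dir prep/   # VOIs + normalizer
recistnet recist --measurements lds.csv    # RECIST categories from an LD table
recistnet train --seed 1 --out metrics.json
recistnet eval --checkpoint run/model.npz --cohort-dir data/ \
    --normalizer run/normalizer.json --out test_metrics.json
recistnet gradcam --checkpoint run/model.npz --voi voi.nii.gz \
    --clinical rec.json --normalizer run/normalizer.json \
    --target-class C2 --out-dir cam/
recistnet run --seed 1 --out-dir run/      # full pipeline, writes a manifest
```

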