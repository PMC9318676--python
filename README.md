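# cardiomorph

Cardiomyopathy-group classification from cardiac short-axis segmentation
label maps. The package implements two stages and everything needed to run
them end to end without external data:

1. **2D thickness encoding** — each patient's multi-slice ED and ES label
   maps (0=background, 1=RV, 2=myocardium, 3=LV) are collapsed into a single
   128×64×3 image. Slice *k* of an *N*-slice frame contributes a fixed
   intensity (the per-*N* tables sum to 255) to the channel of every
   structure it contains (RV→R, MYO→G, LV→B); the encoded ED frame is
   center-cropped, resized to 64×64, and stacked above the ES frame.
2. **Few-shot adaptive-subspace classifier** — a Conv4 encoder is trained
   episodically (5-way / 5-shot / 5-query, 100 episodes per epoch, 10
   epochs, Adam at 1e-3). Each class is represented by the mean and an
   orthonormal basis of its centred support features; queries are scored by
   the negative squared residual of their projection onto each class
   subspace, and a Grassmannian projection-metric regularizer (λ=0.03)
   pushes class subspaces apart. Per-patient labels come from majority
   voting over evaluation episodes, optionally ensembled over independently
   trained runs.

Supporting modules provide segmentation-side operators (auto zero padding,
resizing, channel triplication, probability-map ensembling, connected
component cleanup, Jaccard loss), a synthetic generator producing labeled
multi-slice ED/ES datasets for five morphology groups (DCM, HCM, MINF, NOR,
ARV) with controllable class structure, and ACDC-style NIfTI / PNG / CSV
I/O. The encoder and episodic training run on a small numpy reverse-mode
autodiff engine (`cardiomorph.fewshot.autodiff`), so no deep-learning
framework is required; gradients flow through the subspace construction via
Gram-matrix solves.

## Command line

```sh
cardiomorph generate --out data --n-per-class 20 --seed 0
cardiomorph encode   --data data --out enc
cardiomorph train    --images enc --labels data/labels.csv --out model --runs 5
cardiomorph predict  --support-images enc --support-labels data/labels.csv \
                     --query-images enc --model-dir model --out pred --ensemble
cardiomorph evaluate --predictions pred/predictions_ensemble.csv \
                     --labels data/labels.csv --out eval
```

Every stage honors `--seed`, writes its resolved configuration next to its
outputs, and is byte-reproducible. `train --downsample 4` (the default is 2)
shrinks the thickness images before encoding to trade accuracy for speed on
slow machines.

## Library entry points

```python
from cardiomorph.synthetic import make_dataset
from cardiomorph.thickness import encode_patient
from cardiomorph.fewshot import (FewShotConfig, Conv4Encoder, Conv4Spec,
                                 LabeledImage, train, predict_majority_vote)

patients = make_dataset(n_per_class=20, n_slices=6, seed=0)
images = [encode_patient(p, n_slices=6) for p in patients]
```

See the docstrings in `cardiomorph.fewshot.subspace` for the classifier
math and `cardiomorph.thickness` for the encoding contract.
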