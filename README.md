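# fracband

Multiband subband decomposition with frozen-backbone deep representation
learning for binary fracture / non-fracture classification of
radiograph-like images — implemented in pure scientific Python (numpy /
scipy / scikit-learn / scikit-image), with no deep-learning framework
dependency.

## What it does

1. **Decomposition** (`fracband.decomposition`): every input image
   (resized to 128×128×3) is split into four full-size subband image
   tensors (LL, LH, HL, HH) by one-level 2-D wavelet analysis followed by
   per-subband inverse reconstruction. Available methods: decimated DWT
   (`dwt2`), stationary/undecimated wavelet transform (`swt2`) and SVD
   eigentriple grouping (`svd`); wavelet families: `haar`, `db4`, `db5`,
   `db8` (Daubechies filters built by spectral factorisation). Periodic
   boundary handling makes the four subband images sum *exactly* back to
   the source.
2. **Model** (`fracband.model`, `fracband.nn`, `fracband.backbones`):
   one scoring branch per subband — frozen convolutional backbone →
   flatten → two dense/batch-norm/dropout blocks → sigmoid score. The
   per-subband scores form a probability vector (fixed LL, LH, HL, HH
   order) which is fused by a 128-unit ReLU dense layer and a sigmoid
   output. Training uses binary cross-entropy, Adam (lr 0.001, batch 32,
   up to 50 epochs) and early stopping (patience 5 on validation
   accuracy, best weights restored). Backbones: a fast `tiny` test
   backbone and a full numpy `efficientnetv2b2` feature extractor
   (4×4×1408 feature map for 128×128×3 input; random weights — no
   pretrained downloads). Further classification backbones are registered
   for architecture/shape inspection.
3. **Evaluation** (`fracband.evaluation`): stratified 72/8/20 hold-out
   split (floor/half-up-round/remainder rounding), stratified k-fold CV,
   confusion-matrix metrics (accuracy, precision, recall, F1, Cohen's
   kappa), ROC/AUROC and PR/AUPRC curves, fold aggregation (mean ±
   population SD).
4. **Explainability** (`fracband.explain`): Grad-CAM saliency maps per
   subband branch (gradients of the fused output w.r.t. the branch's
   backbone feature map), with PNG overlay export.
5. **Synthetic data** (`fracband.synthetic`): seeded generator of
   long-bone images with/without crack-like discontinuities; fracture
   images carry elevated high-frequency (HH) subband energy, so the full
   pipeline trains and evaluates end-to-end with no downloads.

## CLI

```bash
# generate a synthetic dataset (class-folder layout + manifest CSV)
fracband simulate --n-fracture 200 --n-nonfracture 200 --seed 0 --out data/

# export the four subband images of one input
fracband decompose --input data/fracture/frac_00000.png --method dwt2 --wavelet haar --out bands/

# train (resize -> decompose -> train -> evaluate; writes a run directory)
fracband train --data data/ --method dwt2 --wavelet haar --backbone tiny \
    --subbands LL,LH,HL,HH --seed 0 --out runs/demo

# score a single image / re-evaluate a partition / cross-validate
fracband predict --run runs/demo --input data/fracture/frac_00000.png
fracband evaluate --run runs/demo --split test
fracband crossval --data data/ --k 5 --seed 0 --backbone tiny

# Grad-CAM overlay for one subband branch
fracband gradcam --run runs/demo --input data/fracture/frac_00000.png --branch HH --out cam.png
```

Every ablation axis (decomposition method, wavelet family, backbone,
subband subset) is a config field; `RunConfig` round-trips through YAML
and rejects unknown keys.

## Layout

```
src/fracband/
  decomposition.py   wavelet/SVD subband decomposition
  backbones.py       frozen numpy feature extractors
  nn.py              dense/BN/dropout layers, Adam, BCE (forward+backward)
  model.py           branches, fusion, training, persistence
  evaluation.py      splits, metrics, curves, fold aggregation
  explain.py         Grad-CAM + overlays
  synthetic.py       synthetic long-bone image generator
  io.py              dataset folder reader, YAML run configuration
  experiment.py      end-to-end run driver, cross-validation
  cli.py             command-line interface
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
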