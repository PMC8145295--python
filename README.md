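# lesionkit

Dermoscopy images of pigmented skin lesions are hard to analyze
automatically: lesions are often low-contrast, irregularly bounded, and the
clinically important classes (melanoma, basal cell carcinoma, nevi, …) are
heavily imbalanced.  `lesionkit` implements a complete analysis chain for
this problem as a tested, composable Python library with a thin CLI:

1. **Contrast enhancement** — a hybrid histogram scheme: the dark
   (lesion) gray-level band is located by Otsu's split, amplified by a
   normalized-variance gain, histogram-equalized in-patch, blended back into
   the image, and sharpened by two separability-scored gain passes.
2. **Deep-saliency segmentation** — a small trainable CNN (three conv
   layers, one pool, softmax head) is trained on image-level lesion labels;
   its 128 third-conv-layer channel activations are fused into a saliency
   map, homogenized over SLIC superpixels, binarized at the map mean
   τ = μ(saliency), cleaned morphologically, and refined with a Chan–Vese
   active contour.
3. **Feature extraction** — deterministic flip/transpose augmentation to
   exact class balance, then global-average-pooled backbone features behind
   one interface (built-in tiny CNN by default; pretrained
   ResNet101/DenseNet201 as optional plug-ins).
4. **Wrapper feature selection** — (improved) moth-flame optimization over
   binary feature gates, scored by `fitness = r·Error + (1−r)·|subset|/Dim`
   with a cubic-SVM hold-out error; the improved variant binarizes through
   adaptive sigmoid-mean and entropy gates.
5. **Correlation fusion** — the two selected feature streams are padded to a
   common width (per-sample entropy padding), paired positionally, and every
   pair with Pearson ρ ≥ threshold contributes both columns to the fused
   matrix.
6. **KELM classification** — a kernel extreme learning machine: output
   weights solve `(I/C + Ω)β = T` for one-hot targets, with accuracy, macro
   sensitivity, FNR and a row-percentage confusion matrix reported.

Everything runs end to end on synthetic dermoscopy-like fixtures (elliptical
lesions with exact ground-truth masks; labeled feature matrices with planted
informative columns), so no external dataset is required; real image/mask
directories are accepted through the same readers.

## Worked example

```python
from lesionkit import dss, enhancement, fixtures
from lesionkit.nn import SaliencyNetSpec

# 60 synthetic lesion images (two classes differing in lesion contrast/size)
ds = fixtures.generate_segmentation_dataset(60, image_size=64, n_classes=2, seed=3)
enhanced = [enhancement.enhance(img) for img in ds.images]

net = dss.build_saliency_net(SaliencyNetSpec(input_size=64, n_classes=2,
                                             epochs=3, seed=0))
dss.train_saliency_net(net, enhanced[:40], ds.labels[:40])

reports = []
for i in range(40, 60):
    mask = dss.segment_image(net, enhanced[i], refine_image=ds.images[i])
    reports.append(dss.evaluate_segmentation(mask, ds.masks[i]))
print(f"mean accuracy {sum(r.accuracy for r in reports)/20:.2f}%  "
      f"mean dice {sum(r.dice for r in reports)/20:.3f}")
```

```
mean accuracy 99.95%  mean dice 0.997
```

The held-out masks agree with the ground truth on 99.95% of pixels, with a
mean Dice overlap of 0.997 — on these controlled fixtures the chain recovers
the lesion almost exactly.  The same stages are scriptable from the shell:

```bash
lesionkit segment --n-images 200 --size 64 --seed 0 --out report.json
lesionkit features --out features.csv
lesionkit select --features features.csv --variant imfo --iters 30 --seed 0 --out selected.csv
lesionkit classify --train train.csv --test test.csv --kernel rbf --out report.json
```

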