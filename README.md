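# sistfuse

Multi-modal medical image fusion in the shift-invariant shearlet domain.

Different imaging modalities of the same anatomy show complementary
information — CT renders bone and sharp boundaries, MRI renders soft
tissue, PET renders function. `sistfuse` merges a co-registered pair of 2-D
slices into a single image that keeps the locally salient detail of both,
for reading, radiotherapy planning, or downstream analysis.

## Method

Both inputs are decomposed by a **shift-invariant shearlet transform**
(SIST): a non-subsampled à-trous pyramid (levels `j = 1..M`, residuals
`g_j = f_{j-1} − f_j`) followed by Meyer-windowed directional filtering in
the FFT domain, with all planes at full resolution. Default configuration:
4 levels with 32, 32, 16, 16 directional subbands.

* **High-pass rule** — a siamese CNN (three 3×3 convs + 2×2 max-pool per
  branch, shared weights, difference head) scores sliding 16×16 patch
  pairs; the overlap-averaged score map `M` is thresholded (`T = 1` iff
  `M > τ`, τ = 0.5) and refined with a guided filter (r = 8, ε = 0.1) into
  a soft decision map `D`, then

      F_H(x,y) = D(x,y)·A_H(x,y) + (1 − D(x,y))·B_H(x,y)

* **Low-pass rule** — SIFT descriptors from both low-pass planes are
  matched (Lowe ratio test by default) and kept only where the keypoints
  are colocated (≤ 2 px); surviving matches rasterise into a binary
  `match_map` and

      F_L(x,y) = match_map(x,y)·A_L(x,y) + (1 − match_map(x,y))·B_L(x,y)

The fused pyramid is inverted (a plain sum, by construction) and the result
is scored with four standard measures: standard deviation (SD), entropy
(En), fusion mutual information MI = I(A;F) + I(B;F), and the
Xydeas–Petrović edge-transfer measure Q^AB/F.

No clinical data ships with the package; `sistfuse.phantoms` generates
seeded synthetic pairs (complementary-blur pairs with known ground truth,
CT/MRI-like modality phantoms, shifted pairs) and the CNN trains on
procedural sharp-vs-blurred patches. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
import numpy as np
from sistfuse import (
    CNNConfig, FusionConfig, average_baseline, build_model, fuse_pair,
    make_training_pairs, mutual_information_fusion, q_abf, train_model,
)
from sistfuse.phantoms import PhantomSpec, make_complementary_blur_pair

# train the patch scorer on synthetic sharp/blurred pairs (~30 s on CPU)
pairs = make_training_pairs(2000, seed=7)
model = train_model(build_model(CNNConfig(seed=1)), pairs, epochs=10, seed=3)
print("held-out accuracy:", model.metadata["holdout_accuracy"])

# fuse a 256x256 phantom pair with known ground truth
a, b, truth = make_complementary_blur_pair(PhantomSpec(seed=11))
result = fuse_pair(a, b, config=FusionConfig(), model=model)
baseline = average_baseline(a, b)

rmse = lambda x: float(np.sqrt(np.mean((x - truth) ** 2)))
print("RMSE  fused:", round(rmse(result.fused), 4), " baseline:", round(rmse(baseline), 4))
print("Qabf  fused:", round(q_abf(a, b, result.fused), 3),
      " baseline:", round(q_abf(a, b, baseline), 3))
print("MI    fused:", round(mutual_information_fusion(a, b, result.fused), 3),
      " baseline:", round(mutual_information_fusion(a, b, baseline), 3))
```

Output:

```
held-out accuracy: 1.0
RMSE  fused: 0.004  baseline: 0.022
Qabf  fused: 0.818  baseline: 0.559
MI    fused: 6.14  baseline: 4.5
```

The fused image sits ~5× closer to the ground truth than naive averaging,
and transfers more edge information (Q^AB/F) and more source information
(MI): the decision maps select the sharp half of each source, while the
average halves every detail's amplitude everywhere.

The same pipeline is available from the shell:

```
sistfuse train-cnn --n-pairs 2000 --seed 7 --epochs 10 -o model.npz
sistfuse make-fixtures --scenario complementary_blur --seed 11 -o fx/
sistfuse fuse fx/source_a.png fx/source_b.png -o fused.png --model model.npz --json report.json
sistfuse evaluate fused.png fx/source_a.png fx/source_b.png
```

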