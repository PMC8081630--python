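# Methods

`sistfuse` fuses two co-registered 2-D medical images (e.g. a CT–MRI or
MRI–PET slice pair) into one image that keeps the salient detail of both.
The method decomposes both inputs with a shift-invariant shearlet transform
(SIST), fuses the high-pass subbands with a decision map scored by a
siamese convolutional network and refined by guided filtering, fuses the
low-pass subband by SIFT-descriptor matching, and inverts the transform.
This note documents the model, the choices made where the design was open,
and what the synthetic test data do and do not establish.

## Shift-invariant shearlet transform

**Multi-scale step.** A non-subsampled (à-trous) pyramid with a
maximally-flat binomial low-pass kernel `[1,4,6,4,1]/16`, dilated by
`2^(j-1)` at level `j`, applied separably with circular (periodic) boundary
handling. The high-pass residual at each level is the difference of
successive low-pass images, `g_j = f_{j-1} − f_j`, so

    f_0 = f_M + Σ_j g_j

holds to machine precision by construction — reconstruction is a plain sum.
Nothing is downsampled, so every plane keeps the input resolution and the
whole transform commutes exactly with circular shifts.

**Directional step.** Each level residual is split into `n_j` orientation
bands by frequency-domain shearing windows. The angular coordinate is
pseudo-polar: direction is parametrised by slope (`ξ_y/ξ_x` on the
horizontal cone, `ξ_x/ξ_y` on the vertical one), giving a periodic
coordinate `u` of circumference 4 on which `n_j` Meyer windows are placed
at equal spacing. The Meyer auxiliary polynomial
`ν(x) = x⁴(35 − 84x + 70x² − 20x³)` satisfies `ν(x) + ν(1−x) = 1`, so the
squared windows tile unity at every frequency bin analytically — no
numerical normalisation is needed. Frequencies are folded through the
origin, so windows are origin-symmetric and every directional plane is real
(the imaginary residue of the inverse FFT is ~1e-15 and discarded). Each
directional plane is `ifft2(fft2(g_j) · U_k²)`: analysis and synthesis
windows are identical and folded into a single application, which makes the
directional planes of one level sum back to `g_j` exactly and keeps the
inverse transform a summation.

Defaults follow the method's reference configuration: 4 levels with
(32, 32, 16, 16) directions, finest level first (finer scales get more
orientation resolution). The window construction needs
`min(H, W) ≥ max(32, n_directions)`. Non-dyadic inputs are reflect-padded
to the next power of two and cropped after reconstruction.

## Siamese patch scorer

The scorer decides, per 16×16 patch pair, which source locally carries the
salient feature. Architecture: two weight-sharing branches of three 3×3
stride-1 convolutions (no padding; 16→14→12→10) with ReLU, channels
(16, 32, 64), followed by one 2×2 stride-2 max-pool (5×5×64 → 1600
features). The head maps the *difference* of the two branch feature
vectors through a bias-free linear layer and a sigmoid. The difference head
is what gives the score its semantics: `score(A,B) + score(B,A) = 1`
exactly, and identical patches score exactly 0.5. A bias term (or a
concatenation head) would break this antisymmetry, which downstream logic
relies on — with the default threshold 0.5, identical subbands produce an
all-zero binary map and the fusion reduces to the identity.

Training: binary cross-entropy, Adam (lr 1e-3, batch 64), 10 epochs, all
in float32 numpy with seeded initialisation and shuffling, so training is
bit-reproducible. Training pairs are procedural: 16×16 band-limited-noise
textures in [0,1], each paired with a Gaussian-blurred copy (σ uniform in
[0.75, 3], spanning mild to severe detail loss at this patch size); the
label marks the sharp member, with exact class balance. 2000 pairs and a
20% held-out split reach held-out accuracy ≈ 1.0 in well under a minute on
one CPU; label-shuffled controls stay at chance.

**What the proxy does and does not show.** The sharp-vs-degraded labelling
is a stand-in for supervision on clinical data, which this package does not
ship. It demonstrates that the scorer discriminates local detail strength,
which is the property the high-pass rule consumes; it does not demonstrate
modality-specific feature judgement on real CT/MRI/PET content.

## High-pass fusion rule

Per level: (1) slide the scorer (stride 2 by default) over the pair of
aggregate detail planes; (2) spread window scores back to pixels, averaging
overlaps, into the feature map `M`; (3) binarise with a strict threshold,
`T = 1` iff `M > τ` (τ = 0.5 by default; sensible range ≈ 0.4–0.7);
(4) refine `T` with a guided filter (radius 8, ε = 0.1) steered by the mean
absolute detail of the two sources, clamp to [0, 1]; (5) combine per pixel,
`F_H = D·A_H + (1−D)·B_H`. `D` stays soft after filtering — the weighted
combination uses it directly rather than re-binarising, which is what lets
the guided filter suppress isolated misclassifications smoothly instead of
re-introducing block boundaries.

Two numerical choices here matter and were validated empirically:

* **What the scorer sees.** The aggregate plane per level is the signed
  band-pass residual (the sum of that level's directional planes), not an
  energy magnitude. Each window pair is jointly divided by its shared
  max-|·| and recentred on 0.5. This maps a detail-free window to a flat
  mid-gray patch — exactly what a heavily blurred training patch looks
  like — so the scorer interpolates inside its training distribution. A
  nonnegative energy representation was tried first and rejected: blurred
  regions map to near-black flat patches the scorer never saw, and its
  extrapolation there inverts the decision map (measured end-to-end: worse
  than the pixel-average baseline; with the mid-gray residual
  representation the fused phantom error is ≈ 5× *below* the baseline).
* **One decision map per level, shared across directions.** Scoring each
  of the 96 directional subbands separately would cost 96 CNN sweeps per
  fusion with no evidence of benefit; a shared per-level map also keeps the
  orientation bands mutually consistent.

The guided filter is implemented on integral-image box sums with windows
clipped at the image border (no padding), matching the textbook per-window
linear regression exactly; tests pin it against an independent brute-force
oracle at 1e-8.

## Low-pass fusion rule

SIFT keypoints and 128-dim descriptors are extracted from both low-pass
planes (each affinely rescaled to [0,1] for detection only). Matching is
nearest-neighbour under Euclidean distance with two acceptance criteria:
the default Lowe ratio test (nearest < 0.75 × second-nearest) and a
"paper"-style unthresholded uniqueness criterion (nearest strictly below
every other distance) kept for fidelity to the original matching-degree
description; the latter accepts almost every query and is not the default.
Because the inputs are co-registered, a genuine content match must also be
colocated: matches whose keypoints sit more than 2 px apart (Euclidean,
boundary-inclusive) are discarded. Exact coordinate equality would never
fire on subpixel keypoints.

Each surviving match stamps a binary disk of radius 6 × (keypoint scale) —
the approximate descriptor support — into the dense match map, and

    F_L = match_map·A_L + (1 − match_map)·B_L

selects the first source inside matched regions, the second elsewhere.
Which source "wins" inside matched regions is a convention (the content
there agrees between the sources by construction, so the stakes are low);
it is configurable by swapping the inputs. When the low-pass planes are too
smooth to yield two descriptors — common at 4 decomposition levels — the
map stays all-zero, the rule degrades to carrying the second source's
low-pass, a warning is emitted, and a per-pixel-average fallback is
available. After 4 à-trous levels the two low-pass planes differ very
little, so this degradation is benign.

## Quality measures

All four measures operate on the 8-bit intensity scale; float [0,1] input
is quantised to 256 levels.

* **SD** — population standard deviation.
* **En** — Shannon entropy of the 256-bin histogram (bits, ≤ 8).
* **MI** — `I(A;F) + I(B;F)` from 256×256 joint histograms. The two-term
  (unnormalised) convention is used. Finite-sample note: with 256² joint
  bins the estimator carries an upward bias of roughly
  `(K−1)(L−1)/(2N ln 2)` bits; no-signal checks are therefore run at
  256×256 image size where the bias is ≲ 1 bit.
* **Q^AB/F** — the Xydeas–Petrović edge-transfer measure: Sobel edge
  strength and orientation per image (circular boundary, so the measure is
  exactly shift-invariant); per-pixel strength-ratio and orientation
  agreement pushed through sigmoids, multiplied, and averaged with source
  edge strength as weights. The classic sigmoid amplitudes
  (Γ_g = 0.9994, Γ_α = 0.9879, with κ_g = −15, σ_g = 0.5, κ_α = −22,
  σ_α = 0.8) cap the measure at ≈ 0.975 even for a perfect copy; by default
  each sigmoid is instead normalised by its value at perfect preservation so
  that `Q^AB/F(A, A, A) = 1` exactly. The raw-amplitude variant remains
  available (`QabfConstants(normalized=False)`), and all constants are
  exposed.

Color images are evaluated and fused on luma only: RGB is converted to a
full-range BT.601 YCbCr (exactly invertible in float), the luma channel is
fused, and the functional source's chroma is carried through unchanged —
the standard recipe for anatomical–functional overlays, where the color
coding must not be altered by fusion.

## Synthetic study data

The generators in `sistfuse.phantoms` are pure functions of their spec
(bit-reproducible) at the method's reference size of 256×256:

* **Complementary-blur pairs** — a textured scene (seeded geometric shapes
  + band-limited noise); copy A is Gaussian-blurred (σ = 3) on the right
  half, copy B on the left. The sharp halves equal the ground truth
  exactly, so fused-vs-truth RMSE is well defined.
* **Modality phantoms** — shared head-like geometry; one rendering with
  bright-rim/dark-interior contrast, one with soft graded interiors; the
  intensity correlation over the shared support is low (< 0.5) while the
  geometry is identical.
* **Shifted pairs** — an image and a known circular shift, for testing
  that descriptor matching survives displacement while colocation
  filtering rejects it.

These fixtures exercise every contract the pipeline states, but they are
not clinical data: passing them shows the machinery is correct and that
fusion beats naive averaging when detail is complementary; it does not
quantify diagnostic quality on real scans.

## Problem sizes and runtime

Chosen as the package's own defaults: scorer training on 2000 pairs / 10
epochs (≈ 30 s, one CPU); a full 256×256 fusion at default settings
(4 levels, 96 directional planes, stride-2 scoring ≈ 59k patch pairs)
takes ≈ 70 s; the brute-force guided-filter oracle is run at 32² with
r ≤ 4. The end-to-end acceptance sweep (`scripts/acceptance.py`) completes
in a few minutes.

## Known limitations

* The scorer is trained on synthetic sharp-vs-blurred textures, not on
  clinical data; its judgement is "where is the detail", not "which
  modality's feature matters clinically".
* Inputs must be co-registered; there is no registration step.
* Only 2-D, single-slice fusion; no DICOM/NIfTI ingestion (PNG/TIFF only).
* The low-pass rule frequently degrades to a fallback at deep
  decomposition levels because heavily smoothed planes yield few SIFT
  keypoints; this is by design and benign, but it means the SIFT machinery
  mostly matters at shallower decompositions.
* Guided-filter refinement can leave thin decision-map transition zones in
  which neither source dominates; with strongly conflicting (rather than
  complementary) sources this soft blending may locally reduce contrast.
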