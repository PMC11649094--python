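# Methods

## The pipeline and its assumptions

The template for one capture is the spatial–spectral cross-section of a
calibrated hyperspectral palm cube along a line anchored to hand anatomy.
The method assumes (i) the landmark detector places the 21-point hand model
consistently across captures, so the line samples nearly the same tissue
every time; (ii) the skin's reflectance structure along that line — spectral
baseline, superficial absorbers, deeper vessels, surface creases — is stable
for a person over the measurement horizon and differs between persons; and
(iii) a texture summary of the section (LBP block histograms) preserves
enough of that structure to separate identities after 2-D embedding.

Stage contracts worth noting:

- **Calibration** `(raw − dark)/(white − dark)` is affine-equivariant: a
  common positive rescaling of all three cubes leaves reflectance unchanged.
  Values above 1 (specular) are kept. Where the denominator is ≤ `eps`
  (default 1e-6) the output is 0 and the voxel is counted in metadata; a
  fully degenerate band plane is an error, because it means the white
  reference never saw light in that band.
- **Denoising** uses a normalized sampled-Gaussian kernel, σ = 2 (the value
  that balances noise suppression against feature integrity for this data
  class), truncated at 4σ, with mirror (reflect) borders so constants are
  preserved.
- **Reslicing** samples at `start + k·step·direction`, `k = 0..⌊L/step⌋`,
  step 1 px by default, bilinear in the four surrounding pixels per band.
  At lattice points bilinear interpolation is exact, so axis-aligned lines
  are bit-exact slices. Samples outside the raster are clipped to the bounds
  with a warning (hand placement is unconstrained; erroring would reject
  legitimate captures), or raise if clipping is disabled.
- **Standardization** resizes bilinearly to 100×100 and maps per-image
  min–max to [0, 255] with round-half-up. Per-image scaling makes the
  8-bit image invariant to illumination gain, which is why downstream
  features tolerate the ±10 % gain jitter. A constant section maps to all
  zeros with a warning. The default orientation keeps spatial samples along
  rows and wavelength along columns; a transposed orientation (λ top to
  bottom, the usual display convention) is available and is immaterial to
  the block-histogram features in aggregate.
- **LBP** compares each pixel's 8-connected neighbors against the center
  with ≥ (ties set the bit, the standard convention; exposed in config) and
  bins pixels by the *count* of passing neighbors, 0..8. This is the only
  natural binning that yields exactly 9 bins for P = 8; it is
  rotation-invariant and invariant under offsets and positive scalings of
  the gray values (and under any strictly increasing transform when the
  strict `>` comparison is chosen). Borders are replicate-padded so each
  20×20 block contributes exactly 400 counts and the whole vector sums to
  10 000. A uniform-pattern variant (bins = P + 2) exists behind the config
  for comparison; it is not the reference path.
- **PCA** is computed from the covariance eigendecomposition directly, with
  the component sign fixed by making the largest-magnitude loading positive;
  only pairwise distances are consumed downstream, so the sign convention is
  cosmetic but keeps runs bit-identical. t-SNE and UMAP run with
  `n_components=2` and a fixed `random_state`; their perplexity/neighbor
  counts are clamped for tiny cohorts so the contract (shape, finiteness,
  determinism) holds at any size.
- **Verification** enumerates ordered pairs of distinct captures (both
  directions), normalizes all distances by the global maximum, and sweeps a
  closed accept rule `d ≤ τ` over 1000 uniform thresholds plus every exact
  score value. EER is read at the FAR = FRR sign change with linear
  interpolation, or at the midpoint if the curves touch over an interval.
  AUC is trapezoidal over ROC points at every distinct score, which equals
  the Mann–Whitney statistic with ties counted half — the tests assert this
  identity on every instance. Welch's t-test uses the Satterthwaite degrees
  of freedom and the t distribution for the two-sided P.

## Synthetic palm cubes

The generator emulates what a line cut through a real palm hyperspectrum
shows, via Beer–Lambert-style attenuation of a smooth baseline:

    R(r,c,λ) = B(λ) · exp(−[m·patch(r,c)·w_short(λ) + vein(r,c)·w_long(λ)
                            + crease(r,c)]) · gain + ε

- `B(λ)`: per-subject sigmoid rising from ~0.1–0.3 below 600 nm to ~0.5–0.8
  above 650 nm, with roll-off near the 400/1000 nm sensor edges and a small
  smooth per-subject wiggle.
- `patch`: a smooth random field (Gaussian-filtered white noise), active
  below ~600 nm (`w_short` is a sigmoid falling at ~590 nm) — the patchy
  superficial absorber pattern.
- `vein`: 3–5 random curvilinear tubes 2–4 px wide, active above ~700 nm
  (`w_long` rises at ~720 nm) — deep vessel-like absorbers.
- `crease`: 2–4 thin straight segments with shallow broadband absorption —
  palm lines, which appear as shadow stripes across the cross-section.
- `m`: a per-subject melanin-like scale on the superficial field.

Each capture applies a rigid perturbation — translation uniform in ±5 px per
axis, rotation uniform in ±10°, illumination gain uniform in [0.9, 1.1] —
and i.i.d. Gaussian sensor noise with σ = 0.01 reflectance units (typical of
a high-SNR calibrated hyperspectral sensor), then clips to (0, 1]. The 21
landmarks undergo the same rigid map, so the ROI tracks the same anatomical
cut; this mirrors a detector that is robust to hand placement. Subjects,
captures and noise all derive deterministically from a master seed.

Default raster: 256×256×121 (a desk-scale stand-in for a full 640×480×121
scan), giving ROI lengths of ~150 px, comparable in line count to real scans.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical scattering and depth-dependent blur,
sensor spectral response and band-correlated noise, non-rigid skin
deformation under pressure, landmark-detector failures, and day-to-day
physiological drift. Real cohorts will separate less cleanly than synthetic
ones; the synthetic study validates the machinery (geometry, features,
metrics), not field accuracy.

## Problem sizes and numerical choices

The test suite exercises reduced problem sizes chosen to keep the full suite
fast while preserving every contract: unit tests use 96×96 rasters with 31
bands, the noise-degradation property uses 4×4 cohorts over 3 noise levels ×
5 seeds, and the end-to-end acceptance study runs the full default
10×10 cohort at 256×256×121. Oracle comparisons use exact equality for
integer quantities (LBP codes, histogram counts, pair counts), 1e-6 for
interpolation and convolution against brute-force loops, and 1e-12 for the
AUC/Mann–Whitney identity.

Degenerate inputs are contracts, not crashes: coincident line anchors,
all-zero distance sets, empty score populations, non-divisible block shapes
and sub-neighborhood images all raise typed errors.

## Design choices where the design was open

- **Ordered pairs** as the reference convention (900/9000 for 10×10), with
  an unordered flag (450/4500); symmetric distances make the metrics
  identical, only the counts differ.
- **Line extension** defaults to 1.0 — the segment ends exactly at the
  #9/#13 midpoint — because those are the only stated anatomical anchors;
  extending to the palm boundary is possible via the `extension` parameter.
- **Per-image min–max 8-bit conversion** rather than a fixed display range:
  deterministic, scale-invariant, and the only consumer is a gray-level-
  comparison feature.
- **Feature histograms kept as raw counts**; distances are computed on the
  2-D embedding, so per-block normalization would only rescale axes.
- **k-means agreement** uses 10 restarts with a fixed seed and reports the
  adjusted Rand index against ground-truth identities.

## Known limitations

- The nonlinear embeddings are reproducible only per pinned backend version;
  the deterministic reference path is PCA.
- EER/AUC on synthetic cohorts saturate (0 % / 100 %) because the identity
  signal dominates the injected jitter; the monotone noise-degradation test
  confirms the metrics respond correctly as noise grows.
- The MediaPipe adapter is out of scope; landmarks are file inputs, and the
  pseudo-RGB rendering exists only to feed an external detector.
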