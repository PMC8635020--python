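# Methods

## Model and assumptions

The pipeline treats a cardiomyocyte as a locally uniform stack of
sarcomeres: α-actinin–stained Z-bands form parallel bright planes with
period T ∈ [1.6, 2.0] µm perpendicular to the cell's long axis. Over a
16 µm cube — smaller than a cell's ~80 µm length but several sarcomeres
deep in every direction — the Z-band signal is well approximated by a
single plane-wave component, so the 3D power spectrum concentrates in a
symmetric pair of peaks at radius 1/T. Orientation estimation reduces to
locating that peak; everything that is not locally periodic in the
sarcomere band (vessels, nerves, fibrosis, noise) contributes little
in-band energy and is rejected by the `Sratio` reliability score rather
than by explicit morphological recognition.

Assumed acquisition geometry: 8-bit grayscale stacks at 0.44 × 0.44 µm
pixels and a 2 µm Z step, Y being the strip's traction axis. The stacks
are assumed stitched and (optionally) deconvolved upstream; both steps
are out of scope here.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `clip_limit` | 0.08 | – | CLAHE strength; strong equalization of depth-dependent brightness |
| CLAHE tile | 128 | px | equalization scale (56 µm); fixed in pixels so it is physical, not frame-relative |
| `k_clusters` | 4 | – | K-means intensity quantization of the segmentation step |
| `chunk_um` | 16 | µm | orientation analysis cube (36 × 36 × 8 voxels) |
| `tissue_fraction_min` | 0.80 | – | chunk acceptance; discards strip-border information |
| `period_range_um` | (1.6, 2.0) | µm | sarcomere band; sets shell radii 8–10 px with Δf = 0.0631 µm⁻¹ |
| `sratio_threshold` | 0.14 | – | reliability cut on the min–max-normalized Sratio |
| `macrovoxel_m_list` | 2…6 | – | disarray scales: 32–96 µm macrovoxels |
| `map_smooth_sigma_um` | 10 | µm | Gaussian smoothing of rendered disarray maps |
| PSF σz / σxy | 1.316 / 0.25 | µm | generator optics: 3.1 µm axial FWHM; lateral FWHM ≈ 0.6 µm (lateral value is a package choice, configurable) |

## Numerical choices

- **DC handling.** The chunk mean is subtracted before the FFT and the
  DC bin is excluded from the Sratio denominator, so the score measures
  structure, not brightness. The min–max normalization downstream makes
  the pipeline insensitive to the absolute scale of this choice.
- **Sratio definition.** Implemented as band energy / total spectral
  energy in [0, 1]. No decibel factor is applied; any fixed factor
  cancels in the per-sample min–max normalization.
- **Zero-padding.** The padded Z bins keep the native spacing
  1/(8·2 µm) = 0.0625 µm⁻¹ against the lateral 0.0631 µm⁻¹; the shell
  uses the single lateral Δf, accepting ≈1% radial anisotropy — this is
  precisely what padding 8 → 36 is for.
- **Peak localization.** The 4×4×4 centroid window is anchored with the
  maximum voxel at offset (1,1,1) and clipped at grid edges. Equal maxima
  resolve to the lowest linear index; vectors with v_y = 0 exactly are
  flipped by v_x, then v_z (deterministic).
- **PSD smoothing.** 3×3×3 Gaussian, σ = 0.8 px, kernel normalized to
  unit sum, reflect padding (boundary handling is a package choice).
- **Outlier pass.** Single pass on a snapshot of the reliability flags:
  a reliable vector deviating > 45° from its reliable 26-neighbourhood
  mean must exceed 2 × the base Sratio threshold. The 45°/2× /
  26-neighbour quantification is a package choice; only the mechanism
  (raise the threshold for deviant vectors) is inherited.
- **Segmentation.** CLAHE-equalized frames are quantized by K-means
  (k-means++ with the config seed; fit subsampled at 10⁵ px for large
  frames) on a 2-px local-mean intensity, and clusters are labeled
  Background/Tissue by whether their centre falls below the Otsu
  threshold of that local-mean image. This "dynamic second
  classification" is a stand-in: the original rule is unpublished. The
  local mean averages away the ~4 px band period so striated tissue reads
  uniformly bright; a plain per-pixel rule fails because CLAHE flattens
  empty-background noise into the same intensity range as tissue.
  Frames with intensity SD < 5 levels are treated as signal-free.
  Morphology: closing then opening with a 2-px disk (bridges the band
  period without merging ~45-px-wide cells), removal of components
  < 100 px and holes ≤ 100 px.
- **Log-normal fits.** µ, σ by ln-moment matching (the log-normal MLE);
  d = 0 values are excluded (ln undefined) and counted; fits are refused
  below 20 positive values. The D'Agostino–Pearson test is applied to
  ln d, since the hypothesis is log-normality.
- **Macrovoxel tiling** starts at the vector-grid origin; partial
  macrovoxels at far edges are discarded (same rule as chunk tiling).

## Synthetic generators

`phantoms` emulates what the orientation stage consumes: binary band
profiles (duty 0.45) along an arbitrary axis, blurred by the anisotropic
Gaussian PSF and quantized to 8 bit. Noise is added **before** the PSF
blur: the pipeline ingests deconvolved stacks whose residual noise is
band-limited, and white post-blur noise would make CLAHE-equalized
background statistically indistinguishable from tissue — an artifact of
the synthetic world, not of real images. What the phantoms do *not*
emulate: intensity texture inside bands, fibrosis, vessels,
depth-dependent signal loss, stitching seams. Passing phantom tests
therefore validates the frequency-analysis machinery and its geometric
calibration, not robustness to every real-tissue nuisance.

The rotation-accuracy experiment resamples fine isotropic gratings
(0.44 µm grid) onto the anisotropic acquisition grid after a rigid
rotation, composed as R = Rz(φ)·Rx(θ) (elevate about X, then azimuth
about the optical axis; the composition order is a documented package
convention). The elevation limit θ = arcsin(T/(2.3 · 2 µm)) ≈ 23° is
implemented with the axial band period D = T/sin θ; the validation grid
(±30°, 5° steps, 13 × 13) brackets that limit.

`virtual` builds strips from one shared synthetic base (period 1.8 µm
along Y; a user TIFF base is accepted), one rotated copy per cell on a
gapless axis-aligned lattice. Rotated cells are re-blurred along Z with
σk = √(σz² − σxy²) and borders smoothed with a 1-px Gaussian. Real
tissue has staggered, interdigitated cells rather than a lattice, and
per-cell structural variability rather than one shared base; the
generator calibrates the disarray metrics against known angular
dispersion, it does not simulate histology.

## Problem sizes

The test suite and the acceptance script use scaled-down experiments
chosen to keep runs interactive while leaving dozens of macrovoxels per
scale: 20 phantom chunks per rotation cell (13 × 13 grid), and virtual
strips of 650 × 200 × 140 µm (560 cells, ~3.8k orientation chunks, 60
macrovoxels at the 64 µm scale) instead of the full 1300 × 400 × 280 µm.
The full-size strip remains the `VirtualSampleSpec` default.

## Known limitations

- Elevations beyond ~23° are unresolvable at the 2 µm Z step; the
  pipeline's validated range is |θ| ≤ 20°, and steep cells surface as
  unreliable chunks rather than as wrong vectors.
- Min–max Sratio normalization is per-sample: on a sample where *every*
  chunk has excellent periodicity, the 14% cut removes the relatively
  weakest chunks. Anchoring requires the sample to contain genuinely
  weak regions (borders, background), which real strips always do.
- The segmentation's cluster-labeling rule is a documented approximation
  of an unpublished procedure; frames with < ~15% tissue under-cover
  somewhat (Jaccard ~0.6 in phantom tests vs ≥ 0.85 at 30–100% tissue).
- Log-normality of local-disarray distributions is an approximate
  empirical property: at ~50 macrovoxels most, but not all, replicate
  virtual samples pass the D'Agostino–Pearson test at α = 0.01; tests
  therefore assess replicates by majority.
- Orientation chunks (16 µm) are smaller than the virtual cells' 20 µm
  cross-section, so some chunks straddle cell boundaries and measure
  orientation mixtures; this slightly inflates measured disarray at high
  dispersion, as it would in real tissue.
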