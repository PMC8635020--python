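# myodisarray

Mapping 3D cardiomyocyte orientation and quantifying myocyte disarray in
volumetric fluorescence images of sarcomeric Z-bands.

## The problem

Cardiomyocytes produce force along their long axis, and many cardiac
diseases (hypertrophic cardiomyopathy, chronic atrial fibrillation)
remodel the tissue so that cells lose their common alignment — *myocyte
disarray*. α-actinin staining highlights the sarcomere Z-bands, which
appear in two-photon reconstructions as bright planes perpendicular to the
cell axis with a period T ≈ 1.6–2.0 µm. This package exploits that
periodicity: the 3D power spectrum of a small tissue chunk shows a pair of
symmetric peaks at spatial frequency 1/T along the local cell axis, so
locating the peak recovers both the fiber direction and the sarcomere
length.

## The method

For each 16 µm cube **p** (36 × 36 × 8 voxels at 0.44 × 0.44 × 2 µm) with
at least 80 % contractile tissue:

1. centered 3D FFT, zero-padded along Z to a 36³ cube (equivalent to
   isotropic 0.44 µm sampling);
2. spherical-shell bandpass keeping periods 1.6–2.0 µm
   (radii ≈ 8–10 px, Δf = 1/(36 · 0.44 µm) = 0.0631 µm⁻¹);
3. reliability score `Sratio` = in-band energy / total spectral energy,
   min–max normalized per sample; chunks above 14 % are *reliable*;
4. orientation v⃗ = vector from the spectrum centre to the intensity
   centroid of a 4³ window around the brightest in-band voxel, flipped
   into the v_y ≥ 0 hemisphere; ‖v⃗‖ = 1/T;
5. a neighbourhood outlier pass discards deviant vectors with weak band
   energy.

Local disarray over macrovoxels **g** of m × m × m vectors (sides
32–96 µm for m = 2…6):

    d_g = (1 − |mean of unit vectors|) · 100 %      a_g = mean v_y

with global statistics D, A averaging the valid macrovoxels, and the
sample-wide local-disarray distribution summarized by a log-normal fit
(mode = exp(µ − σ²), SD = √[(e^σ² − 1)·e^(2µ+σ²)], log-normality checked
with the D'Agostino–Pearson test on ln d).

Because Z-bands tilted out of the imaging plane project on the optical
axis with period T/sin θ, the 2 µm Z step makes elevations beyond
θ = arcsin(T / (2.3 · 2 µm)) ≈ 23° unresolvable — the pipeline's
validated range is |θ| ≤ 20°.

Two generators close the loop without real data: `phantoms` builds
striated volumes with a known 3D axis (used to validate rotation
accuracy), and `virtual` assembles strips of 80 × 20 × 20 µm virtual
cells whose orientations are drawn from N(θ̄, σθ) × N(φ̄, σφ), calibrating
measured disarray against true cellular angular dispersion.

## Worked example

```python
import myodisarray as md

# a virtual tissue strip with 10 deg cellular angular dispersion
spec = md.VirtualSampleSpec(sample_extent_um=(650, 200, 140),
                            sigma_theta_deg=10, sigma_phi_deg=10, seed=3)
volume, truth = md.generate_sample(spec)
field = md.analyze_sample(volume)
print(md.multiresolution_table(field).to_string(index=False))
```

prints (one row per macrovoxel scale):

```
 m  side_um  N_v        D        A     mode  std_dev  lognormal_p
 2     32.0  457 1.045407 0.982695 0.141361 2.167009 9.620525e-07
 3     48.0  103 1.462147 0.983036 0.833428 1.014346 4.701004e-02
 4     64.0   60 1.596462 0.982734 1.119323 0.828559 8.123847e-01
 5     80.0   16 1.587592 0.982920      NaN      NaN          NaN
 6     96.0   12 1.603397 0.983522      NaN      NaN          NaN
```

Read: at the 64 µm scale the strip has global disarray D ≈ 1.6 % and
alignment A ≈ 0.99 with the strip axis; the local-disarray distribution
has its log-normal mode near 1 % and is compatible with log-normality at
the coarser scales (the fit is refused, NaN, where fewer than 20
macrovoxels exist). An aligned sample (σ = 0) gives D ≈ 0 at every scale;
σ = 20° drives D above 4 % at the 96 µm scale.

A command-line interface mirrors the library:
`myodisarray orient | disarray | stats | simulate | validate`.

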