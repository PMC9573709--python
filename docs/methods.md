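# Methods

## The transform

The non-subsampled shearlet transform here is built entirely in the 2-D
DFT domain: every sub-band is the inverse FFT of the input spectrum
multiplied by a smooth window, and boundary handling is circular
throughout. Three properties are then exact by construction rather than
approximate:

- **Perfect reconstruction.** The radial scale windows are differences of
  nested low-pass windows, so they telescope to unity; summing the low
  band and all directional sub-bands reproduces the input to machine
  precision (measured ≈ 3e−15 on a random 64×64 image).
- **Shift equivariance.** Circular shifts commute with pointwise spectral
  multiplication (measured ≈ 2e−16).
- **Directional partition of unity.** The orientation windows at each
  scale sum to one, so the directional sub-bands sum back to the pyramid
  band (measured ≈ 2e−15).

**Scale windows.** Radial frequency is measured as
r = max(|ω₁|, |ω₂|)/π (square annuli, matching the shear windows' cone
geometry). The level-j low-pass is 1 for r ≤ 2⁻ʲ, 0 for r ≥ 1.5·2⁻ʲ,
with a monotone transition by the maximally-flat degree-7 polynomial
ν(x) = x⁴(35 − 84x + 70x² − 20x³), which satisfies ν(x) + ν(1−x) = 1
(`pyramid_filter_id="maxflat"`; a raised-cosine transition is available
as `"cosine"`). Scale k = 1 is the finest band, spanning the outer
annulus r ∈ (0.5, 1]; it receives the dominant weight in the sharpness
score because it is the band most sensitive to defocus.

**Orientation windows.** Orientation is the line angle θ mod π; window l
of an n-direction bank is a smooth bump of width 2π/n centred on l·π/n,
built from the same ν so that adjacent bumps sum to one, and symmetrized
under ω → −ω so real images give real sub-bands (the Nyquist row/column
of an even grid otherwise breaks the symmetry). Directions per scale
default to 4 at each of 3 scales; the sharpness score sums variances over
directions, so it is only weakly sensitive to this count.

`NSSTConfig.shear_filter_size` is accepted and serialized for config
compatibility but has no effect: frequency-sampled windows span the full
grid rather than a fixed FIR support.

Minimum image side is max(32, 2^(n_scales+2)) so the coarsest transition
band is still sampled.

## The sharpness score

Per-sub-band energy is the population variance (divide by MN). The
aggregation is

E_L = V(low), SV′ₖ = Σₗ V(k, l), EₖH = SV′ₖ/2ᵏ,
E_H = s·E₁H + (1−s)·(Σ_{k=2..N} EₖH)/w, h = E_H / max(E_L, ε),

with defaults s = 0.8, w = 3, ε = 1e−12. The ε guard makes a constant
image score 0 (a featureless frame must rank below any structured one)
instead of raising on 0/0. For N = 1 the coarse sum is empty and
h = s·E₁H/E_L.

Baselines use standard definitions: Tenengrad is the Sobel
gradient-magnitude square sum; Roberts and Laplacian the square sums of
their 2×2 / 3×3 kernel responses (reflect boundary); EOG the forward
difference square sum; DCT the fraction of AC energy above an index-sum
cutoff at one quarter of the maximum (0 for a constant image); Canny the
edge-pixel fraction at σ = 1 with hysteresis thresholds 0.1/0.2;
variance the whole-image population variance. These exist for ranking
experiments — only internal consistency matters, not absolute scale.

## Focus curves and the narrow width

Curves are min–max normalized; a constant curve maps to all zeros and is
flagged. The narrow width interpolates level crossings linearly between
samples and takes the outermost crossings of levels 0.4 and 0.8 on each
side of the global peak; the reported ratio is width(0.8)/width(0.4), so
it lies in (0, 1] for unimodal curves and grows with steepness. When a
level is never crossed on one side the width is clipped to the frame
range, a warning is issued, and the result is flagged truncated. With an
explicit `peak_frame` the search is restricted to that peak's monotone
basin and levels are taken relative to the peak's own height — the
natural treatment for stacks with two focus planes reported per-peak.

A sampling note: on a steep curve both level crossings can fall on the
two segments adjacent to the peak, where linear interpolation forces the
ratio to exactly (2·0.2)/(2·0.6) = 1/3. The 21-frame default sweep sits
at this ceiling for the steepest measures; denser frame sampling
resolves it.

Local maxima are strict (plateaus collapse to their leftmost frame;
endpoints count only against their single neighbor); a constant curve
has zero local maxima and is not unimodal.

## Noise protocol

Gaussian noise adds N(0, density) on the [0,1] scale and clips
(`density` is the variance; default 0.01). Salt-and-pepper corrupts
exactly round(density·MN) pixels to 0 or 1 with equal probability
(default density 0.1; per-pixel Bernoulli mode by flag). Poisson
replaces each pixel by Poisson(g·Q)/Q with Q = 255 quantization levels.
All draws come from one seeded generator per stack, so every measure in
an experiment sees identical corrupted frames.

Pre-filters: bilateral (scikit-image; σ_spatial = 3 px, σ_range = 0.1)
and a self-guided guided filter (radius 4, regularization 0.01),
implemented with box filters; as regularization → ∞ the output tends to
the boxwise mean, which the tests check as a limit.

## Synthetic stacks

The phantom places `n_cells` (default 12) non-overlapping quasi-circular
objects — radius 6–14 px, smooth boundary perturbation ≤ 20% of radius —
fully inside a 256×256 frame, brighter than the background by 0.35, with
granular interior texture of amplitude 0.08 (unit-σ smoothed noise,
amplitude-normalized) over a background at 0.55 with mild low-frequency
shading (amplitude 0.02). The sweep blurs the phantom with a Gaussian
(or pillbox) PSF of σ = |i − peak|·0.6 px over 21 frames, so the
endpoints sit at σ = 6. These sizes emulate the sparse-cells-on-uniform-
background regime of sediment micrographs at desk scale.

Two consistency choices matter. The shading field is generated with
periodic (wrap) filtering and the defocus PSF is applied circularly:
since the analysis itself is circular, a non-periodic border seam would
inject a blur-invariant high-band energy floor that turns the far-defocus
tails of the h curve upward. With periodic construction, blur commutes
with the analysis and h decreases strictly with blur distance on both
sides of the peak; every bundled measure attains its maximum at the
in-focus frame on the default stack.

What the phantom does **not** emulate: dense full-frame texture, sensor
noise in the clean frames, illumination drift across the sweep, and
real optical PSFs (aberrations, vignetting). Passing tests on the
phantom therefore demonstrate ordinal correctness of the measures under
controlled defocus, not radiometric fidelity to any instrument.

## Known limitations

- **Impulse noise overwhelms sparse scenes.** Salt-and-pepper at density
  0.1 injects ~2.5e−2 of image variance. A bilateral filter cannot
  remove impulses (the center-pixel similarity weighting preserves them;
  measured MSE reduction is ~1%), and the guided filter removes under
  half. The residual is a frame-constant high-band energy floor of
  ~3–5e−3, while the sparse phantom's in-focus signal E_H is ~2e−5; the
  score's numerator is then flat, h tracks 1/E_L, and because E_L peaks
  at focus the normalized curve inverts. On such phantoms *no* bundled
  high-frequency measure keeps its peak under heavy impulse noise —
  whole-image variance, dominated by coarse structure, is the only
  survivor. Densely textured real micrographs, whose in-focus high-band
  variance is orders of magnitude larger, are the regime where the NSST
  measure's noise advantage can materialize. The robustness module
  reports these outcomes as measured.
- The narrow-width ratio saturates at 1/3 for very steep curves at
  coarse frame sampling (see above).
- The transform's circular boundary model means images with strong
  left/right or top/bottom intensity mismatch contribute some spurious
  fine-scale energy at the wrap seam; for focus *ranking* this offsets
  all frames similarly, but absolute scores on such images should be
  read with care.
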