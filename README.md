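# shearfocus

Noise-robust sharpness evaluation for microscope autofocus, built on the
non-subsampled shearlet transform (NSST).

## The problem

Passive autofocus sweeps the stage through the focal plane, scores every
frame with a *focus measure*, and drives the motor toward the score's
peak. For medical micrographs — urinary-sediment cells are the motivating
case — the scene is a handful of roughly circular cells scattered over a
near-uniform background, and acquisition noise is unavoidable. Classical
gradient measures (Tenengrad, Laplacian, energy of gradient, ...) respond
to that noise as if it were detail: their focus curves grow secondary
peaks and the search strands on the wrong frame.

## The measure

An image *g* is decomposed with the NSST: a non-subsampled pyramid yields
one low-frequency sub-band and *N* high-frequency scales, and shear
filters split each scale into directional sub-bands. Every sub-band keeps
the input's size (no subsampling), so the transform is shift-invariant.
Each sub-band's energy is its population variance

V = (1/MN) Σᵢⱼ (g(i,j) − ḡ)²,

and the score combines them as a high/low energy ratio:

- E_L = V(low band)
- SV′ₖ = Σₗ V(band k, direction l)
- EₖH = SV′ₖ / 2ᵏ  (k = 1 is the finest scale)
- E_H = s·E₁H + (1 − s)·(Σ_{k≥2} EₖH)/w,  with s = 0.8, w = 3
- **h = E_H / E_L**

Defocus drains fine-scale energy, so E_H collapses away from focus while
E_L, the smoothed gist of the scene, moves slowly; h therefore peaks
sharply at the in-focus frame. Focus curves are compared by the *narrow
width* α/β — the ratio of the normalized curve's level-set widths at 80%
and 40% of the peak (closer to 1 = steeper) — and by unimodality
diagnostics.

The package also provides the classical baselines (tenengrad, roberts,
laplacian, eog, dct, canny, variance), a noise-immunity protocol
(Gaussian / salt-and-pepper / Poisson injection with bilateral or guided
pre-filtering), and a synthetic focal-stack generator so everything is
testable without microscope data.

## Worked example

Generate a synthetic 21-frame defocus–focus–defocus stack (12 textured
cell-like objects on a 256×256 background, blur step 0.6 px/frame) and
trace two focus curves:

```sh
shearfocus curve synthetic --seed 0 --measure nsst --measure tenengrad --out demo/
```

`demo/metrics.json` then contains, for the NSST measure:

```json
"nsst": {
  "diagnostics": {"argmax_frame": 10, "n_local_maxima": 1, "is_unimodal": true},
  "narrow_width": {"alpha_width": 1.609, "beta_width": 0.536, "ratio": 0.333}
}
```

The curve peaks exactly at the in-focus frame (frame 10 of 0–20), has a
single local maximum, and its narrow width 0.333 sits at the steepness
ceiling imposed by 21-frame sampling (both level crossings fall on the
segments adjacent to the peak). Tenengrad also peaks at frame 10 on this
clean stack with ratio 0.339; the measures separate under noise, which
`shearfocus noisetest` quantifies:

```sh
shearfocus noisetest synthetic --measure nsst --measure tenengrad \
    --noise salt_pepper --filter bilateral --seed 0 --out robust/
```

writing one row per measure with the corrupted-stack peak location,
local-maximum count, and narrow width.

The same API is available from Python:

```python
from shearfocus import make_phantom, make_stack, score_stack, diagnose_curve
stack = make_stack(make_phantom())
curve = score_stack(stack, "nsst")
print(diagnose_curve(curve).argmax_frame)   # -> 10
```

For real data, point `curve`/`noisetest` at a directory of same-sized
PNG/TIFF/JPEG/BMP frames (lexicographic order) or at a manifest file
listing one frame path per line.

## Limitations

The noise-immunity protocol reports honest outcomes: on sparse synthetic
phantoms the high-frequency energy of *any* measure, including this one,
can be swamped by heavy impulse noise that bilateral filtering cannot
remove (see `docs/methods.md` for the quantitative analysis).
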