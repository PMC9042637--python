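# usenhance

Grayscale ultrasound image enhancement: two-stage adaptive median filtering
for impulse noise, morphological gradient edge detection, edge-region-only
sharpening, and full-reference quality metrics — with a seeded synthetic
ultrasound phantom generator so the whole pipeline is testable without any
clinical data.

## Who this is for

B-mode ultrasound frames (here motivated by pelvic-floor imaging) suffer
from salt-and-pepper impulse corruption on top of speckle texture, and
their diagnostically relevant content is concentrated along edges: organ
boundaries, fascia, the bladder-neck outline.  `usenhance` implements an
enhancement method tailored to that situation: remove impulses without
touching genuine signal, find edges with impulse-robust morphological
gradients, and boost only the edge region, leaving everything else
bit-identical.

## The method

**Impulse detection and removal.**  For each pixel `F(a,b)`, the ascending
sorted array `S` of its `M x M` window (default `M = 3`) yields `S_min`,
`S_max`, `S_med`, and the interior bracket positions `N1` (first entry above
the minimum) and `N2` (last entry below the maximum).  A pixel is a
*quasi-noise candidate* when it equals a window extreme while the median is
not one.  Candidates are confirmed by comparing a local slope against an
adaptive threshold:

    minimum case:  K1 = (S[N1] - F) / ((N1 + 1) / 2)
    maximum case:  K1 = (F - S[N1]) / (M*M - 1 - N2)
    average slope: K2 = (S[N2] - S[N1]) / (N2 - N1)
    threshold:     Q  = S_med / epsilon         (epsilon a positive integer)

with noise declared when `|K1| >= Q` (a stricter rule also requiring
`|K1| > |K2|` is selectable).  Confirmed noise is replaced by the median of
the smallest window in the growth schedule `3 -> 5 -> 7` whose median is
not itself an extreme; signal pixels are copied unchanged.

**Edge detection.**  Five flat-structuring-element gradient operators,
written with dilation `(+)`, erosion `(-)`, opening `o`, closing `*`:

    P1 = (g (+) D) - (g * D)             P4 = ((g o D) (+) D) - (g o D)
    P2 = (g o D)  - (g (-) D)            P5 = (g * D) - ((g * D) (-) D)
    P3 = ((g o D) (+) D) - ((g * D) (-) D)

The opening/closing pre-smoothing makes P3–P5 nearly blind to isolated
impulses while still responding strongly to real steps.

**Enhancement.**  The gradient map is binarised (Otsu on the nonzero
histogram by default) and the edge region is sharpened additively,
`out = clip(denoised + gain * edge)`; non-edge pixels remain exactly the
denoised values.

**Metrics.**  SNR, PSNR, MSE and a global three-factor SSIM
(`luminance x contrast x structure` with `c3 = c2/2`) quantify the
before/after change against a reference.

## Worked example

Generate a phantom, corrupt 10 % of its pixels, and enhance:

```sh
usenhance phantom --height 128 --width 128 --seed 7 --out clean.png --mask structure.png
usenhance corrupt --in clean.png --density 0.1 --seed 11 --out noisy.png
usenhance enhance --in noisy.png --out enhanced.png --reference clean.png \
    --operator P4 --epsilon 2
```

The last command prints the quality metrics of the noisy input, the
denoised intermediate, and the enhanced output against the clean phantom:

```json
{
  "input":    {"snr_db": 0.19,  "psnr_db": 14.98, "mse": 2065.88, "ssim": 0.656},
  "denoised": {"snr_db": 10.82, "psnr_db": 25.62, "mse": 178.46,  "ssim": 0.960},
  "output":   {"snr_db": 7.47,  "psnr_db": 22.27, "mse": 385.91,  "ssim": 0.914}
}
```

Reading these numbers: impulse corruption costs ~15 dB of PSNR; adaptive
median filtering recovers ~10.6 dB of it and lifts SSIM from 0.66 to 0.96;
the edge boost then deliberately departs from the clean reference *on the
edge region only* (PSNR 22.3 dB, SSIM 0.91 — still far above the noisy
input) in exchange for higher edge contrast.

The same comparison over a whole condition grid (noise densities x epsilon
x operators x replicates), with per-run CSV output and per-condition
summaries, is one command:

```sh
usenhance bench --out runs.csv --summary summary.csv
```

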