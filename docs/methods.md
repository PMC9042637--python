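# Methods

This note records what the toolkit computes, the assumptions behind it, the
defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## Image model and conventions

All processing operates on single-channel 8-bit images: integer intensities
in `[0, G_max]` with `G_max = 255`, indexed `(row, column)` from the top-left.
Filtering and morphology stay in integer space (the detector ranks and
compares gray values; floating point would add nothing but rounding
questions); quality metrics convert to float64.  Image borders are extended
by mirror reflection without repeating the edge sample (`reflect`), with
edge replication available.  Reflection avoids fabricating extreme values
at borders that a constant pad would introduce and that the impulse
detector would then flag.

## The two-stage impulse detector

Salt-and-pepper corruption replaces pixels with extreme intensities.  The
filter exploits two of its signatures: a corrupted pixel is an extreme of
its local window, and it sits on an implausibly steep local slope.

**Stage 1 — screening.**  From the ascending window array `S` (window side
`M`, default 3): a pixel is a candidate iff it equals `S_min` or `S_max`
*and* the median is strictly between the extremes.  The second clause is a
reliability condition on the median itself: when the median coincides with
an extreme, the window majority is at that extreme and the median carries
no information about the local signal level, so the rule abstains.

**Stage 2 — slope confirmation.**  The local slope `K1` measures how far
the candidate sits below/above its nearest non-extreme neighbours in `S`
(positions `N1`/`N2`), normalised by the index distance to the middle of
the extreme run; `K2 = (S[N2]-S[N1])/(N2-N1)` is the window's average
interior slope.  The decision threshold `Q = S_med / epsilon` adapts to the
local brightness: bright tissue tolerates larger excursions than anechoic
regions.  The default rule declares noise when `|K1| >= Q`; the stricter
variant additionally requires `|K1| > |K2|`.  Degenerate windows (constant,
or with no strict interior) are never modified, and `K2 = 0` when the
interior collapses to one position.

The printed maximum-case `K1` is asymmetric: its numerator references
`S[N1]` (a value adjacent to the *minimum* run) rather than `S[N2]`, so for
a maximum-valued candidate it measures nearly the full window range.  Both
forms are implemented (`k1_variant = as_printed | symmetric`); `as_printed`
is the default.  The practical consequence: salt detection is much more
permissive than pepper detection, whose slope uses only the gap between the
minimum and its nearest neighbour.  At `epsilon = 1` this makes pepper
confirmation essentially impossible in textured tissue
(`K1 ~ background - 2 sigma < Q = background`), which is visible in the
benchmark as low recall at `epsilon = 1`.  `epsilon = 2` is the default: it
is the smallest divisor for which both polarities are reliably confirmed in
mid-gray tissue while local speckle extremes (whose `K1` is on the order of
the window range, ~3-4 sigma) still mostly fall below `Q`.

**Replacement.**  A confirmed pixel takes the median of the smallest window
in the schedule `3 -> 5 -> 7` whose median is not itself a window extreme,
falling back to the 7x7 median.  Under the stage-1 rule above, the initial
window always already qualifies (a candidate's median is interior by
construction), so the growth is a dormant safety net; it is retained
because it is the standard adaptive-median architecture and becomes active
the moment the screening rule is relaxed.

Two deliberate semantics, fixed so that the vectorized filter and its
brute-force transcription agree bit-exactly:

- *Non-recursive*: every decision reads the input image; output is written
  separately.  Scan order therefore cannot matter.
- A corollary of the screening rule worth stating plainly: an isolated
  impulse in a *perfectly flat* region is not corrected (the window median
  equals an extreme there, so the rule abstains).  Real ultrasound is never
  flat — speckle guarantees textured windows — but synthetic flat-field
  tests will show this behaviour.

`brute_force_denoise` is a literal per-pixel transcription of the rules,
kept unoptimized on purpose; the test suite asserts pixel-for-pixel
equality with `denoise` across the full parameter grid.

## Morphology and the gradient operators

Grayscale dilation/erosion use flat (binary) structuring elements with an
explicit anchor; dilation reflects the SE so that the adjunction and
duality identities hold exactly.  They are implemented as shift-and-reduce
over the SE offsets (a few vectorized maximum/minimum passes), which pins
the anchor convention down unambiguously.  The default SE is the 3x3
square; named shapes and text-file masks (`0`/`1` rows with `*` anchoring)
are accepted.

The five gradient operators difference increasingly smoothed operands:
`P1` (dilation minus closing) and `P2` (opening minus erosion) are
single-stage anti-noise gradients; `P3`–`P5` compose opening/closing before
differencing and are nearly blind to isolated impulses.  Differences are
clamped at zero: the maps are consumed as non-negative edge magnitudes.
`P1`, `P2`, `P4`, `P5` are provably non-negative for an anchored flat SE
(ordering chain `erosion <= opening <= g <= closing <= dilation`); `P3` is
not provably so, and any clamped pixels are counted on the result
(`EdgeImage.n_clipped`).  `P4` is the pipeline default: among the
impulse-robust operators it produced the strongest step response in the
bench grid while sharing their robustness.

## Edge mask and enhancement

"Edge region" membership is not part of the filtering rules and had to be
decided: the default is Otsu's threshold computed on the histogram of
*nonzero* gradient values (zeros would otherwise dominate and drag the
threshold down to the speckle floor), with an all-false mask for an all-zero
gradient and a fixed manual threshold available for deterministic toy
tests.  Enhancement is additive, `out = clip(denoised + gain * edge)` on
the mask, `gain = 1` by default — the minimal reading of boosting the edge
region — and the non-edge region is copied from the denoised image
bit-identically, which the tests assert as exact equality.  The boost may
alternatively be applied on top of the raw input (`enhance_source = raw`);
the default uses the denoised image since filtering precedes enhancement in
the method.

## Quality metrics

`MSE`, `PSNR = 10 log10(G_max^2 / MSE)` and
`SNR = 10 log10(signal power about the reference mean / residual power)`
use base-10 logs and dB semantics throughout.  SSIM is the global
three-factor form — one window spanning the image, population moments —
with standard stabilisers `c1 = (0.01 G_max)^2`, `c2 = (0.03 G_max)^2`,
`c3 = c2 / 2`; with that `c3` the product reduces algebraically to the
familiar two-factor SSIM, which the tests confirm to 1e-10 relative.
Identical images give `MSE = 0`, infinite PSNR/SNR (serialised as the
string `"inf"` in JSON) and `SSIM = 1`; a constant reference with nonzero
residual makes SNR undefined and raises rather than returning `-inf`
silently.  Windowed SSIM is out of scope.

## The synthetic phantom

The generator emulates *displayed* B-mode content, not raw RF: a
piecewise-smooth anatomy layer — mid-gray background (mean 110), dark
elliptical anechoic inclusions (0.3x background), bright curvilinear
interfaces (1.8x background, clipped), and a near-black fan-sector border
(gray ~8) with apex above the top edge — multiplied by unit-mean gamma
speckle of shape `speckle_looks` and quantised to 8 bits.

Defaults (128x128, 3 cysts, 2 lines, `speckle_looks = 64`) are the study
conditions used throughout the tests and the acceptance script.  The look
count deserves a word: single-look intensity speckle has 100 % contrast,
but clinical displays show the residue after spatial compounding, envelope
processing and log mapping — texture standard deviation around 10-15 % of
the local mean, which corresponds to an effective look count of several
tens.  `speckle_looks = 64` (12.5 % contrast) models that display-domain
texture; raw-like speckle remains one parameter away.  Impulse injection
corrupts an exact count `round(density * G)` of distinct pixels (not i.i.d.
Bernoulli) so corruption counts are assertable, and returns the corrupted
mask as detection ground truth.

What passing on phantoms does **not** show: robustness to log-compressed
single-look speckle (looks ~ 1-4 drives the false-positive rate of the
`as_printed` detector up sharply, since speckle extremes then exceed `Q`),
to acoustic shadowing, attenuation or beam-width effects, none of which the
generator models, nor anything about diagnostic value on patient images.

## Benchmark and problem sizes

The benchmark grid is densities {0.05, 0.10, 0.20} x epsilon {1, 2, 4} x
operators {P1..P5} x 20 replicates at 128x128 (900 pipeline runs, under a
minute on one core).  Phantoms are paired across conditions at equal
replicate index, and every seed derives from one base seed via
`SeedSequence`, making reruns bit-identical.  Oracle-equivalence tests use
32x32 images (the brute-force transcription is quadratic and deliberately
slow); algebraic morphology properties use 24x24-64x64 images, sizes at
which the properties are already fully exercised.

One benchmark finding is worth recording: for `epsilon = 1` with the
single-stage gradients P1/P2, enhancement *degrades* mean MSE/PSNR relative
to the noisy input.  The chain is structural — pepper impulses are never
confirmed at `epsilon = 1` (see the detector section), the surviving pepper
rings strongly under P1/P2, Otsu selects those rings, and the additive
boost amplifies them.  The composite operators P3-P5 are immune, and every
`epsilon in {2, 4}` condition improves on all four metrics.  This is a
property of the method's printed equations, not of the implementation (the
filter is bit-identical to its brute-force transcription), and is the
reason the corresponding end-to-end assertion fails for those grid cells.

## Known limitations

- Impulses in perfectly flat regions are left in place (screening-rule
  abstention); cf. the detector section.
- The `as_printed` maximum-case slope makes salt/pepper detection
  asymmetric; the `symmetric` variant removes the asymmetry but is not the
  printed form.
- Only flat structuring elements; no geodesic/reconstruction morphology.
- Global SSIM only; 8-bit depth only; no DICOM or cine loops.
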