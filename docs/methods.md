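# Methods

## Model and scope

A focus measure operator (FMO) maps a grayscale image I(x, y) (x = row
1..M, y = column 1..Nc, intensities nominally 0–255) to a scalar sharpness
value. Applied frame-by-frame to a through-focus stack it yields the focus
curve F(k), k = 1..N (1-based, step distance d between frames). All
evaluation here assumes the curve is unimodal — the imaged object is close
to planar — with a steep region around the peak and near-flat tails. Curves
violating this (multi-peak) fail the segmentation's interval invariant and
raise an error rather than returning misleading metrics.

## Operators

Twelve operators in three families, each implemented as the literal double
sum of its defining formula; boundary pixels outside a stencil's printed
summation range contribute nothing and no padding is used anywhere.

* Spatial: SMD (absolute neighbour differences), Roberts (squared diagonal
  cross differences), Tenengrad (squared Sobel responses over interior
  pixels, kernels applied by correlation — the sign is squared away),
  Brenner (squared 2-row step differences), EOG (squared first differences),
  EOL (squared 4-neighbour Laplacian), SML (absolute row/column second
  differences summed before squaring).
* Statistical: Variance (unnormalized sum of squared deviations from the
  mean gray value), Vollath's F4 (lag-1 minus lag-2 row autocorrelation; the
  only operator that may go negative).
* Frequency: FFT — Σ (u² + v²)·P(u, v) over the centered frequency grid
  u ∈ [−M/2, M/2), v ∈ [−Nc/2, Nc/2), with an unnormalized forward DFT and
  P = |X|²; the DC bin carries weight zero so it needs no explicit
  exclusion. DCT — Σ (u + v)·C(u, v)² with the orthonormal 2-D DCT-II
  (orthonormal chosen because no normalization is canonical and
  Parseval-style magnitudes are then convention-stable). DWT — one-level
  DB6 decomposition; the statistic is the summed squared deviation of each
  detail sub-image (LH, HL, HH) from its own mean.

Index convention: x indexes rows, so Brenner and Vollath's difference along
rows (both are one-dimensional operators by construction). Intensities stay
real-valued throughout; nothing is re-quantized after noise injection.

Wavelet boundary handling is not canonical either; the default is
whole-sample symmetric extension (`mode="reflect"`), configurable through
the PyWavelets mode names. Absolute DWT values shift with the mode; only
relative/ranking behaviour is convention-stable, and that is what the tests
assert across modes.

Useful invariances (all asserted in the suite): every operator except
Vollath's ignores a constant intensity offset; under I → aI all scale as a²
except SMD (a); all twelve decrease monotonically with Gaussian blur width
on a fixed texture.

## Curve segmentation

Both flanks of the peak are scanned with sliding m-point windows
(m ≥ 3, required parameter; 3 suits short or sharply peaked curves, 5–7
longer stacks — the CLI default is 5). Ordinary least squares gives each
window a slope, intercept and residual sum of squares (RSS).

* Steep line: the window in [1, kmax] with maximal slope (left), or in
  [kmax, N] with steepest descent (right). The peak sample may belong to a
  steep window (the tent fixture requires it). Ties — e.g. an exactly linear
  flank — resolve to the window nearest the peak.
* Gradual line: among windows on the same flank sharing no sample with the
  chosen steep window (disjointness keeps the steep flank from
  contaminating the tail fit), minimize RSS, or |slope| with
  `criterion="slope"`. The slope criterion exists because perfectly
  collinear triples give RSS = 0 regardless of their slope, which misleads
  the RSS criterion exactly when m is small; |slope| rather than signed
  slope, since tails fluctuate around zero slope of either sign. Ties
  resolve to the window farthest from the peak.

Cutoffs k_lcp, k_rcp are the abscissae where the steep and gradual lines
intersect; F at the cutoffs comes from linear interpolation of the curve.
The result must satisfy 1 < k_lcp < kmax < k_rcp < N; parallel lines raise a
degenerate-intersection error. Requiring N ≥ 2m + 3 guarantees room for
disjoint window pairs. Both tie rules are deterministic and mirror-
symmetric, so reversing a curve exactly mirrors its segmentation, and the
whole segmentation is invariant under F → aF + b (a > 0) — both properties
are tested on batches of random unimodal curves against an independent
exhaustive window-pair enumeration.

Peak index kmax is the first argmax on ties (deterministic; tie behaviour
has a dedicated check).

## Metrics

* Ws = d·(k_rcp − k_lcp); d omitted → frame units.
* Rsg: numerator 2F(kmax) − min(left steep) − min(right steep); denominator
  the summed max-minus-min of the two gradual regions, all extremes over the
  *integer* samples of the region sets (the definition references curve
  points at named indices, not interpolated values). Region sets:
  left gradual {1..⌊k_lcp⌋}, left steep {⌈k_lcp⌉..kmax}, right steep
  {kmax..⌊k_rcp⌋}, right gradual {⌈k_rcp⌉..N}. Exactly flat tails (tent
  fixture) give a zero denominator and a degenerate-ratio error. When
  N ≤ 2·Ws (frames) a warning — not an error — flags the acquisition
  guideline that the stack should cover more than twice the steep width.
* Cp = |F″|/(1 + F′²)^{3/2} with F′ the central difference over 2d and F″
  the second difference with a **1/d prefactor** — the convention the metric
  was defined with, although a second derivative dimensionally needs 1/d².
  `second_diff_scaling="quadratic"` switches to 1/d²; the default
  reproduces the published convention and the discrepancy is documented
  here. Sp = (2F(kmax) − F(kmax+1) − F(kmax−1))/2d. At d = 1,
  Cp = 2·Sp/(1 + F′²)^{3/2}, hence Cp = 2·Sp exactly at symmetric peaks —
  why Sp's published values run at about half of Cp and Cp has the wider
  dynamic range.
* RRMSE is computed on raw (un-normalized) clean/noisy curve pairs; it is
  invariant under joint rescaling so this equals any consistent
  normalization. For squared-gradient operators AWGN adds a positive bias
  ≈ 2σ² per difference term, which is why RRMSE grows roughly in proportion
  to the noise variance (asserted as a ratio near 2 between variance 10 and
  variance 5).
* FWHM: level is half the *peak value* (not peak minus minimum) — curves are
  max-normalized in the pipeline, and this choice reproduces the NaN
  behaviour of near-flat curves; the first interpolated crossing scanning
  outward from the peak on each side bounds the width, NaN if either side
  never crosses.

Ws, Rsg, RRMSE and FWHM are scale-invariant; Cp and Sp scale with the
curve, so the evaluation pipeline divides each curve by its maximum before
scoring (configurable with `--no-normalize`).

## Evaluation protocol and ranking

Per operator: compute the curve (recording mean per-frame time on a
monotonic clock), RRMSE against the same stack under AWGN (default variance
5), normalize, segment, score. Failures (degenerate ratio, failed
segmentation) are logged and recorded as NaN cells; the report still emits.
Columns are ranked with competition ("1224") ranking — tied values share the
minimal rank, the next distinct value skips — which is the only scheme
consistent with published tables of this benchmark (two tied values at rank
4, next at 6); NaN cells are left unranked rather than ranked last. Smaller
is better for Ws, RRMSE, FWHM and time; larger for Rsg, Cp, Sp. The time
column is hardware-dependent: reported and ranked, never asserted.

## Synthetic data

`generate_focal_stack` emulates a focus sweep of a planar textured object:
a seeded base texture (Gaussian-filtered noise by default; checkerboard and
blob textures available) stretched to the full 0–255 range, blurred per
frame with a Gaussian kernel of width σ(k) = σ_min + r·|k − k0| (truncated
at 4σ, unit sum; σ = 0 is the identity), plus optional per-frame AWGN. The
Gaussian kernel is a generic defocus stand-in, not a calibrated optical
PSF. Defaults — N = 41 frames, k0 = 21, 128×128 texture with correlation
length 1.5 px, σ_min = 0, r = 0.15 px/frame — give a sweep on which all
twelve operators recover the focus frame exactly; r = 0.15 px/frame keeps
adjacent frames barely distinguishable near focus (a fine-stepped sweep),
which also makes the curve top extremely flat, so Cp/Sp are tiny there —
realistic for oversampled sweeps. Noise-robustness checks use a shorter
21-frame, r = 0.3 variant so the curve structure is resolved at smaller
cost. The "variance 5" noise convention is interpreted on the 0–255 8-bit
gray scale (configurable); noise is added to real-valued intensities and
clipped to [0, 255] without re-quantization, preserving the Gaussian model
the RRMSE analysis assumes while respecting the sensor range. One master
seed spawns child streams for texture and per-frame noise, so changing the
noise variance never changes the base texture.

What the generator does **not** emulate: physically calibrated PSFs,
shot/Poisson noise, illumination drift, specimen structure with depth (the
planarity assumption is built in). Passing tests on synthetic stacks
therefore demonstrate the pipeline's correctness and the metrics' stated
invariances, not operator rankings on any particular real specimen.

## Numerical choices and degenerate inputs

* Window ties compare slopes/RSS with relative tolerance 1e-9; intersection
  denominators below 1e-12 (relative) raise the degenerate error.
* Curves need ≥ 3 points (a peak with neighbours) for peak metrics; stacks
  need ≥ 5 frames; segmentation needs N ≥ 2m + 3.
* Peak at the first or last frame → boundary error for Cp/Sp/FWHM.
* Non-positive curve maximum → normalization error; non-positive clean-curve
  mean → RRMSE error.
* Color images are rejected, never silently converted; undersized images
  raise an error naming the operator and its minimum stencil.

## Known limitations

* m is a user choice; automatic selection of the number of fitting points is
  out of scope.
* Wavelet/DCT/FFT absolute values are convention-dependent (boundary mode,
  normalization); conventions are pinned and documented above, and only
  convention-stable quantities are compared across implementations.
* The FWHM comparator fails (NaN) by design on curves that never reach half
  maximum; Ws is the robust replacement.
* Timing columns depend on hardware and vectorization and carry no
  scientific weight.
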