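# Methods

## Scope and model

`parquant` quantifies cortical polarity in single-cell (zygote-stage)
fluorescence microscopy: how strongly a membrane-associated protein is
enriched on one half of the cell, where its domain boundaries lie, how
clustered its cortical population is, and how fast the cortex flows.
The package implements the measurements only; it does not model the
reaction–diffusion–advection dynamics that produce polarity, and its
synthetic generator uses no optics beyond Gaussian blur.

### Membrane profiles

All boundary and asymmetry measurements operate on a *membrane
profile*: intensity along the cell perimeter at normalized arclength
`x ∈ [0, 1)`. Profiles are extracted from midsection images by sampling
a 60-pixel-deep stripe along the local outward normal of a user- or
generator-supplied contour (bilinear interpolation, one row per pixel
of perimeter), then collapsing each row to the mean of the 4 brightest
pixels in the central third of the stripe depth. Cytoplasm and
background levels are estimated from the innermost and outermost sixth
of the stripe; the normalized profile is
`(membrane − background)/(cytoplasm − background)`, which maps pure
cytoplasm to 1 and pure background to 0 and is invariant under affine
intensity transforms of the raw image. The band fractions (central 1/3,
edge 1/6) are configurable; the denominators are smoothed with a
circular moving average (window 5 % of perimeter) before division so
that noise in the context estimates is not amplified.

### Erf boundary models

A domain boundary is modeled as an error-function step,

    I(x) = a + (b/2) · erf(m (x − c))                       (single)
    I(x) = a + (b/2) · [erf(m (x − c1)) − erf(m (x − c2))]  (double)

with `c` (resp. `c1 < c2`) the boundary position in `x` units, `m` the
steepness, and `a`, `b` scale/offset. The argument is written
`m (x − c)` so that `c` is literally the boundary position; with the
alternative grouping `m·x − c` the position would be `c/m`, which
contradicts its role everywhere else in the analysis. `b` is signed:
positive means enrichment inside `[c1, c2]` (a posterior marker),
negative depletion (an anterior marker); swapping `c1, c2` while
negating `b` leaves the model invariant, which is used to canonicalize
fits. The posterior domain center is taken as `(c1 + c2)/2` — the
midpoint — since `(c2 − c1)/2` is half the domain *size*, not a
position.

Domain sizes follow as `posterior = (c2 − c1)/L` and
`anterior = 1 − (c2 − c1)/L` (with `L = 1` for normalized profiles);
they sum to 1 by construction. Segregation efficiency of an anterior
marker is its relative anterior domain size (smaller = more efficient).

**Fitting.** Nonlinear least squares (SciPy trust-region reflective,
tolerances 1e-15) initialized from half-maximum crossings. Circular
profiles are handled by a coarse scan over 8 circular phases, fitting
in each shifted frame and keeping the best residual; boundary positions
map back modulo 1. Single fits fall back to a multi-start over a coarse
grid of candidate positions (both transition directions, three
steepness scales) when the first fit is poor. Flat inputs (range below
1e-8) have no defined boundary and return `converged = False` rather
than raising. Fixed-cell half-profiles are min-max normalized to [0, 1]
before fitting (the convention for multi-channel profile comparison);
live-cell profiles use cytoplasm normalization. Test suites verify that
the optimizer's residual never exceeds a brute-force grid oracle with
the linear parameters solved analytically at each grid node.

### Asymmetry and cluster indices

`ASI = (A − P) / (2 (A + P))` for anterior/posterior measurements A, P
of a feature (membrane or cytoplasm intensity, cross-sectional area, or
punctum density); it is bounded in [−0.5, 0.5] and antisymmetric. Raw
values are divided by the mean raw ASI of the control group, so 1 means
control-like asymmetry and 0 complete loss. Halves are defined by the
perpendicular bisector of the pole-to-pole axis (images) or by circular
distance < 1/4 from the anterior pole (profiles).

The cluster index is the *population* variance of background-
subtracted, mean-normalized intensity in an ROI. Population rather than
sample variance because the index describes the one image, not a parent
distribution; the mean normalization makes it gain-invariant, and it is
offset-invariant whenever the supplied background tracks the offset.

### Punctum detection

A Crocker–Grier-style detector: band-pass (Gaussian smooth at the noise
scale minus boxcar background at the feature diameter), local maxima
above threshold, intensity-weighted centroid refinement in the diameter
window, and greedy merging of candidates closer than half a diameter
(brightest kept). The automatic threshold is mean + 5 sd of the
*unclipped* band-passed image: the zero-clipped image underestimates
the noise spread, and over fields of ~10⁵–10⁶ pixels the maxima of
smoothed Gaussian noise routinely exceed 3–4 sd, so a 3-sd cut produces
large numbers of spurious detections on spot-sparse images. The
sub-pixel centroid uses an intensity-weighted mean rather than a
Gaussian fit, matching the lineage of classic particle-tracking
detectors and keeping the result deterministic.

For density asymmetry the embryo mask is cut at 1/3 and 2/3 of the
pole-axis projection into anterior/middle/posterior regions; the ASI
uses counts per unit area of the anterior and posterior thirds, the
middle excluded (the index compares anterior with posterior). Zero
detected foci yield ASI 0 by convention, with a warning.

### Kinetics

*Total membrane signal*: the stripe is projected along arclength to a
depth profile (background → membrane → cytoplasm), affine-normalized so
the outer edge band is 0 and the inner band 1 (idempotent). A reference
step shape, the pointwise mean over cells with no detectable membrane
signal, is subtracted and the *signed* sum of the difference over the
whole depth is the membrane signal — signed, not positive-part, so that
noise cancels in expectation. Retention measures divide the after-
treatment signal by the before signal; for thin-stripe (4 px)
cytoplasm-normalized profiles the per-cell signal is the sum of
(normalized − 1).

*Flow speed*: a kymograph trace is summarized by the straight line
joining its start and end points; speed = |Δposition|·pixel_size /
(Δtime·frame_interval), reported in μm/min, invariant under time
reversal. Per-embryo speed is the mean over traces, with a warning
below 10 traces.

*FRAP*: mean intensity of a monitoring box per frame, normalized to the
pre-bleach mean only (no whole-cell photobleaching correction — none is
assumed by the measurement). An optional single-exponential fit
`N(t) = plateau − (plateau − floor)·exp(−k (t − t_bleach))` reports the
half-time `ln 2 / k`.

*Retraction* (fixed cells): the marker's posterior boundary is the
intersection of the pole-to-pole line with the line joining the
domain's cortical ends; retraction is the distance from that
intersection to the posterior pole, scaled by pixel size. Parallel
lines raise; intersections outside the pole segment warn.

## Synthetic generator

The generator produces the study conditions every test measures
against, with the generating parameters attached as a `GroundTruth`
record.

* **Midsection**: an ellipse (default elongated, 0.38/0.28 of the frame)
  rendered as a 5-px membrane ring whose per-arclength value is the
  double-erf model, over uniform cytoplasm (100 AU) and background
  (10 AU). Ring pixel lookup uses the nearest point on a densely
  resampled boundary (KD-tree), so the rendered ring agrees with the
  model to well under 2 % after stripe extraction. Arclength zero is the
  posterior pole (rightmost point); the anterior pole is at x = 0.5.
  A 5-px ring (upper end of the 3–5 px range typical of confocal
  midsections) leaves at least 4 uncontaminated membrane pixels per
  arclength column after bilinear straightening; a 3–4 px ring leaves
  the top-4 average visibly diluted by partial-coverage edge pixels.
* **Membrane model defaults**: baseline 120 AU outside the domain,
  amplitude +300 AU inside `[0.3, 0.7]`, steepness m = 30 (a boundary
  width of a few percent of perimeter), chosen to place membrane
  signal a few-fold above cytoplasm as in typical live imaging.
* **Cortical plane**: diffuse level plus `cluster_count` Gaussian spots
  (σ = 2 px, peak 60 AU by default) at uniform positions; optional
  per-third placement weights emulate anterior/posterior punctum bias.
  Overlap is allowed; no spatial statistics beyond uniformity are
  modeled.
* **Kymograph**: linear traces with slope = flow_velocity (default
  7.1 μm/min, the control cortical flow speed) converted through
  pixel_size (0.1 μm) and frame_interval (1 s); traces leaving the
  field are truncated and flagged. True endpoints are recorded so
  measured speeds can be compared to truth exactly.
* **FRAP**: uniform field; at the bleach frame a central 20-px stripe
  drops to a floor (0.2) and recovers as
  `floor + (1 − floor)(1 − 2^(−Δt/half-time))`, so the normalized
  stripe is exactly halfway between floor and 1 one half-time after the
  bleach.
* **Noise**: Poisson on `signal · poisson_scale` photons (disabled at
  scale 0) followed by additive Gaussian read noise (disabled at sd 0).
  Defaults are noiseless; tests add noise explicitly at the SNR they
  probe. Camera parameters are not biologically calibrated — they set
  test SNR only.

What the generator does **not** emulate: real point-spread functions,
membrane curvature effects on the stripe, autofluorescence gradients,
cell-to-cell shape variability beyond the ellipse, or any PAR dynamics.
Passing recovery tests therefore demonstrate correctness of the
measurement code under the stated image model, not robustness to every
artifact of real data.

## Problem sizes and numerical choices

Recovery suites use 256×256 midsection renders (50 embryos for the
end-to-end domain test at SNR 10), 100-profile ladders for the single
fit, 50 instances against the (c1, c2) grid oracle (50×50 grid,
analytic a, b), 20 spot fields of 50 well-separated spots at SNR 10,
and 200 seeded embryos for the 4:1 punctum-bias expectation. The
acceptance script (`scripts/acceptance.py`) re-runs the same
computations at the same or slightly reduced sizes and writes every
measured quantity as JSON. All randomness derives from the `--seed`
argument via `numpy.random.SeedSequence`.

Degenerate inputs are handled as follows: flat profiles → unconverged
fits (NaN boundaries), zero-amplitude domains → size 0/1, empty foci →
ASI 0 with warning, non-positive normalization denominators →
per-position masks with warning (error only when fully masked), zero
before-signal in retention → NaN with warning.

## Interface

The package is a library (like most scientific image-quantification
toolkits); functions and small scripts are the interface. TIFF images
and stacks are read/written with `tifffile`, generator output carries a
JSON sidecar (ground truth, contour, annotations), and tabular results
are plain arrays/dataclasses that convert directly to `pandas` frames.

## Known limitations

* Contours are user- or generator-supplied; there is no automatic
  segmentation.
* Kymograph traces are endpoint annotations; granules are not tracked.
* No model selection between one- and two-boundary fits — the caller
  chooses per assay.
* The double-erf fit assumes a single contiguous domain; multi-domain
  profiles will be summarized by their dominant transition.
* Statistical testing (t-tests etc.) is out of scope; the package
  exports per-embryo values.
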