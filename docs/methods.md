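# Methods

## Scope

`ginkgoflav` implements the standard hyperspectral leaf-analyte workflow —
reflectance calibration, Otsu/EGI segmentation, MSC/SNV/SavGol
pretreatments, Hotelling T² screening, and grid-searched regression of
total flavonoid content (TFC) — together with a synthetic-scene generator
that provides ground truth for every stage.  The wet-lab flavonoid assay
is emulated only as ground-truth values; radiative-transfer leaf optics,
illumination non-uniformity, wavelength selection, and pixelwise TFC
mapping are out of scope.

## Synthetic survey

The generator emulates a survey of 407 leaf groups, 207 lobed (LL) and
200 unlobed (UL), with reflectance over 381.8–1020.5 nm.

**TFC distribution.** Each phenotype draws from a normal(σ = 2.5 mg·g⁻¹)
truncated to [6.1969, 20.5526] mg·g⁻¹, which concentrates the bulk of
mass at 12–15 mg·g⁻¹.  The location parameters are solved (Brent's
method on the truncated-normal mean) so that the *truncated* group means
are exactly 13.5 (UL) and 13.5 + `lobed_tfc_shift` (LL).  A naive
"shift-then-clip" scheme biases the group contrast (the upper truncation
cuts more mass from the shifted group — about 0.13 mg·g⁻¹ at a 2 mg·g⁻¹
shift), whereas solving for the location makes the expected LL−UL
difference equal the configured shift, which is the contract the
phenotype-summary and recovery tests rely on.  The default shift of
1.5 mg·g⁻¹ is a free parameter chosen as a clearly detectable but
overlapping contrast (~0.6 within-group SD); the source observation it
emulates is qualitative (lobed leaves carry more flavonoid).

**Spectra.** A leaf endmember is a fixed vegetation curve — low blue
reflectance, a green peak at 550 nm, a chlorophyll absorption dip at
670 nm, a sigmoid red edge centered at 715 nm rising to an NIR plateau
(~0.4), and weak O–H/water dips at 900/970 nm — plus a TFC-linked
component: Gaussian band weights centered in a 560–620 nm window,
normalized so the window-mean amplitude is exactly
`signal_intercept + signal_gain · TFC` (defaults 0.16 and
−0.004 per mg·g⁻¹: higher flavonoid absorbs more, reflecting less).  The
link is deliberately explicit and configurable — ordinary least squares
of the noiseless window mean on TFC recovers `signal_gain` to 1e−6, which
is the identifiability anchor for the whole pipeline.  Per-band Gaussian
noise of sd `sensor_noise_sd` (default 0.005 reflectance units) is added
to each sample's endmember; optional per-sample affine scatter
(`scatter_gain_sd`, `scatter_offset_sd`, both 0 by default) can be
enabled to give MSC a realistic target.

**Masks.** Leaves are parametric fans opening upward from near the bottom
edge: angular span 1.5–2.0 rad, radius set from a target coverage of
22–42% of the frame, with a low-frequency margin wobble.  Lobed leaves
have 1–3 wedge clefts removed from the margin (depth 40–55% of the
radius), which cannot disconnect the fan.  Coverage is asserted to stay
within 10–60%.

**Scenes.** The raw cube is the exact inverse of the calibration map:
`raw = R·(white − dark) + dark + ε`, with `ε ~ N(0, sensor_noise_sd)`
i.i.d. per voxel.  The white frame sits near full scale (0.98–1.03, a
whiteboard at ~100% reflectance under a mildly banded lamp with ~1%
smooth spatial non-uniformity) and the dark frame near 0.02, so
`white − dark ≈ 1` and raw-intensity noise maps ~1:1 to reflectance
noise.  At zero noise, calibration recovers the assigned reflectance to
machine precision (< 1e−12).

**Gross outliers.** `n_gross_outliers` samples (default 20) have their
endmember shifted by `outlier_shift_sd_multiple` (default 10) times the
per-band cohort SD, with an independent random sign per sample and band.
The random signs matter: if all outliers shared one direction, that
direction would dominate a principal component and the standardized
deviation of each outlier would saturate near √((1−ε)/ε) regardless of
shift size (self-masking), and a non-robust T² screen could not reach
full sensitivity at 5% contamination.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: real leaf optics (the TFC link is imposed,
not derived from pigment absorption), striping/smile artifacts, specular
highlights and shadows, multi-leaf frames, instrument drift between
sessions, and any biology beyond the configured phenotype shift.
Recovery results certify the pipeline's correctness, not field accuracy.

## Pipeline stages

**Calibration.** Elementwise `(raw − dark)/(white − dark)`; references
may be full frames or per-band vectors.  Output is not clipped to [0, 1]:
noise legitimately pushes values slightly out of range and clipping would
bias MSC/SNV.  Pixels with `white − dark < 1e−6` raise an error by
default or become NaN (`mask_degenerate`), excluded from later per-band
means.

**Segmentation.** RGB synthesis bands default to R = 670, G = 550,
B = 450 nm; grayscale uses the 0.299/0.587/0.114 luminance convention.
Otsu thresholds are computed on 256 uniform bins over [min, max] — a
binning choice is unavoidable on continuous reflectance.  Ties in
between-class variance (exact across empty histogram bins) are broken
toward the lowest qualifying bin edge, compared with a 1e−10 relative
tolerance so float noise in the vectorized cumulative moments cannot
scramble the choice; the exhaustive-search oracle applies the same rule
and agreement is then bin-exact.  The gray mask is read as the
*foreground* (above-threshold) region: the literal "background region"
reading would intersect the dark cloth with the green region and be
empty (the `gray_polarity="background"` option keeps that reading
available for exploration).  The intersection is cleaned to its largest
8-connected component; a minimum leaf size of 50 pixels is enforced.

**Pretreatments.** MSC is the canonical form: regress each spectrum on
the reference mean and correct `(xᵢ − bᵢ)/kᵢ`.  (A printed variant that
defines the corrected spectrum from the *fitted* values collapses every
spectrum to the reference and removes all signal; the canonical form is
what matches MSC's stated purpose of removing per-sample scatter.)  MSC
is affine-equivariant — `msc(aX + b) = a·msc(X) + b` — and exactly
idempotent when the reference is held fixed; idempotence under re-fitting
is only approximate because the re-fitted reference shifts by the mean
scaled residual.  In pipeline runs the MSC reference is fitted on the
training split only and reused on the test split (no leakage); a
fit-on-all override exists on the dispatcher, which fits on whatever
matrix it is given.  SNV uses the n−1 denominator.  SavGol defaults to
half-window m = 5 (window 11) and order 2, smoothing only; edge bands
are evaluated from the polynomial fitted to the terminal window
(`mode='interp'`) rather than by padding, because padding schemes break
the defining property that signals of degree ≤ order pass through
unchanged.

**Outlier screen.** PCA (full SVD) on column-centered spectra; retain the
smallest p reaching 95% cumulative variance (capped at n − 2);
`T²ᵢ = Σⱼ t²ᵢⱼ/λⱼ` with λ the n−1 explained variances; control limit
`p(n−1)(n+1)/(n(n−p)) · F(1−α; p, n−p)` with α = 0.05.  All three knobs
are exposed.  The F-based limit is derived for a *new* observation and is
mildly conservative for in-sample points, so the empirical i.i.d. flag
rate sits slightly below α (≈ 0.02–0.03 in the calibration test) — an
accepted property of this classical limit.  Screening happens once on
raw extracted spectra before splitting.  Removal is exact bookkeeping —
retained = n − flagged — and the number of samples a screen flags on
real data is an outcome, not a tunable of the screen: the default
configuration injects 20 gross outliers into 407 samples and the screen
is expected to find them, but nothing forces the flagged count to equal
the injected count.

**Modeling.** The split draws round(0.8·n) training rows uniformly
without replacement (380 → 304/76).  Grids: SVR (RBF) with
C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1, 1}, γ ∈ {scale, 0.01, 0.001};
PLSR components 2–20 (capped by features and fold size); Lasso/Ridge
penalties 10⁻⁴…10⁴ (9 log-spaced); Bayesian ridge and OLS have no grid
(BR self-tunes its hyperpriors by evidence maximization).  Selection is
by 5-fold cross-validated RMSE on training rows, ties to the first grid
point, winner refitted on the full training set.  All bands enter as
predictors; no wavelength selection.  One seed drives scene generation,
the split and the CV shuffle, so a repeated run is byte-identical.

**Evaluation.** R² uses the mean of the evaluated set in its denominator
(test R² uses the test mean).  The best run is the minimal test RMSE,
ties broken by higher test R².  Percent changes are reported against each
family's raw-spectra baseline.  The phenotype contrast is descriptive
only (means, SDs, difference with its standard error).

## Default problem sizes

The default experiment (407 scenes of 64×64×100 bands, 12 model runs)
executes in seconds on one CPU; 100 bands retains the spectral features
at ~6.5 nm spacing while keeping multi-seed recovery studies desk-scale.
The band count is configurable up to the instrument-native resolution.

## Known limitations

- Synthetic spectra are low-rank by construction; model rankings observed
  here (e.g. which pretreatment wins) need not transfer to real surveys,
  where scatter, moisture and cultivar effects dominate.
- The T² screen is non-robust (classical PCA); heavy contamination in a
  shared direction would mask itself.  Robust PCA and Q-residual
  screening are deliberate non-goals.
- Otsu segmentation assumes a single leaf on a dark background; no
  instance separation or shadow handling.
- ENVI I/O covers only the dialect the package writes (BIL, float32,
  band-center wavelengths in the header).
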