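# Methods

This note records the modelling conventions, numerical choices and known
limitations of `nircalib`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Spectra and units

Spectra live on a strictly increasing wavelength grid in nm and are either
reflectance R ∈ (0, 1] or pseudo-absorbance A = log10(1/R) (base-10 log,
the universal NIR convention). Replicate scans are averaged **in
absorbance space**: because the log is concave, averaging in reflectance
and converting afterwards is a different operation (Jensen's inequality),
so `average_replicates` refuses reflectance input and the pipeline fixes
the order convert-then-average.

CSV is the interchange format (wavelength-labelled columns `wl_0900`, …;
floats written with 17 significant digits and parsed with round-trip
precision, so write∘read is the identity). The acquisition mode is
recorded on a leading `# mode=…` line.

## Preprocessing

A math treatment is a scatter correction followed by the four-digit
derivative/smoothing code `d,g,s1,s2`. Conventions the digits alone do
not pin down, chosen once and used by both the implementation and the
test oracles:

* **SNV** z-scores each spectrum with the n−1 SD denominator.
* **MSC** regresses each spectrum on a reference (the mean spectrum of
  the set it was fitted on) and returns (x − a)/b. The fitted reference
  is stored with the model so validation spectra are corrected against
  the *calibration* reference, never their own mean.
* **Detrend** subtracts the least-squares polynomial of order 2 in
  wavelength (order configurable); SNV-DT is SNV followed by detrend.
* The **gap derivative** is the forward difference y[i] = x[i+g] − x[i]
  applied d times; each application shortens the spectrum by g channels.
  Whether the original commercial software differences segment *means*
  rather than single points is not documented; the single-point scheme is
  the simplest reading and is isolated in one function should an
  alternative be needed.
* **Smoothing** is a running mean over the window (the code digits are
  described as "points in an average or smoothing", hence not
  Savitzky–Golay).
* Edges shrink the valid range — no padding, no fabricated data — and
  wavelengths are relabelled to the midpoint of each window, so a code
  `d,g,s1,s2` maps n channels to n − d·g − (s1−1) − (s2−1).

The default candidate grid crosses the 5 scatter options with the codes
{(0,0,1,1), (1,4,4,1), (2,4,4,1), (2,8,6,1), (2,10,10,1)} — 25
treatments.

## MPLS

PLS1 with per-factor residual standardization: after extracting and
deflating each factor, every wavelength column of the spectral residual
matrix is divided by its SD (n−1), so the next factor sees equally
weighted wavelengths. Only the spectral residuals are scaled; the
y-residual is centred once and never rescaled (the "modified" step is
described for the NIR residuals at each wavelength only). X is centred
but not auto-scaled before factor 1; y is centred but not
variance-scaled.

Numerical guards: a residual-column SD below 1e-12 maps to scale 1
(prevents division blow-up on exhausted channels); a weight or score norm
below 1e-12 stops extraction early and flags the model rank-deficient.
With standardization off the algorithm is exactly NIPALS PLS1 (verified
in tests against a loop-level oracle and scikit-learn); at full rank it
reproduces ordinary least squares.

Prediction replays the fit recursion — centring, score projection,
deflation, scaling — so models serialize losslessly to JSON (Python float
repr round-trips doubles).

The factor-count ceiling defaults to min(16, n/3) at the pipeline level;
`fit_mpls` itself only requires n ≥ k + 2 so small exactly-sized problems
remain expressible.

## Outlier elimination

Per pass (at most 2 passes; stops early when a pass removes nothing):

1. **Spectral (H)**: GH = squared Mahalanobis distance in the leading PCA
   score space, divided by the number of components; drop GH > 3. The
   score space is the smallest one explaining 99.6% of variance, *capped
   at 10 components*: smooth NIR spectra concentrate variance in a
   handful of components (4–10 is typical), whereas heavily pretreated
   noisy matrices can spread 99.6% over ~80 near-noise components, which
   both dilutes GH (it divides by the count) and destabilizes the
   covariance. Over a centred calibration set mean GH = (n−1)/n ≈ 1.
2. **Chemical (T)**: T = |y − ŷ_cv| / SECV from grouped cross-validation
   on the current set; drop T ≥ 2.5. Held-out residuals are used so a
   sample cannot mask itself by inflating its own fit. When SECV < 1e-12
   (perfect fit) no T removals are made.

The pass aborts, flagged, rather than trim the set below a refittable
size. Note the H criterion is a *population* criterion: on any spread
composition distribution it flags the most extreme few percent of
samples even on noise-free data — removing a handful of samples from 89
is its expected behaviour, not an error state.

## Cross-validation and ranking

The calibration set is randomly partitioned (seeded) into 6 near-equal
groups; each group is predicted by a model fitted on the other five, at
every factor count. SECV(k) = √(Σ held-out residuals²/n); the chosen
factor count is the argmin with exact ties resolved toward fewer factors.
SEC uses the n − k − 1 denominator; RSQ is the squared Pearson
correlation of reference and fitted values; RPD = SD(y)/SECV with the
retained samples' reference SD (taken from the textual definition — the
tabulated RPDs in the source study are not mutually consistent with any
single SD/SECV column). The applicability range is mean ± 3·SD widened
to include the observed extremes, which reproduces how such tables are
conventionally printed. Treatments are ranked by ascending SECV, ties by
descending RSQ, then declaration order; fold assignment and per-treatment
RNG streams are spawned deterministically from one seed.

## External validation

With residuals e = y_ref − y_pred: bias = mean(e); RMSE = SEP = √(Σe²/n)
(uncorrected); SEP(C) = √(Σ(e − bias)²/(n−1)); paired t = bias/(SEP(C)/√n)
with df = n − 1, two-sided. These definitions make
SEP² = bias² + SEP(C)²·(n−1)/n an exact identity (property-tested).
"Mean residual" is reported as the mean *absolute* residual — on real
validation tables the printed mean residual is close to the RMSE, which a
signed mean would not be — and the signed mean is available as the bias.

## The synthetic generator

`SyntheticConfig` defaults emulate the study conditions: two cultivar
populations (Kennebec n=48: dry matter 19.88 ± 1.63% on [16.0, 22.1],
sugars 0.23 ± 0.09 on [0.15, 0.49]; Agria n=41: 20.19 ± 1.04% on
[17.3, 22.2], 0.15 ± 0.04 on [0.10, 0.37]), 6 replicates per sample
(534 spectra), grid 900 + 6k nm while ≤ 1700 (134 channels; the stated
range/step imply ~134 even though the instrument class carries a 128-pixel
array — the grid is configuration, not a resolved fact), and a 70/19
calibration/validation split.

Reference values are truncated normals drawn by rejection (resample until
in bounds), which honours the printed min/max without distorting the mean
under mild truncation; SD = 0 degenerates to the mean exactly.

Each sample's latent absorbance is a Beer–Lambert-style mixture of
Gaussian bands plus a per-sample linear baseline: water bands near
970/1190/1450 nm tied to moisture (100 − dry matter), carbohydrate bands
near 1200/1580 nm tied to dry matter, sugar bands near 1430/1690 nm tied
to reducing sugars — plausible NIR assignments; nothing in the pipeline's
correctness depends on them. Each replicate is
(1 + s)·latent + offset + channel noise with s ~ N(0, 0.05), offset
~ N(0, 0.01) and iid channel noise N(0, 0.055) in absorbance units.

The channel-noise level is deliberately large for an instrument: it
stands in for everything intact-tuber presentation adds (skin optics,
heterogeneity, positioning) that the band model omits, and it was set so
the cross-validated performance of the default campaign lands in the
mid-range regime the emulated study reports (cross-validated dry-matter
R² ≈ 0.6–0.9, RPD ≈ 1.6–2.6 across seeds) rather than the near-perfect
recovery a noiseless mixture gives. What passing tests show is therefore
that the *pipeline* is correct and well-behaved at realistic difficulty —
not that real tubers behave like Gaussian band mixtures: iid noise has no
wavelength correlation, the baseline is linear, and cultivar differences
enter only through the constituent distributions.

## Determinism

Every stochastic step (reference draws, noise, splitting, fold
assignment, per-treatment RNG streams) flows from explicit seeds or
`numpy` Generators; the same seed reproduces bit-identical spectra and
identical pipeline decisions. `scripts/acceptance.py` derives all its
child seeds from the single `--seed` argument.

## Known limitations

* No radiative-transfer realism; no skin/peel model; no instrument line
  shape. The generator is a structural stand-in, labelled synthetic.
* PLS1 only (one constituent per model); no PLS2, kernel or sparse
  variants; no wavelength-interval selection or calibration transfer.
* The sample-selection step some commercial packages perform via PCA
  distances before calibration is not implemented; splitting is random
  and seeded.
* Whether the original MPLS also standardizes the y-residual per factor
  is undocumented; only X-residuals are scaled here.
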