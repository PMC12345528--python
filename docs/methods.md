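# Methods

This note documents the conventions, defaults, and design choices behind
`fnirscal`: what each stage computes, which decisions were genuinely open,
and what the synthetic data generator does and does not emulate.

## Spectra conventions

Absorbance is `log10(1/R)`; reflectance values ≤ 0 are a hard error naming
the offending sample and wavelength. The default grid is 1100–2498 nm at
2 nm (700 points). Instrument vendors disagree on the exact endpoint
convention for this range, so the grid is a configuration value throughout —
nothing assumes 700 points. Scan replicates (duplicate cup fillings) are
averaged arithmetically per wavelength before any modeling; the replicate
count is kept in sample metadata. The canonical on-disk format is wide CSV
(sample id, then one column per nm); round-trips are exact to 1e-12.

## Preprocessing

**SNV** centres each spectrum and scales it to unit *sample* standard
deviation (ddof = 1); constant spectra are an error. **Detrend** subtracts a
least-squares polynomial baseline in wavelength, degree 2 by default (the
standard SNV-D definition); the fit uses a rescaled-to-[−1, 1] Vandermonde
basis for conditioning, which leaves the residual unchanged. **SNV+D** is
SNV then detrend. **MSC** regresses each spectrum on a reference spectrum
(`x = a + b·ref`) and returns `(x − a)/b`; the reference is the calibration
mean, fixed at fit time and reused unchanged for validation spectra —
slopes below 1e-8 are an error rather than an explosion.

**Gap-segment derivatives** implement the four-digit `d.g.s1.s2` code: two
successive centred running means of widths `s1`, `s2`, then a gap
difference — first derivative `ā(i+⌈g/2⌉) − ā(i−⌊g/2⌋)`, second derivative
`ā(i−g) − 2ā(i) + ā(i+g)`, all in data-point units. The commercial software
that popularised these codes does not document whether it smooths before or
after differencing, or how it treats edges; here smoothing comes first (a
flag reverses it) and edge points with incomplete windows are dropped, with
the wavelength grid shortened (and shifted half a step for even widths) —
padding would invent data. Derivatives are not rescaled by the gap or the
wavelength step: a linear ramp `a_i = m·i` yields the constant `m·g`, a
quadratic `i²` yields `2g²`. The transform is linear, which the property
tests exploit.

Recipes render as `scatter/d.g.s1.s2` (e.g. `SNV+D/2.4.4.1`); scatter runs
before the derivative by default, configurable because conventions differ.

## Calibration engine

PLS1 by NIPALS on mean-centred data. The **modified** variant (default)
divides each wavelength's X-residual column and the y-residual by their
standard deviations after each factor's deflation, before extracting the
next factor — re-weighting later factors toward low-variance residual
structure. With one factor the variants coincide exactly. All stored factor
operations are linear, so the model also exposes an equivalent coefficient
vector and intercept in preprocessed spectral space; predictions replay the
stored weight/loading/scale sequence, which is what the serialization
round-trips bit-exactly (JSON scalars + NPZ arrays).

Cross-validation partitions samples into k = 6 contiguous blocks of a
seeded shuffle. Because NIPALS is sequential, one maximum-factor fit per
fold yields the whole SECV-versus-factors curve by truncation; this is
verified against an explicit leave-one-out refit loop. The selected factor
count is the smallest whose SECV is within 2% of the curve minimum — a
parsimony rule mimicking "fewest factors near the optimum" selection; the
1.02 threshold is configurable. `SECV = sqrt(PRESS/n)` (no degree-of-freedom
correction); `SEC = sqrt(SSE/(n − factors − 1))`.

The calibration/validation split is rank-stratified by default: samples
sorted by analyte value, every 4th rank (for a 75/25 split) held out,
starting inside the range so the extremes anchor the calibration set. A
seeded random split is available.

## Outlier elimination

At most two passes of: fit → flag → remove worst-first → refit. Chemical
outliers satisfy `t = |ŷ − y|/SEC ≥ 2.5` (SEC rather than SECV in the
denominator by default; a flag switches). Spectral outliers satisfy
`GH ≥ 10`, where GH is the squared Mahalanobis distance of a sample's score
vector from the score centroid (covariance ddof = 1) divided by the number
of factors. Cumulative removals never exceed 10% of the original samples;
when more are flagged than the budget allows, offenders are ranked by
`max(t/2.5, GH/10)` and the worst removed first, making the procedure
deterministic and order-independent. A pass that flags nothing ends the
procedure.

A structural caveat the tests document: with heavy *equal-magnitude*
contamination the t-statistic is masked — `Σ(resid/SEC)²` equals the
residual degrees of freedom by construction, so 30% identical gross
outliers each score t ≈ 1.76 and none is flagged. Heterogeneous
contamination (an extreme tier above a moderate tier) is flagged and capped
as intended. This masking is inherent to flag-and-refit schemes, not a
defect of this implementation; robust alternatives are out of scope.

## Figures of merit and model selection

Validation reports bias, bias-corrected `SEP = sqrt(Σ(e − bias)²/(n−1))`
(an uncorrected RMSEP is reported alongside, since published conventions
differ), R² as squared Pearson correlation, the slope of reference on
predicted (the alternate direction is logged too), `RPD = SD/SEP` and
`RER = range/SEP`. Quality classes: *quantitative* needs RPD ≥ 3 **and**
RER ≥ 10; RPD between 2.0 and 2.5 is *acceptable quantitative*; any other
RPD ≥ 2 is *screening*; below 2 is *unreliable*. A zero SEP yields infinite
ratios with a warning rather than an error.

The grid search screens the four scatter corrections × four math treatments
(`1.4.4.1`, `2.4.4.1`, `1.5.5.1`, `2.5.5.1`) through the full pipeline —
split, outlier passes, CV factor selection, external validation — and ranks
by (R²_CV desc, SECV asc, factors asc); a recipe that fails contributes an
error row, never a crash.

## Digestibility

`DMD = 1 − diet/excreta` on matched units and basis. Oxide doses convert to
element basis with standard atomic masses (Ti/TiO₂ = 0.59943,
2·Yb/Yb₂O₃ = 0.87822, documented to four decimals); mixed-basis ratios are
refused because published tables are often ambiguous about element-vs-oxide
reporting. Negative DMD (excreta concentration below dietary) is returned
with a warning — it signals incomplete marker recovery or a unit error, and
silently clipping it would hide exactly the problem a practitioner needs to
see. Cross-marker agreement is the pairwise squared Pearson correlation of
per-sample DMD on complete cases.

## The synthetic generator

The generator provides data with the statistical structure the analysis
assumes, not a physical simulation:

- **Truth process.** Each sample draws DMD from a normal (mean 0.74,
  sd 0.03) truncated by rejection to (0, 0.95); a redraw rate above 1% is
  warned about. Excreta marker concentrations follow the mass balance
  exactly — `diet/(1 − DMD)` — so the DMD round-trip is exact to machine
  precision and, at the default dispersion, marker concentrations inherit a
  ~11% coefficient of variation (the error-propagation factor
  sd/(1 − DMD) ≈ 0.03/0.26).
- **Spectra.** Beer–Lambert mixtures of Gaussian absorption bands on a
  gentle sloped baseline: a six-band organic excreta matrix (C–H, O–H,
  starch/protein positions between 1210 and 2310 nm) whose amount varies
  ~5% between samples; marker *organo-complex* signature bands scaled by
  concentration (free mineral ions barely absorb in the NIR — detectability
  rests on complexes with organic ligands, which is what the small
  signature bands near 1680/2180 nm for Ti and 1560/2050 nm for Yb stand
  for); and a PEG component with sharp, intense bands (16–20 nm widths,
  peak heights to 1.25 AU at 1190/1730/1935/2270 nm) as befits a pure
  crystalline polymer against a broad biological matrix — sharpness
  matters, because gap-segment derivatives strongly attenuate broad
  features.
- **Artifacts.** Per-sample affine scatter — gain U(±5%), offset
  U(±0.02 AU), linear tilt U(±0.01 AU across the grid) — applied after
  mixing, then white absorbance noise (default sd 5e-4 AU) last, mirroring
  the physical measurement order. These are exactly the distortion family
  SNV/detrend/MSC are designed to remove; no particle-size or
  radiative-transfer physics is modeled.
- **Spiking design.** The PEG calibration generator mixes a pooled base
  excreta profile with a PEG spectrum at mass fractions 0–15% in 1% steps,
  duplicating the eleven lowest levels to reach 27 samples (densest support
  at low PEG, where excreta predictions live); the plan is configurable,
  including larger totals by cycling through the levels.

What passing tests on this generator show: the pipeline recovers known
truths through realistic affine artifacts and noise. What they do not show:
performance on real excreta, where scatter is wavelength-dependent,
moisture and particle size interact with chemistry, and marker–matrix
associations are weaker and diet-dependent.

One behaviour worth knowing when interpreting results at full artifact
amplitude: scatter corrections that divide by a per-sample scalar (SNV's
standard deviation, MSC's slope) interact with the additive tilt so that
the analyte signal acquires a small multiplicative error no linear model
can remove; the best recipes on such data are the plain-detrend ones, and
cross-validated R² for the mineral markers settles around 0.89–0.95 — the
same order as published fecal-NIRS marker models. The low-noise parameter-
recovery test therefore uses negligible detector noise (1e-5 AU) with
scatter at half amplitude, isolating pipeline correctness from that
irreducible artifact term while still exercising every correction.

## Problem sizes and determinism

Default study sizes mirror the intended application: 192 excreta samples
(144/48 split) and 27 fortified PEG samples; unit and property tests use
20–60-sample problems, which exercise every code path at interactive speed.
All randomness flows through `numpy.random.default_rng` seeds carried in
the configs; the same config and seed reproduce every artifact, including
CSV outputs, byte for byte.
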