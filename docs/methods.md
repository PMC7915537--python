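# Methods

This note documents the models, conventions and numerical choices
behind `meiboquant`, and what the synthetic-data conditions do and do
not establish about real measurements.

## Scientific setting

Meibum — the lipid secretion of the Meibomian glands that forms the
outer layer of the tear film — is dominated by wax esters (WE) and
cholesteryl esters (CE) with very long fatty-acid chains, with smaller
amounts of free cholesterol (Chl), triacylglycerols (TAG) and
cholesteryl esters of (O)-acylated omega-hydroxy fatty acids
(Chl-OAHFA).  When CE biosynthesis is arrested (as in mice lacking the
cholesterol acyltransferase SOAT1), free cholesterol accumulates,
meibum stiffens and melts at much higher temperatures, and the eye
opening narrows to a slit.  The package implements the quantitative
workflow used to characterize such phenotypes: exact-mass channel
definition, extracted-ion-chromatogram (EIC) quantitation with
response-factor calibration, thermotropic (melting-curve) analysis,
and eye-opening morphometry — all exercised end to end on synthetic
data with known generative truth.

## Exact masses and detection channels

Monoisotopic masses are sums over a fixed atomic-mass table
(C = 12 exact, H = 1.00782503207, O = 15.9949146196, N = 14.0030740048,
Na = 22.9897692809, K = 38.96370668 Da).  Cation m/z values are formula
sums: the electron mass (~0.55 mDa) is deliberately not subtracted,
matching the convention in which the sterol fragment C27H45+ is quoted
as 369.3521.  In positive-mode APCI all sterol lipids share this
analytical ion — water loss from protonated cholesterol, fatty-acid
loss from CE and Chl-OAHFA — so one EIC channel at m/z 369.35 monitors
the whole sterol pool, with species resolved chromatographically.
WE and TAG are monitored as proton adducts.  EIC windows are 50 mDa
*total* width (±25 mDa); the literature phrase "a 50 mDa window" is
ambiguous, so the width is configurable.

Retention times are anchored on a standard mix (Chl 6.93 min,
cholesteryl oleate 21.03 min, cholesteryl nervonate 28.48 min, triolein
18.64 min, lignoceryl oleate 22.35 min) and extended across CE homologs
linearly in *equivalent chain length* (ECL = fatty-acid carbons − 2 per
double bond, ~1.24 min per ECL unit).  One reverse-phase double bond
offsets two methylenes, so Cn:0 co-elutes with C(n+2):1; reporting
labels therefore group these pairs (e.g. "C26:0/C28:1-CE"), matching
routine profiling output.  On proton-adduct channels assignment is
m/z-driven with a wide elution band; on the shared fragment channel it
is retention-time-driven with ±0.5 min windows.

Known inconsistencies are kept visible rather than resolved: the
computed WE 42:1 adduct (619.6393) differs in the fourth decimal from
some quoted values (619.6389/619.6367), and the Chl-OAHFA formula sum
(1100.036) differs from the quoted 1100.02 by ~16 mDa.  The registry
always stores formula-derived values.

## Synthetic chromatograms

The generator is the package's source of ground truth.  Each species
elutes as a Gaussian (σ = 0.1 min) at its registry retention time; the
integrated area is molar amount × per-species response × a global
signal scale (10⁴ counts·min per molar unit).  A species' total
response is split between the sterol-fragment channel and the proton
adduct by a *fragment yield*: 1.0 for Chl (detected only as the
dehydrated fragment), 0 for WE/TAG, and for CE the split that gives a
sterol-channel response interpolated linearly in ECL between the
calibration anchors (cholesteryl oleate 2.21, cholesteryl nervonate
2.41, relative to Chl = 1.00) with unit adduct response.  Every
registry channel carries a flat chemical baseline (50 counts);
centroid m/z values get Gaussian jitter (SD 3 mDa, within the stated
3–10 mDa mass accuracy); intensities get multiplicative Gaussian noise
(CV 2% by default).  All randomness flows from one integer seed.

Composition presets encode the headline statistics of each genotype as
generative truth:

* `wild_type` — free cholesterol exactly 7% of the sterol pool
  (Chl + CE); all 50 CE (C10–C34, 0–1 double bonds) present with a
  smooth unimodal ECL profile (Gaussian in ECL, mode 23, SD 5, 80%
  monounsaturated); molar class split Chl 2.33 / CE 31 / WE 58 /
  TAG 8.67 (percent).  The class split approximates graphical data and
  is documented as an approximation, not a quoted number.
* `het` — identical to `wild_type` (partial enzyme loss does not change
  the lipidome detectably).
* `soat1_null` — no CE with fatty acids above C20; C16–C20 CE at 10⁻⁶
  molar units (orders of magnitude below the quantitation limit);
  cholesterol dominant (33% of total lipid); apparent TAG share roughly
  doubled (17%); WE 50%.
* `standard_mix` — equimolar Chl, cholesteryl oleate, cholesteryl
  nervonate, triolein and lignoceryl oleate with the embedded
  1.00/2.21/2.41 sterol-channel responses.

What the generator does *not* emulate: isotopic envelopes, ion
suppression and matrix effects, retention drift between runs, peak
tailing, chimeric spectra, and profile-mode data.  Passing recovery
tests therefore demonstrates that the quantitation chain is
self-consistent and unbiased under idealized Gaussian-peak conditions,
not that it is robust to every artifact of real acquisitions.

## EIC quantitation

Peak processing, per channel: baseline is a 2-min morphological
opening (erosion then dilation).  A rolling median was rejected
because, with CE homologs eluting every ~1.24 min, more than half of a
2-min window lies on Gaussian tails and the median rides up by ~1% of
peak height; the opening passes under periodic peaks and keeps the
noise-free round trip exact to ~10⁻⁷.  Noise is 1.4826 × MAD of the
baseline-subtracted trace.  Apexes are detected on a lightly smoothed
copy (Gaussian, 1/5 of the 0.5-min minimum peak separation) so
intensity noise cannot split one elution peak into several maxima;
integration is trapezoidal on the raw subtracted trace between
boundaries that descend the smoothed flanks to the noise floor and
never cross the valley between adjacent apexes.  S/N is apex height
over noise; the default lower limit of quantitation is S/N 10.

Calibration reads the three sterol standards off the fragment channel
and the WE/TAG standards off their adduct channels, all as area ratios
to Chl.  CE response factors between the two calibrated chain lengths
are interpolated linearly in ECL and clamped outside — the same
convention the generator embeds, so noise-free round trips recover
molar ratios exactly; with 2% intensity noise, recovered factors are
within ~1.5%.  WE and TAG carry unit (apparent) responses where no
standard exists, so class balances are "apparent" balances.

The cholesterol share of the sterol pool is reported as
100 × Chl/(Chl + CE) — bounded at 100%, consistent with both a "7%"
normal value and a ">99%" CE-free value.  CE peaks below the LLOQ
contribute zero.  Group comparison uses Welch's unequal-variance
two-sided t-test, pairwise, without multiplicity correction (matching
how such cohorts are conventionally reported).

## Melting curves

Birefringence loss during heating follows a two-transition Hill model

    I_br(T) = A − B·T^k/(T1^k + T^k) − C·T^m/(T2^m + T^m),   T in K.

A is the fully crystallized birefringence (1 when normalized), B and C
the contributions of the low- and high-melting liquid-crystal forms or
domains (whether they are aggregation states or compositional domains
is left open), T1 < T2 the transition temperatures, k and m unitless
Hill cooperativities.  Each term is evaluated as B·expit(k·ln(T/T1)) —
algebraically identical but finite for any cooperativity, which
matters because healthy meibum has k ≈ m ≈ 120 and T^120 overflows
double precision.  The naive ratio form is kept only as a test oracle.

Reference parameter sets: CE-deficient meibum T1 = 304 K, T2 = 359 K,
k = 39, m = 29; healthy meibum T1 = 289 K, T2 = 307 K, k = m = 120.
B and C are not reported anywhere; simulations use B = C = 0.5 with
A = 1 (a normalized curve melting fully from 1 to 0).  Note this
equal-split assumption fixes the 50%-melt temperature roughly midway
between T1 and T2 (297.9 K for the healthy parameter set); a reported
"50% melted around 34 °C" for healthy meibum would imply C > B.  Since
B and C are unconstrained by any printed value, the symmetric choice is
used and only T1, T2, k, m are treated as recoverable truth.

Fitting is bounded trust-region least squares (`scipy.optimize
.least_squares`, ftol 1e-10, up to 10 000 evaluations) with k, m
optimized in log-space over [1, 500] and T1, T2 over [200, 500] K.
Auto-initialization takes A from the curve maximum, T1/T2 from
mechanism-free spline transitions (below; quantile fallback),
B = C = half the curve span, k = m = 30.  If the optimizer crosses the
transitions, (T1, k, B) and (T2, m, C) are swapped post hoc so results
always satisfy T1 < T2.  Non-convergence sets a flag instead of
raising.  r² = 1 − SS_res/SS_tot.

Spline transition detection fits a smoothing spline with
GCV-selected penalty (`make_smoothing_spline`), evaluates its analytic
first derivative on a dense grid, and reports local minima (steepest
descent) above 25% of the strongest descent — a mechanism-free
cross-check on the Hill fit.  The 50%-melt temperature solves
(A − I(T))/(B + C) = fraction by bracketed bisection on the monotone
model.

Simulation-and-refit conditions used by the tests and the acceptance
script: 150 evenly spaced points over −25…+125 °C, Gaussian noise
SD 0.01, 20 replicate seeds, medians reported.  Under these conditions
transition temperatures are recovered within a fraction of a Kelvin
and cooperativities within a few percent.

## Morphometry

The eye opening is treated as an ellipse with measured semi-axes
a ≥ b; the package computes the eccentricity e = √(1 − (b/a)²) and the
axis ratio b/a (e² + (b/a)² = 1, both scale-invariant).  A ratio of
0.38 (slit-like) gives e = 0.92; 0.85 (healthy) gives e = 0.527.  Note
that a healthy-eye e quoted as ≈0.57 elsewhere is not exactly
consistent with ratio 0.85; only the self-consistent 0.38/0.92 pair is
used for validation.  Ellipse *fitting* from images is out of scope —
inputs are measured axes.

## Problem sizes and determinism

Chromatogram simulations use a 0–46 min grid at 0.02 min (2301 scans,
~60 centroids each); melting analyses use 150-point curves with 20
replicate fits per condition; the full test suite and the acceptance
script each run in well under a minute.  Every stochastic step takes an
explicit seed and identical seeds yield byte-identical serialized
outputs.

## Known limitations

* Quantitation is relative (molar ratios, normalized profiles); no
  absolute mol-per-sample scale.
* Only 0–1 double bonds per CE chain; no polyunsaturated, branched or
  oxidized species; no isotope correction.
* The ECL retention model is linear by construction; real gradients
  curve at the extremes.
* WE/TAG class shares are apparent (unit response) unless calibrated.
* mzML support covers centroided MS1 spectra (64/32-bit, optional
  zlib); profile spectra are rejected.
* The melting model is agnostic about the physical identity of the two
  components; B and C are not identifiable from a single normalized
  curve beyond their sum and split.
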