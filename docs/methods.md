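# Methods

This note records the models implemented, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## NIR calibration

### Pretreatment

*Savitzky–Golay* is a local polynomial least-squares convolution. Defaults:
window 11 points (77 nm on the 7 nm grid), polynomial order 2, derivative
order 0 — wide enough to suppress detector noise without flattening the
~50–100 nm-wide combination bands of the short-wave NIR. Derivatives are
scaled by the grid step, so order 1 is in absorbance per nm. **Edges** are
handled by refitting the polynomial on truncated windows (clipped at the
spectrum ends, widened to polyorder+1 points when necessary) rather than by
padding: padding fabricates absorbance values, and for 115-point spectra the
ten affected points are a material fraction of the grid.

*SNV* centres each scan to mean 0 and scales to sd 1, using the sample
(n−1) sd — the dominant chemometrics convention, fixed here so tests can be
exact. SNV is invariant to per-scan affine transforms with positive slope,
which is precisely the additive-baseline + multiplicative-scatter model it
exists to remove. A constant scan carries no scatter information and is
rejected by name.

The default chain is smoothing then SNV (`"sg,snv"`); on the synthetic data
the two orderings are practically indistinguishable, matching the common
observation that smoothed and SNV-treated spectra lead to similar
calibrations. The chain is fully configurable from the CLI.

### Models

*PLS1* is fitted by sequential NIPALS: on centred X and y, each latent
variable takes the weight vector w ∝ X'y (maximising covariance), scores
t = Xw, loadings p = X't/t't, q = y't/t't, then deflates X ← X − tp' and
y ← y − qt. The regression vector B = W(P'W)⁻¹q reproduces the scores-path
prediction exactly, and the deflated X after k components is orthogonal to
all extracted weights (both are asserted in tests). *PCR* regresses y on the
first k principal-component scores of centred X (SVD), components ordered by
explained variance with the sign convention "largest-magnitude loading
element positive" for bit-reproducibility.

X is centred but not autoscaled — SNV has already put every scan on a common
scale, and autoscaling NIR wavelengths inflates noise-only channels. y is
centred only.

**Rank handling.** Closure-constrained mixture data (compositions summing to
100 %) has centred rank one less than the number of components, so a
five-nutrient noise-free dataset supports only four latent variables. The
structural bound k ≤ min(n−1, p) is enforced as an error; *numerical* rank
exhaustion is handled gracefully: NIPALS stops early once the response is
fit to machine precision (recording the achieved component count), and PCR
truncates to the effective rank with a warning. This lets "fit with k = 5"
mean "fit with up to 5" on data that exactly satisfies the model, while
still failing loudly when a user requests more components than samples.

### Validation metrics

With residuals r on a subset of n samples:

* RMSE-type statistics use divisor n: RMSE = √(Σr²/n).
* SE-type statistics are the bias-corrected spread after removing mean bias:
  SE = √(Σ(r − r̄)²/(n−1)).

Published calibration tables print both without defining the difference;
these formulas make the reports unambiguous (the two agree when the bias is
zero and n is large). R² = 1 − SS_res/SS_tot and can be negative for models
worse than the mean — useful in permutation checks.

The split design: `n_holdout` samples drawn at random under an explicit,
mandatory seed form the prediction set, giving RMSEP/SEP/R²P and
RPD = sd(holdout reference, n−1) / SEP. Cross-validation statistics
(RMSECV/SECV/R²CV) come from k-fold CV (default 10 folds) or leave-one-out
on the *calibration* subset. Reporting both resolves the common ambiguity
over whether "SECV" was computed on CV folds or on the holdout — here it is
always the former, and the holdout metrics are always the latter.

The number of latent variables is chosen by the RMSECV minimum, ties broken
toward the smaller k (`select_components`); published nut-composition
calibrations rarely state k, and the CV minimum is the standard defensible
choice.

RPD banding defaults: ≥3 excellent, 2–3 very reliable, 1.5–2 limited, <1.5
unreliable. Published band limits disagree with each other (some sources
give "2.5–5 limited", overlapping "2–3 very reliable"); the thresholds are
therefore a configurable argument, and the defaults are the non-overlapping
reading that reproduces the usual qualitative calls.

## NMR fatty-acid classes

The four class equations (README) are an exact linear system in the integral
ratios B/(A+B), E/D, C/(2D); their sum telescopes to 100 for *any* valid
integrals, which is both a correctness check and the reason the inverse map
exists. `integrals_from_profile` inverts them by choosing D = scale and
A+B = D; the forward∘inverse round trip is the identity to 1e-12 and is
property-tested over 1000 random profiles.

Whether integral E is best assigned to the olefinic or the bis-allylic
region is spectroscopically ambiguous; the implementation fixes only the
algebra (E/D enters ω6 and ω9 identically under either assignment given the
stoichiometry used), and both readings are compatible with the code.

Slightly negative class percentages — possible with noisy experimental
integrals — are clamped to 0 with a warning and the profile renormalised to
close at 100, rather than raised, so batch processing survives bad scans.
The ω6:ω3 ratio is reported as `None` when ω3 = 0, never as infinity.

NMR-derived and GC-derived class percentages are *not* asserted equal
anywhere: on real data the two methods correlate strongly but imperfectly,
so only rank-order sanity on synthetic data (where both derive from one
truth) would be a fair check.

## Proximate formulas

Kjeldahl nitrogen uses the atomic mass 14.007 g/mol and reports % of sample
mass; a sample titre below the blank yields a negative value that is warned
about but not clamped (clamping hides titration errors). The
nitrogen-to-protein conversion factor defaults to 1.0 — i.e. the nitrogen
percentage is reported directly, as some composition tables do — with the
conventional 6.25 available as an argument; the choice is explicit because
the two conventions differ by a factor of 6.25 and silently mixing them is a
classic unit error. Carbohydrate by difference closes the budget exactly;
a negative carbohydrate (inputs summing over 100 %) warns rather than
raises, again to let batch replicate processing continue.

## Chromatographic quantification

Standard curves are unweighted ordinary least squares, matching the single
R² usually quoted for such calibrations. The ELSD's physically power-law
response is deliberately modelled as linear over the fitted 100–1200 ppm
range — the documented simplification that linear published calibrations
imply — with a log-log option for when curvature matters.

Peak assignment is nearest-library-analyte within a retention-time tolerance
(default 0.15 min; the closest pair in the sugar library, sorbitol and
galactose, are 0.85 min apart, so any tolerance below 0.425 min is
unambiguous and larger tolerances are rejected at configuration time). Two
peaks never share an analyte: the nearer wins, the other stays unassigned.

Unit conversion: ppm (mg/L) in the extract × volume (L) × dilution / sample
mass (g) × 100 gives mg/100 g; the oil basis multiplies by 1000 to report
µg/100 g. Back-calculated concentrations below zero are flagged and reported
as 0; concentrations outside the fitted standard range are flagged as
extrapolated but still reported. Extraction recovery is assumed 100 % (no
recovery factor is applied).

## Replicate statistics

Means use the sample (n−1) sd. One-way ANOVA is classical (scipy); the
degenerate all-identical case reports F = 0, p = 1. Pairwise comparisons
default to Tukey's HSD (family-wise control over all pairs), with unadjusted
two-sample t tests as an option — published seed/nut tables rarely name
their post-hoc test, and the scattered "no significant difference" claims
cannot disambiguate, so the conservative default is used. In the assembled
report a cell is starred when its sample differs significantly from **every**
other sample for that analyte; "nd" (not detected) cells propagate as
absent — excluded from means and comparisons, never imputed as zero.

## Synthetic data

The generator defines the study conditions the tests run under:

* **Compositions** — oil, moisture, ash, protein uniform within per-nutrient
  ranges, carbohydrate as the closure term (rejection-sampled into its own
  range). The packaged `STUDY_COMPOSITION_RANGES` span the observed extremes
  of a six-sample seed/nut panel (oil 0.2–61 %, moisture 3–14.4 %, ash
  1.7–5.2 %, protein 15.5–48 %, carbohydrate 12.4–63.7 %).
* **Spectra** — each scan is Σ (fraction/100 × pure-component spectrum) ×
  (1 + scatter) + baseline line + additive noise. Pure components are sums
  of Gaussian bands (default sigma 25 nm, amplitude 1) centred at the
  wavelengths where each nutrient's published regression coefficient peaks:
  oil 929/1039/1208/1386/1700 nm, moisture 977/1107/1338/1473 nm, ash
  1149/1305/1411/1494 nm, protein 1153/1308/1411/1494/1673 nm, carbohydrate
  929/1007/1211/1442/1584/1692 nm. Noise defaults (baseline offset sd
  0.01 AU, slope sd 1e-5 AU/nm, scatter sd 5 %, additive sd 0.005 AU) are
  typical handheld-NIR magnitudes, chosen once. 18 replicate scans per
  sample, averaged before calibration.
* **NMR integrals** — exact inversion of the class equations (no noise model
  of its own; noise studies perturb the integrals directly).
* **Standard series** — linear response plus Gaussian noise.

What it does **not** emulate: wavelength-dependent pure-component shapes
beyond Gaussians, band interactions/nonlinearity (water activity shifts,
temperature effects), correlated instrument drift across replicates, NMR
phase/baseline errors, or ELSD curvature. Passing tests therefore show the
*arithmetic and algorithms* are right under the stated statistical model;
they do not certify performance on any particular real instrument.

The grid is 900 + 7k nm, k = 0…114 (115 points, last point 1698 nm): a
closed 7 nm-bandwidth grid cannot land on 1700 exactly.

All randomness flows through explicit integer seeds (numpy `default_rng`);
there is no global random state, and fixed seeds give bit-identical outputs.

## Problem sizes

The default test and acceptance runs use 140 samples × 18 replicate scans ×
115 wavelengths for the full pipeline, 40–60 samples for property checks,
1000 Monte-Carlo seeds for the standard-curve R² check, and 2000 simulations
for the ANOVA type-I rate — sizes at which every stochastic assertion is
stable across seeds while the whole suite runs in seconds.

## Known limitations

* PLS is univariate-response (PLS1) only; multi-nutrient fits loop.
* No wavelength-interval selection, outlier/leverage diagnostics, or
  instrument-transfer correction.
* The chromatography layer starts from integrated peak areas; no raw-trace
  peak detection or MS/MS spectral matching (the resveratrol MRM identity,
  precursor 227 m/z → fragments 143/185 m/z, is carried as metadata only).
* The linear ELSD model under-predicts at range extremes when the true
  response is power-law; use the log-log option there.
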