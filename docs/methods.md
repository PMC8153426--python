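# Methods

This note records the statistical models behind each module, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical decisions a maintainer would want
written down.

## Dilution-plating CFU estimation

A sample is serially diluted 1:10 to 10⁻⁶ and fixed-volume spots
(default 10 µL) are plated at every dilution.  Colony counts are
modeled as Poisson with mean λ·v·d (density × volume × dilution
fraction).  The estimator anchors on the most dilute spot whose count
falls in the countable range (default 3–150 colonies per 10 µL spot;
"countable" has no universal definition, so the range is a parameter)
and pools it with its more dilute neighbour — or with its less dilute
neighbour when the anchor is already the last spot, so the pooled pair
is always the two highest dilutions around the countable endpoint:

    CFU/mL = (c_a + c_b) / ((d_a + d_b) · v)

For adjacent tenfold dilutions d_a + d_b = 1.1·d_a, the familiar
"divide by 1.1 times the less dilute dilution" rule.  Crucially, pair
membership never conditions on the more dilute spot's own count; a
selection rule that requires both spots to be in range truncates the
Poisson tail of the high-dilution spot (E[c | c ≥ 3] > E[c] when
E[c] ≈ 2) and inflates the estimate by ~2.5% at the standard geometry.
With the anchor-and-neighbour rule the estimator is exactly unbiased,
which the test suite verifies over 1,000 simulations.

Low-count series with no in-range spot pool **all** numeric spots
(Σc / (v·Σd)), which remains unbiased; all-zero series are censored
(reported as 0, flagged, interpreted against the detection limit
downstream).  A `literal_1p1_multiplier` flag reproduces the
multiply-by-1.1 phrasing found in protocol write-ups; it scales every
estimate by the constant 1.21, so frequency ratios are unaffected.

Replicate pooling is the arithmetic mean with sample SD (n−1);
censored members enter as 0 with a propagated flag.

## Tolerance distributions

Tolerance frequencies are CFU(c)/CFU(0 mM), with the baseline taken as
the mean over 0 mM replicates; per-concentration dispersion is the
sample SD of replicate frequencies.  The limit of detection of the
plating assay is ceil(1/(v·s)) CFU/mL (34 for 3 × 10 µL); the
corresponding minimum frequency divides a threshold density by the
population density.  Because 1/(v·s) = 33.3 is not an integer, the
frequency basis is a parameter (`unrounded`, `floor`, `ceil`); the
default `floor` gives 33/2×10⁸ = 1.65 × 10⁻⁷ at the standard
population density, the convention used in published figures.

The decline slope is OLS of log₁₀(frequency) on concentration over a
declared point-selection rule: `last_k_nonzero` (k = 4 default) for
curves that fall below detection, `last_k` for curves that stay
measurable.  No changepoint detection is attempted — the selection rule
*is* the analysis choice, and it is recorded in the fit.  Slopes are
compared with a two-sided Welch *t* on independent OLS slopes,
t = Δb/√(se₁² + se₂²), with Welch–Satterthwaite degrees of freedom
from each fit's residual df.  With two 4-point fits the reference
distribution is heavy-tailed (df ≈ 4); the simulated type-I error at
α = 0.05 sits in [0.03, 0.07].  Exact (zero-SE) fits degenerate to
p = 1 for equal slopes and p = 0 with a warning otherwise.

## Competition fitness

W = ln(F₁E/F₀) / ln((1−F₁)E/(1−F₀)) with E the assumed fold expansion
(64 for methanol competitions, 32 under formaldehyde).  W is
independent of the log base, equals 1 exactly when F₁ = F₀, and is
undefined at fixation — fractions of exactly 0 or 1 raise a
censored-competition error rather than being pseudo-counted.  The
fluorophore sits on the reference strain by default
(`test_is_nonfluorescent=True`), so test-strain fractions are
complements of the fluorescent fractions.  Fewer than 1,000 events
warns (the assay's counting floor); a fraction within 0.5% of fixation
warns.  A configuration in which either strain's implied fold change
is ≤ 1 raises a domain error: the formula presumes net growth of both
populations.

## ITC: single-set-of-sites isotherm

The cumulative heat after injection *i* is the Wiseman one-site
isotherm

    Q_i = (n·Mt_i·ΔH·V₀/2) · [1 + r + k − √((1 + r + k)² − 4r)]

with r = Lt/(n·Mt), k = K_d/(n·Mt), and displaced-volume–corrected
running totals Mt_i = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀),
Lt_i = L_syr(ΔV/V₀)(1 − ΔV/2V₀) — the convention of commercial ITC
software.  Per-injection heats add the perfusion term
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.  Heats are handled
in µJ; ΔH is reported in kcal/mol (1 cal = 4.184 J).  The first
(0.3 µL throw-away) injection is generated and displayed but never
fitted.  Blank (buffer:ligand) heats are subtracted per injection with
strict unit checking — no silent µcal/µJ conversion.

Fitting is nonlinear least squares with data-driven starting values
(tight-binding ΔH from the first fitted heat; stoichiometry from the
molar ratio at the steepest heat change when the titration saturates)
and a small multistart over K_d decades, which makes the noise-free
round trip exact to ≳6 significant figures across tight- and
weak-binding designs.  At the standard formaldehyde protocol (20 × 2 µL
of 25 mM ligand into 400 µL of 50 µM protein, K_d ≈ 8 mM) the Wiseman
parameter is c = n·M₀/K_d ≈ 0.006.  In this low-c regime n is not
separately identifiable and is fixed at 1 for noisy fits, the standard
calorimetric practice; K_d and ΔH remain strongly anti-correlated
(ρ ≈ −0.99), so single-titration ΔH estimates scatter with
SD ≈ 2.3 kcal/mol per µJ of injection noise (the Cramér–Rao floor,
which the fitter attains).  Medians over replicate titrations are
unbiased; individual fits at realistic noise are not precise to within
±1.16 kcal/mol, and no estimator can be at this design.

## MST: Hill dose response

F(c) = F_min + (F_max − F_min)·cⁿ/(cⁿ + K_dⁿ), fitted by least squares
with a nonnegative-amplitude parameterization (so F_max ≥ F_min holds
by construction) and data-driven starts (extreme responses, the
concentration nearest half-response, n = 1).  Literature write-ups
sometimes print the equation without the baseline term, which forces
F(0) = 0; a `strict_printed_form` flag reproduces that literal model.
The fitted abscissa is the titrant (formaldehyde) concentration.
Constant responses raise a flat-curve error; an unconstrained K_d
(SE > 10·K_d) warns.

## Colorimetric quantification and translation ratios

Standard curves are unweighted OLS lines (≥ 3 distinct standards);
back-calculation applies the dilution factor and floors below-blank
readings at 0 with a flag.  Per-well back-calculation precedes any
averaging.  Intracellular concentration scales the lysate concentration
by extraction volume over total cell volume
(CFU/mL × culture volume × 2.63 fL/CFU, 1 fL = 10⁻¹² mL); both sides
are molar, so the output unit is mM.  The translation ratio is
labeled/unlabeled (222/218 m/z) so that it rises with incorporation of
heavy methionine into new protein; the orientation is a declaration,
not an inference.

## Growth kinetics

The rate is the steepest OLS slope of ln(OD) over sliding windows
(default 5 points); ln(OD) is smoothed with a 3-point moving average
and floored at OD 10⁻³ before the log.  Window quality is judged
against the raw points: windows whose ln-residual RMSE exceeds 0.05
(≈5% relative scatter) are excluded unless none qualifies, which stops
near-blank noise from masquerading as steep growth while leaving
noise-free curves untouched.  For noisy plate-reader data the window
should span at least one doubling.  The lag is where the winning
tangent crosses the initial OD (clipped at 0); under formaldehyde
stress this "apparent lag" conflates death and recovery of tolerant
subpopulations and is reported as an operational quantity only.
Resistance panels threshold the OD gain (default ΔOD ≥ 0.05) and
report the highest permissive concentration, with explicit none-grew
and right-censored (grew at every dose) outcomes.

## Synthetic generators

Each generator draws from the minimal standard noise model of its
measurement class: Poisson colony counts, binomial cytometry
positives, additive Gaussian instrument noise (ITC heats, MST
fluorescence, OD).  Defaults encode the standard assay conditions:
2 × 10⁸ CFU/mL populations plated as triplicate 10 µL spots over a
tenfold series to 10⁻⁶; ≥ 1,000 cytometry events; a 16-point twofold
MST dilution series from 100 mM with noise at 2% of the response
amplitude; the 20 × 2 µL/25 mM/50 µM ITC protocol with a constant
−2 µJ dilution heat and 1 µJ per-injection noise; lagged-logistic
growth from an inoculum of OD 0.005.  The tolerance distribution is
flat-then-log-linear with a floor — chosen because the assay's summary
statistic is exactly a log-linear tail slope — and is an operational
form, not a mechanistic claim about single-cell physiology.

Seeds are mandatory; there is no global random state, and a fixed seed
reproduces byte-identical outputs.  What the generators deliberately
omit: colony merging and countability artifacts on crowded spots,
cytometry gating error and doublets, ITC baseline drift and peak
integration, MST raw-trace processing, plate-reader evaporation and
condensation.  Passing round-trip tests therefore demonstrates
estimator correctness under each assay's idealized sampling model, not
robustness to every real-world artifact.

## Pipeline

Runs are YAML configs (ordered stages with parameter maps, an output
directory, one global seed).  Stage seeds are derived via
`SeedSequence(seed, spawn_key=(stage_index,))`, so per-stage streams
are independent and reproducible.  Unknown stage names fail validation
before anything executes; a failed stage is recorded and later stages
that would consume its in-memory products are skipped.  Reports carry
package version, seed, config and per-stage summaries; identical
config + seed give identical payloads (timings aside).

## Problem sizes

Simulation-backed checks use 200 replicates for binding-parameter
recovery, 500 for slope-recovery bias, 1,000 for CFU unbiasedness and
2,000 for the slope-test type-I error — sizes at which Monte-Carlo
error is several times smaller than each tolerance being asserted.
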