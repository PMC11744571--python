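# Methods

`exercog` implements a multi-level analysis that links an acute
exercise-break intervention to executive function through two physiological
windows: the retinal microvasculature (vessel calibers from fundus
gradings) and cortical hemodynamics (fNIRS activation and effective
connectivity).  The study design it targets is a randomized crossover:
every participant completes three conditions — uninterrupted sitting (SIT),
moderate-intensity cycling (MIC), and vigorous-intensity cycling (VIC) —
each with pre- and post-intervention assessments.  All inferential
machinery therefore revolves around condition x time interactions and
their marginal-means difference-in-differences (DiD).

## Retinal vessel equivalents

CRAE and CRVE summarise the six largest arterioles/venules (µm) by the
revised Knudtson procedure: repeatedly sort, combine the largest with the
smallest width via `k * sqrt(w1^2 + w2^2)` (k = 0.88 arterioles, 0.95
venules), carry the middle element when the count is odd, until one value
remains.  Six inputs always pass through a 3-element intermediate round,
which is why the odd-count carry rule matters.  The AVR is reported as
CRAE/CRVE (the arteriole-to-venule ratio) by default; a `paper_literal`
CRVE/CRAE variant is selectable and the convention used is recorded in
every output row, so the two conventions can never be silently confused.
Fewer than six vessels are accepted with a quality flag rather than an
error, matching real grading practice.  Grader reproducibility is
quantified with the two-way mixed, absolute-agreement, single-measure
ICC(A,1).

## Dual-task Stroop scoring

Each subject x condition x timepoint x block cell (36 test trials; 50%
congruent / 25% incongruent / 25% neutral within every 12-trial sequence)
is scored as mean RT over correct trials, error rate, and the inverse
efficiency score IES = RT / (1 − ER).  Omitted responses count as errors
and contribute no RT.  Cells with no correct trials are flagged and
excluded downstream.  Measures are z-scored per measure and block against
the pool of all subjects' *pre-intervention* cells, and that pre-pool
mean/SD standardises both timepoints — so post-intervention z-values read
as change against the pre-intervention population distribution.
Alternative pools (global, per-condition) are available.

## fNIRS signal chain

Intensities at 760/850 nm are converted to optical-density changes
relative to the recording mean, screened per channel by coefficient of
variation (excluded iff CV >= 15% at either wavelength — inclusive
threshold), and inverted through the modified Beer-Lambert law with
DPF = 6, 3 cm inter-optode distance, and Gratzer/Cope extinction
coefficients (not printed by typical acquisition software manuals; shipped
as overridable constants).  Because the OD reference is the recording
mean, absolute hemoglobin baselines are unobservable; every quantity is a
concentration *change*, and forward/inverse consistency holds exactly on
mean-centered series.

For connectivity, concentration series are band-passed to 0.01–0.08 Hz
with a 3rd-order Butterworth applied forward-backward.  Zero-phase
filtering is a consequential choice: a causal filter would inject
direction-dependent lag distortion into the Granger step.  Narrowband
filtering before lag-based connectivity is itself known to blur VAR lag
structure; it is retained because it is the analysis being modelled, but
generator-level causal checks are run on unfiltered inversions.  The
leading spatial principal component (configurable) is regressed out to
suppress global systemic physiology, and retained channels are averaged
per ROI over the packaged nine-ROI montage (medial frontal; left/right
superior frontal, middle frontal, precentral, parietal).

## Activation GLM (AR-IRLS)

Task regressors are block boxcars convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1:6, peak-normalised),
plus 3rd-order Legendre drift.  Fitting alternates (i) BIC selection of an
AR model on the current residuals — estimated on residuals winsorized at
the bisquare cutoff so gross artifacts cannot masquerade as
autocorrelation — (ii) pre-whitening of response and design, and (iii)
Tukey-bisquare IRLS (c = 4.685) on the whitened sample, until betas move
less than 1e−6 (relative) or 20 iterations.  With white errors and no
outliers this reduces to OLS.  Default maximum AR order is 41 (≈4 s of
lags at 10.2 Hz).  Group level: channel betas average within ROI, cells
are tested against zero, and Benjamini-Hochberg FDR runs across
ROI x condition tests.

## Effective connectivity

A VAR(p) over the nine ROI series is estimated by per-equation least
squares; p minimises the multivariate BIC over 1..20 on a common sample
(≈2 s of lags at 10.2 Hz spans hemodynamic delays while keeping the
parameter count far below the 3060 samples of a 5-min resting segment).
Stability (companion spectral radius < 1) is enforced; AIC and per-equation
Ljung-Box whiteness are recorded but non-fatal.  For each ordered pair
(i → j), the reduced model drops only source i's lags from equation j,
conditioning on all other ROIs; the GC magnitude is
`ln(RSS_reduced / RSS_full)` and significance comes from the matching
nested-model F-test, BH-FDR corrected across the 72 ordered pairs.  Both
the magnitude and the F statistic are stored: printed edge differences on
the order of 0.01 are only compatible with the magnitude/effect scale, not
raw F values, so keeping both reconciles reporting with testing.  Causal
density is reported unweighted (significant fraction of 72 pairs, the
default) and weighted (mean GC magnitude).

## Group inference

Every outcome is modelled as
`y ~ condition * timepoint [* block] + sex + age + bmi + (1 | subject)`
with maximum likelihood and treatment coding (SIT / pre / baseline-block
references), so the condition x time coefficients are DiDs directly.
Marginal means are computed on the model's reference grid with covariates
at their sample means; condition contrasts are post−pre differences
between conditions, FDR-adjusted within one outcome's family.  On balanced
data the DiD contrast equals the interaction coefficient exactly (tested).
Inference is large-sample Wald (z); with 71 subjects the small-sample df
correction is negligible, and keeping the inference analytic makes the
contrast layer exactly reproducible.  Diagnostics: Shapiro-Wilk on
residuals, Breusch-Pagan against fitted values, Durbin-Watson on
within-subject orderings.  Failures trigger a variance-stabilising refit
(log for positive outcomes, rank-based inverse normal otherwise) and, if
still failing, subject-level case-resampling bootstrap CIs (2000 draws);
the remediation path is recorded.

## Mediation

Change scores (post − pre, exercise conditions averaged, relative to the
SIT change; per-condition variant available) feed a three-regression
linear mediation with a shared covariate set (sex, age, BMI):
M ~ X + Z, Y ~ X + M + Z, Y ~ X + Z.  The identity c = c′ + a·b then holds
to machine precision, and the packaged path profile satisfies it:
−0.51 + (1.0)(−0.82) = −1.33.  Inference for the indirect effect is a
bias-corrected percentile bootstrap (10,000 case resamples over subjects;
BCa intentionally not the default — only the median-bias correction is
applied).  A preceding screening step computes pairwise partial
correlations (controlling the same covariates) with FDR across pairs.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input for an n-subject crossover
(default n = 71, ~51% female, age 20.9 ± 1.9, BMI 21.7 ± 3.8).  A master
seed is split into per-subject, per-domain counter-keyed streams, so
subject data are independent of iteration order and identical inputs give
bit-identical outputs.

**Behavior.**  Trial RTs are lognormal (median 680 ms, σ_log = 0.2,
block-scaled ×1.0/1.15/1.25 for the baseline/color-dual/lexical-dual
blocks, truncated to the 200–3000 ms response window) with a lognormal
per-subject speed multiplier; errors are Bernoulli with a Beta-distributed
subject error probability (mean 0.10, SD 0.08).  Effects are stated in the
profile as z-unit DiDs and injected on the raw scale: an additive ms shift
for RT and a multiplicative factor on the error probability, each equal to
θ times the exact population SD of the corresponding pre-pool cell summary
(computed by numerical integration over the Beta-binomial error mixture,
closed forms for the lognormal part).  Because IES is a deterministic
function of RT and ER, the (rt, er, ies) z-triple of the calibration
condition cannot be chosen freely once the noise model is fixed; the one
remaining degree of freedom — the subject speed-multiplier variance — is
solved (Brent's method) so the implied z-IES DiD matches the profile.
That solve lands at σ_u ≈ 0.48 (between-subject speed spread of roughly
±50%, the RT-heavy variance mix the encoded triple implies).  For further
conditions RT and ER are honored exactly and the IES DiD is emergent
(VIC: ≈ −0.31 under the default profile).  Two residual biases of the
*pipeline*, not the generator, are documented: dividing by the empirical
pre-pool SD at n = 71 inflates z magnitudes by a Jensen term of ~2–4%,
and clipping at the response window is negligible by construction.

**Vessels and causal density.**  These generators work backwards from the
estimated quantity: per-cell CRAE/CRVE targets (population mean + subject
intercept + injected effect + residual, in µm) are realised as six-vessel
width sets rescaled so the Knudtson reduction reproduces the target
exactly (the reduction is scale-equivariant; multiplicative jitter
provides realistic width profiles).  Causal-density observations are
Gaussian cells emulating the estimator's output directly — not bounded to
[0, 1], since clipping would bias the injected effect, and far cheaper
than simulating and re-estimating recordings.  Both support the full
three-condition design and a two-condition (sitting vs exercise) reduced
design whose single interaction coefficient equals the profile's
interaction value — the reduced design exists because a three-condition
interaction spans two coefficients and a single printed β maps onto it
ambiguously.

**fNIRS.**  The latent cortical signal is a stable sparse VAR over the
nine ROIs (default: four planted directed edges, self-lags 0.3); task
blocks add canonical-HRF responses (synthesis HRF = analysis HRF, so GLM
recovery is unbiased up to noise); ROI series are copied to member
channels with independent noise, HbR is an anticorrelated scaled copy
(−0.35), and the forward Beer-Lambert projection plus cardiac (1.1 Hz),
respiratory (0.3 Hz), Mayer-wave (0.1 Hz), drift, and white OD noise
yields two-wavelength intensities.  Condition effects on connectivity in
full-study fNIRS generation are a qualitative coupling boost, not
calibrated to printed values — the calibrated causal-density path is the
per-cell generator above.

Passing recovery tests therefore demonstrate that the estimators are
unbiased for effects injected under this statistical structure; they do
not validate behavior on real recordings with motion artifacts,
short-separation physiology, optode coupling loss, practice effects, or
congruency-specific RT structure, none of which are modelled.

## Numerical choices and degenerate inputs

Zero-phase filtering requires ~190 samples minimum; shorter series error.
PCA denoising requires at least two channels and fewer components than
channels; zero components is the identity.  An all-error cell yields an
infinite IES flag; an all-excluded ROI is dropped with a warning, not an
error.  VAR fitting rejects collinear series and unstable selected models.
Mediation requires 10 complete cases and rejects collinear path designs.
Bootstrap quantile indices clamp the bias-correction proportion away from
0/1.  LMM optimisation tries L-BFGS, then Powell, then CG, then
Nelder-Mead before giving up.

## Problem sizes in the shipped experiments

The recovery experiments run at the study's size (n = 71) with 20
replicate seeds in the test suite; the reproduction script uses 30–60
replicates per experiment (more for the cheap estimators) to shrink the
seed-average Monte-Carlo error.  Null-calibration properties (FDR edge
control, type-I error, bootstrap coverage) are checked at reduced sizes
(5-node networks, 40–150 simulations) that keep the whole suite around
two minutes while leaving the asserted property intact.

## Known limitations

- No SNIRF reader/writer; recordings travel as CSV matrices plus a YAML
  montage.
- No short-separation regression or motion-artifact spline/wavelet
  correction (robust GLM weighting is the only artifact defence, as in
  the modelled analysis).
- Granger estimation on band-passed series inherits the filtering
  caveats above.
- Satterthwaite/Kenward-Roger df are not implemented; inference is Wald.
- The simulated menstrual-phase, nutrition, and fitness covariates of the
  original design are out of scope; only sex/age/BMI are modelled.
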