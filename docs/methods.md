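# Methods

This note documents the models, parameter choices and numerical decisions
behind `depthtms`, and what the synthetic-data tests do and do not
demonstrate about real trial data.

## Clinical model

### The C-DEPTH score

The score is the mean of baseline HDRS-21 item scores normalized by their
instrument maxima over a mood-and-anxiety item cluster, so it is
dimensionless and lies in [0, 1]. The item maxima follow the standard
21-item instrument (items 1, 2, 3, 7, 8, 9, 10, 11, 15, 19 → 4; items 16
and 20 → 3; the remainder → 2) and are configurable, since scale variants
exist. The score is monotone non-decreasing in every cluster item and
invariant to all others — both are enforced as property tests.

### LOFO optimization

The cluster is refined greedily: at each round, every item's omission is
scored and the removal with the largest improvement is committed. The
objective is |r_H1 − r_H7|, the absolute gap between per-arm Pearson
correlations of the score with percent improvement. The analysis exists to
*differentially* predict coil response, and these two correlations are
exactly what the optimized cluster is evaluated on, so maximizing their gap
is the natural objective; alternatives (interaction terms in a logistic
model, per-side χ²) behaved similarly on synthetic data but are less
directly tied to the reported quantities.

A removal is committed only when it improves the objective by more than
`min_improvement` (default 0.02). Leave-out objectives are evaluated on
nearly identical scores, so chance fluctuations of a few hundredths are
routine at trial-scale n; without the tolerance, a stepwise loop on pure
noise would almost always find some "improving" removal. The default makes
the null case (no item carries signal) terminate at the initial cluster in
the large majority of runs while removals of genuinely uninformative items
(which dilute the score's signal measurably) still clear the bar. Ties
break toward the lowest item index; the loop stops at `min_size` (default
4) items.

### Threshold selection

The decision threshold is scanned on a grid (step 0.05 over [0.1, 0.9]);
at each candidate, patients split into above/below subgroups and the
objective is the *smaller* of the two per-side response χ² statistics,
subject to at least 15 patients per side with both arms represented. A
threshold is only clinically useful if both sides discriminate between
coils, which the max–min form encodes. Ties break toward the grid
midpoint. The exhaustive-scan equivalence of the grid search is verified
against an independent re-implementation in the tests.

### Contingency statistics

χ² is the Pearson statistic without continuity correction — the choice is
pinned by the source data: the validation cohort's reconstructed response
table [[15, 3], [33, 21]] yields exactly 3.0 without correction (Yates
would give ≈ 2.08, contradicting the printed value). Odds ratios are
cross-products with a Wald log-scale 95% CI; any empty cell triggers the
Haldane–Anscombe +0.5 correction (flagged in the output), and a fully empty
row or column leaves the ratio undefined rather than inventing a value.
Orientation is explicit metadata: "in favor of arm X" means
odds(response | X) / odds(response | other), with X the better-performing
arm on that side.

### Reconstructing the published tables

Patient-level data for the source trial are private, but the printed
subgroup sizes (43 above / 101 below the threshold among completers), the
per-arm response and remission percentages on each side, and the completer
arm totals implied by the printed overall completer response rates (62.5%
H1 → 64 patients; the remainder, 80, in H7) admit exactly one integer
arm-by-side split whose eight reconstructed rates all round back to the
printed percentages. `published.reconstruct_main_tables` performs that
search and fails loudly if the solution were not unique. The same rounding
construction yields the external-validation tables. All published χ² and
odds-ratio values then reproduce: 11.55 (printed 11.5), 6.29 (6.3), odds
ratios 21.27 (21) and 2.86 (printed 2.8 — the discrepancy is in the source,
not the arithmetic), remission 2.59 (2.6) and 2.36 (2.4), validation 3.0
(exact) and 4.87 (4.9).

## Trial statistics

Outcomes follow the protocol definitions with strict boundaries: a
reduction of exactly 50% *is* a response; an endpoint total of exactly 10
is *not* a remission. Patients lacking a baseline or endpoint visit are
flagged non-evaluable and excluded from completer-set outputs.

The noninferiority assessment fits a fixed-effects ANCOVA of the endpoint
change score on arm, baseline total, center and stratum labels, and forms
the one-sided 95% upper confidence limit of the adjusted H1 − H7
difference; the H7 arm is noninferior when that limit is below the margin
(δ = 3 HDRS points, the conventional threshold for a clinically meaningful
difference). This deliberately approximates a repeated-measures mixed
model with a single-endpoint ANCOVA: the repeated-measures machinery needs
the per-visit patient data, and on simulated data the ANCOVA shows the
expected operating characteristics (equal arms declared noninferior,
a planted 4-point deficit rejected, CI width shrinking with n), which is
the testable surface here. Collinear covariate columns are pruned by rank
inspection (never the arm indicator) and reported.

The cross-lagged model regresses each subcluster at wave t (depression =
items 1 + 7 + 8, anxiety = items 9 + 10 + 11) on both subclusters at wave
t − 1, per wave transition and group, by least squares with listwise
deletion per transition. For a saturated observed-variable path model the
per-equation estimates coincide with the joint structural-equation fit, so
nothing is lost at the estimand level; standard errors are per-equation
OLS. No multiplicity correction is applied across transitions (flagged in
the output). Per-transition estimates at n = 150 carry standard errors
near 0.07–0.10, so recovery tests assert the across-transition mean.

## EEG pipeline

### Epoching and referencing

Measured train markers take precedence over the nominal schedule; the
schedule (onsets at k·(t_on + t_off) while the on-window fits the session)
is used for simulation and marker plausibility. Post-train epochs cover
[offset + 1 s, offset + 3 s) and pre-train epochs [onset − 1 s, onset) —
all intervals half-open, samples 0-based. Epochs exceeding the recording
are dropped; an epoch containing any sample beyond 150 µV (post-reference,
configurable) is rejected, and a train contributes only if both its epochs
survive. AVR subtracts the instantaneous channel mean. CSD applies a
spherical-spline surface Laplacian (spline stiffness 4, regularization
1e−5, 50 Legendre terms — conventional defaults) via MNE on standard 10–20
positions; its output units are arbitrary, which the downstream ratio
metrics do not depend on.

### Spectra and baseline deviation

Welch spectra use 1 s Hamming segments, giving a 1 Hz grid that tiles both
bands, with density normalization (integral ≈ variance, verified against
Parseval within 10%).

Reducing transient noise by deviating each train's post spectrum by its
pre spectrum is implemented as a per-bin **ratio** (a subtraction mode is
available behind a flag). The ratio makes the metrics unitless and fully
scale invariant — multiplying the recording by any constant leaves every
deviated metric unchanged, a property test — which is what makes
between-subject correlation of the metrics meaningful across amplifiers
and gains.

Two numerical points matter here. First, a 1 s spectral estimate has ~2
degrees of freedom per bin, and ratios of such low-dof estimates are
heavy-tailed (the expectation of an inverse-χ²₂ diverges), so an
arithmetic mean of per-train ratios is dominated by near-zero denominator
bins. The aggregate across trains is therefore the **geometric mean**, the
natural location estimate for multiplicative deviations. Second, the
geometric mean is unbiased in the log domain only when numerator and
denominator estimators carry equal degrees of freedom; each 2 s post epoch
is therefore split into two non-overlapping 1 s segments, each deviated by
the train's single 1 s pre segment. Identical post and pre spectra give
exactly 1, and a uniform doubling gives exactly 2. Zero-power bins are
flagged and excluded from the aggregate.

Band power is the mean (not the sum) over bins inside the band, keeping
the 5-bin alpha and 11-bin gamma bands comparable. Asymmetry is
P(left)/P(right) over the bundled 10–20 homologous-pair table (left in the
numerator, recorded in the output); hemisphere-swapped input yields
exactly reciprocal values. Resting recordings use consecutive 2 s epochs,
amplitude rejection, and absolute (undeviated) power; fewer than 10
accepted epochs raises a warning flag.

### E-DEPTH statistics

Correlations are Pearson on residuals after regressing both the metric and
percent improvement on site indicator variables; with one site this equals
the plain correlation to machine precision. The p-value uses n − 2 − k
degrees of freedom (k site indicators). A site with a single patient loses
its indicator, not its patient. Stabilization is a single pass — iterating
a 3 SD rule can cascade on small samples — removing observations with
|standardized residual| > 3 or leverage above mean + 3 SD of leverages;
removing more than 20% of observations raises a hard warning. Fisher's Z
uses n − 3 with n the post-exclusion count, ignoring the partialled
covariates: the classical test is defined for simple correlations, the
covariate adjustment is small, and the published Z from the printed
(rounded) correlations lies between the variants. An optional log10
transform is provided for ratio-type metrics (multiplicative quantities
are symmetric on the log scale, and skewed raw values otherwise hand the
outlier pass high-leverage points); its use is recorded in the output.

## Synthetic data

### Clinical cohorts

Baseline item vectors are categorical draws per item, exponentially tilted
by a patient-level severity factor u ~ N(0, 1) (tilt weight 1.5 per item by
default): P(s) ∝ w_s·exp(λᵢ·u·s/mᵢ). The shared factor correlates items
within a patient, which both matches real symptom co-variation and gives
the cluster score a realistic between-patient spread (SD ≈ 0.16, mean ≈
0.47, roughly a third of patients above the 0.5 threshold, baseline totals
centred near 30 with the ≥ 20 eligibility floor enforced by resampling).
Setting an item's tilt to zero makes it pure noise with respect to
severity — the construction used to plant LOFO-removable items.

Response is Bernoulli with log-odds intercept_arm + β_arm·(c − 0.5); the
default β = (+4, −2) plants the qualitative interaction (high scores favor
H1). A "switch" form replaces (c − 0.5) by ±½ depending on the side of the
threshold, planting a sharp cutoff for threshold-recovery tests.
Responders draw a trajectory depth in [0.75, 1], non-responders in
[0, 0.55]; week-k totals are baseline·(1 − f_k·depth) plus N(0, 1 HDRS
point) noise with the fixed ramp f = (0, .15, .30, .45, .60, .70, .75),
rounded and apportioned across items by largest remainder proportional to
the patient's baseline items under the item caps. The depth ranges leave a
margin around the 50% response boundary so trajectory noise rarely flips
the endpoint label (> 95% agreement, tested). Dropout (default 0.11,
matching the trial's early-termination fraction) truncates a patient's
visits at a random week; such patients are non-evaluable and absent from
completer outcomes. All randomness derives from one integer seed with
fixed sub-stream offsets.

### EEG sessions

Signal = 1/f background (spectrally shaped white noise, exponent 1) +
narrowband alpha (Gaussian spectral bump, SD 1.2 Hz at 10 Hz) with
independent left/right/midline equivalent-sinusoid amplitudes + midline
low-gamma (35 Hz, SD 3 Hz — low-gamma is broadband in vivo) + an 18 Hz
clipped square burst of ±2000 µV inside train windows, with markers at
onsets. Oscillations are narrowband Gaussian processes rather than fixed
sinusoids so that phase relations decorrelate across epochs; with fixed
phases, the average-reference subtraction would add a constant
interference term to every epoch and bias asymmetries.

Planted metric–outcome correlations work through post-train gains: inside
[offset + 0.5 s, offset + 3.5 s) (covering the analysis epoch) the named
oscillation's amplitude is multiplied by √m, so the deviated metric
recovers m. Per-patient (metric, improvement) pairs are drawn jointly at
the requested correlation on the log-metric scale (log-SD 0.5, a
severalfold between-subject spread typical of band-power ratios), with the
noise component orthogonalized so the realized sample correlation equals
the plant exactly — recovery tests then measure pipeline fidelity, not
draw-level sampling error.

### What the generator does not emulate

No ocular/EMG artifact classes, no biophysical TMS artifact modeling
(artifacts are idealized saturating bursts confined to train windows), no
volume-conduction forward model (channels are statistically, not
physically, coupled), no site-specific hardware differences beyond the
site covariate, and no item-level floor/ceiling dynamics in trajectories
beyond the caps. Passing recovery tests therefore demonstrates that the
analysis recovers effects of the assumed form at realistic sizes and
noise levels — not that real recordings meet those assumptions.

## Problem sizes

Simulations are sized for single-CPU runs: cohort tests use 200–600
patients per arm (1,500 for the stepwise-null property), EEG sessions
250 Hz with 15 trains (330 s) for unit tests and 30–40 trains for
recovery tests, and the planted-correlation cohort 60 sessions of 30
trains. The protocol arithmetic (55 trains, 1,980 pulses) always uses the
full 20-minute schedule. Recovery claims are stated as success rates
across seeds at these sizes.

## Known limitations

- The LOFO objective and stopping rule, the threshold-optimality
  criterion, and the deviation arithmetic (ratio vs difference) are not
  uniquely determined by the source material; the choices above are
  documented and configurable where reasonable.
- The mixed-model and structural-equation analyses are approximated by
  ANCOVA and per-equation OLS respectively, as discussed.
- EDF and BrainVision are read via MNE; only BrainVision is written (a
  minimal text-header writer), so EDF round trips are out of scope.
- The stabilization pass can remove genuinely informative high-leverage
  observations when a metric is strongly skewed; the log-transform option
  is the intended mitigation for ratio metrics.
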