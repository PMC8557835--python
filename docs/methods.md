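# Methods

This note documents the models, algorithms and design choices behind
`circlock`, in the order data flows through the pipeline.

## Scientific setting

Peripheral circadian clocks (here, the liver clock) are cell-autonomous
oscillators entrained by rhythmic systemic signals: rest-activity,
body temperature, food intake, corticosterone and melatonin.  The
package asks which of these signals act on the expression of core clock
genes, and how strongly, given only (i) biomarker time series, (ii)
clock-gene mRNA time series in four mouse classes (2 strains x 2 sexes)
and (iii) a calibrated ODE model of the clock free of systemic input.
The method inverts the clock ODE into *residual trajectories* — the
forcing a gene would have to receive to produce the observed mRNA — and
then searches linear combinations of the candidate regulators that
explain those trajectories.

Liver cells lack melatonin receptors, so melatonin is carried through
the entire analysis as a negative control: a sound pipeline must rank
it last, not drop it a priori.

## Synthetic data generator

The generator emulates the statistical structure of a four-class mouse
chronobiology dataset.  All default numbers are synthetic placeholders
in plausible units, not measurements.

* **Biomarkers.** Each biomarker follows a cosinor
  `mesor + A cos(2*pi*(t - phi)/24)` with Gaussian replicate noise.
  Sampling designs: activity/temperature every 10 min for 72 h with 8
  replicates; hormones every 3 h over 24 h with 3 replicates; food
  intake as 4-h weighing intervals over 48 h with 3 replicates (the
  recorded value is the integral of the underlying rate over the bin, a
  step signal like differenced cage-food weights).  Class contrasts:
  females have higher activity mesor and relative amplitude; temperature
  is virtually identical across classes; food intake is robustly
  rhythmic in strain-A classes only; corticosterone is damped in class
  2; acrophases are preserved classwise.
* **In vitro expression** is the unforced clock model's limit cycle,
  sampled every 2 h over 48 h, with multiplicative log-normal noise
  (log-sd 0.05) — the usual error structure of expression measurements.
* **In vivo expression** forces ONE target gene with
  `f(t) = 1 + eps_scale * s(t)/sd(s)`, `s = sum_j beta_j zbar_j` over
  the class panel, multiplying transcription (H1) or degradation (H2);
  `eps_scale` defaults to 0.3 and the per-class scale `sd(s)` is
  recorded so recovered weights can be mapped back to the ground-truth
  scale.  The non-target states stay on the unforced limit cycle, so
  the H1 inversion identity is exact in continuous time.  Circadian
  time 0 is anchored at the Bmal1 mRNA peak throughout; 3 replicates
  every 2 h over 24 h, log-normal noise (log-sd 0.05).

What the generator does *not* emulate: non-sinusoidal waveforms of
activity and feeding, sensor artifacts and missingness, inter-animal
phase dispersion, and coupling between regulators.  Passing tests on
these data therefore demonstrate correctness of the machinery, not
performance on real mouse data.

## Preprocessing

Replicate series are collapsed to per-time means and smoothed by a
Gaussian process with kernel `constant * periodic(24 h) + white noise`,
hyperparameters by maximum marginal likelihood with seeded restarts
(default 5).  A squared-exponential decay factor was deliberately left
out: the downstream machinery needs a mean function that is 24 h-
periodic by construction.  Strictly positive mRNA profiles are smoothed
in log space, which keeps relative error uniform — important near deep
expression troughs, where the ODE inversion divides by small numbers.

Rhythmicity is validated by single-harmonic cosinor regression with an
F-test of the two rhythmic terms against the constant model.

Each regulator enters the model search twice: directly, and as an
*integral regulator* — the cumulative integral of the mean-centred
signal, standing in for an unobserved intermediate produced linearly by
the regulator (its rate constant is absorbed into the regression
weight).  Centring before integration is required for the integral of a
periodic signal to be periodic; the raw integral of a positive
biomarker is an unbounded ramp that no periodic trajectory could match
(`center=False` restores the literal running integral).  The 10 columns
(5 direct + 5 integral) are standardized to mean 0, sd 1 on an hourly
24-point circadian grid (configurable); the standardization record is
kept for inverse transforms.

## Clock model

A 15-state ODE model with the canonical liver-clock architecture:
CLOCK/BMAL activates *Per2*, *Cry1*, *Rev-Erbα* and *Rorγ*; PER/CRY
represses that activation; REV-ERB represses *Bmal1* and *Cry1*; ROR
activates *Bmal1*; *Clock* is constitutive (flag-exempt from rhythm
criteria).  mRNAs follow `dx/dt = Vmax * Transc(M, gamma) - alpha x`
with Hill-type multipliers; proteins are produced from their mRNAs,
CLOCK and BMAL dimerize into nuclear CLOCK/BMAL, PER and CRY proteins
form a cytoplasmic complex that is imported into the nucleus.

Two structural choices were forced by oscillation requirements and are
worth recording.  First, PER/CRY repression multiplies the whole
activated transcription unit rather than attenuating the activator
inside the Hill term: the attenuation form caps the feedback loop's
log-gain below the Hopf threshold for any plausible Hill coefficient.
Second, explicit PER and CRY protein stages precede complex formation;
the added first-order stages supply the phase lag a ~24 h relaxation
oscillation needs at realistic degradation rates (0.05–0.5 /h).

The reference parameter set is a hand-designed, versioned fixture.  It
was tuned for the qualitative phenomenology expected of a liver clock —
sustained oscillations of every species, period 24.0 h (obtained by an
exact global time rescaling of all rate constants), relative amplitudes
above 5%, REV-ERB vs ROR and PER/CRY vs CLOCK/BMAL peaking more than
6 h apart, and a Bmal1 mRNA rhythm with a deep trough (minimum ~0.19 of
its mean), as observed in liver.  The inference layer is agnostic to
the particular parameter values.

`fit_invitro` calibrates the model to expression data by multi-start
bounded least squares in log-parameter space (relative residuals per
gene, seeded log-uniform starts, oscillation filter on the optima).  The
default free set is the per-gene transcription levels and degradation
rates (12 of 58 parameters) — enough to absorb scale and damping
mismatches at desk scale; the full vector can be freed via `free=`.

`sobol_select` screens parameters by first-order Sobol indices
(Saltelli pick-freeze estimator over scrambled Sobol matrices, own
implementation) of the circadian mean, relative amplitude and phase of
each modulator species over a +/-50% hypercube.  The per-output top-p
sets are intersected and p grown until the intersection reaches the
target size (5), or the largest size below it.  The shipped fixture
(`data/sobol_set.json`) was computed once over the 30 rate-type
parameters at 256 Sobol samples, seed 12345, and selected
{deg_per2, vmax_bmal1, vmax_per2, vmax_ror}.  Phase is measured as
argmax time; its circular discontinuity adds estimator noise that the
top-p intersection tolerates.

## Residual trajectories

Under H1 (forcing on transcription)
`y_i = (dx/dt + alpha x) / Transc(M, gamma)`, under H2 (forcing on
degradation) `y_i = (Vmax Transc(M, gamma) - dx/dt) / x`, computed on
the first N-1 grid points.  `dx/dt` is the forward difference, which is
second-order accurate at the interval midpoint; the algebraic terms are
therefore evaluated at the midpoints too (trapezoidal x, periodic
interpolation for Transc).  With the inconsistent all-at-t_i
evaluation, discretization error alone reached a loss of ~0.2 on
sharply peaked profiles; the consistent scheme brings it below 0.01.
Learning samples remain paired with the regulator panel at t_i.
Each trajectory is standardized per trajectory (mean 0, sd 1), which
makes the empty-model loss exactly 1.

Parameter uncertainty (H3): selected coordinates receive additive
Gaussian noise with sd `theta_j * sigma_eff`, resampled until
admissible.  The nominal scaling factor sigma = 10 is read as an
inverse scale (sigma_eff = 1/sigma = 0.1); the literal reading
(sd = 10 theta_j) would leave essentially no perturbed clock passing
the realism filter and is available via `literal=True`.  The perturbed
set is the target gene's Vmax/alpha/Hill parameters plus the Sobol
fixture.  Perturbed clocks are kept only if every non-constitutive
state is rhythmic with period in [20, 28] h and relative amplitude
strictly above 5%, and both antagonist pairs are separated by strictly
more than 6 h (circular distance).  Accepted draws yield one residual
per class from the anchored limit cycle, so n is equal across classes;
base parameter sets rotate round-robin.

## Model search

Admissible models are subsets of the 10 features containing no
{regulator, its own integral} pair — sizes 1..5 give 10/40/80/80/32
models, 242 in total.  Fits are intercept-free OLS per class per
trajectory on standardized data; the total error E averages the
minimized per-trajectory losses over the 4 classes, so E = 1 for the
empty model and E = 0 for a perfect fit.

Shapley values are computed over the 32 admissible 5-feature models.
Coalition predictions are the fitted model with terms outside the
coalition dropped; under that convention the weighted coalition average
telescopes exactly to `phi_j(t_i) = beta_j zbar_j(t_i)` (verified
against explicit enumeration at machine precision).  Refitting per
coalition would not reduce to the shortcut when features correlate.
Mean absolute values are pooled over time points, trajectories, classes
and the 16 subsets containing each feature.

Model complexity is judged by the elbow of best-E versus size (the
steepest drop between consecutive sizes; the empty-to-1-term drop is
ignored as trivially largest).  A hypothesis is accepted iff its best
2-term model — the complexity that balances fit and degrees of freedom
for these data — achieves E at or below a configurable threshold
(default 0.15).  Nested best models are compared per trajectory by
F-tests; because ensemble trajectories are pseudo-replicates, only the
median p and the fraction below 0.05 are reported, never a pooled p.
Overfitting is monitored by shuffled-timepoint 4-fold cross-validation
per trajectory.

## Class statistics

Per-trajectory weights of a chosen model are analyzed as realizations
of a random variable: two-way fixed-effects ANOVA (sex, strain,
interaction) per feature — flagged as pseudo-replicate inference —
kernel-density summaries (Scott bandwidth) with mode detection,
profile-likelihood identifiability (each weight fixed on a grid of
+/-5 standard errors, others re-optimized; identifiable iff the profile
crosses `loss_min * (1 + chi2_1(0.95)/dof)` on both sides), and
sign-constrained refitting (per-feature signs enforced across classes
via non-negative least squares on sign-flipped columns; the ratio of
constrained to unconstrained total error measures how much classwise
opposite regulator action is required by the data).

## Numerical choices

* Integrator: LSODA, rtol 1e-8, atol 1e-10, 10-cycle burn-in (240 h);
  calibration and sensitivity screening use rtol 1e-6 and shorter
  burn-in for speed.
* Limit-cycle extraction anchors circadian time 0 at the Bmal1 mRNA
  peak and rescales the last full period onto the 24 h grid.
* Relative amplitude is peak-to-trough over the circadian mean;
  period is the mean spacing of successive maxima; phase is the last
  peak time folded by the period.  Signals with relative span below
  1e-6 are flagged non-rhythmic.
* Rank-deficient designs fall back to minimum-norm least squares with a
  warning; dominant-term ties break toward the lower feature index.
* Standardization uses the population convention (ddof 0) so the
  empty-model loss is exactly 1.

## Problem sizes

Default study conditions: hourly grid (N = 24), ensembles of n = 2000
trajectories per class and gene.  The shipped tests and the acceptance
script run the same machinery at desk scale — n = 200 trajectories,
GP restarts 2–5, Sobol screens at 128–512 samples — sizes chosen so a
full run completes on a single CPU while leaving the Monte-Carlo
estimates' standard errors well inside the asserted tolerances.

## Known limitations

* The clock model is structurally faithful but not a reproduction of
  any published parameterization; absolute concentrations are
  arbitrary units.
* Biomarkers are single-harmonic by construction, so the regulator
  panel spans little beyond the first Fourier mode; discrimination
  between hypotheses leans on the nonlinearities of the ODE inversion.
* For the same reason the 10 features are strongly mutually correlated
  (any 24 h first harmonic is a combination of two phase-shifted ones).
  Model subsets lacking a true regulator can synthesize its phase with
  large opposed weights on correlated pairs, which inflates and
  destabilizes mean absolute Shapley values; the ranking is reliable on
  well-conditioned designs and should be read jointly with its spread
  on cosinor-shaped panels.
* The H1/H2 decision at the fixed 0.15 threshold is sharp by design;
  with weak forcing or very noisy data both hypotheses can fail it.
* ANOVA p-values quantify ensemble variability, not animal-level
  replication.
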