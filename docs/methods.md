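# Methods

This note records the models, estimators, numerical choices, and
simulation design behind `alphastates`, at the level of detail a user
would need to judge what the package's passing tests do and do not
establish.

## Generative model of the synthetic cohort

The generator emulates a parcellated MEG detection-task study: 52
parcels at 250 Hz, 32 subjects, 8 blocks of 80 main trials with
exactly half grating-present, and a block-level priming condition
(conservative/liberal) that enters the behavioral model only through
the subject-by-condition random effects. These defaults are the
emulated study conditions; tests and the recovery experiment
instantiate smaller cohorts explicitly and report the sizes they use.

**State dynamics.** A first-order Markov chain over K network states
(default 8, sticky transitions with stay probability 0.96 ≈ 100-ms
mean dwell). Each state k expresses a narrowband oscillation at its
own peak frequency (defaults spread over 9.8–11 Hz, the range of
individual alpha peaks such studies report) on a state-specific set
of parcels, gated by the state indicator.

**Oscillation model.** An amplitude-modulated sinusoid whose phase
drifts as the integral of an Ornstein–Uhlenbeck
instantaneous-frequency deviation (mean-reversion 1 s⁻¹, stationary SD
0.8 Hz), giving a spectral line of ~1.9 Hz FWHM — comparable to
empirical alpha peaks and wide enough to be fittable after multitaper
smoothing. A bounded (stationary) phase-noise process would *not*
broaden the line, which is why the drift is integrated. Slow OU
amplitude modulation (depth 0.2) adds realistic envelope variability.

**Background.** Each parcel adds spectrally shaped 1/f^χ noise
(default χ = 1.0, SD 1.0 in signal units). The generator's SNR
(oscillation amplitude 1.0 against that background) makes state-masked
spectral peaks clearly detectable at a few minutes of data, which is
what matters for recovery tests.

**Behavior.** Reports are Bernoulli draws through the probit of the
full S×P×A factorial (coefficients b0..b7) plus bivariate normal
random intercept and S-slope per subject:condition cell (default SDs
0.3, uncorrelated; correlation configurable). Default coefficients
(−0.95, 1.5, 0, 0, 0, −0.3, 0, −0.2) describe a mildly conservative
observer (c ≈ 0.2) at threshold sensitivity (d′ = 1.5) whose
sensitivity falls with network alpha power, more when the network is
on — the qualitative pattern the analysis is designed to detect.

**Trial geometry.** Onsets sit on a fixed 2-s grid with a 2-s edge
buffer, so 500-ms analysis windows never straddle neighboring trials;
the inter-trial interval of the emulated task is not documented, so
this spacing is a free design parameter chosen for analysis-window
separation. Signal/absent balance within a block is exact by
construction, not sampled.

**What the generator does not emulate:** sensor-level physics (forward
models, beamforming, parcellation leakage), artifacts (eye, cardiac),
non-stationary aperiodic backgrounds, supra-threshold priming trials,
or between-state amplitude correlations. Tests that pass on this
synthetic family therefore validate the estimators under a correctly
specified (if simplified) model; they do not certify robustness to
source-reconstruction error or artifact contamination.

## TDE-HMM

Per-parcel z-scoring precedes embedding so the zero-mean Gaussian
observation model is well posed. The embedding concatenates all
parcels at each of L symmetric lags (L odd; 15 lags = ±28 ms at
250 Hz); edge samples are excluded from the likelihood and their
posteriors are imputed from the nearest valid sample for trial
alignment. An optional PCA of the embedded space is available but off
by default (synthetic dimensionality is small).

Inference is maximum-likelihood EM: scaled forward–backward E-step
(per-sample rescaling of emission likelihoods; exact posteriors),
closed-form M-step with covariance regularization ε·I, ε = 1e-6 ×
mean diagonal (prevents collapse on short runs). Restarts (default
10) start from seeded random responsibilities; the best final
log-likelihood wins, playing the role that lowest variational free
energy plays for the Bayesian fits of the same generative model —
the posterior state time courses, not parameter uncertainty, are what
downstream stages consume. Viterbi ties break toward the lower state
index. Forward–backward and Viterbi are verified against brute-force
path enumeration (T ≤ 8, K ≤ 3, 1e-8), and EM monotonicity is asserted
per run.

Evoked state responses epoch the gammas around onsets (window a
parameter, default −1…+1 s) and subtract the mean of the 100-ms
pre-stimulus baseline from the trial average.

## State-conditioned spectra

A 2-s window is assigned to state k when at least half of its samples
carry Viterbi label k (the conditioning rule across state transitions
is otherwise underdetermined; gamma-weighted assignment is available
via soft inputs, hard masking is the default). Seven unit-energy
Slepian tapers (time-halfbandwidth 4) on 2-s windows give the 0.5-Hz
grid with ±2 Hz smoothing; coherence is |S_ij|²/(S_ii·S_jj) after
averaging cross-spectra over tapers and windows. A state owning no
window yields missing spectra with a warning.

Band discovery stacks subject- and state-wise coherence spectra and
factorizes them with two-mode NMF (deterministic NNDSVD-A
initialization; modes ordered by peak frequency).

**Spectral parameterization** fits log10 power over 1–45 Hz as a
no-knee aperiodic line plus up to 3 Gaussians: robust two-pass
aperiodic fit (refit on the quartile of points closest to the line
from below), tallest-first peak extraction with a residual-SD
threshold (2) and minimum height (0.3 log10 units), joint bounded
least-squares refinement, FWHM limits [0.2, 12] Hz, and one
aperiodic/periodic alternation. Overlapping peaks (centers within
0.75 of their summed SDs) keep only the tallest — shoulders of a
dominant peak are artifacts of the smoothing kernel, not separate
oscillations. On constructed spectra the exponent is recovered within
±0.05 and an alpha-band center frequency within ±0.3 Hz. On
taper-smoothed spectra of narrow lines over a 1/f floor the fitted
center frequency carries a structural upward skew of up to ~0.5 Hz
(log-compression of the sloping floor); recovery of state peak
frequencies is therefore scored on the state-masked PSD argmax (±0.5
Hz), while the fit route is validated on constructed ground truth.

The individual alpha frequency per subject and state is the fitted
in-band (7–14 Hz) center frequency, the lowest when several fall in
band; subjects with no in-band peak receive the group mean of fitted
values, flagged `group-fallback` (undefined, and an error, if no
subject has one). Critical nodes are the endpoints of the top 0.25 %
of parcel-pair edges by alpha-band coherence (~top 3 of 1326 edges on
52 parcels, 6–7 nodes); a fraction that rounds to zero edges falls
back to the single strongest edge with a warning.

## Network alpha power and activation

Sliding-window power uses only the first Slepian taper of a 500-ms
window (time-halfbandwidth 1.5 = ±3 Hz smoothing), stepped every
40 ms; power is the squared magnitude of the tapered Fourier
coefficient at the grid frequency nearest the individual alpha
frequency (2-Hz grid for 0.5-s windows — within 1 Hz of the target,
far inside the smoothing bandwidth, and free of interpolation).
Edge-overlapping windows are missing. Network power is the plain mean
over critical nodes (missing-propagating). The activation indicator
A_t is 1 when the state is on at *any* sample of the same centered
window. Power is natural-log transformed then z-scored within subject
(the stated motivation is between-subject heterogeneity, so
within-subject is the default; pooled standardization is a grouping
argument away).

Trial alignment uses the window −500…+250 ms: the time axis starts at
−0.5 s and advances in 40-ms steps to the last point inside the
window, giving 19 points (−0.50…+0.22 s) — reported explicitly, since
+0.25 is not a multiple of the step. Trials reaching outside the
valid grid are dropped and counted, escalating above a 10 % fraction.

## Probit SDT mixed model

Fixed effects are the full S×P×A factorial; random intercept and
S-slope per subject:condition cell. Estimation maximizes the Laplace
approximation of the marginal likelihood: for a candidate
random-effect Cholesky factor, a penalized Newton solve (observed
information, step-halving) finds the joint mode of (β, u) over
spherical effects; the Laplace deviance adds the per-cell log-dets;
Nelder–Mead with non-negativity bounds searches the three free
Cholesky elements. Coefficient covariance is the fixed-effect block
of the inverted joint observed information at the mode (conditional
on the variance components — the same convention mixed-model software
reports). Per-term and per-contrast statistics are Wald F = (est/se)²
with 1 numerator df against F(1, n−p). Against `lme4::glmer` (probit
family, same formula) on a common dataset the estimates agree to
~0.005 and SEs to ~2 %; the suite pins those frozen reference values.

Degenerate designs follow an explicit rule: a constant A (or P) drops
the terms containing it, the reduced factorial is fitted, omitted
terms are flagged and contrasts touching them return missing. A
non-convergent mixed fit falls back to the plain probit GLM with
cluster-robust (by grouping cell) covariance, flagged, never silent.
The calibration study (100 cohorts of 16 cells × 640 trials) puts
95 % CI coverage of every coefficient in [0.90, 0.99] with absolute
bias below 0.05.

SDT contrasts are exact linear maps of the coefficients: d′ power
slopes b5 (state off) and b5+b7 (on), difference b7; criterion slopes
−(b2+b5/2) and −(b2+b5/2+b4+b7/2), with the on/off difference
reported as b4+b7/2 following the convention that states the
interaction coefficient without the leading sign of the criterion
equation. Per-timepoint fits pool both priming conditions into one
model, condition entering only through the grouping factor.

## Cluster-based permutation inference

Clusters are maximal runs of timepoints whose uncorrected p (from the
fit's own per-timepoint statistics; threshold p < 0.05, strict
inequality) are supra-threshold; the cluster statistic is the summed
F (or signed summed T), compared against the permutation distribution
of the maximal cluster mass. Monte-Carlo p-values use the add-one
rule and can never be zero. Only temporal adjacency is clustered.

Three schemes: (1) GLMM coefficients — whole per-trial (P, A) rows
shuffled jointly across trials within subject (joint shuffling
preserves the P–A dependence under the null), the per-timepoint model
refitted per permutation with the same estimator as the observed
statistic; (2) evoked condition contrasts — within-subject label
flips; (3) evoked vs. baseline — per-subject swaps with a zero
series. Both evoked schemes reduce to sign flips of a difference
series.

For permutation-scale refitting the fixed-effects probit is the
statistic of choice (batched Newton across permutations ×
timepoints); permutation validity requires only that observed and
permuted data receive the same statistic. The family-wise error of
the full procedure, measured on 200 null simulations × 200
permutations at a reduced scale (6 subjects × 64 trials, 6
timepoints, AR(1) power time courses mimicking sliding-window
overlap), lies within [0.01, 0.10] for every contrast, and an
injected 5-timepoint sensitivity effect is detected at p ≤ 0.01 with
400 permutations.

## Recovery experiment

Four sub-experiments, sized to run on one CPU in minutes (sizes are
design choices reported in the output):

1. **Transition dynamics** — 2-state chain (stay 0.98), 50,000
   samples, 10:1 emission variance ratio; after Hungarian label
   matching on gamma correlation, transition-matrix max-abs error ≤
   0.02 and state accuracy ≥ 0.95.
2. **State peak frequencies** — 3 states, 6 parcels, 240 s;
   state-masked multitaper PSD argmax within ±0.5 Hz of the
   configured peaks.
3. **Coefficient coverage** — replicate cohorts at the default
   recovery scale (8 subjects × 2 conditions × 320 trials, K=3, 10
   parcels; stay probability 0.99 so the 500-ms any-on indicator
   stays informative rather than saturating). Responses are generated
   from the *measured* network power at the generative timepoint, so
   the response model is exactly specified and coverage is
   interpretable; 95 % CI coverage across replicates × coefficients
   must lie in [0.90, 0.99] and each coefficient's mean error within
   3.5 Monte-Carlo SEs of zero (an absolute bias gate at small
   replicate counts would measure noise, not bias; the raw maximum
   bias is reported alongside).
4. **Effect localization** — a strong sensitivity effect injected
   through the mean measured power over −300…−100 ms; the detected
   significant cluster must overlap the true window with Jaccard ≥
   0.2 (window overlap spreads the effect to neighboring timepoints,
   so perfect Jaccard is not expected).

## Known limitations

- The HMM provides point estimates only; no posterior over parameters
  and no state-number selection.
- The Laplace covariance conditions on the estimated variance
  components; with very few grouping cells, coefficient SEs are
  mildly optimistic (visible as coverage nearer 0.90 for the
  intercept in the calibration).
- The spectral peak model (Gaussian on log power) mis-centers narrow
  lines sitting on steep 1/f floors after multitaper smoothing; see
  above.
- Equal-variance SDT throughout: no ROC/zROC slope estimation, no
  lapse rates.
- The pipeline fits one HMM to concatenated subjects (as group-level
  analyses do); per-subject embedding edge effects at concatenation
  boundaries are imputed, not modeled.
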