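# Methods

## Task structure

Each simulated participant completes four sessions, one per target emotion
(happy, neutral, fear, disgust), in a randomized order. A session has 60
trials: 30 target-emotion stimuli and 10 stimuli from each of the three
other emotions, every 10-stimulus non-target set balanced 5 female / 5 male
speakers. Each trial carries a fixation jitter drawn uniformly from
[300, 500] ms (rounded to integer ms), a 3,000 ms stimulus, a 3,000 ms
blank and a 500 ms inter-trial interval. A 120-stimulus catalog (30 per
emotion, 15 per speaker sex) supports this: an emotion's 30 stimuli all
serve as targets in that emotion's session, and are partitioned into three
disjoint sex-balanced sets of 10 for the three sessions where the emotion
is a non-target. Every stimulus therefore occurs exactly twice per
experiment. (A reuse scheme in which each stimulus appears four times is
arithmetically incompatible with 10 non-targets per emotion per session;
the disjoint partition is the unique scheme satisfying all stated counts.)

Randomization uses one master seed per participant with fixed,
independently derived sub-streams for stimulus selection, session order,
non-target partitioning, trial order and fixation jitter, so changing one
consumer cannot perturb the others and every design is bit-reproducible.

## Stimulus preparation

Speech power is the mean square of the full clip (all channels pooled),
measured before trimming. Masking adds zero-mean Gaussian white noise with
*theoretical* variance P_signal / 10^(SNR/10) — the convention of standard
additive-white-Gaussian-noise utilities — so the realized sample SNR of any
one clip fluctuates around the 10 dB target; `realized_snr` quantifies this
(at 3 s / 44.1 kHz the spread is a few hundredths of a dB). The masked clip
is then trimmed to its first 3,000 ms. No loudness normalization is applied
across stimuli.

Two dichotic headphone-screening stimuli are generated: an antiphase pure
tone (default 200 Hz; right channel sign-inverted, so channels cancel
exactly when summed) and a Huggins-pitch pair (default 600 Hz ± 6% band):
one white-noise realization presented to both ears except for a narrow band
whose phase is rotated by π in one ear — a phase-only manipulation, leaving
the per-channel magnitude spectra identical. Scoring protocols for these
screens are out of scope; only the stimuli are constructed.

## Observer model

Decision evidence on a non-target trial is x ~ N(0, 1); on a target trial
x ~ N(d′_e, σ) with σ = 1 by default (unequal variance is exposed as a
parameter, giving population AUC Φ(d′/√(1+σ²))). The observer answers
"target" iff x exceeds a decision criterion c and reports confidence
1 + #{cuts below |x − c|} with five equally spaced cuts.

Defaults: criterion c = −0.5 and cut spacing 0.5 evidence units. These were
chosen so that the six ROC thresholds (c, c + 0.5, …, c + 2.5) straddle the
ROC midpoint: the rating ROC is built only from "target"-judgment
confidences, so all thresholds lie at or above c, and a conservative
criterion would leave the upper limb of the curve spanned by one long chord.
With these defaults the asymptotic (infinite-trial) trapezoid deficit of
the six-point construction is at most 0.0074 in eAUC over d′ ∈ [0, 2.5]
(it is a deficit — chords under a concave curve — hence the empirical eAUC
is mildly conservative; the finite-trial tests quantify this rather than
assume unbiasedness).

### Cohort structure

The default cohort mirrors the observed sample: 15 Low-anxious observers
(STAI trait 33–39) and 13 High-anxious (40–47), trait and state scores
drawn discrete-uniform within the group ranges (state 29–42). STAI scoring
itself is implemented exactly (20 items, 1–4, reverse-keyed items
contribute 5 − response; total 20–80). Baseline sensitivity is d′ = 0.75
for every emotion (population eAUC ≈ 0.70, inside the reported per-emotion
average range of 0.65–0.72). Anxiety acts purely as a group-level d′
deficit for the negative emotions: High-group d′ is reduced by 0.40 (fear)
and 0.35 (disgust), whose asymptotic Low − High eAUC gaps (≈ 0.104 and
≈ 0.091) sit at the reported effect magnitudes (≈ 0.09–0.11). This
parameterization is a generative stand-in for exercising the pipeline at
known ground truth, not a mechanistic model: there is no per-trial state
modulation, no attention lapses or fatigue, and no reaction times. Passing
tests therefore certify the *analysis machinery* (scoring, exclusion,
inference), not any claim about real listeners.

## Scoring

Corrected rates (h + 0.5)/(n + 1) are applied at every confidence
threshold with the same denominators. Cumulative thresholding from the
most-confident "target" responses downward is the only construction that
yields six monotone operating points from the 2 × 6 response table; a
non-cumulative reading produces invalid (non-monotone) ROCs. Anchors (0,0)
and (1,1) close the curve and the area is the trapezoidal rule over the
points sorted by false-alarm rate (duplicated points contribute zero
width). Exclusion is strict: a participant is retained only if eAUC > 0.50
in all four emotions.

## Inference

* **Split**: trait ≤ 39 → Low (a score of exactly 39 is Low).
* **Normality**: Lilliefors (statsmodels table p-values) where parameter
  estimation should be accounted for; plain Kolmogorov–Smirnov against the
  fitted normal where that is the procedure being mirrored.
* **Sphericity**: Mauchly's W from the determinant/trace of the covariance
  projected onto orthonormal Helmert contrasts, chi-square approximation
  (cross-checked against pingouin).
* **Mixed ANOVA**: unweighted-means classical sums of squares (harmonic-mean
  cell weighting) — the within layout is complete and only the group factor
  is unbalanced, so this coincides with the Type-III convention; error
  terms are subjects-within-groups (between effect) and
  emotion × subjects-within-groups (within and interaction effects);
  partial η² = SS_effect/(SS_effect + SS_error). No sphericity correction
  is applied to the reported degrees of freedom (the mirrored analysis
  reports uncorrected df after a non-significant Mauchly test).
* **Simple main effects**: per-emotion pooled-variance two-sample contrasts
  (Low − High), Bonferroni-corrected over the four emotions.
* **Mann–Whitney**: U from midranks; z from the tie-corrected normal
  approximation without continuity correction (this convention reproduces
  |z| = 4.49 for the fully separated 15/13 trait comparison); p is exact
  (full null distribution by recursion) when the pooled sample is untied
  and ≤ 20, asymptotic otherwise. Two effect sizes are reported —
  rank-biserial r = 1 − 2U/(n₁n₂) and z/√N — because published r values
  for this design are internally inconsistent under either standard
  definition (complete separation forces rank-biserial r = 1), so neither
  is privileged.
* **Effect-size conversion**: f = √(η²/(1 − η²)) and its inverse are both
  exposed; the sample-size utility searches the smallest total N whose
  within-between interaction power, under noncentrality
  λ = N·f²·mε/(1 − ρ) with df ((g−1)(m−1)ε, (N−g)(m−1)ε), reaches the
  target. It is validated against a Monte-Carlo simulation of the
  equicorrelated generative model rather than against any published sample
  size (the published η² = 0.40 → f = 0.44 conversion does not follow from
  the standard formula, which gives f = 0.8165; both are computable here).
* α = 0.05, two-tailed, throughout.

## Numerical and scale choices

Calibration and power runs use a vectorized evidence → counts → eAUC path
sharing its response mapping and its cumulative-count/trapezoid arithmetic
with the record-level simulator (equality of the two paths is tested to
float precision). Problem sizes in the test suite — 5,000 trials per
condition for recovery, 1,000 replicate studies for type-I calibration,
1,000 random curves for the polygon-area oracle, 10,000 trials for jitter
marginals — were chosen so Monte-Carlo error is several times smaller than
the tolerance being checked while the whole suite stays interactive
(≈ 10 s).

## Known limitations

* The observer model is stationary; real participants drift, lapse and
  change criterion across 90 minutes.
* The synthetic speech-like clip reproduces only coarse spectro-temporal
  statistics (harmonic structure, syllabic envelope); none of the emotion
  prosody that motivates the task.
* The eAUC from six operating points and 30 + 30 trials is biased toward
  0.5 relative to the population AUC; analyses compare groups on the same
  scale, so the bias largely cancels, but absolute eAUC values should not
  be read as unbiased sensitivity estimates.
* Group inference assumes the deficit parameterization; it cannot
  distinguish sensitivity loss from criterion or confidence-mapping
  differences, which the paradigm itself does not identify.
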