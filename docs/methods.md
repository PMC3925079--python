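# Methods

## Problem setting

Two-class (left vs. right hand) motor-imagery BCIs decode intent from
sensorimotor rhythms: the mu rhythm (~8–12 Hz) and the beta rhythm
(~16–22 Hz), whose amplitude drops contralaterally during imagery
(event-related desynchronization, ERD). Which frequencies are informative
varies strongly across people, and a sizeable minority show no usable
modulation at all. The package addresses two linked problems:

1. **Decoding**: estimate, per subject, a posterior distribution over the
   discriminative frequency band and classify trials with an ensemble of
   band-specific spatial-filter pipelines.
2. **Screening**: from two minutes of resting EEG recorded before any
   task, predict the subject's later imagery accuracy.

## Band posterior (decoding)

A frequency band is a vector `B = (b_s, b_e)` on a 0.5 Hz grid between
4 and 40 Hz with `b_e − b_s ≥ 2` Hz. The posterior `p(B | X, Ω)` given
trials `X` with labels `Ω` is proportional to a likelihood times a uniform
prior over valid grid cells. The likelihood of a band is the probability
that the trials are classified correctly after restricting the signal to
that band; it is estimated as the mean accuracy of 4-fold *chronological*
inner cross-validation of the chain

    band-pass (Butterworth order 5, zero phase)
    → CSP (generalized eigenproblem S1 w = λ (S1+S2) w on class-mean,
      trace-normalized per-trial covariances; m = 2 filter pairs)
    → log-variance features → Fisher LDA (pooled covariance, equal priors).

The posterior is represented by 100 weighted particles and refined by
iterated importance resampling: weight by likelihood, systematic
resampling, Gaussian rejuvenation (σ = 1 Hz per endpoint, snapped to the
grid, reflected at the range bounds, re-drawn while the minimum bandwidth
is violated), for at most 10 iterations or until the weighted mean band
moves less than 0.25 Hz. Because inner-CV accuracies live in [0.5, 1],
raw weights exert weak selection pressure; weights are therefore
sharpened as `accuracy^τ` with τ = 10 (configurable, including τ = 1 for
raw accuracies). If no band beats chance by a margin (0.1 by default) the
posterior is left uniform and flagged. Classification of new trials is a
posterior-weight-weighted vote over the per-particle LDA decisions.

Likelihood evaluations are memoized per band: after the first iteration
the particle cloud concentrates on few distinct grid cells, which makes
the fit roughly an order of magnitude cheaper than naive re-evaluation.

### 1-D spectral profiles

The particle posterior accumulated on the grid is a 2-D pdf over
(start, end). It is reduced to a per-frequency profile by summing, at each
frequency `f`, the mass of all bands covering `f` and subtracting the same
sum under a uniform band distribution. Positive values mark frequencies
carrying more evidence than a flat band prior would place there; the area
under the positive part (trapezoidal) summarizes a subject's overall
spectral evidence and tracks decoding accuracy.

## Resting-state profile (screening)

Per channel, the Welch PSD (2 s Hann windows, 50% overlap, all segments
pooled) is evaluated on a 0.5 Hz grid from 2 to 34 Hz, and a 1/f
background `g(f) = k1 + k2 / f^λ` is fitted by least squares with grid
points inside 7–14 and 15–25 Hz excluded (the rhythm bands must not bias
the floor), `k2 ≥ 0`, `λ ∈ [0.1, 3]`. The fit profiles the exponent — for
fixed λ the (k1, k2) solve is linear — on a coarse λ grid, then polishes
all three parameters with bounded least squares; a flat PSD degenerates to
`k1 = mean, k2 = 0` with a logged warning. The frequency-related
information `FRI(f) = psd(f) − g(f)` is stored unclipped.

The band likelihood is the band-mean of the positive part of the FRI,
summed over channels; normalizing gives a 2-D band pdf, reduced to a 1-D
profile exactly as above. Positive-FRI values below 1e−9 of the PSD
maximum are treated as zero so that a subject whose PSD equals the fitted
background exactly yields an exactly-zero likelihood, a uniform band pdf,
a zero profile and a zero subject weight — instead of having float
residuals renormalized into an arbitrary pdf.

Normalization discards absolute power, which is the very thing that
separates strong-rhythm from weak-rhythm subjects; the subject weight
`η = Σ_channels max_f FRI⁺(f)` restores it. η is computed from the FRI
rather than the raw PSD so the 1/f floor does not inflate it (switchable
via `eta_source="psd"`). The final profile is the deliberately
unnormalized `Ξ(f) = η · w(f) · pdf1d(f)`, where `w` is a Gaussian-mixture
frequency weight encoding that mu and beta frequencies matter for imagery.

### Choice of the mixture weight

The default mixture is `0.6·N(10, 5²) + 0.4·N(19, 5²)`. The component
widths were set by a design constraint rather than by the width of the
rhythms themselves: the weight must emphasize the sensorimotor range over
the spectrum edges *without displacing a subject's individual peak
frequency*. The membership-sum profile of a genuine spectral peak has
adjacent-bin ratios as low as ~1.08, so the weight's growth toward its
centers must stay below ~5% per Hz across 8–12 Hz, which requires σ ≳ 5.
Narrower components (σ = 2–3) demonstrably pull an 8 or 12 Hz peak toward
10 Hz by up to 1 Hz. The mixture cancels out of the predictor's grid
features entirely (z-scoring removes any fixed per-frequency factor), so
this choice only affects peak readout and the AUC scalar.

## Performance predictor

Each subject contributes an augmented vector `[Ξ on the grid, AUC(Ξ), η]`
(67 numbers). Coordinates are z-scored across the cohort — otherwise the
two scalars would be negligible against 65 grid values — and reduced by
PCA retaining 95% variance (capped at n−1 components). Ward hierarchical
clustering (scipy, exact for the Ward criterion) groups the cohort into
K = 5 clusters by default; a subject's predictor vector holds its
Euclidean distances to the K cluster centers, and ordinary least squares
with intercept maps distance vectors to observed accuracies. Prediction
for a new subject is projection → distances → linear model. Evaluation is
leave-one-out: the held-out subject enters neither the z-scoring, the
PCA, the clustering, nor the regression. `sweep_cluster_count` repeats
this for K = 1..20.

## Synthetic data generator

No public recordings accompany the original cohort, so the generator is a
first-class, tested component that defines the study conditions.

Signals are built by frequency-domain amplitude shaping of white Gaussian
noise, giving every channel exactly the intended expected PSD: a per-channel
1/f floor `k1 + k2/f^λ` (defaults 0.5, 20, 1.2 — floor ≈ 1.7 μV²/Hz at
10 Hz) plus Gaussian-shaped rhythm peaks. Each rhythm component owns a
left- and a right-hemisphere source placed under C3/C4 and projected onto
the cap through a geometric mixing matrix (Gaussian fall-off with lattice
distance, spread 1.5). Stationary spectral shaping was chosen over
amplitude-modulated burst trains because it matches the analytic target
PSD exactly in expectation, which the generator's own validation tests
rely on; the planted spectral shape is identical either way.

During imagery, the source contralateral to the imagined hand is
attenuated in amplitude by the ERD depth (default 0.8). The default
planted rhythm sits at 12 Hz with width 1 Hz and peak amplitude
2 μV²/Hz — a moderate, realistic peak over the floor. Critically, each
trial draws lognormal amplitude jitter: per-channel background scale
(σ = 0.4 in log amplitude) and per-source rhythm scale (σ = 0.3). This
models the large trial-to-trial power non-stationarity of real EEG.
Without it, broadband variance features are implausibly stable across
trials, every band containing the rhythm classifies perfectly, and the
band posterior cannot concentrate — frequency-band selection only carries
information because wide bands admit fluctuating broadband power.

The cohort generator draws mu-type (peak 5–15 μV²/Hz near 10 Hz, ERD
0.6–0.9), beta-type (2–7 μV²/Hz near 19 Hz, ERD 0.5–0.8) and flat-type
(≤ 0.5 μV²/Hz, ERD ≤ 0.3) subjects; true performance is
`0.5 + 0.45·sigmoid((√(amp·erd) − 1.46)/0.61)` plus Gaussian noise
(σ = 0.05), calibrated so the type means land near 0.9 / 0.8 / 0.55.
Resting and imagery data derive from the same subject parameters, so
resting spectra statistically predict imagery performance — the structure
the screening pipeline assumes.

What the generator does **not** emulate: eye/muscle artifacts,
eyes-open/closed alpha reactivity, volume-conduction-accurate forward
models, session drift, and occipital alpha sources sharing the mu band.
Passing tests therefore demonstrate correctness of the estimation
machinery under a faithful spectral model of EEG, not robustness to every
artifact of real recordings.

## Numerical choices and degenerate inputs

- Covariances are shrunk toward a scaled identity only when their
  condition number exceeds 1e10 (logged); a zero matrix shrinks to the
  identity.
- Zero-variance projections are floored at 1e−12 before the log.
- LDA ties (score exactly 0) go to the first label in sorted order.
- Chronological folds are contiguous blocks; remainders go to the earliest
  blocks; folds whose training block is single-class are skipped with a
  warning.
- Ward ties break toward the lowest pair index (the Ward criterion is
  reducible, so the scipy merge order sorted by height equals greedy
  agglomeration; a brute-force oracle in the tests checks this).
- An undefined Pearson correlation (zero variance) is reported as NaN by
  `pearson` and as 0 with a flag by the cluster-count sweep.

## Problem sizes

Validation runs use the study-scale protocol throughout: 150 imagery
trials (75 per class, 4 s at 100 Hz, 16 channels), 150 s of resting data
per subject, 80-subject cohorts, 100 particles, 8 outer / 4 inner
chronological folds. Band-posterior parameter-recovery checks use 5
seeded repetitions; likelihood memoization keeps a full 8-fold outer CV
of the Bayesian pipeline at roughly three minutes on one core.

## Known limitations

- With very strong rhythms the inner-CV accuracy saturates at 1 for every
  band containing the rhythm, and the posterior honestly spreads over all
  such bands; the posterior concentrates only where the likelihood
  discriminates. This is a property of accuracy-based likelihoods, not of
  the particle scheme.
- The heuristic band-selection baseline expands until the correlation
  score falls below 5% of its maximum; with 150 trials the null
  correlation level (~0.2 across 16 channels) rarely falls that low, so
  the selected band is typically broad.
- The 1/f fit is identifiable only with enough floor-dominated grid
  points; pathological spectra fall back to a λ = 1 fit with a warning.
- Electrode neighbor maps for the Laplacian montages come from an
  idealized 10-10 lattice; physical caps differ at the edges, and the
  maps are user-overridable.
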