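# Methods

## The task and what the generator emulates

The single-exposure visual memory task shows each image exactly twice:
once as *novel*, later as *repeated*, with `n_back` intervening trials.
`generate_task_sequence` schedules pairs greedily so realized n-backs are
drawn as uniformly as packing permits from a target set (default
{1, 2, 4, 8, 16, 32, 64}); pairs that cannot be placed on target become
flagged fillers at the nearest free slot, mirroring how real sequences
are completed.  Each image carries a memorability score in [0, 1]
(uniform by default) shared by both presentations.  The categorical task
variant organizes trials into five blocks of 80 images; 80% of a block's
images come from its majority category and pairs never span blocks.
Because a block of 80 images cannot host a 64-back pair, the categorical
variant uses its own target set {1, 2, 4, 8, 16, 32} — the real
categorical task likewise restricted analysis to a narrow n-back range.

## The population model

Neurons sit uniformly on a 4 × 4 mm sheet (default 2000).  The firing
rate of neuron *i* on a trial is

    lambda_i = b_i · (1 + g_mem (m − 0.5)) · c_i(cat) · s(n)
    s(n) = 1 − s0 · exp(−(n − 1)/tau)   (repeated trials; 1 otherwise)

with per-neuron baselines `b_i` gamma-distributed around 10 Hz
(CV 0.3), memorability slope `g_mem = 0.3`, repetition suppression
`s0 = 0.4` decaying with recency constant `tau = 24` n-backs, and
category gain `c_i` equal to `1 + 0.8` for the neuron's preferred
category (1 otherwise).  Spike counts are Poisson in a 300 ms window.
The exponential decay of suppression is a modeling choice; the data it
emulates only establish a monotone decline with n-back.

Category preference comes from per-category Gaussian latent fields over
the sheet: with `clustering_length = 0` the fields are i.i.d. and the
preference map is salt-and-pepper; with a positive squared-exponential
correlation length (default 1.0 mm for the clustered scheme) preference
forms patches.  `nearest_neighbor_morans_i` verifies the two regimes
against a permutation null in the tests.

**Channels.**  24 channels on a regular grid each pool the sheet with
Gaussian weights (SD = pooling_radius/2 = 1 mm, truncated at 2 mm,
normalized to sum to 1).  The channel aggregate pools the *true* rates —
not the realized counts — of every neuron in the radius, plus additive
Gaussian noise (SD 2.5 Hz per trial).  This is the core asymmetry of the
model: a channel averages the activity of >1000 effective neurons while
only two of them are exported as sorted units, so trial-by-trial Poisson
variability (~6 Hz SD for a 10 Hz unit in 300 ms) is largely absent from
the channel signal.  That is what makes magnitude codes *more*
data-efficient per channel than per unit, while any pattern whose spatial
scale is below the pooling kernel cancels to a residual of order
1/sqrt(K_eff).  The pooling factor of a real probe is unknown; it is a
free parameter here, and the default was chosen (together with the
channel noise) so that the three coding-scheme regimes are cleanly
separated at desk scale: salt-and-pepper washout robustly near chance,
1 mm clusters surviving pooling, magnitude codes amplified.  A degenerate
`pool="counts"` mode pools each channel's own exported unit counts
instead, making channel and unit observations informationally identical —
the control under which the efficiency ratio is 1 by construction.

**Voltage mode** exists solely to exercise the spectral chain: pooled
Poisson spike trains convolved with a 2 ms biphasic kernel, an evoked
transient (`evoked_gain = 2`) in the response window, 1/f background
noise flattened below 1 Hz (true 1/f diverges at DC and would alias a
slow drift into every epoch; hardware high-passes in this range), and an
optional 60 Hz contaminant.  It is not a biophysical LFP model — no
dendritic currents or volume conduction — and the absolute HGA
percentages it produces are not calibrated to tissue.

**Behavior.**  The simulated observer reports "repeated" when a noisy
copy of the suppression signal `s0·exp(−(n−1)/tau)` exceeds a criterion
(default `s0/2`, readout noise SD 0.15), producing hit rates that fall
with n-back and false-alarm rates set by the criterion.

## Spectral chain

Voltage is low-passed below 250 Hz (8th-order type-I Chebyshev, 0.05 dB
ripple, applied zero-phase), decimated to 500 Hz, and line noise is
removed by harmonic regression (least-squares sine/cosine fit at 60 Hz;
harmonics configurable).  Amplitude is estimated with 8-cycle Morlet
wavelets on the 50-point grid of squares of values linearly spaced
between sqrt(2) and sqrt(200) — the quadratic spacing spans 2–200 Hz with
widening gaps.  Kernels are normalized so a unit sinusoid at a grid
frequency reads amplitude ~1; the transform mirror-pads the trace and
flags samples within one wavelet half-length (4 sigma_t) of the recording
ends.  Percent change is computed per trial and per frequency against the
mean amplitude in [−200, 0) ms; band responses average grid frequencies
inside inclusive band bounds, then time inside a half-open window.

A caveat the tests make explicit: the percent-change estimator with a
200 ms per-trial baseline is positively biased for noise-dominated
signals.  An 8-cycle wavelet at f Hz has sigma_t = 8/(2*pi*f) s, so below
~100 Hz the baseline window holds only a few effective amplitude samples
and E[post/mean(base)] > 1 (Jensen's inequality applied to 1/mean; +7–10%
for pure pink noise across the grid).  Stationarity tests therefore
compare against the Monte-Carlo null distribution of the statistic, not
against a naive 0%.  For evoked, signal-dominated responses the bias is
second-order.

## Pseudopopulation alignment

Per session, images are kept only if both presentations are usable (at a
target n-back, not a filler, and — for behaving sessions — reported on
both rows).  Images are grouped by n-back (or category), ranked by
memorability with ties broken by image id, and the per-group pseudoimage
count is the minimum across sessions; richer sessions are thinned by
taking ranks `round(linspace(1, m, k))`, which spans the full
memorability range without duplicates.  The k-th ranked image of every
session is merged into one pseudoimage whose memorability is the mean of
its contributors.  The exact cross-session pairing rule is one consistent
reading of rank-ordering; nothing downstream depends on it beyond
determinism.  A channel serving several sorted units contributes one
identical row per unit, so spike- and channel-based populations have
matched sizes; cross-validation always splits by image, never by
observation, so this duplication cannot leak between train and test.

## Decoding

The spike-count classifier is `w·x > b` with `w_i = 1/N` and
`b = w·(mu_nov + mu_rep)/2`; ties go to "repeated" (deterministic,
conservative toward the suppressed class).  It is exactly the rule
"population mean count above the midpoint threshold".  The FLD uses
`w = (mu_nov − mu_rep)/sigma^2` with the sample variance averaged across
classes and off-diagonal covariance set to zero; a zero-variance
observation gets weight 0 with a logged notice.  Both are verified in the
tests against independent oracles (mean-threshold rule; a brute-force
diagonal-Gaussian likelihood ratio).

Cross-validation: `n_subsample` resamplings of the observation subset; in
each, every observation's image assignment is shuffled within
matched-n-back sets to destroy artificial across-session correlations,
then `n_cv/n_subsample` stratified 80/20 image splits (at least 5 images
per stratum) are evaluated.  Defaults in the pipeline are n_cv = 200,
n_subsample = 20 — enough for stable curve means at desk scale; the
library accepts the conventional 1000/50.

Power-law fits of accuracy vs. size profile the exponent: for fixed `b`,
`y = a·x^b + c` is linear in `(a, c)`, so only `b` is searched (grid plus
bounded refinement on (0, 2]) — deterministic, multi-start-free, and
exact on noiseless model data.  `n_at(0.75)` inverts the fitted curve;
a fit with negligible growth term (|a| < 1e−9) is treated as flat and the
target as unattained.  The efficiency ratio is `n_at` for spikes over
`n_at` for channels.

**Behavioral rescaling.**  FLD decision values of held-out items are
collected per condition (novel, and each n-back) at several measured
population sizes.  Their means grow with population size while spreads
plateau, so the per-condition mean is fit *through the origin* against
size (proportional growth keeps the across-condition rank order of
predictions exactly invariant under rescaling), the SD is fixed at the
mean per-condition SD at the largest measured size, and performance at a
candidate size is the Gaussian probability of the correct sign of the
decision variable (criterion at 0, i.e. the projected class midpoint).
The candidate size minimizing MSE against behavior is chosen;
PQ = 1 − MSE_neural/MSE_benchmark with the benchmark a flat 50%.
Per-condition SD plateaus vs. a pooled plateau was an open choice; the
pooled mean is used.  Novel-trial performance enters the MSE alongside
the per-n-back conditions.

**Category decoding.**  RSA z-scores each observation across images and
correlates image pairs.  The prototype decoder holds out one random image
per category per iteration, averages the rest into prototypes, and
assigns each held-out image to the prototype it Pearson-correlates with
most strongly (ties to the lowest category index; degenerate zero-variance
pairs score −inf).  Note the scheme's accuracy on pure noise concentrates
per dataset at 0.20–0.25 rather than exactly 0.2 — small-sample structure
in a fixed dataset is exploitable even without labels — which is why the
salt-and-pepper channel-level accuracy hovers slightly above nominal
chance.  A Euclidean nearest-centroid variant exists only as a robustness
check on the choice of classifier.

## Alignment verdicts

A variable is *aligned* when channel-level decodability above chance
reaches at least `alignment_threshold` (default 0.5) of unit-level
decodability above chance.  The threshold is deliberately below 1:
Gaussian pooling with a kernel comparable to the cluster size blurs
pattern codes partially, so a clustered code that channels decode at
0.7–0.9 (chance 0.2) should count as aligned even when units are at
ceiling; at 0.5 the rule coincides with the margins used in the
acceptance tests (clustered ≥ 0.6 aligned, salt-and-pepper ≤ 0.35
misaligned).

## Default problem sizes

Three sessions of 112 images (memory task) or 400 images in five blocks
(categorical task); 2000 neurons, 24 channels, 48 exported units;
neuron-dropping sizes 1–48; 200 CV iterations in 20 resampling groups;
300 prototype iterations; FLD projections at sizes {8, 16, 32, 48} with
a 160-point geometric candidate grid up to 5000.  These sizes give
stable qualitative results (verified across seeds) with the whole
framework evaluation completing in seconds on one core.  Under these
conditions the magnitude-code efficiency ratio comes out around 4–5,
salt-and-pepper prototype decoding is ~1.0 from units and ~0.2–0.3 from
channels, clustered channel decoding is ~0.7–0.9, and prediction quality
for behavior generated from the readout is ~1.0 for both measures — each
of these is recomputed, not asserted, by `scripts/acceptance.py` and the
test suite.

## What passing tests do and do not show

The generator realizes the *mechanisms* (Poisson spiking, spatial
pooling of rates, multiplicative gains) but not many properties of real
recordings: no correlated trial-to-trial variability within a session, no
adaptation beyond the repetition effect, no drift or electrode
instability, no biophysical LFP generation, and channel noise that is
white rather than 1/f in rate mode.  Passing the suite shows the analysis
chain is correct and that the coding-scheme logic follows from the stated
assumptions — not that real cortex satisfies those assumptions.

## Known limitations

* The sequence packer is greedy; extreme n-back mixtures that a
  constraint solver could schedule may be reported infeasible.
* `preprocess_lfp` requires the input rate to be an integer multiple of
  500 Hz.
* The per-trial percent-change baseline is biased upward for
  noise-dominated signals (quantified above).
* `rescale_to_behavior` assumes proportional mean growth; readouts whose
  means saturate with population size would need a different growth
  model.
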