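# Methods

This note documents the generative model behind the simulator, the
analysis procedures, the parameter choices that matter, and the known
limitations — in particular, what passing the test suite on simulated
sessions does and does not establish about real recordings.

## Electrode geometry

A standard 8×8 MEA grid (200 µm pitch) with the four corners absent and
one reference position (column 1, row 5) omitted gives 59 recording
electrodes.  The microtunnel device is aligned so rows 1–3 lie in Well A,
rows 4–5 beneath the tunnel bridge, and rows 6–8 in Well B.  The probe
stimulus is delivered on the outer Well-A row (electrode "41" by default);
the stimulated channel is excluded from analysis.

## The two-well simulator

### Spiking model

Each electrode fires a homogeneous Poisson baseline (default 1.3 Hz,
within the 0.94–2.32 Hz range typical of these cultures).  A network burst
in a well adds, independently per electrode, an inhomogeneous Poisson
packet under an alpha-function envelope

r(t) = R·(t/τ)·exp(1 − t/τ),  truncated at 300 ms,

with peak rate R = 50 spikes/s and rise time τ = 30 ms.  Burst-spike
offsets are therefore Gamma(2, τ) draws (resampled beyond the truncation
point), ≈4.1 spikes per electrode per burst in expectation.  The alpha
envelope was chosen because it has a single well-defined peak — the
quantity the peak-to-peak delay estimator needs — while remaining
right-skewed like measured burst profiles.

### Burst timetable

Every stimulus (60 per session, one per 10 s, ±800 mV/200 µs biphasic
metadata) evokes a source-well burst at a latency of 10 ± 3 ms.  Each well
additionally produces spontaneous bursts as a Poisson process (default
1.2/min, mid-range of the measured 0.71–2.85/min group rates).  Every
source-well burst crosses to the opposite well with probability
`transmission_probability(n_axons)` and onset delay
Normal(`mean_transmission_delay(n_axons)`, 30 ms) truncated positive;
spontaneous bursts in the downstream well cross backwards with the same
probability scaled by `reverse_coupling_factor` (default 0.1, emulating
the few axons that grow against the plating direction).  Transmitted
bursts do not re-transmit.  Reverse plating (`source_well = "B"`) swaps
the roles of the wells symmetrically.

### Dose-response calibration

The calibration is anchored to the printed dose-response values at ~10
axons per tunnel:

- **Success probability**: piecewise-linear through (0, 0), (20, 0.20),
  (50, 0.50), (100, 0.80) axons, constant 0.80 beyond 100 (the propagation
  probability plateaus around ten tunnels).  No values are invented for
  the 15- and 51-tunnel groups.
- **Mean onset delay**: µ(n) = 90 + 210·exp(−(n − 20)/60) ms for n ≥ 20
  axons, clamped to 300 ms below 20.  Only the two printed bounds (300 ms
  near 20 axons; < 100 ms near 510) constrain the curve; the exponential
  shape between them is a modelling choice, flagged as such.  The 30 ms
  delay jitter reflects trial-to-trial recruitment variability.

### Tunnel relays

Tunnels are assigned to grid columns from the device centre outward.  For
each source-well burst, every pooled burst spike is relayed through a
column with probability min(1, 0.02 × local axon count) — 0.02 per axon so
a single 10-axon tunnel relays 20% of burst spikes — and reaches the two
tunnel-row electrodes at 1/3 and 2/3 of that axon's total conduction delay
D ~ Uniform(0.4, 2.2) ms (a 400 µm tunnel at the reported 180–1140 mm/s
conduction velocities).  The shared relayed spikes, ordered near-row
first, are what give the tunnel electrode pairs their direction-resolved
Granger structure.

### Raw traces

`render_raw_trace` emits 25 kHz voltage: Gaussian noise, a ~1 ms
negative-leading biphasic template whose trough aligns with each spike
timestamp (default amplitude 8× noise SD; amplitudes below 6× are
rejected as ill-posed for 5×-SD detection), and per-stimulus decaying
exponential artifacts (5 ms time constant).  Overlapping events superpose
linearly.

### Determinism

All randomness in a session flows from a single integer seed through
`numpy.random.SeedSequence` spawns (event timetable, envelope spikes,
relays, baselines), so identical `(config, seed)` reproduce identical
outputs.

## Preprocessing

Noise SD is estimated robustly as MAD/0.6745 over the quiet half of the
trace (100 ms windows whose peak |amplitude| is below the median window
peak), so bursts do not inflate the threshold.  Spikes are negative
crossings of −k·SD (k = 5) timestamped at the local trough within 1 ms,
with a 1 ms dead time.  Around each stimulus, 5 ms is blanked to the local
baseline and the following 20 ms replaced by the residual of a local
degree-≤3 polynomial fit; samples outside these windows are never
touched.  All parameters are exposed in the configuration.

## Burst detection (summex)

Per electrode, the burstlet ISI threshold is 25% of the inverse mean
detection rate computed over the *whole* recording (recomputing in short
evoked windows is unstable); silent electrodes are skipped.  Burstlets are
maximal runs of ≥4 spikes with all ISIs below threshold.  Network bursts
are connected components of the closed-interval overlap graph over a
region's burstlets — for interval graphs this is an exact start-ordered
sweep — discarding components shorter than 10 ms.

A practical subtlety drives two classification parameters.  With ~1.3 Hz
baselines the ISI threshold is ~0.15 s, so (a) chance 4-spike baseline
runs create frequent single-electrode "bursts", and (b) a genuine network
burst's earliest burstlet often chains backwards over pre-burst baseline
spikes, placing the event *start* up to a few hundred ms before the true
network onset.  Trial classification therefore requires a burst to span
≥4 electrodes (`min_electrodes`), takes its onset as the **core onset** —
the earliest moment ≥8 electrodes (`core_electrodes`) burst
simultaneously — and accepts evoked onsets up to 300 ms before the
stimulus (`lead`; stimuli are 10 s apart, so misattribution is
negligible).  Against simulator ground truth these settings classify
trials with ≈1–2% false positives (almost all genuine spontaneous
downstream bursts that coincide with the analysis window, which no
spike-level observer could distinguish from propagation) and ≲1% false
negatives.

## Propagation metrics

PSTHs use 5 ms half-open bins over the 500 ms post-stimulus window,
excluding blanked spikes and the stimulated electrode; trials whose window
overruns the recording are dropped and logged.  The region profile is the
across-electrode mean.  For peak finding the profile is smoothed with a
Gaussian of SD = 1 bin and the global maximum taken, ties resolved toward
the earlier bin (a separate 3-bin display smoothing is available but never
used for analysis).  Peak-to-peak delay is the difference of the two
wells' peak-bin centres, defined only for trials classified as successful.
First-spike latency at threshold f ∈ {0.1, 0.2, 0.5} is the first pooled
region spike at or after the earliest bin (at or before the peak) where
the smoothed profile reaches f × peak; if the level is never reached the
peak-bin start is used.  This construction makes the 10% ≤ 20% ≤ 50%
latency ordering structural.  Success fractions are successes over trials
with a detected evoked burst; means carry 95% t-intervals.

## Conditional Granger causality

Electrodes must exceed 0.5 Hz over the whole recording (not per window) to
enter.  Per trial, spike counts in 1 ms bins are clipped to binary and
convolved with the causal kernel exp(−t/4 ms), truncated at 10τ; trials
remain separate segments and are mean-centred per channel, so smoothing
and regression never cross trial boundaries (pooling lagged covariance
across the evoked windows rather than concatenating them avoids spurious
cross-trial lags).  A VAR(10) is fitted by pooled least squares.  An
order-selection utility (AIC/BIC) is provided but the order is fixed at 10
by default.

CGC(i→j) = ln(RSS_restricted/RSS_full) for target j with and without
source i's ten lag columns, conditioned on all other channels; negative
estimates are clipped to zero.  The all-pairs matrix uses the exact nested
ordinary-least-squares identity RSS_r = RSS_f + b_Sᵀ[(ZᵀZ)⁻¹_SS]⁻¹b_S, so
one Gram inversion serves every ordered pair; the pairwise route fits both
regressions explicitly, and the two agree to numerical precision.
Significance is the F-test that the ten lag coefficients are jointly zero,
Benjamini–Hochberg-corrected over all ordered pairs at q = 0.001.

Summaries report (a) the cross-well percentage of significant A→B edges,
with both printed normalisations available — edges originating in Well A,
or all edges among well electrodes — since the two definitions are
deliberately preserved, and (b) the tunnel directional bias: significant
CGC weight between the two tunnel rows in the plating direction versus
against it, as percentages of their sum.  Graphs (nodes: electrodes with
region/row/column; edges: significant pairs weighted by CGC) are written
as GEXF and GraphML for external layout tools.

## Problem sizes used in validation

Dose-response checks pool 20 seeded sessions × 60 stimuli per tunnel group
(2, 5, 10, 15, 51 tunnels), ~1200 classified trials per group, and compare
pooled success percentages to the calibration anchors within 3 binomial
standard errors and pooled mean delays within 3 standard errors of the
mean (2-tunnel group) or against the 100 ms bound (51-tunnel group).
Oracle suites run 500 random trains against brute-force burst detection, a
spectral (Kolmogorov) closed form and an independent regression oracle for
CGC (10⁻⁸ relative agreement), 20-replicate null FDR calibration at 15 Hz,
and ground-truth-reversing directional-bias checks.

## Known limitations

- **No millisecond-scale well-to-well coupling.**  Downstream burst spikes
  are drawn from their envelope, not triggered spike-by-spike through the
  tunnels, so direct A→B CGC edges are essentially absent in simulation
  and the cross-well connection percentage stays near zero rather than
  rising to the tens of percent seen in real cultures.  The directional
  structure lives on the tunnel electrodes, where it is calibrated and
  tested.  Passing tests therefore validates the estimator mechanics, not
  a quantitative cross-well connectivity prediction.
- **Coincidence contamination is irreducible.**  Spontaneous downstream
  bursts landing in an analysis window are counted as propagation by any
  spike-level pipeline (ours and the original); at the default spontaneous
  rate this inflates the 2-tunnel success estimate by ~1.5–2 percentage
  points and pulls its pooled delay a few ms below the generative 300 ms.
- **F-test tails on very sparse trains.**  Binary-smoothed trains have
  Bernoulli innovations; below a few Hz their kurtosis (~1/p) inflates the
  10⁻³ tail of the F statistic by an order of magnitude, making the FDR
  mask anticonservative for near-threshold electrodes.  At burst-range
  rates (≥15 Hz), where the evoked-window analysis operates, the mask is
  cleanly calibrated.  A permutation-based p-value would remove the bias
  at considerable cost and is left out of scope.
- **Non-goals.**  No biophysical neuron or synapse models, no spatial axon
  growth, no spike sorting (analysis is multi-unit per electrode), no
  reproduction of the non-monotone reverse-direction percentages reported
  for real devices (reverse coupling is a single scalar), and no
  force-directed layout (graphs are exported for Gephi-class viewers).
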