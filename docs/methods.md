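# Methods

## Detection model

The detector treats seizure finding as chunk classification followed by
temporal smoothing.  A recording sampled at f_s = 256 Hz (telemetry band
1–160 Hz) is tiled into half-open 5-s windows; a trailing partial window is
dropped so every chunk yields a fixed-length feature vector.  A chunk is
labeled ictal iff it overlaps a labeled ictal interval by strictly more than
0 s — no minimum-overlap fraction is imposed, so a seizure clipped by a chunk
boundary still marks that chunk.

Each chunk maps to 15 features: coastline Σ|x_{i+1} − x_i|, variance,
skewness, excess kurtosis, RMS, peak-to-peak, zero crossings (on the
mean-subtracted signal), the 95th percentile of |x|, integrated Welch power
in 1–4, 4–8, 8–12, 12–30, 30–70 and 70–120 Hz, and normalized spectral
entropy.  Spectral estimates use Welch averaging with 1-s Hann segments at
50% overlap — long enough for 1 Hz resolution, short enough to average nine
segments per chunk.  Degenerate inputs follow a fixed convention: skewness,
kurtosis and entropy of a constant chunk are 0.  The feature list is
pluggable (`FeatureConfig`) so an alternative set can be substituted without
touching the classifier; the default covers amplitude, waveform shape and
band power, the classes of descriptor a visual reviewer uses.

The chunk classifier is a random forest (100 trees, class-balanced weights,
mandatory seed) over z-scored features; the z-scoring statistics are
computed on the training library and stored with the model.  Cross-validated
predictions parameterize a two-state HMM: hidden states are the human
annotations, emissions the classifier's discrete predicted labels.
Cross-validation folds are grouped by session (default 5 folds) because
neighboring chunks of one recording are strongly dependent; splitting them
across folds would leak and inflate the emission matrix's diagonal.
Transition, emission and initial probabilities are add-one-smoothed counts:
without smoothing, a training corpus with no observed ictal→ictal transition
would forbid the smoother from ever remaining in the ictal state.

Posteriors γ_t(s) = P(s_t | o₁…o_T) come from the forward–backward
recursion with per-step scaling (the scale factors are reused in the
backward pass), which is exact and underflow-free for sequences of at least
10⁶ chunks.  Chunks with γ_t(ictal) ≥ 0.5 become candidate ictal chunks;
maximal runs are merged into events, and runs separated by at most one
interictal chunk are joined (a one-chunk dip inside a seizure is more often
classifier noise than two seizures 5 s apart).  Threshold and gap are
configurable; 0.5 and one chunk are the defaults.  Emissions are discrete
labels rather than class-probability vectors; probability emissions would be
a natural extension but change the estimator for B.

Event boundaries therefore lie on the 5-s grid.  The review round trip
(`export_for_review` / `import_review`) lets a human reject events and move
boundaries off-grid; human overrides win verbatim and re-import yields a
`provenance="verified"` annotation set.

Evaluation is seizure-level: a true event counts as detected iff any
detected event overlaps it; the false-negative rate is misses/true events;
detected events overlapping no true event are false positives, reported per
day.  False positives are deliberately tolerated (they are removed during
review); the design optimizes against misses.

## Synthetic ECoG

The generator emulates the statistical structure the detector relies on, not
the biophysics of chemoconvulsant seizures.  Background is Gaussian 1/f^β
noise (default β = 1, RMS 50 µV), band-limited to 1–160 Hz by FFT shaping;
its average log-log periodogram slope over 2–60 Hz reproduces −β within
±0.3.  Seizures are rhythmic 5 Hz discharges with 2nd/3rd harmonics, a slow
amplitude modulation and 1–1.5 s edge ramps, added on top of the continuing
background and scaled so the total ictal RMS is `ictal_amplitude_ratio`
(default 6) times background.  Event times and durations are caller-supplied
ground truth; annotations carry them exactly.

What passing tests show: the pipeline separates high-amplitude rhythmic
events from 1/f background at the stated contrast, the smoothing respects
event structure, and the bookkeeping (labels, events, metrics) is exact.
What they do not show: performance on real kainic-acid EEG, whose artifacts
(movement, electrode noise, spike-wave variants) the generator does not
model.

Problem sizes in the test and acceptance suites are scaled to the synthetic
setting: 20-minute sessions (8 for training with ~6 seizures each, held-out
sessions with ~10 seizures each until 300 true events are seen, ~10 h of
signal).  Seizure durations are drawn uniformly from 20–40 s with 40–80 s
gaps — the regime of generalized convulsive events rather than brief
electrographic bursts.

## Model neuron and current-clamp analysis

The model cell is an exponential integrate-and-fire (EIF) neuron:
τ dV/dt = −(V − E_L) + Δ_T exp((V − V_T)/Δ_T) + R·I, with defaults
E_L = −70 mV, R = 150 MΩ, τ = 15 ms, V_T = −45 mV, Δ_T = 2 mV, reset
−65 mV, 2 ms absolute refractory.  When V reaches the blow-up cutoff
(V_T + 5Δ_T) a stereotyped spike is pasted — linear rise at 400 mV/ms to
+35 mV, linear repolarization (default 100 mV/ms) to reset — giving
well-defined peak times, a genuine 0 mV crossing, an upstroke far above the
20 mV/ms criterion, and a repolarization-rate knob that monotonically
controls the half-width.  Forward-Euler integration at 0.02 ms (the 50 kHz
digitization rate of patch recordings); the Euler bias on a 15 ms membrane
time constant at this step is below 0.1%, and a 10× finer integration serves
as the spike-count oracle in tests.  Sweep noise is additive white Gaussian
voltage noise (default 0.2 mV RMS): at 50 kHz its central-difference dV/dt
contribution is ~7 mV/ms, safely below the spike criterion.

AP detection: one event per upward 0 mV crossing whose preceding rising
phase reaches dV/dt > 20 mV/ms (central differences); the next event is not
registered until the trace falls back below 0 mV.  The threshold point is
found by walking backward from the crossing through the contiguous run of
samples with dV/dt ≥ 20 mV/ms — the paper trail for this criterion states
the thresholds but not the numerical scheme, so central differences and the
backward search are this package's choices.  Half-width is full width at
half the threshold-to-peak amplitude with linear interpolation between
samples (threshold-to-peak is one of several conventions in use; it is
documented rather than asserted as canonical).

Passive properties: per-step R = steady-state ΔV/ΔI with the steady state
averaged over the final 20% of the step; reported R averages the two most
negative steps and the first subthreshold positive step; τ is a
least-squares single-exponential fit of the relaxation on the largest
hyperpolarizing step.  The fitted trace is boxcar-smoothed over 1 ms — a
linear filter leaves an exponential's time constant unchanged away from the
onset, so the first millisecond is excluded and the model carries a free
onset offset — and the fit window is 8 initial-τ-estimates long with the
initial estimate taken from the 63% crossing of the smoothed trace (a raw
crossing can be triggered spuriously by one noise excursion).  C = τ/R
(ms/MΩ = nF, reported in pF).  Sweeps with holding instability are the
caller's exclusion responsibility; recording-quality thresholds (e.g. access
resistance) concern acquisition, not this offline analysis.

## Activity clamp

Dynamic-clamp current I = g_exc(E_exc_eff − V) + g_inh(E_inh_eff − V) in
pA (nS × mV), iterated at 15 kHz against the EIF cell.  Set reversals are
0 / −75 mV; the junction correction is applied as E_eff = E_set − 14.9 mV
(recorded potentials read more depolarized than true).  The sign of this
correction on the original rig is not documented, so it is configurable; the
chosen sign is stated here rather than asserted.  Conductance templates are
24 disjoint bursts (300 ms Hann envelopes with slow positive modulation,
inhibition lagging excitation by 3 ms), with peaks normalized exactly to the
requested values.  Default peaks are excitation-dominated (12 / 4 nS, E/I
3:1) so the combined synaptic reversal (≈ −34 mV after junction correction)
lies above the spike threshold — a barrage whose combined reversal sits
below threshold can never evoke a spike at any scale, and the epileptiform
input being emulated is by definition pro-convulsive.

The conductance threshold is the smallest common scale factor on both
templates evoking ≥ 1 spike, found by geometric bracketing (doubling from
1% of the search ceiling) and bisection to 1% relative width; a fine-grid
scan is the test oracle.  A static potassium-like conductance
(E_rev = −90 mV) added to the cell monotonically suppresses the spike count
— the direction of the excitability effect this assay is designed to read
out.  Integration-step adequacy is checked by re-running at a 4× finer step
with linear template interpolation (agreement within ±1 spike).

## Statistics

- Discrimination index: (t_altered − t_unchanged)/(t_altered + t_unchanged),
  in [−1, 1]; undefined (None) with no exploration.
- ΔΔCT: ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the mean
  control ΔCT (default) or, with `paired_by`, the control ΔCT within the
  sample's own pairing group (the within-animal contralateral design); fold
  change 2^(−ΔΔCT).
- Fisher's exact test: two-sided p by summing hypergeometric probabilities
  of all margin-fixed tables whose probability is ≤ the observed one, with a
  1e-7 relative tolerance on the comparison so floating-point ties are
  included.  Degenerate margins return p = 1.
- Cohort summaries classify an animal "fewer" only if its treatment-phase
  daily seizure rate is strictly below baseline; ties count against "fewer"
  (rates, not raw counts, are compared, so unequal phase durations are
  handled).  Inclusion requires a baseline rate of at least one seizure per
  week.  Cumulative curves are normalized to the baseline total.

## Known limitations

- The synthetic seizure morphology is a single family (rhythmic discharge);
  classifier generalization across seizure types is untested by design.
- The EIF cell has no adaptation or subthreshold resonance; passive-property
  recovery tolerances assume a single-exponential relaxation.
- EDF output is minimal single-signal EDF (not EDF+); annotations travel in
  a separate CSV, not embedded in the EDF.
- Emissions are binary labels; classifier confidence is only used through
  the posterior threshold, not the emission model.
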