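# Methods

This note describes the analysis implemented by `apnoea_eeg`: how breathing
pauses are found in neonatal respiration traces, how the surrounding EEG is
quantified, and how pause-locked EEG changes are related to vital-sign and
clinical covariates. It also documents the synthetic-data generator used to
validate every stage against known ground truth.

## 1. Respiration preprocessing and breath detection

Raw respiration (e.g. thoracic impedance) is high-pass filtered at 0.5 Hz
with a 2nd-order Butterworth filter applied forwards and backwards
(zero-phase). Movement artifacts are then removed iteratively: samples whose
filtered amplitude exceeds 5 standard deviations are flagged, the flagged
samples are repaired by linear interpolation in the raw trace, and the trace
is re-filtered; this repeats up to 10 iterations or until no sample is
flagged. Repairing in the raw trace (rather than the filtered one) prevents
the zero-phase filter's ring-down around a removed spike from surviving
just under threshold.

Breaths are detected as upward crossings of an adaptive threshold set to
0.5 x the signal's standard deviation computed over the span of the
previous 120 breaths, with a 0.5 s refractory period; before enough breaths
have accumulated, the threshold is seeded from the first 60 s of signal.
The previous generation of the algorithm (0.4 x SD over 15 breaths) is
available through the `k` and `w` parameters. Traces shorter than 60 s are
rejected.

## 2. Pause definition, isolation, and baselines

The inter-breath interval (IBI) is the time between consecutive detected
breaths. An IBI of 5-15 s is a **short breathing pause**; an IBI >= 15 s is
an **apnoea**. An event is **isolated** when no other candidate pause
(>= 5 s) starts or ends within the window from 60 s before its start to
90 s after its end; only isolated events enter the EEG analysis, so each
event's surround is uncontaminated by neighbouring pauses.

Each event gets a matched **baseline window** of normal breathing: 30 s for
apnoeas, 10 s for short pauses, searched on a 1-s grid over the 90 s before
the event start (ending at least 15 s / 5 s before it). The grid position
minimising the maximum overlapping IBI is chosen, earliest position on
ties; events with insufficient pre-event data are excluded.

## 3. Candidate vetting (classifier)

Adaptive-threshold detection produces false candidates (shallow but present
breathing). Each candidate is summarised by six features: mean absolute
amplitude and standard deviation of the cleaned trace in three windows —
before ([start-10, start-1) s), inside ([start+1, end-1) s), and after
([end+1, end+10) s) the pause — each normalised by the full-recording
standard deviation, making the features amplitude-scale invariant.

A plain logistic regression (no regularisation) maps the six features to a
probability of being a true cessation; a probability strictly above 0.5 is
required for a "true" verdict (ties fail). Performance is assessed with
leave-one-infant-out cross-validation and reported as balanced accuracy,
(sensitivity + specificity)/2, so infant-level leakage and class imbalance
cannot inflate the estimate.

## 4. EEG time-frequency analysis

EEG (nine 10-20 channels: Fp1, Fp2, C3, Cz, C4, T3, T4, O1, O2) is
band-pass filtered 0.1-30 Hz (2nd-order zero-phase Butterworth). The
time-frequency amplitude map uses 29 logarithmic amplitude envelopes: for
each centre frequency 1.5, 2.5, ..., 29.5 Hz, the signal is band-pass
filtered to +/-1 Hz around the centre (2nd-order, zero-phase), the
instantaneous amplitude is taken as the modulus of the analytic (Hilbert)
signal, and log10 is applied with a floor of 1e-6 uV. Two seconds at each
epoch edge are discarded as filter transient. Channels whose raw amplitude
exceeds +/-500 uV anywhere in an event's epoch are rejected for that event
only.

Event-locked analysis windows are [-90, +150] s for apnoeas and
[-90, +90] s for short pauses; for statistics, segments of +/-15 s
(apnoea) or +/-5 s (short pause) around the pause start and end are
compared sample-wise with the event's own baseline-window map.

## 5. Vital signs

Heart rate outside 40-230 bpm and SpO2 above 100% are treated as missing;
SpO2 readings of exactly 60% are kept but flagged, since cot-side monitors
truncate below that value. The per-event change is the minimum over
[end-5, end+60] s minus the mean over the event's baseline window, and is
only valid when at least 50% of the window's samples survive cleaning.

## 6. Statistics

**Paired t-maps.** For each event category and lock (start/end), the
event-segment stack and baseline stack are compared with a sample-wise
paired t-test (each event paired with its own baseline). The resulting
p-map is thresholded with Benjamini-Hochberg FDR at q = 0.01, applied
jointly over all time x frequency x channel samples of the map.

**Mixed models.** The per-event scalar outcome Y is the mean EEG change
(log10 units) over the [-5, +5] s end-locked window, all frequencies and
retained channels. Five covariates are each fitted in a separate linear
mixed model (REML) with fixed intercept + slope and per-infant random
intercept + random slope:

    Y_n = b0 + b1 X_n + u0_i(n) + u1_i(n) X_n + e_n

Covariates: heart-rate change, SpO2 change, pause duration,
postmenstrual age (with Y first averaged per recording, one row per
recording), and sleep state as a 4-level categorical (TA reference) with
random intercept only and a joint Wald test over its three contrasts. A
singular random-slope covariance triggers a flagged refit with random
intercept only. In the zero-random-variance limit the slope estimate
matches ordinary least squares to within 1e-6 relative error (verified).

## 7. Synthetic-data generator

All numerical claims are validated on synthetic cohorts with known ground
truth. Defaults emulate a neonatal intensive-care recording and are the
study conditions (they were fixed before outcomes were inspected, not tuned
to them):

- **Respiration**: quasi-periodic breathing at 0.75 Hz with smoothly
  jittered instantaneous rate (fractional SD 0.04); three channels
  (thorax/abdomen/nasal) with relative amplitudes and phase offsets.
  Pauses (default: durations 6-25 s, gaps 150-250 s so they are isolated)
  are snapped to the noiseless breath grid, so the ground-truth interval is
  an exact inter-breath gap. During a pause the envelope drops to 2% of
  normal (true cessation); labelled *false* candidates for classifier
  training instead drop only to 20-40% (shallow breathing).
- **EEG**: nine channels of 1/f-power noise (flat below a 0.5 Hz knee) at
  30 uV RMS, multiplied by 10^s during each pause, where
  s = -0.2 log10 units by default. Suppression persists 5 s past the
  pause end (`post_suppression_s`), matching the observed lag of amplitude
  recovery behind breathing resumption — without it, a symmetric
  [-5, +5] s end-locked window would average suppressed and recovered
  halves. A per-infant random slope can couple s to the event's
  heart-rate dip.
- **Vitals** (1 Hz): heart rate baseline 120-170 bpm with slow drift;
  Gaussian-shaped dips of 1.5 bpm per second of pause duration, nadir 10 s
  after the pause end (SD 8 s). SpO2 baseline 97% with dips of 0.5
  percentage points per second, nadir at +25 s (SD 12 s), clipped at the
  60% monitor floor.
- **Sleep states**: four labels (TA, HVS, ASI, LVI) in 30-s epochs from a
  Markov chain with stay probability 0.85.

Randomness is drawn from independent per-modality streams keyed by
(seed, infant index, modality), so omitting a modality (e.g. respiration-
only experiments) leaves the others byte-identical, and every run is
deterministic given the seed.

Scope and limits: the generator produces stationary backgrounds with
stylised event shapes; it does not model state-dependent EEG spectra,
periodic breathing, shared artifacts across modalities, or realistic
inter-channel covariance. It is a test harness for the analysis chain, not
a physiological simulator.

## 8. Numerical choices and problem sizes

Zero-phase filtering uses second-order sections throughout for numerical
stability. The TFA segments kept for statistics are decimated in time by a
factor of 10 (envelope bandwidth is +/-1 Hz, so 25 Hz sampling retains the
information); the FDR family is the full decimated map. Validation problem
sizes were chosen so the whole suite runs on one CPU in minutes: cohorts of
8-20 infants at 15-30 minutes per recording for end-to-end checks, 60
infants x 20 events x 100 replicates for mixed-model recovery.
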