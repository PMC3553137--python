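# Methods

## Problem and approach

`p300cit` decides, for a **single subject**, whether a concealed-salient
item (the subject's own name, the *Probe*) evoked a larger brain
response than matched control items (*Irrelevants*) in a rapid serial
visual presentation (RSVP) stream. The signal of interest is the P300
complex on the condition-minus-Irrelevant1 difference wave: an early
fronto-central positive-then-negative cycle (P3a, maximal at Fz/Cz) and
a later broad parietal positivity (P3b, maximal at Pz).

The decision statistic chain is:

1. **Peak-to-peak on difference waves.** A "peak" is the mean over a
   100 ms *inner* window slid one sample at a time across a *bounding*
   window (P3a: 150–1000 ms, P3b: 300–1000 ms). The statistic is the
   highest window mean minus the lowest window mean found at or after
   the first non-overlapping position following the highest one. For
   the P3a, the highest-peak search is capped: the inner window must
   *end* by 300 ms, so the P3b cannot be mistaken for the P3a's
   positive peak. We read the cap as end-constrained (rather than
   start-constrained) because its stated purpose is to exclude any
   overlap with the P3b region; the cap is configurable
   (`PeakParams.high_limit`).

2. **Per-electrode randomisation test.** Window placement is chosen
   post hoc to maximise the measure, so parametric reference
   distributions do not apply. Instead, the null distribution of the
   *maximal* statistic is estimated by relabelling: the valid Probe and
   Irrelevant1 trials are matched to the smaller count m, pooled
   (2m trials), and B times reshuffled into two m-sized surrogate
   conditions whose ERP difference is scored with the same peak-to-peak
   procedure. A trial is a triple (Fz/Cz/Pz segments) and the
   relabelling is shared across electrodes, preserving within-trial
   cross-electrode correlation. The observed statistic uses *all* valid
   trials (the subject's true ERPs). p = #(null > observed)/B with
   strict inequality, so ties count toward significance.

3. **Fisher combination with a resampled reference.** The three
   electrode p-values are combined as −2·Σ ln p (any strictly
   decreasing function of the p-product gives the same resampled
   p-value). Because the electrodes are correlated, the score is *not*
   referred to a χ² distribution: each null-matrix row is converted to
   its own triple of within-column p-values and Fisher-scored, giving
   B null scores that inherit the correlation structure. The combined
   p is the fraction of null scores above the observed score. Zero
   p-values are replaced by the resolution floor 1/B before the log
   (with B = 1000 that floor is 0.001); a reported p of 0 is displayed
   as "<1/B".

## Numerical choices

* **Time grid.** Epochs are half-open `[epoch_start, epoch_end)` with
  samples at left edges; sample count = `round(span·fs/1000)` for any
  rate. Default synthesis rate is 250 Hz (100 ms windows = 25 samples).
* **Window geometry.** An inner window starting at sample time t covers
  `[t, t+inner)` ms and must lie wholly inside its bounding range;
  starts advance one sample at a time. Argmax/argmin ties break to the
  earliest start, making results independent of storage order.
* **Degenerate low search.** If no full inner window fits after the
  highest peak, the verdict is conservative: p2p = 0 with a
  `degenerate` flag rather than an error.
* **Floating-point tie guard.** Observed and null statistics travel
  different floating-point paths (plain means vs a weight-matrix
  product), so a relabelling that reproduces the true labels can come
  out an ulp away from the observed value. First-level counting
  therefore uses `null > observed + 1e-9·(1+|observed|)`; genuine ties
  are counted toward significance, as the strict-inequality rule
  requires, and for continuous data the guard changes nothing else.
* **Randomness.** Every workflow draws from one `numpy` Generator per
  invocation, seeded from config; sub-draws are ordered (trial
  matching, then resample shuffles), so reports are bit-reproducible.

## Control analyses

* **Early–late habituation control.** Peak-to-peak of the
  (Late − Early) Irrelevant2 difference wave is compared, per channel
  and subject, against peak-to-peak of the (Even − Odd) Irrelevant1
  difference wave — a split in which no temporal effect can exist,
  which matters because peak-to-peak is positively biased under the
  null. Halving uses the chronological order of valid trials; with an
  odd count the early half gets the extra trial. Parity is assigned on
  the 1-based *within-condition rank*, not the raw chronological index,
  so interleaved conditions or rejected trials cannot skew it.
* **Latency difference.** The latency of a component is the start of
  the maximal-mean inner window (P3a: 50 ms windows in 150–400 ms, P3b:
  100 ms windows in 300–1000 ms) on the pooled fixed-effects grand
  average (every trial weighted equally across subjects). Significance
  of the Fake − Probe difference comes from B draws of two disjoint
  m-sized sets from the merged pool (m = smaller condition count; if
  2m exceeds the pool, m is reduced to ⌊pool/2⌋ with a warning).
* **Intrinsic validity.** Null-true datasets are fabricated by randomly
  relabelling epochs from a no-signal pool (distractor-locked segments,
  which keep the background temporal autocorrelation of real EEG) into
  Probe/Fake/Irrelevant1/Irrelevant2 and running the full pipeline.
  The fraction of runs with p < α estimates the intrinsic false-positive
  rate; it should approach α, and the mean null p should approach 0.5.
* **Pairwise screen.** Three interchangeable no-signal conditions give
  six ordered pairs, each analysed with the first member as Probe; the
  significant fraction across a cohort estimates the *empirical*
  false-positive rate of the whole protocol.

## Synthetic data generator

The generator emulates the RSVP design at desk scale: four critical
conditions of 50 epochs each (−100…1000 ms, Fz/Cz/Pz) plus a
distractor-locked pool (default 240 epochs ≈ 4 usable segments from
~60 artifact-free irrelevant trials), chronologically interleaved.

* **Background**: per-channel noise with a 1/f power spectrum,
  flattened below 1 Hz. The flattening mirrors the recording chain's
  high-pass and keeps the process variance well-defined and estimable —
  with unbounded 1/f weight the lowest frequency bin dominates any
  variance estimate; the 1–30 Hz log-log slope stays ≈ −1. Channels
  are mixed to a uniform pairwise correlation (default 0.7, a typical
  value for neighbouring midline electrodes); a 10 Hz alpha sinusoid
  (default 2 µV, random phase per trial, shared across channels) adds a
  rhythmic nuisance component. Default stochastic SD is 10 µV.
* **Components**: one or two Gaussian bumps with per-channel gains —
  a biphasic fronto-central P3a template (guilty default: +8 µV at
  240 ms, σ 40 ms; −6 µV at 400 ms, σ 60 ms; Fake shifted to
  280/440 ms) and a broad monophasic parietal P3b (+10 µV at 500 ms,
  σ 120 ms; Fake at 560 ms). Per-trial latency jitter (20–30 ms SD)
  and per-subject amplitude (15% SD) and latency (20 ms SD)
  perturbations give the cohort random-effects structure. These
  defaults place observed peak-to-peak values in the 5–25 µV range a
  strong own-name effect produces; they are generator conventions, not
  estimates of any individual's physiology.

What the generator does **not** emulate: scalp topography beyond three
electrodes, ocular/muscle artifacts (rejection is exercised only by
amplitude excursions of the noise itself), overlapping responses from
the 133 ms SOA stream, non-stationarity across the session, and
realistic single-trial P3 variability (true trial-to-trial jitter in
this paradigm is unknown; the defaults are assumptions). Passing
calibration and power tests on this generator therefore demonstrates
the statistical machinery's correctness under exchangeable EEG-like
noise, not field performance on real recordings.

## Problem sizes used by the shipped checks

The calibration simulation runs 15 synthetic subjects × 200 fabricated
null datasets × B = 200 resamples (50 epochs per fabricated condition),
chosen as the smallest design whose pooled binomial standard error
(≈0.004 on a 0.05 rate) makes a ±0.02 check meaningful at desk scale.
Oracle-agreement checks use 500 random waves and an exhaustive 20-split
permutation instance; power checks use 100 guilty subjects and 20
latency-shift cohorts.

## Known limitations

* First-level p-values have resolution 1/B and can be exactly 0 or 1;
  a p of 0 means only "beyond the B-resample floor".
* The observed statistic uses all valid trials while the null matches
  conditions to the smaller count m; with strongly unequal counts the
  observed and null statistics have slightly different variances
  (the effect vanishes when counts are equal, as in the validity
  simulation).
* The pooled latency analysis is fixed-effects: subjects with more
  valid trials weigh more, and surrogate sets may straddle subjects
  unevenly — the literal reading of the resampling design.
* Group t-test confidence intervals assume approximate normality of
  per-subject peak-to-peak differences; with 8–15 subjects this is a
  convention, not a guarantee.
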