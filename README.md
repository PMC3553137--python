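# p300cit

Single-subject P300 concealed-information detection from epoched
RSVP-EEG, built on resampling statistics.

## The problem

In a rapid serial visual presentation (RSVP) stream, a subject's own
name — even when they deny it is theirs — evokes a larger P300 complex
than matched irrelevant names: an early fronto-central
positive-then-negative deflection (P3a, electrodes Fz/Cz) and a later
broad parietal positivity (P3b, electrode Pz). `p300cit` implements the
statistical machinery to turn that effect into a **per-individual
decision** with a calibrated false-positive rate:

* **Peak-to-peak statistic** on the (condition − Irrelevant1)
  difference wave: slide a 100 ms inner window across a bounding window
  (P3a 150–1000 ms, P3b 300–1000 ms), take the highest window mean
  minus the lowest window mean found after it. For the P3a the highest
  peak must end by 300 ms, so the P3b cannot masquerade as it.
* **Per-electrode randomisation test**: B relabellings of the pooled
  Probe/Irrelevant1 trials (trials kept as Fz/Cz/Pz triples) give the
  null distribution of the maximal statistic;
  p = #(null > observed)/B. Because the null is built from *maximal*
  statistics, the post-hoc window placement needs no multiple-comparison
  correction.
* **Fisher combination**: the three electrode p-values are combined as
  −2·Σ ln p, referred not to χ² but to the B Fisher scores of the
  resampled null itself, which preserves inter-electrode correlation.
  Zero p-values are replaced by the resolution floor 1/B (0.001 at
  B = 1000). The subject is flagged when the combined p falls below α.

The package also provides the surrounding analyses: intrinsic
false-positive-rate simulation on fabricated null data, a six-way
pairwise screen of interchangeable no-signal conditions, the
early–late vs even–odd habituation control, group paired t-tests, the
pooled latency-difference randomisation, and a synthetic RSVP-EEG
generator (1/f + alpha background, Gaussian-bump P3a/P3b templates)
used throughout the test-suite. See `docs/methods.md` for the model
details and assumptions.

## Worked example

Generate one synthetic "guilty" subject (Probe carries an 8 µV P3a and
10 µV P3b over 10 µV background noise, 50 trials/condition) and analyse
it:

```sh
p300cit synth --config guilty1.json --out subject.tsv --seed 11
p300cit detect --epochs subject.tsv --out report.json --resamples 1000 --seed 7
```

```
INFO subject=synth-01 m=46 B=1000 seed=7 valid_in_file={'Probe': 50, 'Fake': 50,
  'Irrelevant1': 50, 'Irrelevant2': 50, 'distractor': 240} fisher_p=<0.001 decision=True
```

`report.json` (abridged):

```json
{
  "observed_p2p_uv": {"Fz": 12.72, "Cz": 9.42, "Pz": 8.35},
  "p_per_channel":   {"Fz": 0.0,   "Cz": 0.0,  "Pz": 0.0},
  "p_display":       {"Fz": "<0.001", "Cz": "<0.001", "Pz": "<0.001"},
  "fisher_p": 0.0, "fisher_p_display": "<0.001",
  "alpha": 0.05, "decision": true, "B": 1000, "m": 46
}
```

Reading it: after ±50 µV artifact rejection the smaller condition kept
m = 46 valid trials; the observed Probe−Irrelevant1 peak-to-peak was
12.7 µV at Fz, 9.4 at Cz and 8.4 at Pz — each beyond all 1000
relabelled nulls, so every p is below the 0.001 floor and the subject
is (correctly) flagged. The same command on a no-signal subject
(`--preset null`, seed 5) returns unremarkable p-values and a negative
decision:

```
p_per_channel={'Fz': 0.19, 'Cz': 0.295, 'Pz': 0.499}  fisher_p=0.309  decision=False
```

Other workflows: `p300cit validate` (intrinsic false-positive-rate
simulation), `p300cit screen` (pairwise null screen), `p300cit group`
(early–late control, Probe-vs-Irrelevant2 contrast, latency-difference
randomisation). Every command takes `--seed` and is bit-reproducible.

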