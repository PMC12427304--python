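# pigvox

Acoustic analysis of fattening-pig vocalizations for animal-welfare
monitoring.

Pigs in conventional fattening barns vocalize in behavioural contexts an
expert observer can label on the spot: contact grunts, play barks,
screams during conflicts over feed, fights, oral manipulation or
aversive physical contact by pen mates, alarm barks, plus non-vocal
sounds (cough, sneeze, ear shaking, snoring).  `pigvox` implements the
desk side of such a study for researchers in livestock bioacoustics and
precision-livestock-farming engineers: it turns continuous barn WAV
recordings plus an observer's annotation table into per-sound acoustic
features and per-class distribution statistics that separate
welfare-relevant ("negative") vocalizations from positive/neutral ones.

## What it computes

Each annotated sound event is band-pass filtered (Butterworth,
20 Hz–20 kHz, order 4, applied zero-phase), optionally re-segmented by a
short-time-energy onset search within ±2 s of the annotated times
(emulating observer reaction time), and described by six features:

* **Q1, Q2, Q3** — the frequencies (Hz) at which the cumulative
  intensity of the event's power spectrum reaches 25 %, 50 % and 75 %;
  Q2 is the spectral midpoint.
* **∑Aᵢ** — cumulative amplitude modulation: the sum of absolute
  differences between consecutive waveform extrema (the peak-to-peak
  dimensions Aᵢ), normalised by the event duration.
* **Ā** — mean of the absolute dB-level differences between consecutive
  extrema (the Aᵢ of the logarithmic time signal); scale invariant.
* **Var** — variance of the linear-scale time signal.

Per sound class (valence or behaviour) the package reports boxplot
statistics (quartiles, Tukey whiskers clipped to the data range),
quartile-based Bowley skewness labels, pairwise interquartile-range
overlap (none / slight / strong), radar-chart axis limits
(0.5·q1 to k·q3 of a reference class, k ∈ {2, 3, 5.5}), and the
observation-count percentage arithmetic of the behavioural framework.

Because the original barn recordings are not publicly deposited, the
package bundles (a) the published observation counts and per-class
feature quartiles as reference tables (`pigvox.reference`) and (b) a
seeded synthetic session generator (`pigvox.synth`) whose per-behaviour
presets reproduce the qualitative class contrasts — low-frequency quiet
grunts, high-frequency loud negative calls, very loud alert barks,
broadband sneezes — so the whole pipeline is testable end to end.

## Worked example

Generate a default synthetic session (660 s at 48 kHz, 117 events, every
valence ≥ 30 calls) and analyse it:

```sh
pigvox demo --out demo --seed 0
```

This writes `demo/session/` (WAV, jittered annotation CSV, exact truth
CSV) and `demo/analysis/` (features.csv, class_summary.csv/json,
class_comparison.csv, radar_axes.json, manifest.json).  The per-valence
feature medians extracted from that run:

```
                  sum_ai  a_bar_db      var  q1_hz  q2_hz  q3_hz
alert               1287     10.14  0.04816  643.1   1034   1548
negative            3089     9.918  0.03343   1470   3092   4640
other                604     9.044 0.007955  2908   5172   7554
positive_neutral   236.4     4.716 0.002765  249.6  251.5  501.7
```

Reading this: negative vocalizations have a higher median than
positive/neutral ones on **all six** features (e.g. spectral midpoint
Q2 = 3092 Hz vs 252 Hz — screams versus grunts; amplitude activity
∑Aᵢ 3089 vs 236 per second), and the alert class has the highest
time-signal variance median (0.048 vs 0.033) — exactly the qualitative
separation structure the expert framework predicts for barn recordings.
In `class_summary.csv` the ∑Aᵢ and Var cells are displayed ×10 and
×10⁶ respectively, mirroring the conventional table layout.

The same stages are available individually (`pigvox generate`,
`pigvox extract`, `pigvox summarize`, `pigvox report`; see `--help`) and
as plain functions (`pigvox.pipeline.run_pipeline` et al.) for your own
recordings: a PCM WAV plus a CSV with columns
`start_s,end_s,behavior,pen,note`.

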