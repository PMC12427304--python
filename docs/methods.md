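# Methods

## Scope and data model

The package analyses behaviour-annotated barn audio.  Its unit of
analysis is one annotated sound event: a slice of a continuous mono
recording (`AudioSegment`, samples normalised to [−1, 1], rate in Hz)
labelled with a behaviour from an eleven-behaviour taxonomy.  The
taxonomy has three levels: vocalization vs. other (non-vocal-tract
sounds: coughing, sneezing, ear shaking, snoring), a welfare valence for
vocalizations (positive/neutral: grunting, playing; negative: conflict
over resources, fight, oral manipulation, aversive physical contact;
alert as its own category), and the behaviour itself.  Alert is a
separate valence level, not a flag, because alarm barks are neither
clearly positive nor preceded by an identifiable negative context.
Snoring is carried under "other" although it is marginal (it is a
vocal-tract sound, but reflexive); it appears in the observation counts
and therefore needs a slot.  Valence is assigned only from the observed
behaviour label, never inferred from audio.

An alias table ("physical contact" → aversive_physical_contact, etc.)
absorbs the short and long label forms that occur in field notes; it is
consulted only when strict matching is off.

## Preprocessing and event segmentation

All audio is band-pass filtered 20 Hz – 20 kHz with a Butterworth filter
of order 4 (the microphone's nominal flat range).  The filter is applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with doubled effective
order, because the time-domain features depend on extrema positions and
a causal filter would shift them; phase handling is our choice, the
corner frequencies and order are the stated preprocessing.  If the
upper corner sits at or above Nyquist (resampled material), it is
clamped to 0.95 × Nyquist with a logged warning rather than failing.

Annotated times carry observer reaction delay, so event boundaries can
be refined: within [start − w, end + w] (w = 2 s by default) the
short-time energy (10 ms frames, 5 ms hop) is compared against a noise
floor estimated as the 10th percentile of frame energies in the window;
a region qualifying as the event must exceed 10 × that floor for at
least 30 ms.  The first and last qualifying runs set the refined
bounds.  These four constants are engineering defaults (configurable);
they replace the original manual listening/inspection step.  If nothing
qualifies, the annotated bounds are used and the result carries a
warning flag.  Intervals are half-open [start, end); slicing without
refinement is exact sample arithmetic.

Overlapping annotations (interval intersection of positive length) are
excluded by default before feature extraction, mirroring the field
protocol that discarded unattributable overlapping calls; a flag keeps
them.

## The six features

Frequency quartiles Q1/Q2/Q3: one power spectrum of the whole segment
(squared rFFT magnitude, no taper, DC bin excluded) is cumulated over
frequency; Q_p is the frequency where the cumulative curve first reaches
p of its total, linearly interpolated inside the crossing bin.  A single
whole-segment spectrum is used — no Welch averaging or windowing —
because each event is characterised by one spectrum; a Hann-window
option exists but defaults off.  Monotonicity of the cumulative curve
guarantees Q1 ≤ Q2 ≤ Q3.  Constant or silent segments are rejected
("silent segment"); the rejection threshold is relative (non-DC power
< 1e−15 of total) to absorb FFT round-off on exactly constant input.

Extrema: candidate turning points come from sign changes of the first
difference (plateaus compressed to their first sample), giving a
strictly alternating max/min sequence.  Adjacent extrema pairs whose
swing is below 1 % of the segment's global peak (configurable) are
merged away, smallest swing first, which suppresses float-noise
micro-extrema while preserving alternation; the procedure is
O(n log n) via a heap with lazy invalidation.  Extrema are taken on the
band-passed waveform itself, matching the definition of the
peak-to-peak dimensions Aᵢ between consecutive waveform extrema; an
`envelope_ms` option computes them instead on a smoothed
analytic-signal envelope for users who prefer envelope modulation.

∑Aᵢ = (Σ |v_{i+1} − v_i|) / duration over consecutive extrema; 0 for
fewer than two extrema.  For a pure sine of amplitude a and frequency f
this is 4af (two swings of 2a per cycle), which the tests use as a
closed-form oracle.

Ā converts each extremum magnitude to a level
L_i = 20 log₁₀(max(|v_i|, ε)) and averages |L_{i+1} − L_i|.  Because
only level differences enter, the (unstated) dB reference cancels and
the feature is amplitude-scale invariant, except near the log floor
ε = 10^(floor_db/20) (default −80 dB re full scale) which guards
log(0).  A pure tone gives 0 dB; peaks alternating between a and a/2
give 20 log₁₀ 2 ≈ 6.02 dB.

Var is the population variance of the linear-scale samples (population
rather than sample variance: negligible at audio n, fixed for
bit-reproducibility).  Closed forms a²/2 (sine) and b²/3 (uniform
noise) serve as oracles.

Scaling laws (asserted as properties): multiplying the waveform by c
leaves Q1/Q2/Q3 and Ā unchanged, scales ∑Aᵢ by c and Var by c².

## Class statistics

Quartiles of per-class feature samples use linear interpolation between
order statistics (the common default; no convention was stated).
Whiskers follow Tukey's rule clipped to the data range: whisker_low is
the smallest datum ≥ q1 − 1.5·IQR, whisker_high the largest datum
≤ q3 + 1.5·IQR.  Skewness is labelled from Bowley's quartile skewness
B = (q3 + q1 − 2·median)/(q3 − q1) with |B| > 0.33 as the default
threshold; quartile-based labels cannot reproduce every visually
assigned label in the literature, so they are reported, not forced.
IQR overlap between two classes is the length of the intersection of
[q1, q3] intervals divided by the smaller IQR; 0 → none,
≤ 0.25 → slight, > 0.25 → strong (thresholds chosen to reproduce the
published slight/strong dichotomy on the bundled reference table;
configurable).  Radar axes span 0.5·q1 to k·q3 of a reference class,
k ∈ {2, 3, 5.5}.

Percentages are computed as 100·count/denominator with the presentation
rounding of the source material (one decimal for behaviour shares of
the full observation set, integers for subcategory splits).  The
bundled reference counts contain internal inconsistencies (subcategory
sums that miss their stated totals); shares therefore always use the
stated denominator of the corresponding published figure.  The
aggregate "negative + alert" share is computed as the sum of the
per-behaviour one-decimal shares, which is how the published aggregate
figure arises; the unrounded quotient differs by 0.1 percentage point.

## Synthetic sessions

The generator exists because the original recordings are not deposited:
it produces sessions whose *class structure* — not sound — matches the
analysis assumptions.  Per behaviour a preset distribution over call
parameters is drawn per event: grunts are harmonic stacks with
fundamental 60–300 Hz, few harmonics, low amplitude (peak 0.05–0.15);
play barks are short 300–2000 Hz calls; the four negative behaviours
share one preset (harmonic, f0 500–2500 Hz, 5–8 slowly decaying
harmonics, amplitude-modulation depth 0.5–0.9, peak 0.35–0.85) because
the published distributions of the negative subcategories are nearly
indistinguishable; alert barks are short, very loud (peak 0.75–1.0)
with strongly varying envelopes; sneezes are 500–10000 Hz noise bursts,
coughs 200–2000 Hz noise bursts, ear shaking an 8–15 Hz impulse train,
snoring a low-frequency amplitude-modulated rumble.  Durations and
amplitudes are engineering choices (no per-class duration or level
statistics are published) and are documented in `default_presets`.

Calls get random phases and per-event parameter draws so class
distributions have spread; all randomness flows from the single session
seed.  Events are placed sequentially with a minimum gap of 4.5 s —
larger than jitter + search window so that refinement windows never
capture a neighbouring call — over white background noise at −40 dB
relative to the mean call peak (loud enough to exercise onset
refinement, quiet enough not to dominate spectra).  Annotated times are
jittered uniformly within ±2 s of truth; exact times go to a sidecar
truth CSV.  The default session is 660 s at 48 kHz with 117 events and
at least 30 calls per valence (alert is deliberately over-represented
relative to field frequencies so its medians are stable).

What passing tests on synthetic sessions do show: the feature
definitions, segmentation, and statistics reproduce the intended class
ordering (all six negative medians above positive/neutral; alert with
the largest Var) when the acoustics have that structure.  What they do
not show: robustness to real barn interference (feed chains,
ventilation), overlapping calls, reverberation, or microphone placement
— none of which the generator emulates.

## Numerical and degenerate-input conventions

* WAV I/O via `scipy.io.wavfile`; integer PCM scaled by dtype full
  scale, multichannel mixed to mono by averaging, empty or unreadable
  files rejected by name.  Written PCM is 16-bit by default.
* Annotation CSVs round-trip exactly: floats are written with `%.17g`
  and parsed with round-trip precision.
* Empty extrema sequences yield 0 for both amplitude-modulation
  features; empty classes and zero denominators are rejected with the
  offending name; zero IQR yields skew "none" and a degenerate overlap
  label.
* Pipelines are deterministic: identical config and inputs give
  byte-identical feature CSVs; the manifest records seed, config hash
  and library versions.

## Known limitations

Absolute feature magnitudes depend on recording gain, microphone and
segmentation conventions and are therefore not comparable across
studies; only orderings, ratios and overlap structure are asserted
against the bundled reference table.  The alert-class Var-IQR ratio in
that table is ≈ 3.6× the negative class (asserted as > 3); the
negative-to-positive Var-IQR ratio is ≈ 3.9× and is not asserted at a
stricter bound.  No hypothesis testing and no classifier are included;
the feature table the pipeline writes is the intended hand-off point to
downstream machine learning.
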