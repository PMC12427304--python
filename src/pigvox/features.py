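"""Six per-sound acoustic features.

Frequency domain (from one power spectrum of the whole segment):

* ``q1``, ``q2``, ``q3`` — the frequencies at which the cumulative
  spectral intensity reaches 25 %, 50 % and 75 % of its total.  ``q2``
  is the spectral midpoint ("centre of the spectrum").

Time domain (from the sequence of alternating waveform extrema):

* ``sum_ai`` — cumulative amplitude modulation: the sum of absolute
  differences between consecutive extrema (the peak-to-peak dimensions
  A_i), normalised by the sound duration.  Units: normalised amplitude
  per second.  Reflects loudness activity.
* ``a_bar`` — mean of the absolute dB-level differences between
  consecutive extrema (the logarithmic-scale A_i).  Scale invariant.
* ``var`` — population variance of the linear-scale time signal.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass


import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.ndimage import uniform_filter1d
from scipy.signal import get_window, hilbert

from pigvox.audio_io import AudioSegment


@dataclass(frozen=True)
class ExtremaSequence:
    """Alternating local maxima/minima of a time signal.

    ``kinds`` holds +1 for a maximum and -1 for a minimum and strictly
    alternates; ``times`` (seconds) strictly increase.
    """

    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray

    def __len__(self) -> int:
        return self.values.size

    @property
    def swings(self) -> np.ndarray:
        """|v_{i+1} - v_i| for consecutive extrema (the A_i)."""
        return np.abs(np.diff(self.values))


@dataclass(frozen=True)
class FeatureVector:
    """The six per-sound features plus the event duration."""

    sum_ai: float
    a_bar: float
    var: float
    q1: float
    q2: float
    q3: float
    duration: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "sum_ai": self.sum_ai,
            "a_bar_db": self.a_bar,
            "var": self.var,
            "q1_hz": self.q1,
            "q2_hz": self.q2,
            "q3_hz": self.q3,
        }


FEATURE_NAMES = ("sum_ai", "a_bar", "var", "q1", "q2", "q3")


@dataclass(frozen=True)
class FeatureParams:
    """Knobs for feature extraction.

    min_prominence — extrema whose swing is below this fraction of the
    segment's global peak are merged away (suppresses float-noise
    micro-extrema).  floor_db — log floor (dB re full scale) guarding
    log(0) in the dB-level conversion.  envelope_ms — when set, extrema
    are taken on the smoothed analytic-signal envelope instead of the
    raw waveform.  window — optional FFT taper name (default: none; the
    spectrum is taken over the whole untapered segment).
    """

    min_prominence: float = 0.01
    floor_db: float = -80.0
    envelope_ms: float | None = None
    window: str | None = None


def find_extrema(
    seg: AudioSegment, min_prominence: float = 0.01
) -> ExtremaSequence:
    """Locate the alternating local extrema of a waveform.

    Candidates come from sign changes of the first difference (plateaus
    are compressed to their first sample).  Adjacent extrema pairs whose
    swing is below ``min_prominence`` x the global absolute peak are then
    removed, smallest swing first — removing the pair keeps the
    max/min alternation intact.  A constant signal yields an empty
    sequence.
    """
    x = seg.samples
    idx, kinds = _raw_extrema(x)
    if idx.size == 0:
        empty = np.empty(0)
        return ExtremaSequence(empty, empty, np.empty(0, dtype=np.int8))
    floor = min_prominence * np.max(np.abs(x))
    idx, kinds = _prune_pairs(x, idx, kinds, floor)
    return ExtremaSequence(idx / seg.rate, x[idx], kinds)


def _raw_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and kinds (+1 max / -1 min) of strict turning points."""
    d = np.diff(x)
    nz = np.flatnonzero(d != 0)
    if nz.size < 2:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int8)
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[1:] != s[:-1])
    # turning point sits where the next nonzero difference changes sign
    idx = nz[turn] + 1
    kinds = np.where(s[turn] > 0, 1, -1).astype(np.int8)
    return idx.astype(np.intp), kinds


def _prune_pairs(
    x: np.ndarray, idx: np.ndarray, kinds: np.ndarray, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively drop the adjacent extrema pair with the smallest swing
    while that swing is below *floor*.

    Removing an adjacent (max, min) pair preserves the alternation of
    the survivors, so only pair removal is needed.  A heap over pair
    swings with lazy invalidation keeps this O(n log n); swing values
    never change, only adjacency does, so a popped entry is valid iff
    its left node is alive and still adjacent to its right node.
    """
    m = idx.size
    if m < 2 or floor <= 0:
        return idx, kinds
    vals = x[idx]
    nxt = list(range(1, m)) + [-1]
    prv = [-1] + list(range(m - 1))
    alive = [True] * m
    heap = [(abs(vals[i + 1] - vals[i]), i, i + 1) for i in range(m - 1)]
    heapq.heapify(heap)
    while heap:
        swing, i, j = heapq.heappop(heap)
        if not (alive[i] and alive[j] and nxt[i] == j):
            continue
        if swing >= floor:
            break
        alive[i] = alive[j] = False
        p, q = prv[i], nxt[j]
        if p >= 0:
            nxt[p] = q
        if q >= 0:
            prv[q] = p
        if p >= 0 and q >= 0:
            heapq.heappush(heap, (abs(vals[q] - vals[p]), p, q))
    keep = np.flatnonzero(alive)
    if keep.size == 1 and abs(vals[keep[0]]) < floor:
        keep = keep[:0]
    return idx[keep], kinds[keep]


def sum_amplitude_modulation(ext: ExtremaSequence, duration: float) -> float:
    """Cumulative amplitude modulation: sum of A_i over the duration."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if len(ext) < 2:
        return 0.0
    return float(ext.swings.sum() / duration)


def mean_amplitude_modulation_db(
    ext: ExtremaSequence, floor_db: float = -80.0
) -> float:
    """Mean peak-to-peak dimension of the logarithmic (dB) time signal.

    Each extremum magnitude is converted to a level
    L_i = 20 log10(max(|v_i|, eps)) with eps = 10^(floor_db/20); the
    result is the mean of |L_{i+1} - L_i| over consecutive extrema.
    Because only level differences enter, the dB reference cancels and
    the feature is invariant under amplitude scaling (as long as no
    extremum is clamped at the floor).
    """
    if len(ext) < 2:
        return 0.0
    eps = 10.0 ** (floor_db / 20.0)
    levels = 20.0 * np.log10(np.maximum(np.abs(ext.values), eps))
    return float(np.mean(np.abs(np.diff(levels))))


def time_signal_variance(seg: AudioSegment) -> float:
    """Population variance of the linear-scale time signal."""
    return float(np.var(seg.samples))


def spectral_quartiles(
    seg: AudioSegment, window: str | None = None
) -> tuple[float, float, float]:
    """Frequencies at 25/50/75 % of the cumulative spectral intensity.

    One power spectrum (squared rFFT magnitude, DC excluded) of the
    whole segment is cumulated over frequency; each quartile is the
    frequency where the cumulative curve first reaches the target
    fraction, linearly interpolated inside the crossing bin.
    """
    x = seg.samples
    if window is not None:
        x = x * get_window(window, x.size)
    spec = np.abs(rfft(x)) ** 2
    freqs = rfftfreq(x.size, d=1.0 / seg.rate)
    power = spec[1:]
    freqs = freqs[1:]
    total = power.sum()
    # DC-only (constant) or all-zero input carries no spectral shape;
    # the relative floor absorbs FFT round-off on exactly constant signals
    if total <= 0 or total < 1e-15 * spec.sum():
        raise ValueError("silent segment: spectral quartiles undefined")
    cum = np.cumsum(power)
    # prepend the 0 Hz anchor so interpolation is defined in the first bin
    grid = np.concatenate(([0.0], freqs))
    curve = np.concatenate(([0.0], cum)) / total
    qs = []
    for p in (0.25, 0.50, 0.75):
        k = int(np.searchsorted(curve, p, side="left"))
        k = min(k, curve.size - 1)
        if curve[k] == curve[k - 1]:
            qs.append(float(grid[k]))
        else:
            frac = (p - curve[k - 1]) / (curve[k] - curve[k - 1])
            qs.append(float(grid[k - 1] + frac * (grid[k] - grid[k - 1])))
    return qs[0], qs[1], qs[2]  # monotone curve => q1 <= q2 <= q3


def _envelope(seg: AudioSegment, envelope_ms: float) -> AudioSegment:
    env = np.abs(hilbert(seg.samples))
    size = max(1, int(round(envelope_ms * 1e-3 * seg.rate)))
    smoothed = uniform_filter1d(env, size=size)
    return AudioSegment(smoothed, seg.rate)


def extract_features(
    seg: AudioSegment, params: FeatureParams | None = None
) -> FeatureVector:
    """Bundle the five operations above into one feature vector.

    The segment is expected to be band-passed already.  Deterministic
    for fixed input and params.  A segment whose spectrum carries no
    power (silence/DC) is rejected.
    """
    params = params or FeatureParams()
    q1, q2, q3 = spectral_quartiles(seg, window=params.window)
    source = (
        _envelope(seg, params.envelope_ms)
        if params.envelope_ms is not None
        else seg
    )
    ext = find_extrema(source, min_prominence=params.min_prominence)
    duration = seg.duration
    return FeatureVector(
        sum_ai=sum_amplitude_modulation(ext, duration),
        a_bar=mean_amplitude_modulation_db(ext, floor_db=params.floor_db),
        var=time_signal_variance(seg),
        q1=q1,
        q2=q2,
        q3=q3,
        duration=duration,
    )


def features_to_row(vec: FeatureVector) -> dict[str, float]:
    row = vec.as_dict()
    row["duration_s"] = vec.duration
    return row
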