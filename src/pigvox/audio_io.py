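"""WAV input/output, band-pass preprocessing, and annotated-event slicing.

Barn recordings are continuous mono WAV files (nominally 48 kHz).  An
observer's annotation table gives approximate start/end times for each
behaviour-labelled sound event; because observer reaction time is on the
order of seconds, event boundaries can be refined by a short-time-energy
onset search inside a +/-2 s window around the annotated times.

Preprocessing is a 20 Hz - 20 kHz Butterworth band-pass of order 4,
applied forward-backward (zero phase) so that peak positions used by the
time-domain features are not shifted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("start_s", "end_s", "behavior", "pen", "note")


@dataclass(frozen=True)
class AudioSegment:
    """A sampled waveform with its sampling rate.

    ``samples`` are dimensionless amplitudes normalised to [-1, 1];
    ``rate`` is the sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("AudioSegment needs a 1-D array of at least 2 samples")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.samples.size / self.rate

    def scaled(self, factor: float) -> "AudioSegment":
        return AudioSegment(self.samples * factor, self.rate)


@dataclass(frozen=True)
class PreprocessConfig:
    """Band-pass parameters: corner frequencies in Hz and filter order."""

    low_cut: float = 20.0
    high_cut: float = 20_000.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class AnnotationRecord:
    """One behaviour-labelled sound event with approximate timing."""

    start: float
    end: float
    behavior: str
    pen: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"need 0 <= start < end, got start={self.start}, end={self.end}"
            )


@dataclass(frozen=True)
class SliceResult:
    """Outcome of :func:`slice_event`: the cut segment plus provenance."""

    segment: AudioSegment
    start: float
    end: float
    refined: bool
    warning: str | None = None


def read_audio(path: str | Path) -> AudioSegment:
    """Read a PCM WAV file as a mono, [-1, 1]-normalised segment.

    Multichannel input is mixed down by averaging channels.  Integer PCM
    is scaled by the full-scale value of its dtype; float WAV is taken
    as already normalised.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on bad containers
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        # unsigned 8-bit PCM is offset binary
        offset = (info.max + info.min + 1) / 2
        scale = (info.max - info.min) / 2
        samples = (data.astype(np.float64) - offset) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if samples.size < 2:
        raise ValueError(f"WAV file too short to be a signal: {path}")
    return AudioSegment(samples, float(rate))


def write_audio(path: str | Path, seg: AudioSegment, bit_depth: int = 16) -> None:
    """Write a segment as integer PCM WAV (16- or 24-ish via 32-bit)."""
    clipped = np.clip(seg.samples, -1.0, 1.0)
    if bit_depth == 16:
        data = np.round(clipped * 32767.0).astype(np.int16)
    elif bit_depth == 32:
        data = np.round(clipped * 2147483647.0).astype(np.int32)
    else:
        raise ValueError("bit_depth must be 16 or 32")
    wavfile.write(Path(path), int(round(seg.rate)), data)


def _design_sos(cfg: PreprocessConfig, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if cfg.low_cut >= nyq:
        raise ValueError(
            f"low_cut {cfg.low_cut} Hz is at or above Nyquist ({nyq} Hz)"
        )
    high = cfg.high_cut
    if high >= nyq:
        # keep the stated corner usable on resampled material
        high = 0.95 * nyq
        logger.warning(
            "high_cut %.0f Hz >= Nyquist %.0f Hz; clamped to %.0f Hz",
            cfg.high_cut, nyq, high,
        )
    return signal.butter(
        cfg.order, [cfg.low_cut, high], btype="bandpass", fs=rate, output="sos"
    )


def bandpass(seg: AudioSegment, cfg: PreprocessConfig | None = None) -> AudioSegment:
    """Apply the Butterworth band-pass, zero phase (forward-backward).

    Same length and rate are preserved; the forward-backward application
    doubles the effective order but leaves event timing untouched.
    """
    cfg = cfg or PreprocessConfig()
    sos = _design_sos(cfg, seg.rate)
    filtered = signal.sosfiltfilt(sos, seg.samples)
    return AudioSegment(filtered, seg.rate)


def bandpass_response_db(
    cfg: PreprocessConfig, rate: float, freqs: Sequence[float]
) -> np.ndarray:
    """Magnitude response (dB) of the *zero-phase* filter at given Hz.

    Forward-backward filtering applies the magnitude twice, so the dB
    gain of the designed filter is doubled.
    """
    sos = _design_sos(cfg, rate)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=rate)
    mag = np.abs(h)
    with np.errstate(divide="ignore"):
        return 2.0 * 20.0 * np.log10(mag)


def _frame_energy(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n = 1 + max(0, (x.size - frame)) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    frames = x[idx]
    return np.mean(frames * frames, axis=1)


def slice_event(
    recording: AudioSegment,
    ann: AnnotationRecord,
    search_window: float = 2.0,
    refine: bool = False,
    frame_s: float = 0.010,
    hop_s: float = 0.005,
    threshold: float = 10.0,
    min_duration: float = 0.030,
) -> SliceResult:
    """Cut one annotated event out of a continuous recording.

    With ``refine=False`` the annotated interval [start, end) is sliced
    exactly.  With ``refine=True`` the onset/offset are re-estimated
    inside [start - w, end + w] (w = *search_window*): short-time energy
    (frames of *frame_s*, hop *hop_s*) must exceed a noise-floor estimate
    times *threshold* for at least *min_duration*; the first and last
    such supra-threshold run define the refined bounds.  If no run
    qualifies, the annotated bounds are kept and a warning is set.
    """
    rate = recording.rate
    n = recording.samples.size
    if ann.end * rate > n + 1:
        raise ValueError(
            f"annotation [{ann.start}, {ann.end}] s extends beyond "
            f"recording end ({n / rate:.3f} s)"
        )

    if not refine:
        i0 = int(round(ann.start * rate))
        i1 = int(round(ann.end * rate))
        return SliceResult(
            AudioSegment(recording.samples[i0:i1].copy(), rate),
            ann.start, ann.end, refined=False,
        )

    w0 = max(0.0, ann.start - search_window)
    w1 = min(n / rate, ann.end + search_window)
    j0, j1 = int(round(w0 * rate)), int(round(w1 * rate))
    window = recording.samples[j0:j1]
    frame = max(2, int(round(frame_s * rate)))
    hop = max(1, int(round(hop_s * rate)))
    if window.size < frame:
        return _fallback(recording, ann, "search window shorter than one frame")
    energy = _frame_energy(window, frame, hop)
    # noise floor: a low quantile of frame energies within the window
    floor = max(np.quantile(energy, 0.1), np.finfo(float).tiny)
    above = energy > threshold * floor
    min_frames = max(1, int(np.ceil((min_duration - frame_s) / hop_s)) + 1)
    runs = _runs(above)
    runs = [(a, b) for a, b in runs if b - a >= min_frames]
    if not runs:
        return _fallback(recording, ann, "no onset found")
    first_a, _ = runs[0]
    _, last_b = runs[-1]
    start = w0 + first_a * hop_s
    end = w0 + (last_b - 1) * hop_s + frame_s
    i0 = int(round(start * rate))
    i1 = min(n, int(round(end * rate)))
    return SliceResult(
        AudioSegment(recording.samples[i0:i1].copy(), rate),
        start, end, refined=True,
    )


def _fallback(recording: AudioSegment, ann: AnnotationRecord, why: str) -> SliceResult:
    warnings.warn(f"slice_event: {why}; using annotated bounds", stacklevel=3)
    i0 = int(round(ann.start * recording.rate))
    i1 = int(round(ann.end * recording.rate))
    return SliceResult(
        AudioSegment(recording.samples[i0:i1].copy(), recording.rate),
        ann.start, ann.end, refined=False, warning=why,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [a, b) index runs where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read the annotation CSV (columns start_s,end_s,behavior,pen,note)."""
    df = pd.read_csv(
        path,
        dtype={"behavior": str, "pen": str, "note": str},
        float_precision="round_trip",
    )
    missing = [c for c in ("start_s", "end_s", "behavior") if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = float(row.start_s), float(row.end_s)
        if end <= start:
            raise ValueError(
                f"annotation row {i + 1}: end_s ({end}) must exceed start_s ({start})"
            )
        records.append(
            AnnotationRecord(
                start=start,
                end=end,
                behavior=str(row.behavior),
                pen="" if _isnull(getattr(row, "pen", "")) else str(row.pen),
                note="" if _isnull(getattr(row, "note", "")) else str(row.note),
            )
        )
    return records


def _isnull(v: object) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write records as the annotation CSV dialect (round-trips with read)."""
    df = pd.DataFrame(
        {
            "start_s": [r.start for r in records],
            "end_s": [r.end for r in records],
            "behavior": [r.behavior for r in records],
            "pen": [r.pen for r in records],
            "note": [r.note for r in records],
        }
    )
    # %.17g guarantees float round-trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")
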