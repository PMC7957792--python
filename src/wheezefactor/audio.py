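"""Audio segment container and WAV input/output.

Every downstream constant (the 8 Hz bin->Hz map, the 100-1000 Hz analysis
band) assumes the canonical auscultation sampling rate of 4096 Hz, so all
audio is coerced to mono / 4096 Hz at load time.  Amplitude is deliberately
left unnormalised here: the spectrogram normalisation makes the whole
pipeline scale-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical sampling rate (Hz) of the analysis pipeline.
TARGET_RATE = 4096

#: Minimum duration (s) of a continuous adventitious sound per the CORSA
#: guidelines; shorter segments cannot be a wheeze.
MIN_DURATION = 0.1


class AudioValidationError(ValueError):
    """Raised when an audio input violates the pipeline's contracts."""


@dataclass
class AudioSegment:
    """A mono audio segment at a known sampling rate.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitude sequence, single channel.
    sample_rate : int
        Sampling rate in Hz.
    label : str, optional
        Wheeze class annotation (``"MP"`` / ``"PP"``), if known.
    subtype : str, optional
        MP subtype annotation (``"Type1"`` / ``"Type2"``), if known.
    """

    samples: np.ndarray
    sample_rate: int = TARGET_RATE
    label: str | None = None
    subtype: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioValidationError(
                f"AudioSegment requires a single channel, got shape {self.samples.shape}"
            )

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return len(self.samples) / self.sample_rate


def _to_float(data: np.ndarray) -> np.ndarray:
    """Map integer PCM to float in [-1, 1); pass floats through."""
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        # int16 -> /32768, int32 -> /2^31; uint8 is offset binary
        if info.min == 0:
            half = (info.max + 1) / 2
            return (data.astype(np.float64) - half) / half
        return data.astype(np.float64) / abs(info.min)
    return data.astype(np.float64)


def resample_to(segment: AudioSegment, rate: int = TARGET_RATE) -> AudioSegment:
    """Resample a segment to `rate` Hz with a polyphase filter."""
    if segment.sample_rate == rate:
        return segment
    ratio = Fraction(rate, int(segment.sample_rate)).limit_denominator(10000)
    out = resample_poly(segment.samples, ratio.numerator, ratio.denominator)
    return AudioSegment(out, rate, segment.label, segment.subtype, dict(segment.meta))


def load_audio(path: str | Path, min_duration: float = MIN_DURATION) -> AudioSegment:
    """Read a WAV file and canonicalise it to mono 4096 Hz.

    Multi-channel input is averaged to mono; other sampling rates are
    polyphase-resampled.  Segments shorter than the 100 ms CORSA minimum
    after resampling are rejected.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise AudioValidationError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioValidationError(f"empty WAV file: {path}")
    samples = _to_float(np.atleast_1d(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    seg = resample_to(AudioSegment(samples, int(rate)), TARGET_RATE)
    if seg.duration < min_duration:
        raise AudioValidationError(
            f"segment of {seg.duration * 1e3:.1f} ms is below the 100 ms CORSA "
            f"minimum for a continuous adventitious sound"
        )
    return seg


def save_audio(segment: AudioSegment, path: str | Path, subtype: str = "float32") -> None:
    """Write a segment to WAV (``float32`` lossless or ``pcm16``)."""
    samples = np.asarray(segment.samples, dtype=np.float64)
    if samples.size == 0:
        raise AudioValidationError("refusing to write an empty audio segment")
    if not np.all(np.isfinite(samples)):
        raise AudioValidationError("audio samples must be finite")
    if subtype == "float32":
        wavfile.write(path, segment.sample_rate, samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(samples, -1.0, 32767 / 32768)
        wavfile.write(path, segment.sample_rate, np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")
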