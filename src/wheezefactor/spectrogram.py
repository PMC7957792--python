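"""Time-frequency representation of respiratory sound segments.

The factorisation operates on a normalised, band-limited magnitude
spectrogram: a Hamming-windowed STFT with N = 256 samples (62.5 ms at
4096 Hz), 10% inter-window overlap and a 2N-point DFT (8 Hz bins),
restricted to the 100-1000 Hz band where wheezes live, then divided by
its grand mean so that factorisation penalties see a matrix of unit mean
regardless of recording level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window

from .audio import AudioSegment, AudioValidationError


@dataclass
class MagnitudeSpectrogram:
    """Non-negative F x T magnitude matrix with explicit axes.

    Attributes
    ----------
    values : ndarray, shape (F, T)
        Non-negative magnitudes.
    freqs : ndarray, shape (F,)
        Bin-centre frequencies in Hz, strictly increasing.
    times : ndarray, shape (T,)
        Frame-centre times in seconds.
    window_len, hop, dft_size : int
        Analysis parameters in samples / bins.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_len: int
    hop: int
    dft_size: int

    @property
    def df(self) -> float:
        """Frequency resolution in Hz (uniform grid)."""
        return float(self.freqs[1] - self.freqs[0]) if len(self.freqs) > 1 else float("nan")


def compute_spectrogram(
    segment: AudioSegment,
    window_len: int = 256,
    overlap_fraction: float = 0.1,
    dft_size: int = 512,
) -> MagnitudeSpectrogram:
    """One-sided Hamming-windowed STFT magnitude of a segment.

    The hop is ``window_len - round(overlap_fraction * window_len)``
    (230 samples for the defaults); trailing samples shorter than one
    window are dropped, giving ``T = 1 + floor((L - N) / hop)`` frames.
    """
    x = np.asarray(segment.samples, dtype=np.float64)
    n = int(window_len)
    if len(x) < n:
        raise AudioValidationError(
            f"segment of {len(x)} samples is shorter than one {n}-sample window"
        )
    hop = n - int(round(overlap_fraction * n))
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[::hop]
    window = get_window("hamming", n, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * window, n=dft_size, axis=1)).T
    freqs = np.fft.rfftfreq(dft_size, d=1.0 / segment.sample_rate)
    times = (np.arange(frames.shape[0]) * hop + n / 2) / segment.sample_rate
    return MagnitudeSpectrogram(spec, freqs, times, n, hop, dft_size)


def band_limit(
    spec: MagnitudeSpectrogram, fmin: float = 100.0, fmax: float = 1000.0
) -> MagnitudeSpectrogram:
    """Restrict rows to bins with fmin <= freq <= fmax (idempotent).

    With the default 8 Hz resolution this keeps bins 13..125
    (104-1000 Hz), i.e. F = 113 rows.
    """
    if not fmin < fmax:
        raise ValueError(f"need fmin < fmax, got {fmin} >= {fmax}")
    mask = (spec.freqs >= fmin) & (spec.freqs <= fmax)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{fmin}, {fmax}] Hz")
    return replace(spec, values=spec.values[mask], freqs=spec.freqs[mask])


def normalize_spectrogram(spec: MagnitudeSpectrogram) -> MagnitudeSpectrogram:
    """Divide by the grand mean so the output has mean exactly one.

    This makes the decomposition independent of recording level and
    segment size, and is a fixed point: normalising twice is a no-op.
    """
    mean = spec.values.mean()
    if not mean > 0:
        raise ValueError("degenerate segment: all-zero spectrogram cannot be normalised")
    return replace(spec, values=spec.values / mean)


def analysis_spectrogram(
    segment: AudioSegment,
    window_len: int = 256,
    overlap_fraction: float = 0.1,
    dft_size: int = 512,
    fmin: float = 100.0,
    fmax: float = 1000.0,
) -> MagnitudeSpectrogram:
    """Full front end: STFT -> band-limit -> grand-mean normalisation."""
    spec = compute_spectrogram(segment, window_len, overlap_fraction, dft_size)
    return normalize_spectrogram(band_limit(spec, fmin, fmax))
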