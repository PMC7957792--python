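"""Synthetic wheeze segments and respiratory-noise interference.

The labelled auscultation corpus the method targets is not publicly
available, so this module emulates its statistical structure: monophonic
Type 1 wheezes (a single narrowband tone), monophonic Type 2 wheezes (a
basal tone plus integer harmonics), and polyphonic wheezes (several
mutually non-harmonic tones), each 0.1-0.7 s at 4096 Hz, mixed at a
controlled SNR with wideband normal respiratory noise whose energy is
concentrated in 60-1000 Hz.

Wheezes are continuous adventitious sounds: slowly varying narrowband
tones.  They are synthesised as sums of sinusoidal partials sharing a
slow sinusoidal frequency drift (applied multiplicatively so harmonic
relations are preserved exactly) under a raised-cosine on/off envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt, windows

from .audio import MIN_DURATION, TARGET_RATE, AudioSegment

__all__ = [
    "SyntheticSegmentSpec",
    "generate_wheeze",
    "generate_respiratory_noise",
    "mix_at_snr",
    "generate_dataset",
]

#: Analysis band (Hz) every planted component must stay inside.
BAND = (100.0, 1000.0)
#: Non-harmonicity guard band for polyphonic specs (Hz).  Must exceed the
#: worst-case half main-lobe width of a drifting basal peak (~18 Hz) plus
#: grid quantisation, so that a planted polyphonic peak can never land
#: inside a harmonic tolerance interval: four 8 Hz analysis bins.
GUARD_HZ = 32.0


@dataclass
class SyntheticSegmentSpec:
    """Recipe for one labelled synthetic segment.

    ``frequencies`` holds the planted partial frequencies: for MP1 a
    single tone, for MP2 exactly {f0, 2 f0, ..., (1+n_harmonics) f0},
    for PP several tones none of which sits within ``GUARD_HZ`` of an
    integer multiple of the lowest.
    """

    wheeze_class: str  # "MP1" | "MP2" | "PP"
    f0: float | list[float]  # basal Hz (MP) or peak list Hz (PP)
    n_harmonics: int = 0  # MP2 only: harmonics above the basal tone
    partial_amplitudes: list[float] | None = None
    fm_depth: float = 10.0  # Hz, slow drift amplitude on the basal tone
    fm_rate: float = 2.0  # Hz
    duration: float = 0.5  # s
    snr_db: float = math.inf  # wheeze-to-noise power ratio; inf = clean
    seed: int | None = None

    @property
    def frequencies(self) -> list[float]:
        if self.wheeze_class == "MP1":
            return [float(self.f0)]
        if self.wheeze_class == "MP2":
            return [float(self.f0) * h for h in range(1, self.n_harmonics + 2)]
        return [float(f) for f in np.atleast_1d(self.f0)]

    @property
    def label(self) -> str:
        return "MP" if self.wheeze_class in ("MP1", "MP2") else "PP"

    @property
    def subtype(self) -> str | None:
        return {"MP1": "Type1", "MP2": "Type2"}.get(self.wheeze_class)

    def validate(self) -> None:
        if self.wheeze_class not in ("MP1", "MP2", "PP"):
            raise ValueError(f"unknown wheeze class {self.wheeze_class!r}")
        if not MIN_DURATION <= self.duration <= 0.7 + 1e-9:
            raise ValueError(f"duration {self.duration} s outside [0.1, 0.7] s")
        freqs = self.frequencies
        if self.wheeze_class == "MP2" and self.n_harmonics < 1:
            raise ValueError("MP2 needs n_harmonics >= 1")
        if self.wheeze_class == "PP":
            if len(freqs) < 2:
                raise ValueError("PP needs at least two peak frequencies")
            fmin = min(freqs)
            for f in freqs:
                if f == fmin:
                    continue
                nearest = round(f / fmin) * fmin
                if abs(f - nearest) < GUARD_HZ:
                    raise ValueError(
                        f"PP frequency {f} Hz is within {GUARD_HZ} Hz of a "
                        f"multiple of the basal {fmin} Hz"
                    )
        for f in freqs:
            if not BAND[0] <= f <= BAND[1]:
                raise ValueError(f"component at {f} Hz outside {BAND} Hz")


def generate_wheeze(spec: SyntheticSegmentSpec, sample_rate: int = TARGET_RATE) -> AudioSegment:
    """Synthesise the clean wheeze tone described by ``spec``.

    All partials share one slow sinusoidal frequency drift applied as a
    common additive offset ``d(t) = fm_depth * (sin(2 pi fm_rate t + phi)
    - mean)`` with a random shared phase phi.  The drift is centred on
    the analysed segment (its segment mean is subtracted) so that every
    partial's time-averaged instantaneous frequency equals its declared
    nominal frequency exactly, and every component stays within
    ``fm_depth`` Hz -- one to two analysis bins -- of nominal; phases
    are integrals of the instantaneous frequencies.  A raised-cosine
    attack/decay envelope avoids onset clicks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    freqs = spec.frequencies
    amps = spec.partial_amplitudes
    if amps is None:
        amps = [1.0 / (i + 1) for i in range(len(freqs))]  # 1/h rolloff
    # integral of the mean-centred d(t) over time, shared by all partials
    if spec.fm_depth > 0 and spec.fm_rate > 0:
        phi = rng.uniform(0, 2 * np.pi)
        omega = 2 * np.pi * spec.fm_rate
        raw_int = (np.cos(phi) - np.cos(omega * t + phi)) / omega
        mean_drift = raw_int[-1] / t[-1] if t[-1] > 0 else 0.0
        drift_int = spec.fm_depth * (raw_int - mean_drift * t)
    else:
        drift_int = np.zeros(n)
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        phase0 = rng.uniform(0, 2 * np.pi)
        x += a * np.sin(2 * np.pi * (f * t + drift_int) + phase0)
    x *= windows.tukey(n, alpha=0.2)
    return AudioSegment(x, sample_rate, spec.label, spec.subtype, {"spec": spec})


#: Band (Hz) where normal respiratory sound concentrates its energy.
NOISE_BAND = (60.0, 1000.0)


def _breath_sos(sample_rate: int):
    band = butter(4, NOISE_BAND, btype="bandpass", fs=sample_rate, output="sos")
    tilt = butter(1, 200.0, btype="lowpass", fs=sample_rate, output="sos")
    return band, tilt


def generate_respiratory_noise(
    duration: float, seed: int | None = None, sample_rate: int = TARGET_RATE
) -> AudioSegment:
    """Wideband normal-respiratory-sound interference.

    Gaussian noise band-passed to 60-1000 Hz with a gentle -6 dB/octave
    tilt above 200 Hz and a slow breath amplitude modulation; at least
    90% of the output power lies inside 60-1000 Hz.
    """
    if duration < MIN_DURATION:
        raise ValueError(f"duration {duration} s below {MIN_DURATION} s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n + sample_rate // 4)  # pad for filter warm-up
    band, tilt = _breath_sos(sample_rate)
    x = sosfiltfilt(band, sosfilt(tilt, white))[-n:]
    t = np.arange(n) / sample_rate
    breath_rate = rng.uniform(0.2, 0.4)  # Hz, adult respiratory cycle
    env = 1.0 + 0.5 * np.sin(2 * np.pi * breath_rate * t + rng.uniform(0, 2 * np.pi))
    return AudioSegment(x * env, sample_rate, "noise")


def _band_power(x: np.ndarray, sample_rate: int) -> float:
    band, _ = _breath_sos(sample_rate)
    return float(np.mean(sosfiltfilt(band, x) ** 2))


def mix_at_snr(wheeze: AudioSegment, noise: AudioSegment, snr_db: float) -> AudioSegment:
    """Add noise scaled so the in-band wheeze/noise power ratio is snr_db.

    Power is measured after band-limiting both parts to 60-1000 Hz (the
    band both sources occupy).  ``snr_db = inf`` returns the clean
    wheeze.
    """
    if wheeze.sample_rate != noise.sample_rate:
        raise ValueError("sample-rate mismatch between wheeze and noise")
    if math.isinf(snr_db) and snr_db > 0:
        return AudioSegment(
            wheeze.samples.copy(), wheeze.sample_rate, wheeze.label, wheeze.subtype,
            dict(wheeze.meta),
        )
    n = len(wheeze.samples)
    noise_x = noise.samples
    if len(noise_x) < n:  # loop the noise to cover the wheeze
        noise_x = np.tile(noise_x, int(np.ceil(n / len(noise_x))))
    noise_x = noise_x[:n]
    pw = _band_power(wheeze.samples, wheeze.sample_rate)
    pn = _band_power(noise_x, wheeze.sample_rate)
    if pw <= 0 or pn <= 0:
        raise ValueError("zero in-band power in wheeze or noise")
    gain = math.sqrt(pw / (pn * 10.0 ** (snr_db / 10.0)))
    meta = dict(wheeze.meta)
    meta["snr_db"] = snr_db
    return AudioSegment(
        wheeze.samples + gain * noise_x, wheeze.sample_rate, wheeze.label,
        wheeze.subtype, meta,
    )


def _random_spec(kind: str, rng: np.random.Generator, snr_db: float) -> SyntheticSegmentSpec:
    duration = rng.uniform(MIN_DURATION, 0.7)
    seed = int(rng.integers(0, 2**31 - 1))
    fm_depth, fm_rate = 10.0, 2.0  # defaults; drift phase varies per seed
    if kind == "MP1":
        return SyntheticSegmentSpec(
            "MP1", f0=float(rng.uniform(150.0, 450.0)), fm_depth=fm_depth,
            fm_rate=fm_rate, duration=duration, snr_db=snr_db, seed=seed,
        )
    if kind == "MP2":
        f0 = float(rng.uniform(150.0, 450.0))
        max_h = int(1000.0 // f0) - 1  # keep (1 + n_harmonics) * f0 <= 1000 Hz
        n_h = int(rng.integers(1, max(2, min(3, max_h) + 1)))
        return SyntheticSegmentSpec(
            "MP2", f0=f0, n_harmonics=min(n_h, max_h), fm_depth=fm_depth,
            fm_rate=fm_rate, duration=duration, snr_db=snr_db, seed=seed,
        )
    # PP: 2-5 mutually non-harmonic peaks, rejection-sampled
    n_peaks = int(rng.integers(2, 6))
    basal = float(rng.uniform(150.0, 450.0))
    freqs = [basal]
    attempts = 0
    while len(freqs) < n_peaks and attempts < 500:
        attempts += 1
        f = float(rng.uniform(BAND[0] + GUARD_HZ, BAND[1] - GUARD_HZ))
        fmin = min(freqs + [f])
        ok = all(abs(g - round(g / fmin) * fmin) >= GUARD_HZ or g == fmin
                 for g in freqs + [f])
        ok = ok and all(abs(f - g) >= 40.0 for g in freqs)  # resolvable peaks
        if ok:
            freqs.append(f)
    freqs.sort()
    return SyntheticSegmentSpec(
        "PP", f0=freqs, partial_amplitudes=[1.0] * len(freqs), fm_depth=fm_depth,
        fm_rate=fm_rate, duration=duration, snr_db=snr_db, seed=seed,
    )


def generate_dataset(
    n_mp1: int = 100,
    n_mp2: int = 100,
    n_pp: int = 200,
    snr_db: float = 5.0,
    seed: int | None = None,
) -> list[AudioSegment]:
    """Labelled synthetic corpus emulating the 100/100/200 MP1/MP2/PP design.

    Basal frequencies are uniform in [150, 450] Hz (so MP2 harmonics stay
    below 1000 Hz), PP segments carry 2-5 peaks, durations are uniform in
    [0.1, 0.7] s, and each wheeze is mixed with independent respiratory
    noise at ``snr_db``.  Fully reproducible from ``seed``.
    """
    if min(n_mp1, n_mp2, n_pp) < 0:
        raise ValueError("segment counts must be non-negative")
    rng = np.random.default_rng(seed)
    segments: list[AudioSegment] = []
    for kind, count in (("MP1", n_mp1), ("MP2", n_mp2), ("PP", n_pp)):
        for _ in range(count):
            spec = _random_spec(kind, rng, snr_db)
            wheeze = generate_wheeze(spec)
            if math.isinf(snr_db) and snr_db > 0:
                segments.append(wheeze)
                continue
            noise = generate_respiratory_noise(
                spec.duration, seed=int(rng.integers(0, 2**31 - 1))
            )
            segments.append(mix_at_snr(wheeze, noise, snr_db))
    return segments
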