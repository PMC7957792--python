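"""End-to-end wheeze classification: audio segment -> MP/PP label.

Chains the front end (STFT, band-limit, grand-mean normalisation), the
constrained low-rank factorisation, and the harmonic-structure analysis
of xi(f).  The whole chain is unsupervised: ``fit`` learns nothing, it
only finalises parameters, so the estimator drops into sklearn model
selection and pipelines as a stateless predictor.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .audio import AudioSegment
from .factorization import CLRNMF
from .harmonic import MP, PP, WheezeClass, classify_peaks, detect_peaks
from .spectrogram import analysis_spectrogram

__all__ = ["WheezeClassifier", "classify_segment"]


class WheezeClassifier(BaseEstimator, ClassifierMixin):
    """Monophonic/polyphonic wheeze classifier over audio segments.

    Parameters mirror the factorisation estimator plus the front-end and
    peak-detection knobs.  ``n_runs`` > 1 repeats the (randomly
    initialised) factorisation with consecutive seeds and reports the
    majority label, ties broken toward PP (the clinically distinct COPD
    alarm).

    Attributes
    ----------
    classes_ : ndarray
        ``["MP", "PP"]`` after ``fit``.
    """

    def __init__(
        self,
        n_wheeze_components: int = 4,
        n_resp_components: int = 32,
        alpha: float = 0.5,
        beta: float = 0.5,
        lam: float = 0.5,
        max_iter: int = 50,
        tol: float = 0.0,
        epsilon: float = 1e-12,
        window_len: int = 256,
        overlap_fraction: float = 0.1,
        dft_size: int = 512,
        fmin: float = 100.0,
        fmax: float = 1000.0,
        prominence_fraction: float = 0.05,
        n_runs: int = 1,
        random_state: int | None = None,
    ):
        self.n_wheeze_components = n_wheeze_components
        self.n_resp_components = n_resp_components
        self.alpha = alpha
        self.beta = beta
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.epsilon = epsilon
        self.window_len = window_len
        self.overlap_fraction = overlap_fraction
        self.dft_size = dft_size
        self.fmin = fmin
        self.fmax = fmax
        self.prominence_fraction = prominence_fraction
        self.n_runs = n_runs
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "WheezeClassifier":
        """No-op fit (the method is unsupervised and training-free)."""
        self.classes_ = np.array([MP, PP])
        return self

    def _classify_once(self, segment: AudioSegment, seed) -> WheezeClass:
        spec = analysis_spectrogram(
            segment,
            self.window_len,
            self.overlap_fraction,
            self.dft_size,
            self.fmin,
            self.fmax,
        )
        nmf = CLRNMF(
            n_wheeze_components=self.n_wheeze_components,
            n_resp_components=self.n_resp_components,
            alpha=self.alpha,
            beta=self.beta,
            lam=self.lam,
            max_iter=self.max_iter,
            tol=self.tol,
            epsilon=self.epsilon,
            random_state=seed,
        ).fit(spec.values)
        xi = nmf.spectral_energy_distribution()
        peaks = detect_peaks(xi, spec.freqs, self.prominence_fraction)
        return classify_peaks(peaks)

    def classify_segment(self, segment: AudioSegment) -> WheezeClass:
        """Classify one segment; with ``n_runs`` > 1, majority vote over
        consecutive seeds (ties -> PP)."""
        base = self.random_state
        if self.n_runs <= 1:
            return self._classify_once(segment, base)
        votes = [
            self._classify_once(segment, None if base is None else base + r)
            for r in range(self.n_runs)
        ]
        n_mp = sum(1 for v in votes if v.label == MP)
        if n_mp > self.n_runs - n_mp:
            winner = next(v for v in votes if v.label == MP)
        else:
            winner = next((v for v in votes if v.label == PP), votes[0])
        winner.detail["votes"] = [v.label for v in votes]
        return winner

    def predict(self, X) -> np.ndarray:
        """Predict MP/PP for a sequence of :class:`AudioSegment`."""
        if not hasattr(self, "classes_"):
            self.fit()
        return np.array([self.classify_segment(seg).label for seg in X])

    def predict_detail(self, X) -> list[WheezeClass]:
        """Like ``predict`` but returning full :class:`WheezeClass` records."""
        if not hasattr(self, "classes_"):
            self.fit()
        return [self.classify_segment(seg) for seg in X]


def classify_segment(
    segment: AudioSegment, seed: int | None = None, n_runs: int = 1, **params
) -> WheezeClass:
    """One-call classification of a segment with pipeline defaults."""
    clf = WheezeClassifier(random_state=seed, n_runs=n_runs, **params).fit()
    return clf.classify_segment(segment)
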