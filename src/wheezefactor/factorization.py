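"""Constrained low-rank NMF separating wheeze and respiratory spectra.

The normalised magnitude spectrogram X (F x T) is modelled as the sum of
two non-negative factorisations,

    X  ~  X_hat  =  B_R A_R + B_W A_W,

where the wheeze part uses few components (Kw << Kr) whose bases are
pushed to be sparse in frequency and whose activations are pushed to be
smooth in time, while the many respiratory components are pushed to be
smooth in frequency (wideband).  The global objective is

    D = D_KL(X | X_hat) + alpha * psi(B_W) + lam * phi(A_W) + beta * phi(B_R)

with D_KL the generalised Kullback-Leibler divergence, psi the L1
sparseness penalty and phi the RMS-normalised squared-difference
smoothness penalty.  Minimisation uses multiplicative updates built from
the negative/positive split of each partial derivative, so all matrices
stay elementwise non-negative.  The classifier input is the spectral
energy distribution xi(f), the row-sum of B_W over its components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CLRNMF",
    "FactorizationResult",
    "SpectralEnergyDistribution",
    "kl_divergence",
    "spectral_sparseness",
    "temporal_smoothness",
    "spectral_smoothness",
    "global_objective",
    "factorize",
    "spectral_energy_distribution",
]


# ---------------------------------------------------------------------------
# Penalty terms
# ---------------------------------------------------------------------------

def kl_divergence(X: np.ndarray, Xhat: np.ndarray, epsilon: float = 1e-12) -> float:
    """Generalised Kullback-Leibler divergence sum X log(X/Xhat) - X + Xhat.

    Uses the convention 0*log0 = 0, so entries where X == 0 contribute
    Xhat.  Non-negative, zero iff X == Xhat.
    """
    X = np.asarray(X, dtype=np.float64)
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Xhat.shape}")
    Xhat = np.maximum(Xhat, epsilon)
    pos = X > 0
    logterm = np.zeros_like(X)
    logterm[pos] = X[pos] * np.log(X[pos] / Xhat[pos])
    return float(np.sum(logterm - X + Xhat))


def spectral_sparseness(B: np.ndarray) -> float:
    """L1 sparseness penalty psi(B): the plain sum of a non-negative matrix."""
    B = np.asarray(B, dtype=np.float64)
    if np.any(B < 0):
        raise ValueError("sparseness penalty requires a non-negative matrix")
    return float(B.sum())


def _smoothness(M: np.ndarray, axis_len_name: str) -> float:
    # rows = components, smoothing along axis 1; sigma_k^2 = mean of squares
    K, T = M.shape
    if T < 2:
        raise ValueError(f"smoothness penalty needs {axis_len_name} >= 2, got {T}")
    E = np.sum(M * M, axis=1)  # T * sigma_k^2
    D = np.sum(np.diff(M, axis=1) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_k = np.where(E > 0, T * D / np.where(E > 0, E, 1.0), 0.0)
    return float(per_k.sum())


def temporal_smoothness(A: np.ndarray) -> float:
    """Temporal-continuity penalty phi(A) on a K x T activation matrix.

    Sum over components of squared frame-to-frame differences divided by
    sigma_k^2 = (1/T) sum_t A[k,t]^2; scale invariant per component, and
    all-zero rows contribute zero by convention.
    """
    A = np.asarray(A, dtype=np.float64)
    return _smoothness(A, "T")


def spectral_smoothness(B: np.ndarray) -> float:
    """Spectral-continuity penalty phi(B) on an F x K basis matrix.

    Same form as the temporal penalty, but over adjacent frequency bins
    of each basis column.
    """
    B = np.asarray(B, dtype=np.float64)
    return _smoothness(B.T, "F")


@dataclass
class FactorizationResult:
    """Estimated factors of the two-part decomposition plus diagnostics."""

    BW: np.ndarray  # F x Kw wheeze bases
    BR: np.ndarray  # F x Kr respiratory bases
    AW: np.ndarray  # Kw x T wheeze activations
    AR: np.ndarray  # Kr x T respiratory activations
    objective_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def Xhat(self) -> np.ndarray:
        return self.BR @ self.AR + self.BW @ self.AW


@dataclass
class SpectralEnergyDistribution:
    """xi(f): per-bin wheeze energy, the column-sum of B_W over components."""

    xi: np.ndarray
    freqs: np.ndarray | None = None


def global_objective(
    X: np.ndarray,
    result: FactorizationResult,
    alpha: float = 0.5,
    beta: float = 0.5,
    lam: float = 0.5,
    epsilon: float = 1e-12,
) -> float:
    """Constrained objective D_KL + alpha*psi(BW) + lam*phi(AW) + beta*phi(BR).

    Smoothness terms are taken as zero when the corresponding axis is too
    short to have adjacent differences (T < 2 or F < 2).
    """
    d = kl_divergence(X, result.Xhat, epsilon)
    if alpha:
        d += alpha * spectral_sparseness(result.BW)
    if lam and result.AW.shape[1] >= 2:
        d += lam * temporal_smoothness(result.AW)
    if beta and result.BR.shape[0] >= 2:
        d += beta * spectral_smoothness(result.BR)
    return d


# ---------------------------------------------------------------------------
# Multiplicative updates
# ---------------------------------------------------------------------------

def _smoothness_grad_parts(M: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative parts of d phi / d M for rows smoothed along axis 1.

    phi_k = T * D_k / E_k with D_k the squared-difference sum and
    E_k = sum_t M[k,t]^2 (so sigma_k^2 = E_k / T).  Differentiating the
    quotient gives, per entry,

        d phi / d M[k,t] = (T/E_k) dD_k/dM[k,t] - (2 T D_k / E_k^2) M[k,t]

    whose split into non-negative parts is: positive (T/E_k) * {4M
    interior, 2M at the two ends}; negative (T/E_k) * 2 * (neighbour sum)
    plus (2 T D_k / E_k^2) * M.  Rows with E_k = 0 contribute nothing.
    """
    K, T = M.shape
    pos = np.zeros_like(M)
    neg = np.zeros_like(M)
    if T < 2:
        return pos, neg
    E = np.sum(M * M, axis=1)
    D = np.sum(np.diff(M, axis=1) ** 2, axis=1)
    invE = np.where(E > 0, 1.0 / np.maximum(E, eps), 0.0)
    coef = (T * invE)[:, None]

    gpos = 4.0 * M
    gpos[:, 0] = 2.0 * M[:, 0]
    gpos[:, -1] = 2.0 * M[:, -1]

    gneg = np.zeros_like(M)
    gneg[:, 0] = 2.0 * M[:, 1]
    gneg[:, -1] = 2.0 * M[:, -2]
    if T > 2:
        gneg[:, 1:-1] = 2.0 * (M[:, :-2] + M[:, 2:])

    pos = coef * gpos
    neg = coef * gneg + (2.0 * T * D * invE * invE)[:, None] * M
    return pos, neg


def initial_factors(
    rng: np.random.Generator, F: int, T: int, kw: int, kr: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded uniform-(0, 1] starting factors (BW, BR, AW, AR).

    Strictly positive draws avoid multiplicative lock-in at zero.
    """
    BW = 1.0 - rng.random((F, kw))
    BR = 1.0 - rng.random((F, kr))
    AW = 1.0 - rng.random((kw, T))
    AR = 1.0 - rng.random((kr, T))
    return BW, BR, AW, AR


class CLRNMF(BaseEstimator):
    """Constrained low-rank NMF of a wheeze-bearing magnitude spectrogram.

    Decomposes a non-negative F x T matrix into a low-rank wheeze part
    (``n_wheeze_components`` sparse-in-frequency bases with smooth
    activations) plus a high-rank respiratory part
    (``n_resp_components`` smooth-in-frequency bases), by multiplicative
    updates of the penalised KL objective.

    Parameters
    ----------
    n_wheeze_components : int, default=4
        Kw, number of wheeze bases (2..6 recommended).
    n_resp_components : int, default=32
        Kr, number of respiratory bases (>= 32 recommended).
    alpha : float, default=0.5
        Weight of the L1 sparseness penalty on the wheeze bases.
    beta : float, default=0.5
        Weight of the spectral-smoothness penalty on respiratory bases.
    lam : float, default=0.5
        Weight of the temporal-smoothness penalty on wheeze activations.
    max_iter : int, default=50
        Maximum number of multiplicative-update iterations M.
    tol : float, default=0.0
        Relative objective-change early-stop threshold; 0 runs all
        ``max_iter`` iterations.
    epsilon : float, default=1e-12
        Floor for denominators and log arguments.
    random_state : int or numpy Generator, optional
        Seeds the uniform-(0, 1] initialisation of all four factors.

    Attributes
    ----------
    wheeze_basis_ : ndarray, shape (F, Kw)
    resp_basis_ : ndarray, shape (F, Kr)
    wheeze_activations_ : ndarray, shape (Kw, T)
    resp_activations_ : ndarray, shape (Kr, T)
    objective_trajectory_ : ndarray
        Objective value at initialisation and after each full iteration.
    n_iter_ : int
        Iterations actually run.
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
        random_state: int | np.random.Generator | None = None,
    ):
        self.n_wheeze_components = n_wheeze_components
        self.n_resp_components = n_resp_components
        self.alpha = alpha
        self.beta = beta
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.epsilon = epsilon
        self.random_state = random_state

    def _validate(self) -> None:
        if self.n_wheeze_components < 1 or self.n_resp_components < 1:
            raise ValueError("component counts must be >= 1")
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.epsilon > 0 or self.tol < 0:
            raise ValueError("need epsilon > 0 and tol >= 0")

    def fit(self, X: np.ndarray, y: None = None) -> "CLRNMF":
        """Run the multiplicative-update loop on an F x T matrix."""
        self._validate()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2D magnitude matrix")
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("X must be finite and non-negative")
        if not X.mean() > 0:
            raise ValueError("X must have a positive grand mean")
        F, T = X.shape
        eps = self.epsilon
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        BW, BR, AW, AR = initial_factors(
            rng, F, T, self.n_wheeze_components, self.n_resp_components
        )

        def objective() -> float:
            return global_objective(
                X,
                FactorizationResult(BW, BR, AW, AR),
                self.alpha,
                self.beta,
                self.lam,
                eps,
            )

        trajectory = [objective()]
        n_iter = 0
        for it in range(self.max_iter):
            # Step 3: wheeze bases (KL + alpha * dpsi, dpsi/dBW = 1 all-ones)
            R = X / np.maximum(BR @ AR + BW @ AW, eps)
            num = R @ AW.T
            den = AW.sum(axis=1)[None, :] + self.alpha
            BW *= num / np.maximum(den, eps)

            # Step 4: respiratory bases (KL + beta * spectral smoothness)
            R = X / np.maximum(BR @ AR + BW @ AW, eps)
            num = R @ AR.T
            den = AR.sum(axis=1)[None, :]
            sm_pos, sm_neg = _smoothness_grad_parts(BR.T, eps)
            BR *= (num + self.beta * sm_neg.T) / np.maximum(den + self.beta * sm_pos.T, eps)

            # Step 5: wheeze activations (KL + lam * temporal smoothness)
            R = X / np.maximum(BR @ AR + BW @ AW, eps)
            num = BW.T @ R
            den = BW.sum(axis=0)[:, None]
            sm_pos, sm_neg = _smoothness_grad_parts(AW, eps)
            AW *= (num + self.lam * sm_neg) / np.maximum(den + self.lam * sm_pos, eps)

            # Step 6: respiratory activations (plain KL rule)
            R = X / np.maximum(BR @ AR + BW @ AW, eps)
            num = BR.T @ R
            den = BR.sum(axis=0)[:, None]
            AR *= num / np.maximum(den, eps)

            for name, M in (("BW", BW), ("BR", BR), ("AW", AW), ("AR", AR)):
                if not np.all(np.isfinite(M)):
                    raise FloatingPointError(
                        f"non-finite values in {name} at iteration {it + 1}"
                    )

            trajectory.append(objective())
            n_iter = it + 1
            if self.tol > 0 and len(trajectory) >= 2:
                prev, cur = trajectory[-2], trajectory[-1]
                if abs(prev - cur) <= self.tol * max(abs(prev), eps):
                    break

        self.wheeze_basis_ = BW
        self.resp_basis_ = BR
        self.wheeze_activations_ = AW
        self.resp_activations_ = AR
        self.objective_trajectory_ = np.asarray(trajectory)
        self.n_iter_ = n_iter
        return self

    def fit_transform(self, X: np.ndarray, y: None = None) -> np.ndarray:
        """Fit and return the spectral energy distribution xi(f)."""
        return self.fit(X).spectral_energy_distribution()

    @property
    def result_(self) -> FactorizationResult:
        check_is_fitted(self, "wheeze_basis_")
        return FactorizationResult(
            self.wheeze_basis_,
            self.resp_basis_,
            self.wheeze_activations_,
            self.resp_activations_,
            self.objective_trajectory_,
        )

    def spectral_energy_distribution(self) -> np.ndarray:
        """xi(f) = sum over wheeze components of B_W[f, k]."""
        check_is_fitted(self, "wheeze_basis_")
        return self.wheeze_basis_.sum(axis=1)


def factorize(X: np.ndarray, **params) -> FactorizationResult:
    """Functional wrapper over :class:`CLRNMF` returning the raw factors."""
    return CLRNMF(**params).fit(X).result_


def spectral_energy_distribution(
    result: FactorizationResult, freqs: np.ndarray | None = None
) -> SpectralEnergyDistribution:
    """Collapse the wheeze bases into the classifier input xi(f).

    Summing over all components handles the case where the narrowband
    peaks of one wheeze are split across several bases.
    """
    return SpectralEnergyDistribution(np.asarray(result.BW).sum(axis=1), freqs)
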