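"""The analytically solvable ring hypercolumn (toy model) and its oracles.

M output neurons with preferred angles theta_i = 2*pi*i/M receive a
2-dimensional input x = r (cos theta0, sin theta0): theta0 is the stimulus
angle (full 360-degree periodicity) and r its contrast.  The feedforward
rows are unit vectors (cos theta_i, sin theta_i), so neuron i has a cosine
tuning curve peaked at theta_i.

In the zero-contrast limit, for a translation-invariant interaction profile
K(theta_i - theta_j) = (1/M) sum_n k_n cos(n theta), the objective depends
only on the first cosine harmonic k1:

    eps(k1) - eps(0) = 2 ln(1 - gamma0 k1 / 2),

which diverges to -infinity as k1 -> k1c = 2/gamma0.  The infomax-optimal
profile is therefore a pure cosine with amplitude M*K = 2/gamma0 (= 8 for
the logistic, gamma0 = 1/4): the network sits at the edge of the pattern-
forming instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParams, LOGISTIC


@dataclass(frozen=True)
class RingSpec:
    """Ring geometry plus the input-contrast statistics used for training."""

    M: int = 141
    mean_contrast: float = 0.1
    contrast_sd_fraction: float = 0.1

    def __post_init__(self):
        if self.M < 3:
            raise ValueError("ring needs M >= 3 neurons")

    @property
    def preferred_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.M) / self.M


def ring_angles(M: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(M) / M


def build_ring(M: int) -> NetworkParams:
    """Ring network: W rows are unit vectors at equally spaced angles, K=0."""
    if M < 3:
        raise ValueError("ring needs M >= 3 neurons")
    theta = ring_angles(M)
    W = np.column_stack([np.cos(theta), np.sin(theta)])
    return NetworkParams(W=W, K=np.zeros((M, M)), tau=1.0,
                         nonlinearity=LOGISTIC)


def sample_ring_inputs(spec: RingSpec, n: int, seed=None) -> np.ndarray:
    """Draw n inputs x = r (cos theta0, sin theta0).

    theta0 ~ Uniform[0, 2pi); r ~ Normal(mean_contrast,
    contrast_sd_fraction * mean_contrast).  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = rng.normal(spec.mean_contrast,
                   spec.contrast_sd_fraction * spec.mean_contrast, size=n)
    return r[:, None] * np.column_stack([np.cos(theta0), np.sin(theta0)])


@dataclass
class FourierProfile:
    """Cosine harmonics of a circularly averaged interaction profile.

    Normalization follows K(theta) = (1/M) sum_n k_n cos(n theta): a matrix
    K_ij = (c/M) cos(theta_i - theta_j) yields k1 = c.  ``k[0]`` is the
    mean (uniform) term with the same convention (constant c/M -> k0 = c).
    ``circulant_residual`` is the rms deviation of K from its circular
    (diagonal) average, relative to the rms of the average itself.
    """

    k: np.ndarray
    profile: np.ndarray          # circularly averaged profile over offsets
    offsets: np.ndarray          # angular separations theta_d = 2 pi d / M
    circulant_residual: float

    @property
    def k1(self) -> float:
        return float(self.k[1])


def circular_average_profile(K: np.ndarray) -> np.ndarray:
    """Average K over its (wrapped) diagonals: p[d] = mean_i K[(i+d)%M, i]."""
    K = np.asarray(K, dtype=float)
    M = K.shape[0]
    idx = (np.arange(M)[:, None] + np.arange(M)[None, :]) % M
    # p[d] = mean over i of K[i+d, i]
    return K[idx, np.arange(M)[None, :]].mean(axis=1)


def fourier_profile(K: np.ndarray, n_max: int | None = None) -> FourierProfile:
    """Extract cosine harmonics k_n of a (near-)circulant interaction matrix.

    Non-circulant matrices are first circularly averaged over diagonals and
    the residual reported (large residuals are not fatal).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    M = K.shape[0]
    p = circular_average_profile(K)
    recon = p[(np.arange(M)[:, None] - np.arange(M)[None, :]) % M]
    # relative rms deviation of K from its circulant part
    denom = float(np.sqrt(np.mean(p**2)))
    resid = float(np.sqrt(np.mean((K - recon) ** 2)))
    residual = resid / denom if denom > 0 else resid

    if n_max is None:
        n_max = M // 2
    n_max = min(n_max, M // 2)
    spec = np.fft.rfft(p)
    k = np.empty(n_max + 1)
    k[0] = float(np.real(spec[0]))                  # sum_d p[d]
    k[1:] = 2.0 * np.real(spec[1:n_max + 1])
    offsets = 2.0 * np.pi * np.arange(M) / M
    return FourierProfile(k=k, profile=p, offsets=offsets,
                          circulant_residual=residual)


def cosine_interaction(M: int, k1: float) -> np.ndarray:
    """Pure-cosine circulant interaction matrix (k1/M) cos(theta_i-theta_j)."""
    theta = ring_angles(M)
    return (k1 / M) * np.cos(theta[:, None] - theta[None, :])


def optimal_ring_K(M: int, gamma0: float) -> np.ndarray:
    """Infomax-optimal zero-contrast interactions (2/(M gamma0)) cos(dtheta)."""
    if M < 3:
        raise ValueError("ring needs M >= 3 neurons")
    if gamma0 <= 0:
        raise ValueError("gamma0 must be positive")
    return cosine_interaction(M, 2.0 / gamma0)


def critical_k1(gamma0: float) -> float:
    """First-harmonic amplitude at which the uniform state loses stability."""
    return 2.0 / gamma0


def analytic_objective_shift(k1: float, gamma0: float) -> float:
    """eps(k1) - eps(0) = 2 ln(1 - gamma0 k1 / 2) in the zero-contrast limit.

    Only defined below the critical amplitude k1c = 2/gamma0; at and above
    it the susceptibility diverges and the objective is -infinity.
    """
    if k1 >= critical_k1(gamma0):
        raise ValueError(
            f"k1={k1} is supercritical (k1c={critical_k1(gamma0)}); "
            "the objective diverges")
    return 2.0 * float(np.log1p(-0.5 * gamma0 * k1))


def analytic_susceptibility(k1: float, angles: np.ndarray,
                            gamma0: float) -> np.ndarray:
    """Closed-form ring susceptibility at zero contrast, shape (M, 2).

    chi_i1 = gamma0 cos(theta_i) / (1 - gamma0 k1 / 2) and the sine analog
    for the second input component.
    """
    if k1 >= critical_k1(gamma0):
        raise ValueError(
            f"k1={k1} is supercritical (k1c={critical_k1(gamma0)})")
    angles = np.asarray(angles, dtype=float)
    denom = 1.0 - 0.5 * gamma0 * k1
    return gamma0 / denom * np.column_stack([np.cos(angles), np.sin(angles)])
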