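"""Random Fourier features (RFF) approximating the Gaussian kernel.

The shift-invariant Gaussian kernel kappa(x - x') = exp(-||x - x'||^2 / 2 sigma^2)
has, by Bochner's theorem, a non-negative spectral measure: an isotropic
normal with per-coordinate standard deviation 1/sigma. Drawing Q frequencies
omega_q from that measure and phases b_q uniformly on [0, 2pi), the explicit map

    phi_hat(x) = sqrt(2/Q) * [cos(omega_q . x + b_q)]_{q=1..Q}

satisfies E[phi_hat(x) . phi_hat(x')] = kappa(x - x'), with Monte-Carlo
variance shrinking like 1/Q. The segmentation networks apply this map
independently at every spatial position of their bottleneck feature grid
(a 1x1-convolution pattern), so an R x C x D grid becomes R x C x Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RFFParams",
    "sample_rff_params",
    "rff_map",
    "rff_layer_apply",
    "kernel_approx_error",
    "gaussian_kernel",
    "median_heuristic_sigma",
    "GaussianRFF",
]


@dataclass
class RFFParams:
    """Frozen spectral sample defining one RFF mapping.

    omega : (Q, P) frequency matrix, rows ~ N(0, I/sigma^2)
    b     : (Q,) phases in [0, 2pi)
    sigma : Gaussian-kernel bandwidth (> 0)
    trainable : whether a network treats omega/b as learnable
    """

    omega: np.ndarray
    b: np.ndarray
    sigma: float
    trainable: bool = False
    Q: int = field(init=False)
    P: int = field(init=False)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.omega.ndim != 2:
            raise ValueError("omega must be a Q x P matrix")
        self.Q, self.P = self.omega.shape
        if self.b.shape != (self.Q,):
            raise ValueError("b must have length Q")
        if np.any(self.b < 0) or np.any(self.b >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2*pi)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def sample_rff_params(P: int, Q: int, sigma: float, seed: int) -> RFFParams:
    """Draw the (omega, b) spectral sample for a Gaussian kernel of bandwidth sigma.

    Frequencies are i.i.d. N(0, 1/sigma^2) per coordinate — the Fourier
    transform of exp(-||delta||^2 / 2 sigma^2) — and phases are uniform on
    [0, 2pi). Deterministic given ``seed``.
    """
    if P < 1 or Q < 1:
        raise ValueError("P and Q must be >= 1")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    omega = rng.normal(0.0, 1.0 / sigma, size=(Q, P))
    b = rng.uniform(0.0, 2 * np.pi, size=Q)
    return RFFParams(omega=omega, b=b, sigma=float(sigma))


def rff_map(x: np.ndarray, params: RFFParams) -> np.ndarray:
    """Map one P-vector to its Q-dimensional random Fourier representation."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (params.P,):
        raise ValueError(f"expected a vector of length {params.P}, got {x.shape}")
    return np.sqrt(2.0 / params.Q) * np.cos(params.omega @ x + params.b)


def rff_layer_apply(F: np.ndarray, params: RFFParams) -> np.ndarray:
    """Apply the RFF map at every spatial position of an R x C x D grid.

    Position-wise independent (a 1x1 convolution with fixed weights), so the
    spatial layout is preserved: output is R x C x Q.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 3 or F.shape[-1] != params.P:
        raise ValueError(
            f"expected an R x C x {params.P} grid, got shape {F.shape}")
    z = np.tensordot(F, params.omega.T, axes=1) + params.b
    return np.sqrt(2.0 / params.Q) * np.cos(z)


def gaussian_kernel(x: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Exact kernel value exp(-||x - x'||^2 / 2 sigma^2)."""
    d = np.asarray(x, dtype=np.float64) - np.asarray(x2, dtype=np.float64)
    return float(np.exp(-np.dot(d, d) / (2.0 * sigma ** 2)))


def kernel_approx_error(params: RFFParams, pairs) -> float:
    """Worst-case |phi_hat(x).phi_hat(x') - kappa(x - x')| over the given pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    worst = 0.0
    for x, x2 in pairs:
        approx = float(rff_map(x, params) @ rff_map(x2, params))
        worst = max(worst, abs(approx - gaussian_kernel(x, x2, params.sigma)))
    return worst


def median_heuristic_sigma(X: np.ndarray, max_points: int = 500,
                           seed: int = 0) -> float:
    """Median pairwise Euclidean distance of the rows of X (the median heuristic).

    Subsamples to ``max_points`` rows for large inputs. Falls back to 1.0 when
    the median distance is zero (e.g. constant features).
    """
    X = np.asarray(X, dtype=np.float64).reshape(len(X), -1)
    if len(X) > max_points:
        idx = np.random.default_rng(seed).choice(len(X), max_points, replace=False)
        X = X[idx]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    med = float(np.sqrt(np.median(d2[np.triu_indices(len(X), k=1)])))
    return med if med > 0 else 1.0


class GaussianRFF(TransformerMixin, BaseEstimator):
    """scikit-learn transformer exposing the RFF map for flat feature matrices.

    Parameters
    ----------
    n_components : number of random features Q.
    sigma : Gaussian-kernel bandwidth; "median" applies the median heuristic
        to the training rows at fit time.
    random_state : seed for the spectral sample.
    """

    def __init__(self, n_components: int = 100, sigma="median",
                 random_state: int = 0):
        self.n_components = n_components
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        sigma = (median_heuristic_sigma(X, seed=self.random_state)
                 if isinstance(self.sigma, str) else float(self.sigma))
        self.sigma_ = sigma
        self.rff_params_ = sample_rff_params(
            X.shape[1], self.n_components, sigma, self.random_state)
        return self

    def transform(self, X):
        check_is_fitted(self, "rff_params_")
        X = np.asarray(X, dtype=np.float64)
        p = self.rff_params_
        z = X @ p.omega.T + p.b
        return np.sqrt(2.0 / p.Q) * np.cos(z)
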