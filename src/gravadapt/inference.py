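"""Likelihood, posterior-weight, and MAP machinery of the particle filter.

Each gravity hypothesis produces a reduced sensory-conflict (innovation)
vector ``e = [||e_a||, ||e_f||, ||e_omega||]``.  The Normalized Innovation
Squared statistic ``eps = e' S^-1 e`` (S the scaled biological noise
covariance) scores how surprising the current measurements are under that
hypothesis, and the measurement likelihood is the zero-mean Gaussian density
``N(e; 0, S)``.  Posterior particle weights follow by Bayes' rule; with
bootstrap resampling at every step the weights reduce to normalized
likelihoods.  The central gravity estimate is the maximum a posteriori value
on the discrete hypothesis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "NoiseCovariance",
    "GravityGrid",
    "ParticleSet",
    "nis",
    "log_likelihood",
    "likelihood",
    "reweight",
    "posterior_on_grid",
    "map_estimate",
]


@dataclass
class NoiseCovariance:
    """Symmetric positive-definite scaled biological noise covariance.

    The default is diagonal with standard deviations (0.02 g, 0.1, 0.05
    rad/s) for the acceleration, GIF-direction, and angular-velocity conflict
    norms.  These are modeling constants that set how sharply likelihood
    falls off with conflict (and hence the adaptation rate); they are not
    fitted to data.
    """

    S: np.ndarray = field(
        default_factory=lambda: np.diag([0.02**2, 0.1**2, 0.05**2])
    )

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (3, 3):
            raise ValueError("S must be 3x3")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("S must be symmetric")
        try:
            self._chol = linalg.cholesky(self.S, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("S must be positive definite") from exc
        self._inv = linalg.cho_solve((self._chol, True), np.eye(3))
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def n(self) -> int:
        return 3

    @property
    def inv(self) -> np.ndarray:
        return self._inv

    @property
    def log_norm_const(self) -> float:
        """log of (2*pi)^(-n/2) |S|^(-1/2)."""
        return -0.5 * (self.n * np.log(2.0 * np.pi) + self._logdet)

    @property
    def max_density(self) -> float:
        """Density of a zero-conflict measurement (the likelihood ceiling)."""
        return float(np.exp(self.log_norm_const))


def nis(reduced: np.ndarray, S: NoiseCovariance) -> np.ndarray | float:
    """Normalized Innovation Squared ``e' S^-1 e`` (vectorized over leading
    axes)."""
    e = np.asarray(reduced, dtype=float)
    out = np.einsum("...i,ij,...j->...", e, S.inv, e)
    return float(out) if out.ndim == 0 else out


def log_likelihood(reduced: np.ndarray, S: NoiseCovariance) -> np.ndarray | float:
    """Log of the Gaussian measurement likelihood N(e; 0, S)."""
    return S.log_norm_const - 0.5 * nis(reduced, S)


def likelihood(reduced: np.ndarray, S: NoiseCovariance) -> np.ndarray | float:
    """Gaussian measurement likelihood; underflows to 0 for extreme conflict
    (the engine works in log space where ratios matter)."""
    return np.exp(log_likelihood(reduced, S))


@dataclass
class GravityGrid:
    """Uniform discrete grid of gravity-magnitude hypotheses (g units)."""

    g_min: float = 0.05
    g_max: float = 5.00
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.g_min < 0 or self.step <= 0 or self.g_max <= self.g_min:
            raise ValueError("invalid grid bounds")
        n = (self.g_max - self.g_min) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(g_max - g_min) must be an integer multiple of step")
        self._n = int(round(n)) + 1

    @property
    def n_bins(self) -> int:
        return self._n

    @property
    def values(self) -> np.ndarray:
        return self.g_min + self.step * np.arange(self._n)

    def index_of(self, x: np.ndarray | float, strict: bool = True) -> np.ndarray | int:
        """Bin index of grid-aligned values; ``strict`` rejects off-grid."""
        xa = np.asarray(x, dtype=float)
        idx_f = (xa - self.g_min) / self.step
        idx = np.rint(idx_f).astype(int)
        if strict and np.any(np.abs(idx_f - idx) > 1e-6):
            raise ValueError("value is not grid-aligned")
        if np.any(idx < 0) or np.any(idx >= self._n):
            raise ValueError("value outside grid bounds")
        return int(idx) if np.isscalar(x) else idx

    def snap(self, x: float) -> float:
        """Nearest grid value (clipped to the bounds)."""
        i = int(np.clip(np.rint((x - self.g_min) / self.step), 0, self._n - 1))
        return float(self.g_min + i * self.step)


@dataclass
class ParticleSet:
    """Gravity-magnitude hypotheses with posterior weights and likelihoods."""

    x: np.ndarray
    w: np.ndarray
    lik: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.x.shape != self.w.shape or self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("x and w must be matching 1-D arrays")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def n(self) -> int:
        return self.x.size


def reweight(ps: ParticleSet, liks: np.ndarray) -> ParticleSet:
    """Posterior weights proportional to likelihoods (bootstrap-resampled
    prior is uniform).  Raises on an all-zero likelihood vector rather than
    silently uniformizing -- the engine's log-space path prevents that case.
    """
    liks = np.asarray(liks, dtype=float)
    if liks.shape != ps.x.shape:
        raise ValueError("likelihood vector length mismatch")
    if np.any(liks < 0):
        raise ValueError("likelihoods must be nonnegative")
    total = liks.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero likelihoods")
    return ParticleSet(x=ps.x.copy(), w=liks / total, lik=liks.copy())


def posterior_on_grid(ps: ParticleSet, grid: GravityGrid) -> np.ndarray:
    """Accumulate particle weights into grid bins (all particles must be
    grid-aligned)."""
    idx = grid.index_of(ps.x)
    post = np.zeros(grid.n_bins)
    np.add.at(post, idx, ps.w)
    return post


def map_estimate(posterior: np.ndarray, grid: GravityGrid) -> float:
    """Grid value of the maximal posterior bin; exact ties resolve to the
    lowest gravity value (np.argmax returns the first maximal index)."""
    post = np.asarray(posterior, dtype=float)
    if post.shape != (grid.n_bins,):
        raise ValueError("posterior length must match the grid")
    if not np.any(post > 0):
        raise ValueError("all-zero posterior has no MAP")
    return float(grid.values[int(np.argmax(post))])
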