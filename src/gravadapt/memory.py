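"""Short- and long-term memory components of the particle transition kernel.

Short-term memory (STM) is an exploration/exploitation "jitter" search: new
hypotheses are drawn from a Gaussian centered on each parent, whose standard
deviation sigma_jitter grows as an inverse power of the history of maximum
likelihood (HML), an exponentially forgotten average of the best per-step
hypothesis likelihood.  Sustained high likelihood (certainty) shrinks the
search; a buildup of sensory conflict widens it.

Long-term memory (LTM) retains "harmonious" central estimates -- those whose
central NIS fell below a threshold nu -- inside a sliding window T_wind, and
re-proposes them as grid point masses weighted by the fraction of the window
spent harmonious.  STM and LTM mix with a sigmoid weight W(sigma_jitter), so
memory of learned gravity levels is consulted exactly when the model is
exploring.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import math

import numpy as np

from .inference import GravityGrid

__all__ = [
    "StmState",
    "LtmState",
    "TransitionModel",
    "update_hml",
    "jitter_sigma",
    "stm_density",
    "update_harmonious",
    "ltm_density",
    "mixture_weight",
    "transition_density",
    "sample_transitions",
]


@dataclass
class StmState:
    """Jitter-search state: HML and the current search width.

    ``sigma = clip(c_jitter / HML**chi1, sigma_min, sigma_max)``; chi1 sets
    how aggressively the search widens when likelihood drops, c_jitter fixes
    the proportionality (in density**chi1 * g units), and the clip bounds
    keep the kernel from degenerating to zero width or spanning the grid
    many times over.
    """

    hml: float
    f: float = 1.0
    chi1: float = 1.0
    c_jitter: float = 3.0
    sigma_min: float = 0.005
    sigma_max: float = 1.0
    sigma: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("forgetting factor must be in [0, 1]")
        if self.hml < 0:
            raise ValueError("HML must be nonnegative")
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError("need 0 < sigma_min <= sigma_max")


def update_hml(stm: StmState, liks: np.ndarray) -> None:
    """Exponentially weighted average of the per-step maximum likelihood:
    ``HML_k = (1 - 1/(1+f)) HML_{k-1} + 1/(1+f) max(liks)``."""
    liks = np.asarray(liks, dtype=float)
    if liks.size == 0:
        raise ValueError("need at least one likelihood")
    a = 1.0 / (1.0 + stm.f)
    stm.hml = (1.0 - a) * stm.hml + a * float(liks.max())


def jitter_sigma(stm: StmState) -> float:
    """Refresh sigma from HML by the clipped inverse power law; a vanished
    HML maps to the maximal (fully exploratory) width."""
    if stm.hml <= 0.0:
        stm.sigma = stm.sigma_max
    else:
        stm.sigma = float(
            np.clip(stm.c_jitter / stm.hml**stm.chi1, stm.sigma_min, stm.sigma_max)
        )
    return stm.sigma


def stm_density(parent_x: float, sigma: float, grid: GravityGrid) -> np.ndarray:
    """Gaussian jitter kernel centered on the parent, discretized on the grid
    and renormalized to unit mass."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (grid.values - parent_x) / sigma
    dens = np.exp(-0.5 * z * z)
    total = dens.sum()
    if total <= 0:  # parent absurdly far off-grid
        raise ValueError("jitter kernel has no mass on the grid")
    return dens / total


@dataclass
class LtmState:
    """Time-stamped buffer of harmonious central estimates.

    Entries older than ``t_wind`` are pruned, so learned states age out when
    the model spends long enough away from them.  ``n_wind = t_wind / dk``
    (the number of filter steps spanning the window) normalizes the density,
    making its total mass the harmonious fraction of the window.
    """

    nu: float = 2.0 * math.log(2.0)
    t_wind: float = 400.0
    dk: float = 0.5
    entries: deque = field(default_factory=deque)  # (timestamp, estimate)

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.t_wind <= 0 or self.dk <= 0:
            raise ValueError("nu, t_wind and dk must be positive")
        n = self.t_wind / self.dk
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_wind must be an integer multiple of dk")
        self._n_wind = int(round(n))

    @property
    def n_wind(self) -> int:
        return self._n_wind


def update_harmonious(
    ltm: LtmState, central_estimate: float, central_nis: float, t_now: float
) -> None:
    """Store the central estimate if its NIS is beneath the harmony threshold,
    then prune entries that have aged out of the window."""
    if ltm.entries and t_now < ltm.entries[-1][0]:
        raise ValueError("timestamps must be nondecreasing")
    if central_nis < ltm.nu:
        ltm.entries.append((t_now, central_estimate))
    cutoff = t_now - ltm.t_wind
    while ltm.entries and ltm.entries[0][0] < cutoff:
        ltm.entries.popleft()


def ltm_density(ltm: LtmState, grid: GravityGrid) -> np.ndarray:
    """Window-normalized point masses at learned grid values; total mass is
    the fraction of the window spent harmonious (<= 1), zero when nothing is
    remembered."""
    if not ltm.entries:
        return np.zeros(grid.n_bins)
    hs = np.fromiter((h for _, h in ltm.entries), dtype=float, count=len(ltm.entries))
    idx = np.clip(
        np.rint((hs - grid.g_min) / grid.step).astype(int), 0, grid.n_bins - 1
    )
    return np.bincount(idx, minlength=grid.n_bins) / ltm.n_wind


@dataclass
class TransitionModel:
    """Mixture weight model: W = sigmoid(sigma * chi2) - 1/2, in [0, 1/2)."""

    chi2: float = 4.0
    W: float = 0.0


def mixture_weight(sigma: float, chi2: float) -> float:
    """Prioritization of long- over short-term memory as a logistic function
    of the jitter width: 0 when fully exploitative, approaching 1/2 under
    maximal exploration."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    w = 1.0 / (1.0 + np.exp(-sigma * chi2)) - 0.5
    # the sigmoid saturates in floats; keep the supremum strict
    return float(min(w, np.nextafter(0.5, 0.0)))


def _mix(p_stm: np.ndarray, p_ltm: np.ndarray | None, W: float) -> np.ndarray:
    p = (1.0 - W) * p_stm
    if p_ltm is not None and W > 0:
        p = p + W * p_ltm
    total = p.sum()
    if total <= 0:
        raise ValueError("transition density has no mass")
    return p / total


def transition_density(
    parent_x: float, stm: StmState, ltm: LtmState, tm: TransitionModel, grid: GravityGrid
) -> np.ndarray:
    """Normalized mixture ``(1-W) p_STM + W p_LTM`` on the grid.  With an
    empty LTM the renormalization makes this exactly the STM kernel."""
    return _mix(stm_density(parent_x, stm.sigma, grid), ltm_density(ltm, grid), tm.W)


def sample_transitions(
    parent_x: np.ndarray,
    stm: StmState,
    ltm: LtmState,
    tm: TransitionModel,
    grid: GravityGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one grid-aligned child per parent from its transition density.

    Parents sharing a grid bin share a density, so sampling is grouped by
    unique parent value; the draw order (and hence the RNG stream) is fixed
    by the sorted unique values for determinism.
    """
    parent_x = np.asarray(parent_x, dtype=float)
    children = np.empty_like(parent_x)
    values = grid.values
    p_ltm = ltm_density(ltm, grid) if (tm.W > 0 and ltm.entries) else None
    uniq, inv = np.unique(parent_x, return_inverse=True)
    for u_idx, px in enumerate(uniq):
        mask = inv == u_idx
        dens = _mix(stm_density(float(px), stm.sigma, grid), p_ltm, tm.W)
        cdf = np.cumsum(dens)
        cdf[-1] = 1.0
        draws = np.searchsorted(cdf, rng.random(int(mask.sum())), side="right")
        children[mask] = values[np.minimum(draws, values.size - 1)]
    return children
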