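"""The Rao-Blackwellized particle filter over gravity-magnitude hypotheses.

Per filter step (every ``dk`` model seconds) the engine

1. advances a lockstep bank of conditioned observers -- one per grid value --
   on the shared (noisy) afference and reads each hypothesis' sensory
   conflict, averaged over the interval;
2. scores every hypothesis with the Gaussian conflict likelihood (log space),
   reweights the particles, and takes the MAP gravity estimate;
3. adopts the bank observer at the MAP value as the "central observer",
   recording its NIS and perception (the model's current percept);
4. updates the memory machinery: HML -> sigma_jitter -> mixture weight W,
   and, when enabled, the long-term memory of harmonious states;
5. bootstrap-resamples the particles from the posterior and draws their next
   positions from the STM/LTM mixture transition kernel.

Three named RNG streams (noise, resample, transition) derive from one master
seed so that toggling the LTM or the resampling scheme leaves the sensory
noise realization untouched -- the basis for paired-seed comparisons.

``brute_force_reference`` runs the same model as an exhaustive discrete Bayes
filter (no sampling) for use as a correctness oracle on small grids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import math

import numpy as np

from .inference import GravityGrid, NoiseCovariance, map_estimate, nis
from .memory import (
    LtmState,
    StmState,
    TransitionModel,
    jitter_sigma,
    ltm_density,
    mixture_weight,
    sample_transitions,
    stm_density,
    transition_density,
    update_harmonious,
    update_hml,
)
from .observer import (
    AfferentSignals,
    HeadMotion,
    ObserverParams,
    TruthTrajectory,
    add_sensory_noise,
    advance_bank,
    init_bank_state,
    integrate_head_kinematics,
    simulate_afference,
)

logger = logging.getLogger(__name__)

__all__ = ["EngineConfig", "SimulationResult", "Engine", "run_simulation", "brute_force_reference"]


@dataclass
class EngineConfig:
    """Everything that parameterizes one filter run (the scenario's motion is
    supplied separately).  ``dk`` must be an integer multiple of the observer
    integration step."""

    n_particles: int = 100
    grid: GravityGrid = field(default_factory=GravityGrid)
    observer: ObserverParams = field(default_factory=ObserverParams)
    noise_cov: NoiseCovariance = field(default_factory=NoiseCovariance)
    noise_power: float = 1e-8
    dk: float = 0.5
    ltm_enabled: bool = True
    f_forget: float = 1.0
    chi1: float = 1.0
    c_jitter: float = 3.0
    sigma_min: float = 0.005
    sigma_max: float = 1.0
    nu: float = 2.0 * math.log(2.0)
    t_wind: float = 400.0
    chi2: float = 4.0
    resample: str = "multinomial"
    seed: int = 0
    store_particles: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        ratio = self.dk / self.observer.dt_sim
        if self.dk < self.observer.dt_sim or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dk must be an integer multiple of dt_sim")
        if self.resample not in ("multinomial", "systematic"):
            raise ValueError("resample must be 'multinomial' or 'systematic'")

    @property
    def substeps(self) -> int:
        return int(round(self.dk / self.observer.dt_sim))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_cov"] = self.noise_cov.S.tolist()
        return d


@dataclass
class SimulationResult:
    """Per-step filter records plus the per-substep central perception."""

    t_step: np.ndarray          # (K,) time at each interval end
    map_g: np.ndarray           # (K,) MAP gravity estimate
    central_nis: np.ndarray     # (K,)
    hml: np.ndarray             # (K,)
    sigma: np.ndarray           # (K,)
    W: np.ndarray               # (K,)
    max_lik: np.ndarray         # (K,) max particle likelihood (density units)
    posterior: np.ndarray       # (K, n_bins)
    ltm_mass: np.ndarray        # (K, n_bins)
    t_sim: np.ndarray           # (N,) substep time grid
    central_roll: np.ndarray    # (N,) perceived roll of the central observer, rad
    actual_roll: np.ndarray     # (N,) true roll, rad
    g_true_step: np.ndarray     # (K,) true gravity at each interval end
    particle_x: Optional[np.ndarray] = None  # (K, N_s) if stored
    metadata: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.t_step.size

    def steps_to_adapt(self, t_transition: float, target: float, tol: float = 0.05) -> int:
        """Number of filter steps after the transition until the MAP estimate
        first enters ``target +- tol``; the record count if it never does."""
        mask = self.t_step > t_transition + 1e-9
        idx = np.nonzero(mask)[0]
        within = np.abs(self.map_g[idx] - target) <= tol
        hits = np.nonzero(within)[0]
        return int(hits[0]) + 1 if hits.size else int(idx.size)


class Engine:
    """Stateful filter over a fixed motion scenario; use :func:`run_simulation`
    for the one-shot interface."""

    def __init__(self, config: EngineConfig, motion: HeadMotion):
        if abs(motion.dt - config.observer.dt_sim) > 1e-12:
            raise ValueError("motion grid must match observer dt_sim")
        self.config = config
        self.motion = motion
        self.truth: TruthTrajectory = integrate_head_kinematics(motion)
        ss = np.random.SeedSequence(config.seed)
        s_noise, s_resample, s_transition = ss.spawn(3)
        self._rng_resample = np.random.default_rng(s_resample)
        self._rng_transition = np.random.default_rng(s_transition)
        clean = simulate_afference(self.truth, config.observer)
        self.afference: AfferentSignals = add_sensory_noise(
            clean, config.noise_power, config.observer.dt_sim, np.random.default_rng(s_noise)
        )

        grid = config.grid
        self.grid_values = grid.values
        self.bank = init_bank_state(self.grid_values)

        g0 = float(motion.g_true[0])
        snapped = grid.snap(g0)
        if abs(snapped - g0) > 1e-9:
            warnings.warn(f"initial gravity {g0} is off-grid; snapped to {snapped}")
        self._init_bin = grid.index_of(snapped, strict=False)
        self.particle_bins = np.full(config.n_particles, self._init_bin, dtype=int)

        # start in exploitation: HML at the likelihood of a zero-conflict
        # measurement, its ceiling
        self.stm = StmState(
            hml=config.noise_cov.max_density,
            f=config.f_forget,
            chi1=config.chi1,
            c_jitter=config.c_jitter,
            sigma_min=config.sigma_min,
            sigma_max=config.sigma_max,
        )
        jitter_sigma(self.stm)
        self.ltm = LtmState(nu=config.nu, t_wind=config.t_wind, dk=config.dk)
        self.tm = TransitionModel(chi2=config.chi2, W=mixture_weight(self.stm.sigma, config.chi2))
        self.central_bin = self._init_bin
        self.k = 0
        self.n_filter_steps = motion.n_steps // config.substeps
        self._alloc_records()

    def _alloc_records(self) -> None:
        k, nb = self.n_filter_steps, self.config.grid.n_bins
        n = self.n_filter_steps * self.config.substeps
        self._rec = {
            name: np.zeros(k)
            for name in ("t_step", "map_g", "central_nis", "hml", "sigma", "W", "max_lik", "g_true_step")
        }
        self._rec["posterior"] = np.zeros((k, nb))
        self._rec["ltm_mass"] = np.zeros((k, nb))
        self._central_roll = np.zeros(n)
        store = self.config.store_particles and self.config.n_particles <= 1000
        self._particle_x = np.zeros((k, self.config.n_particles)) if store else None

    def filter_step(self) -> dict:
        """Advance one filter interval; returns the step record as a dict."""
        cfg = self.config
        k = self.k
        if k >= self.n_filter_steps:
            raise RuntimeError("scenario exhausted")
        sub = cfg.substeps
        sl = slice(k * sub, (k + 1) * sub)

        mean_red, _, rolls = advance_bank(
            self.bank, self.afference, sl, self.grid_values, cfg.observer, roll_probe=self.central_bin
        )
        self._central_roll[sl] = rolls

        log_lik = cfg.noise_cov.log_norm_const - 0.5 * nis(mean_red, cfg.noise_cov)
        lik = np.exp(log_lik)  # density scale; may underflow far from truth

        # posterior over bins: counts (bootstrap prior) times likelihood,
        # normalized in log space
        counts = np.bincount(self.particle_bins, minlength=cfg.grid.n_bins)
        occupied = counts > 0
        shift = log_lik[occupied].max()
        post = np.zeros(cfg.grid.n_bins)
        post[occupied] = counts[occupied] * np.exp(log_lik[occupied] - shift)
        total = post.sum()
        if total <= 0:
            raise RuntimeError("degenerate posterior after log-space handling")
        post /= total

        map_g = map_estimate(post, cfg.grid)
        map_bin = cfg.grid.index_of(map_g)
        central_nis = float(nis(mean_red[map_bin], cfg.noise_cov))

        particle_liks = lik[self.particle_bins]
        update_hml(self.stm, particle_liks)
        jitter_sigma(self.stm)
        self.tm.W = mixture_weight(self.stm.sigma, cfg.chi2)

        t_now = float(self.afference.t[sl.stop - 1])
        if cfg.ltm_enabled:
            update_harmonious(self.ltm, map_g, central_nis, t_now)

        # bootstrap resample, then propose the next generation
        if cfg.resample == "multinomial":
            parent_counts = self._rng_resample.multinomial(cfg.n_particles, post)
        else:
            u = (self._rng_resample.random() + np.arange(cfg.n_particles)) / cfg.n_particles
            parent_counts = np.bincount(
                np.searchsorted(np.cumsum(post), u, side="right"), minlength=cfg.grid.n_bins
            )
        parent_x = np.repeat(self.grid_values, parent_counts)
        children = sample_transitions(
            parent_x, self.stm, self.ltm, self.tm, cfg.grid, self._rng_transition
        )
        self.particle_bins = cfg.grid.index_of(children)
        self.central_bin = map_bin

        rec = self._rec
        rec["t_step"][k] = t_now
        rec["map_g"][k] = map_g
        rec["central_nis"][k] = central_nis
        rec["hml"][k] = self.stm.hml
        rec["sigma"][k] = self.stm.sigma
        rec["W"][k] = self.tm.W
        rec["max_lik"][k] = float(particle_liks.max())
        rec["g_true_step"][k] = float(self.motion.g_true[sl.stop - 1])
        rec["posterior"][k] = post
        rec["ltm_mass"][k] = ltm_density(self.ltm, cfg.grid)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "k=%d t=%.2f map=%.2f nis=%.3g hml=%.3g sigma=%.4f W=%.4f",
                k, t_now, map_g, central_nis, self.stm.hml, self.stm.sigma, self.tm.W,
            )
        if self._particle_x is not None:
            self._particle_x[k] = children
        self.k += 1
        return {name: rec[name][k] for name in ("t_step", "map_g", "central_nis", "sigma", "W")}

    def run(self) -> SimulationResult:
        while self.k < self.n_filter_steps:
            self.filter_step()
        n = self.n_filter_steps * self.config.substeps
        return SimulationResult(
            t_step=self._rec["t_step"],
            map_g=self._rec["map_g"],
            central_nis=self._rec["central_nis"],
            hml=self._rec["hml"],
            sigma=self._rec["sigma"],
            W=self._rec["W"],
            max_lik=self._rec["max_lik"],
            posterior=self._rec["posterior"],
            ltm_mass=self._rec["ltm_mass"],
            t_sim=self.afference.t[:n].copy(),
            central_roll=self._central_roll,
            actual_roll=self.truth.roll[:n].copy(),
            g_true_step=self._rec["g_true_step"],
            particle_x=self._particle_x,
            metadata={"config": self.config.to_dict()},
        )


def run_simulation(motion: HeadMotion, config: EngineConfig) -> SimulationResult:
    """Integrate, sense, and filter a full scenario; bit-reproducible from
    (motion, config) including the seed."""
    return Engine(config, motion).run()


def brute_force_reference(motion: HeadMotion, config: EngineConfig) -> SimulationResult:
    """Exhaustive discrete Bayes filter: the exact N_s -> infinity limit of
    the particle filter, propagating the full grid distribution through the
    transition kernel and likelihoods with no sampling.

    Requires a small grid (<= 50 bins) and noise off, so the comparison with
    the particle filter isolates Monte-Carlo error.
    """
    if config.grid.n_bins > 50:
        raise ValueError("oracle is restricted to grids of <= 50 bins")
    if config.noise_power != 0:
        raise ValueError("oracle requires noise off")
    cfg = config
    truth = integrate_head_kinematics(motion)
    afference = simulate_afference(truth, cfg.observer)
    grid_values = cfg.grid.values
    bank = init_bank_state(grid_values)

    stm = StmState(
        hml=cfg.noise_cov.max_density,
        f=cfg.f_forget,
        chi1=cfg.chi1,
        c_jitter=cfg.c_jitter,
        sigma_min=cfg.sigma_min,
        sigma_max=cfg.sigma_max,
    )
    jitter_sigma(stm)
    ltm = LtmState(nu=cfg.nu, t_wind=cfg.t_wind, dk=cfg.dk)
    tm = TransitionModel(chi2=cfg.chi2, W=mixture_weight(stm.sigma, cfg.chi2))

    g0 = cfg.grid.snap(float(motion.g_true[0]))
    prior = np.zeros(cfg.grid.n_bins)
    prior[cfg.grid.index_of(g0, strict=False)] = 1.0

    sub = cfg.substeps
    n_steps = motion.n_steps // sub
    rec = {
        name: np.zeros(n_steps)
        for name in ("t_step", "map_g", "central_nis", "hml", "sigma", "W", "max_lik", "g_true_step")
    }
    posterior = np.zeros((n_steps, cfg.grid.n_bins))
    ltm_mass = np.zeros((n_steps, cfg.grid.n_bins))

    for k in range(n_steps):
        sl = slice(k * sub, (k + 1) * sub)
        mean_red, _, _ = advance_bank(bank, afference, sl, grid_values, cfg.observer)
        log_lik = cfg.noise_cov.log_norm_const - 0.5 * nis(mean_red, cfg.noise_cov)
        lik = np.exp(log_lik)

        support = prior > 0
        shift = log_lik[support].max()
        post = np.zeros_like(prior)
        post[support] = prior[support] * np.exp(log_lik[support] - shift)
        post /= post.sum()

        map_g = map_estimate(post, cfg.grid)
        map_bin = cfg.grid.index_of(map_g)
        central_nis = float(nis(mean_red[map_bin], cfg.noise_cov))

        # the HML recursion maximizes over the *hypothesis set*; for the
        # exact filter that is every bin a particle set of the configured
        # size would be expected to populate (predicted mass >= 1/N_s)
        hyp_set = prior >= min(1.0 / cfg.n_particles, prior[support].max())
        update_hml(stm, lik[hyp_set])
        jitter_sigma(stm)
        tm.W = mixture_weight(stm.sigma, cfg.chi2)
        t_now = float(afference.t[sl.stop - 1])
        if cfg.ltm_enabled:
            update_harmonious(ltm, map_g, central_nis, t_now)

        # exact prediction: mix every parent bin's transition kernel
        nxt = np.zeros_like(prior)
        for i in np.nonzero(post > 1e-14)[0]:
            nxt += post[i] * transition_density(float(grid_values[i]), stm, ltm, tm, cfg.grid)
        prior = nxt / nxt.sum()

        rec["t_step"][k] = t_now
        rec["map_g"][k] = map_g
        rec["central_nis"][k] = central_nis
        rec["hml"][k] = stm.hml
        rec["sigma"][k] = stm.sigma
        rec["W"][k] = tm.W
        rec["max_lik"][k] = float(lik[support].max())
        rec["g_true_step"][k] = float(motion.g_true[sl.stop - 1])
        posterior[k] = post
        ltm_mass[k] = ltm_density(ltm, cfg.grid)

    n = n_steps * sub
    return SimulationResult(
        t_step=rec["t_step"],
        map_g=rec["map_g"],
        central_nis=rec["central_nis"],
        hml=rec["hml"],
        sigma=rec["sigma"],
        W=rec["W"],
        max_lik=rec["max_lik"],
        posterior=posterior,
        ltm_mass=ltm_mass,
        t_sim=afference.t[:n].copy(),
        central_roll=np.zeros(n),
        actual_roll=truth.roll[:n].copy(),
        g_true_step=rec["g_true_step"],
        metadata={"config": cfg.to_dict(), "oracle": True},
    )
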