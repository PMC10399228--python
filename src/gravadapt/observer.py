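"""Vestibular truth dynamics, sensor models, and the conditioned observer.

This module simulates the physical stimulus (head kinematics and gravity),
generates canal/otolith afference from it, and runs an internal-model
("observer") estimator of orientation perception that is *conditioned on a
hypothesized gravity magnitude*.  The observer compares actual afference with
the afference its internal models expect and feeds the disparities -- the
sensory conflicts ``e_a`` (linear acceleration), ``e_f`` (gravito-inertial
force direction), and ``e_omega`` (angular velocity) -- back into its state
estimates.  A bank of such observers, one per gravity hypothesis, is the
analytic ("Rao-Blackwellized") half of the adaptation model.

Coordinate conventions
----------------------
Head frame: x forward, y left, z up.  World: z up, gravity points down.
``g_hat`` and the truth trajectory store the *upward* gravito-reaction vector
(the direction the otoliths report when stationary), so a stationary upright
head at 1 g senses specific force ``(0, 0, 1)`` g.  Positive roll tilts the
up-vector toward +y: ``g_up = (0, sin(phi), cos(phi)) * g``, and perceived
roll is recovered as ``atan2(g_hat_y, g_hat_z)``.

All observer state arrays carry a leading bank dimension ``(M, 3)`` so a full
hypothesis grid advances in lockstep with numpy; ``M = 1`` recovers the
single-observer case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "HeadMotion",
    "TruthTrajectory",
    "AfferentSignals",
    "ObserverParams",
    "PerceptionState",
    "ConflictVector",
    "integrate_head_kinematics",
    "simulate_afference",
    "add_sensory_noise",
    "observer_step",
    "advance_bank",
    "init_bank_state",
    "extract_tilt_perception",
]

_EPS_NORM = 1e-9


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (faster than np.cross for small M)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


# ---------------------------------------------------------------------------
# stimulus and truth
# ---------------------------------------------------------------------------


@dataclass
class HeadMotion:
    """A time history of head angular velocity, inertial acceleration and
    true gravity magnitude on a uniform time grid.

    Attributes
    ----------
    t : (N,) array, model seconds, uniform spacing ``dt``.
    omega : (N, 3) array, head-frame angular velocity, rad/s.
    accel : (N, 3) array, head-frame inertial linear acceleration, g units.
    g_true : (N,) array, true gravity magnitude, g units (piecewise constant).
    q0 : (4,) unit quaternion (scalar-last), head-to-world at t[0].
    """

    t: np.ndarray
    omega: np.ndarray
    accel: np.ndarray
    g_true: np.ndarray
    q0: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.g_true = np.asarray(self.g_true, dtype=float)
        self.q0 = np.asarray(self.q0, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("need at least two time samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * max(steps[0], 1.0)):
            raise ValueError("time grid must be uniform")
        if steps[0] <= 0:
            raise ValueError("dt must be positive")
        for name in ("omega", "accel"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape (N, 3)")
        if self.g_true.shape != (n,):
            raise ValueError("g_true must have shape (N,)")
        if np.any(self.g_true < 0):
            raise ValueError("g_true must be nonnegative")
        for name in ("t", "omega", "accel", "g_true", "q0"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        if abs(np.linalg.norm(self.q0) - 1.0) > 1e-9:
            raise ValueError("q0 must be a unit quaternion")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_steps(self) -> int:
        return int(self.t.size)


@dataclass
class TruthTrajectory:
    """Integrated ground truth: orientation, gravity in head frame, specific
    force.  ``g_up_head`` is the upward reaction vector (magnitude g_true)."""

    t: np.ndarray
    quat: np.ndarray          # (N, 4) head-to-world, scalar-last
    omega: np.ndarray         # (N, 3) copy of the stimulus
    g_up_head: np.ndarray     # (N, 3)
    specific_force: np.ndarray  # (N, 3) = accel + g_up_head
    roll: np.ndarray          # (N,) actual roll angle, rad
    dt: float


def _quat_mul(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-last quaternions (compose rotations r∘q)."""
    x1, y1, z1, w1 = q
    x2, y2, z2, w2 = r
    return np.array(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ]
    )


def integrate_head_kinematics(motion: HeadMotion) -> TruthTrajectory:
    """Integrate orientation from angular velocity and resolve gravity and
    specific force into the head frame.

    The quaternion is advanced by the body-frame rotation increment
    ``omega[k] * dt`` each step and renormalized; gravity in the head frame is
    the world up-vector rotated into the head frame and scaled by ``g_true``.
    """
    dt = motion.dt
    n = motion.n_steps
    # per-step increments as quaternions (scalar-last)
    dq = Rotation.from_rotvec(motion.omega * dt).as_quat()
    quats = np.empty((n, 4))
    q = motion.q0.copy()
    quats[0] = q
    for k in range(1, n):
        # body-frame increment: q_{k} = q_{k-1} ∘ dq_{k-1}
        q = _quat_mul(dq[k - 1], q)
        q /= np.linalg.norm(q)
        quats[k] = q
    rot = Rotation.from_quat(quats)
    up_world = np.zeros((n, 3))
    up_world[:, 2] = motion.g_true
    g_up_head = rot.inv().apply(up_world)
    f = motion.accel + g_up_head
    roll = np.arctan2(g_up_head[:, 1], g_up_head[:, 2])
    return TruthTrajectory(
        t=motion.t.copy(),
        quat=quats,
        omega=motion.omega.copy(),
        g_up_head=g_up_head,
        specific_force=f,
        roll=roll,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------


@dataclass
class ObserverParams:
    """Gains, time constants and weights of the conditioned observer.

    The four feedback gains follow the classic observer-model literature
    (k_omega = 8, k_f = 4, k_fomega = 8, k_a = 4 as positive corrective
    gains); they are configurable defaults, not values fitted to data.
    ``oto_weights`` implements differential per-axis weighting of the otolith
    conflict components (x, y, z); the default doubles the interaural shear
    component, which is what lets an unadapted observer overestimate roll
    tilt in hypergravity (the G-excess pattern).  ``(1, 1, 1)`` recovers the
    unweighted observer.
    """

    k_omega: float = 8.0
    k_f: float = 4.0
    k_fomega: float = 8.0
    k_a: float = 4.0
    tau_canal: float = 5.7
    tau_a: float = 1.0
    oto_weights: tuple[float, float, float] = (1.0, 2.0, 1.0)
    dt_sim: float = 0.05

    def __post_init__(self) -> None:
        if self.tau_canal <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        if any(w < 0 for w in self.oto_weights):
            raise ValueError("oto_weights must be nonnegative")

    @property
    def canal_alpha(self) -> float:
        """One-step decay factor of the canal low-pass state."""
        return float(np.exp(-self.dt_sim / self.tau_canal))


@dataclass
class AfferentSignals:
    """Canal and otolith afference on the simulation grid."""

    t: np.ndarray
    canal: np.ndarray  # (N, 3) rad/s
    oto: np.ndarray    # (N, 3) g units (specific force)
    noisy: bool = False
    dt: float = 0.0

    def __post_init__(self) -> None:
        if self.canal.shape != self.oto.shape or self.canal.shape[0] != self.t.size:
            raise ValueError("afference arrays must share the motion time grid")
        if not (np.all(np.isfinite(self.canal)) and np.all(np.isfinite(self.oto))):
            raise ValueError("afference contains non-finite values")


def _highpass(x: np.ndarray, alpha: float) -> np.ndarray:
    """First-order high-pass tau*s/(tau*s + 1), exponential discretization.

    Realized as input minus a leaky average: ``lp[k] = alpha*lp[k-1] +
    (1-alpha)*x[k]``, output ``x - lp``; lp starts at zero.
    """
    lp = np.empty_like(x)
    acc = np.zeros(x.shape[-1])
    for k in range(x.shape[0]):
        acc = alpha * acc + (1.0 - alpha) * x[k]
        lp[k] = acc
    return x - lp


def canal_gain(freq_rad: float, tau: float) -> float:
    """Continuous-time canal transfer-function magnitude |jwt/(jwt+1)|."""
    wt = freq_rad * tau
    return wt / np.hypot(wt, 1.0)


def simulate_afference(truth: TruthTrajectory, params: ObserverParams) -> AfferentSignals:
    """Generate noise-free afference from the truth trajectory.

    Canals: per-axis first-order high-pass of angular velocity with time
    constant ``tau_canal``.  Otoliths: specific force, identity dynamics.
    """
    if params.dt_sim >= params.tau_canal / 2:
        raise ValueError("dt_sim too coarse for the canal time constant")
    if abs(params.dt_sim - truth.dt) > 1e-12:
        raise ValueError("params.dt_sim must match the motion grid")
    canal = _highpass(truth.omega, params.canal_alpha)
    return AfferentSignals(
        t=truth.t.copy(), canal=canal, oto=truth.specific_force.copy(), dt=truth.dt
    )


def add_sensory_noise(
    signals: AfferentSignals,
    noise_power: float,
    dt_sim: float,
    rng: np.random.Generator | int | None,
) -> AfferentSignals:
    """Add white sensory noise with power-spectral-density height
    ``noise_power``; per-sample variance is ``noise_power / dt_sim`` so the
    disturbance is dt-invariant in distribution."""
    if noise_power < 0:
        raise ValueError("noise_power must be nonnegative")
    if noise_power == 0:
        return replace(signals, canal=signals.canal.copy(), oto=signals.oto.copy())
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sd = np.sqrt(noise_power / dt_sim)
    canal = signals.canal + gen.normal(0.0, sd, signals.canal.shape)
    oto = signals.oto + gen.normal(0.0, sd, signals.oto.shape)
    return AfferentSignals(t=signals.t.copy(), canal=canal, oto=oto, noisy=True, dt=signals.dt)


# ---------------------------------------------------------------------------
# the conditioned observer
# ---------------------------------------------------------------------------


@dataclass
class PerceptionState:
    """Internal state of one or a bank of conditioned observers.

    All arrays are ``(M, 3)``; ``g_hat`` holds the perceived upward gravity
    vector whose magnitude is constrained to the conditioning hypothesis
    after every step.  ``canal_state`` is the leaky-average state of the
    internal canal model applied to ``omega_hat``.
    """

    g_hat: np.ndarray
    a_hat: np.ndarray
    omega_hat: np.ndarray
    canal_state: np.ndarray

    def copy(self) -> "PerceptionState":
        return PerceptionState(
            self.g_hat.copy(), self.a_hat.copy(), self.omega_hat.copy(), self.canal_state.copy()
        )


@dataclass
class ConflictVector:
    """Per-observer sensory conflict; ``reduced`` stacks the three norms
    ``[||e_a||, ||e_f||, ||e_omega||]`` (the innovation vector)."""

    e_a: np.ndarray
    e_f: np.ndarray
    e_omega: np.ndarray

    @property
    def reduced(self) -> np.ndarray:
        out = np.empty(self.e_a.shape[:-1] + (3,))
        out[..., 0] = np.sqrt(np.einsum("...i,...i->...", self.e_a, self.e_a))
        out[..., 1] = np.sqrt(np.einsum("...i,...i->...", self.e_f, self.e_f))
        out[..., 2] = np.sqrt(np.einsum("...i,...i->...", self.e_omega, self.e_omega))
        return out


def init_bank_state(x_hyp: np.ndarray) -> PerceptionState:
    """Stationary upright fixed point for each hypothesis: perceived gravity
    upright at the hypothesized magnitude, zero acceleration and rotation."""
    x = np.atleast_1d(np.asarray(x_hyp, dtype=float))
    m = x.size
    g = np.zeros((m, 3))
    g[:, 2] = x
    return PerceptionState(g, np.zeros((m, 3)), np.zeros((m, 3)), np.zeros((m, 3)))


def observer_step(
    state: PerceptionState,
    y_canal: np.ndarray,
    y_oto: np.ndarray,
    x_hyp: np.ndarray | float,
    params: ObserverParams,
) -> ConflictVector:
    """Advance the observer bank one integration step in place and return the
    conflicts that drove the update.

    Update laws (dt = params.dt_sim, w = oto_weights):

    * expected canal afference = internal canal model of ``omega_hat``;
      ``e_omega = y_canal - expected``.
    * expected specific force ``f_hat = a_hat + g_hat``;
      ``e_a = w * (y_oto - f_hat)``;
      ``e_f = w * (u_meas x u_exp)`` with the unit GIF directions (zero when
      either norm is degenerate).
    * ``omega_hat += dt * (k_omega * e_omega + k_fomega * e_f)``
    * ``g_hat`` rotated by ``dt * (-omega_hat - k_f * e_f)`` (the second term
      rotates the expected GIF toward the measured one), then rescaled to the
      hypothesis magnitude.
    * ``a_hat += dt * (k_a * e_a - a_hat / tau_a)``
    """
    x = np.atleast_1d(np.asarray(x_hyp, dtype=float))
    if np.any(x < 0):
        raise ValueError("gravity hypothesis must be nonnegative")
    dt = params.dt_sim
    w = np.asarray(params.oto_weights)

    # internal canal model (same discretization as the sensor)
    alpha = params.canal_alpha
    state.canal_state *= alpha
    state.canal_state += (1.0 - alpha) * state.omega_hat
    expected_canal = state.omega_hat - state.canal_state
    e_omega = y_canal - expected_canal

    f_hat = state.a_hat + state.g_hat
    e_a = w * (y_oto - f_hat)

    ny = float(np.sqrt(y_oto @ y_oto))
    nf = np.sqrt(np.einsum("ij,ij->i", f_hat, f_hat))[:, None]
    if ny < _EPS_NORM:
        e_f = np.zeros_like(f_hat)
    else:
        u_meas = y_oto / ny
        u_exp = f_hat / np.maximum(nf, _EPS_NORM)
        e_f = w * _cross(np.broadcast_to(u_meas, u_exp.shape), u_exp)
        e_f[nf[:, 0] <= _EPS_NORM] = 0.0

    state.omega_hat += dt * (params.k_omega * e_omega + params.k_fomega * e_f)

    # rotate g_hat: passive -omega_hat transport plus corrective -k_f * e_f
    theta = dt * (-state.omega_hat - params.k_f * e_f)
    state.g_hat += _cross(theta, state.g_hat)
    norm_g = np.sqrt(np.einsum("ij,ij->i", state.g_hat, state.g_hat))[:, None]
    state.g_hat *= np.where(norm_g > _EPS_NORM, x[:, None] / np.maximum(norm_g, _EPS_NORM), 0.0)

    state.a_hat += dt * (params.k_a * e_a - state.a_hat / params.tau_a)

    return ConflictVector(e_a=e_a, e_f=e_f, e_omega=e_omega)


def advance_bank(
    state: PerceptionState,
    signals: AfferentSignals,
    sl: slice,
    x_hyp: np.ndarray,
    params: ObserverParams,
    roll_probe: int | None = None,
):
    """Advance the bank over a contiguous slice of afference samples.

    Returns ``(mean_reduced, last_reduced, probe_roll)`` where
    ``mean_reduced`` is the per-observer conflict-norm vector averaged over
    the interval (the evidence the filter consumes), ``last_reduced`` the
    final-substep value, and ``probe_roll`` the per-substep perceived roll of
    observer ``roll_probe`` (rad) or None.
    """
    idx = range(*sl.indices(signals.canal.shape[0]))
    m = state.g_hat.shape[0]
    acc = np.zeros((m, 3))
    last = np.zeros((m, 3))
    rolls = np.empty(len(idx)) if roll_probe is not None else None
    for j, k in enumerate(idx):
        conflict = observer_step(state, signals.canal[k], signals.oto[k], x_hyp, params)
        last = conflict.reduced
        acc += last
        if rolls is not None:
            g = state.g_hat[roll_probe]
            rolls[j] = np.arctan2(g[1], g[2])
    acc /= max(len(idx), 1)
    return acc, last, rolls


def extract_tilt_perception(g_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Perceived roll and pitch (degrees) from the perceived gravity vector.

    Roll is the tilt of the up-vector toward +y, pitch toward +x; both are
    invariant to rescaling of ``g_hat``.
    """
    g = np.asarray(g_hat, dtype=float)
    if np.any(np.linalg.norm(g, axis=-1) < _EPS_NORM):
        raise ValueError("tilt undefined for zero perceived gravity")
    roll = np.degrees(np.arctan2(g[..., 1], g[..., 2]))
    pitch = np.degrees(np.arctan2(g[..., 0], g[..., 2]))
    return roll, pitch
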