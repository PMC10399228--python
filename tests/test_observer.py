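"""Truth kinematics, sensor models, and conditioned-observer dynamics."""

import numpy as np
import pytest

from gravadapt import (
    HeadMotion,
    ObserverParams,
    add_sensory_noise,
    extract_tilt_perception,
    integrate_head_kinematics,
    simulate_afference,
)
from gravadapt.observer import advance_bank, canal_gain, init_bank_state, observer_step

from conftest import roll_motion, stationary_motion


class TestKinematics:
    def test_stationary_upright_specific_force_opposes_gravity(self):
        truth = integrate_head_kinematics(stationary_motion(g=1.0))
        assert np.allclose(truth.specific_force, [0.0, 0.0, 1.0], atol=1e-12)

    def test_constant_roll_rate_rotates_gravity_vector(self):
        # roll at 1 deg/s for 10 s -> 10 deg tilt of the up-vector
        dt = 0.01
        t = np.arange(0.0, 10.0 + dt, dt)
        omega = np.zeros((t.size, 3))
        omega[:, 0] = np.radians(1.0)
        m = HeadMotion(t=t, omega=omega, accel=np.zeros((t.size, 3)), g_true=np.ones(t.size))
        truth = integrate_head_kinematics(m)
        phi = np.radians(10.0)
        assert np.allclose(truth.specific_force[-1], [0.0, np.sin(phi), np.cos(phi)], atol=1e-4)
        assert truth.roll[-1] == pytest.approx(phi, rel=1e-4)

    def test_specific_force_linear_in_gravity_magnitude(self):
        m1 = roll_motion(duration=5.0, g=1.0)
        m4 = roll_motion(duration=5.0, g=4.0)
        f1 = integrate_head_kinematics(m1).specific_force
        f4 = integrate_head_kinematics(m4).specific_force
        assert np.allclose(f4, 4.0 * f1, atol=1e-12)

    def test_rejects_nonuniform_grid_and_nan(self):
        t = np.array([0.0, 0.1, 0.3])
        z = np.zeros((3, 3))
        with pytest.raises(ValueError, match="uniform"):
            HeadMotion(t=t, omega=z, accel=z, g_true=np.ones(3))
        t = np.arange(3) * 0.1
        bad = z.copy()
        bad[1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            HeadMotion(t=t, omega=bad, accel=z, g_true=np.ones(3))


class TestAfference:
    def test_canal_highpass_of_zero_is_zero(self, params):
        truth = integrate_head_kinematics(stationary_motion())
        aff = simulate_afference(truth, params)
        assert np.allclose(aff.canal, 0.0)

    def test_canal_step_response_decays_with_tau(self, params):
        dt = params.dt_sim
        t = np.arange(0.0, 30.0, dt)
        omega = np.zeros((t.size, 3))
        omega[:, 0] = 0.1
        m = HeadMotion(t=t, omega=omega, accel=np.zeros((t.size, 3)), g_true=np.ones(t.size))
        aff = simulate_afference(integrate_head_kinematics(m), params)
        resp = aff.canal[:, 0]
        assert resp[0] == pytest.approx(0.1, rel=0.02)
        k_tau = int(params.tau_canal / dt)
        assert resp[k_tau] == pytest.approx(0.1 * np.exp(-1.0), rel=0.05)
        assert resp[-1] < 0.01

    def test_canal_sinusoid_amplitude_matches_transfer_function(self, params):
        m = roll_motion(duration=120.0, freq=1.0)
        aff = simulate_afference(integrate_head_kinematics(m), params)
        half = m.n_steps // 2
        amp = np.max(np.abs(aff.canal[half:, 0])) / np.radians(10.0)
        assert amp == pytest.approx(canal_gain(1.0, params.tau_canal), rel=0.01)

    def test_rejects_unstable_discretization(self):
        p = ObserverParams(tau_canal=0.09, dt_sim=0.05)
        truth = integrate_head_kinematics(stationary_motion(dt=0.05))
        with pytest.raises(ValueError, match="coarse"):
            simulate_afference(truth, p)


class TestSensoryNoise:
    def test_zero_power_is_identity_and_seed_reproducible(self, stationary_afference):
        _, aff = stationary_afference
        clean = add_sensory_noise(aff, 0.0, 0.05, 0)
        assert np.array_equal(clean.canal, aff.canal)
        a = add_sensory_noise(aff, 1e-6, 0.05, 42)
        b = add_sensory_noise(aff, 1e-6, 0.05, 42)
        assert np.array_equal(a.canal, b.canal) and np.array_equal(a.oto, b.oto)

    def test_noise_variance_follows_psd_convention(self):
        # variance = noise_power / dt
        dt, power = 0.1, 1e-4
        t = np.arange(0.0, 3400.0, dt)
        from gravadapt.observer import AfferentSignals

        aff = AfferentSignals(t=t, canal=np.zeros((t.size, 3)), oto=np.zeros((t.size, 3)), dt=dt)
        noisy = add_sensory_noise(aff, power, dt, 7)
        assert t.size * 3 > 1e5  # sample size backing the 5% tolerance
        assert noisy.canal.var() == pytest.approx(power / dt, rel=0.05)


class TestObserverStep:
    def test_matched_stationary_hypothesis_is_fixed_point(self, params, stationary_afference):
        _, aff = stationary_afference
        x = np.array([1.0])
        state = init_bank_state(x)
        _, last, _ = advance_bank(state, aff, slice(0, aff.t.size), x, params)
        assert np.all(last < 1e-9)
        assert np.allclose(state.g_hat, [[0.0, 0.0, 1.0]], atol=1e-9)

    def test_omega_hat_stays_zero_without_drive(self, params):
        p = ObserverParams(k_fomega=0.0)
        state = init_bank_state(np.array([1.0]))
        for _ in range(100):
            observer_step(state, np.zeros(3), np.array([0.0, 0.0, 1.0]), np.array([1.0]), p)
        assert np.allclose(state.omega_hat, 0.0, atol=1e-12)

    def test_magnitude_constraint_holds_every_step(self, params):
        m = roll_motion(duration=10.0, g=4.0)
        aff = simulate_afference(integrate_head_kinematics(m), params)
        x = np.array([2.5])
        state = init_bank_state(x)
        for k in range(m.n_steps):
            observer_step(state, aff.canal[k], aff.oto[k], x, params)
            assert np.linalg.norm(state.g_hat[0]) == pytest.approx(2.5, abs=1e-9)

    def test_steady_conflict_monotone_in_hypothesis_mismatch(self, params, stationary_afference):
        _, aff = stationary_afference
        norms = []
        for hyp in [1.0, 1.3, 2.0, 3.0, 4.0]:
            x = np.array([hyp])
            state = init_bank_state(x)
            _, last, _ = advance_bank(state, aff, slice(0, aff.t.size), x, params)
            norms.append(np.linalg.norm(last))
        assert norms[0] < 1e-9
        assert np.all(np.diff(norms) > 0)

    def test_scale_property_of_conflicts(self, params):
        # doubling truth and hypothesis doubles e_a; direction conflict unchanged
        m1 = roll_motion(duration=5.0, g=1.0)
        m2 = roll_motion(duration=5.0, g=2.0)
        out = {}
        for m, hyp in ((m1, 1.0), (m2, 2.0)):
            aff = simulate_afference(integrate_head_kinematics(m), params)
            x = np.array([hyp * 1.5])  # deliberately mismatched to keep conflicts alive
            state = init_bank_state(x)
            c = None
            for k in range(m.n_steps):
                c = observer_step(state, aff.canal[k], aff.oto[k], x, params)
            out[hyp] = c
        assert np.allclose(out[2.0].e_a, 2.0 * out[1.0].e_a, atol=1e-9)
        assert np.allclose(out[2.0].e_f, out[1.0].e_f, atol=1e-9)

    def test_rejects_negative_hypothesis(self, params):
        state = init_bank_state(np.array([1.0]))
        with pytest.raises(ValueError):
            observer_step(state, np.zeros(3), np.zeros(3), np.array([-1.0]), params)


class TestTiltPerception:
    @pytest.mark.parametrize(
        "g_hat, roll_deg",
        [
            ((0.0, 0.0, 1.0), 0.0),
            ((0.0, np.sin(np.radians(10)), np.cos(np.radians(10))), 10.0),
        ],
    )
    def test_roll_angle_examples(self, g_hat, roll_deg):
        roll, pitch = extract_tilt_perception(np.array(g_hat))
        assert roll == pytest.approx(roll_deg, abs=1e-9)
        assert pitch == pytest.approx(0.0, abs=1e-9)

    def test_scale_invariance(self):
        g = np.array([0.1, 0.3, 0.9])
        assert extract_tilt_perception(g) == pytest.approx(extract_tilt_perception(4.0 * g))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            extract_tilt_perception(np.zeros(3))


class TestGExcess:
    """Unadapted hypergravity overestimates roll; adapted perception is
    accurate -- on a single deterministic noise-free observer run."""

    @staticmethod
    def _peak_ratio(g_level, hyp, params):
        m = roll_motion(duration=120.0, g=g_level)
        truth = integrate_head_kinematics(m)
        aff = simulate_afference(truth, params)
        x = np.array([hyp])
        state = init_bank_state(x)
        _, _, rolls = advance_bank(state, aff, slice(0, m.n_steps), x, params, roll_probe=0)
        half = m.n_steps // 2
        return np.max(np.abs(rolls[half:])) / np.max(np.abs(truth.roll[half:]))

    def test_unadapted_hypergravity_overestimates_roll(self, params):
        assert self._peak_ratio(4.0, 1.0, params) > 1.0

    def test_adapted_hypergravity_is_accurate(self, params):
        assert self._peak_ratio(4.0, 4.0, params) == pytest.approx(1.0, abs=0.05)

    def test_unadapted_hypogravity_underestimates_roll(self, params):
        assert self._peak_ratio(0.5, 1.0, params) < 1.0
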