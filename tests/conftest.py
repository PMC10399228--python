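import numpy as np
import pytest

from gravadapt import (
    EngineConfig,
    GravityGrid,
    HeadMotion,
    NoiseCovariance,
    ObserverParams,
    ScenarioConfig,
    build_motion,
    integrate_head_kinematics,
    simulate_afference,
)


@pytest.fixture
def params():
    return ObserverParams()


@pytest.fixture
def cov():
    return NoiseCovariance()


@pytest.fixture
def grid():
    return GravityGrid()


def stationary_motion(duration=10.0, g=1.0, dt=0.05):
    t = np.arange(0.0, duration, dt)
    return HeadMotion(
        t=t,
        omega=np.zeros((t.size, 3)),
        accel=np.zeros((t.size, 3)),
        g_true=np.full(t.size, float(g)),
    )


def roll_motion(duration=60.0, g=1.0, freq=1.0, peak_vel_deg=10.0, dt=0.05):
    t = np.arange(0.0, duration, dt)
    omega = np.zeros((t.size, 3))
    omega[:, 0] = np.radians(peak_vel_deg) * np.cos(freq * t)
    return HeadMotion(
        t=t, omega=omega, accel=np.zeros((t.size, 3)), g_true=np.full(t.size, float(g))
    )


@pytest.fixture
def stationary_afference(params):
    motion = stationary_motion()
    truth = integrate_head_kinematics(motion)
    return truth, simulate_afference(truth, params)


def small_engine_config(**kw):
    kw.setdefault("store_particles", True)
    return EngineConfig(**kw)


def short_scenario(segments, duration, name="test"):
    return ScenarioConfig(name=name, duration=duration, segments=segments)


@pytest.fixture
def const_motion_1g():
    return build_motion(ScenarioConfig(name="const", duration=30.0, segments=[(0.0, 1.0)]))
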