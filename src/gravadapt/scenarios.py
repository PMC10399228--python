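"""Canonical motion scenarios, configuration files, and result I/O.

The reference stimulus is passive sinusoidal roll tilt at 1 rad/s (0.159 Hz)
with 10 deg/s peak angular velocity (10 deg peak displacement), under a
piecewise-constant gravity schedule stepping among {0.5, 1, 2, 4} g.  Every
canonical scenario starts at 1 Earth gravity.  Segment durations are package
choices (the underlying model deliberately leaves absolute time untuned):
each level is held for several multiples of the observed adaptation time so
that learned states can form before the next transition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import EngineConfig, SimulationResult
from .inference import GravityGrid, NoiseCovariance
from .observer import HeadMotion, ObserverParams

__all__ = [
    "ScenarioConfig",
    "make_roll_tilt_profile",
    "make_gravity_schedule",
    "build_motion",
    "canonical_scenarios",
    "load_config",
    "save_config",
    "write_results",
    "read_results",
]

#: default hold time per gravity level (model seconds); a comfortable
#: multiple (>5x) of the observed 1 -> 4 g adaptation time under defaults
SEGMENT_SECONDS = 120.0


@dataclass
class ScenarioConfig:
    """A named motion + gravity-schedule specification."""

    name: str = "custom"
    freq: float = 1.0              # rad/s
    peak_vel_deg: float = 10.0     # deg/s
    duration: float = 480.0        # model seconds
    dt_sim: float = 0.05
    segments: list = field(default_factory=lambda: [(0.0, 1.0)])  # (start, level g)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        starts = [s for s, _ in self.segments]
        if starts != sorted(set(starts)):
            raise ValueError("segment start times must be strictly increasing")
        if not self.segments or abs(self.segments[0][0]) > 1e-12:
            raise ValueError("first segment must start at t = 0")
        if any(level < 0 for _, level in self.segments):
            raise ValueError("gravity levels must be nonnegative")
        if starts[-1] >= self.duration:
            raise ValueError("segment start beyond scenario duration")

    @property
    def transition_times(self) -> list[float]:
        return [s for s, _ in self.segments[1:]]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segments"] = [list(seg) for seg in self.segments]
        return d


def make_roll_tilt_profile(
    freq: float, peak_vel_deg: float, duration: float, dt_sim: float
) -> HeadMotion:
    """Sinusoidal roll-velocity stimulus ``omega_x = peak_vel * cos(freq t)``
    (implied peak roll displacement ``peak_vel / freq``), zero inertial
    acceleration, unit gravity placeholder."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    if peak_vel_deg < 0:
        raise ValueError("peak angular velocity must be nonnegative")
    if dt_sim > np.pi / (10.0 * freq):
        raise ValueError("dt_sim undersamples the stimulus")
    t = np.arange(0.0, duration, dt_sim)
    omega = np.zeros((t.size, 3))
    omega[:, 0] = np.radians(peak_vel_deg) * np.cos(freq * t)
    return HeadMotion(
        t=t, omega=omega, accel=np.zeros((t.size, 3)), g_true=np.ones(t.size)
    )


def make_gravity_schedule(segments: list, t: np.ndarray) -> np.ndarray:
    """Piecewise-constant gravity series on the motion grid; transitions are
    instantaneous at segment start times."""
    starts = np.array([s for s, _ in segments], dtype=float)
    levels = np.array([lv for _, lv in segments], dtype=float)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("segments overlap or are unordered")
    if starts[0] > t[0] + 1e-12:
        raise ValueError("schedule must cover the start of the motion")
    if starts[-1] > t[-1]:
        raise ValueError("segment start beyond motion duration")
    idx = np.searchsorted(starts, t, side="right") - 1
    return levels[idx]


def build_motion(scenario: ScenarioConfig) -> HeadMotion:
    """Assemble the scenario's HeadMotion: roll-tilt profile plus schedule."""
    motion = make_roll_tilt_profile(
        scenario.freq, scenario.peak_vel_deg, scenario.duration, scenario.dt_sim
    )
    g = make_gravity_schedule(scenario.segments, motion.t)
    return HeadMotion(t=motion.t, omega=motion.omega, accel=motion.accel, g_true=g, q0=motion.q0)


def canonical_scenarios() -> dict[str, ScenarioConfig]:
    """The figure scenarios: step schedules among {0.5, 1, 2, 4} g, all
    beginning at 1 g.  fig7 is the first 1 -> 4 g transition with the roll
    perception probes (always recorded)."""
    d = SEGMENT_SECONDS

    def seg(levels: list[float]) -> list[tuple[float, float]]:
        return [(i * d, lv) for i, lv in enumerate(levels)]

    return {
        "fig2": ScenarioConfig(name="fig2", duration=1.5 * d, segments=[(0.0, 1.0), (0.5 * d, 4.0)]),
        "fig3": ScenarioConfig(name="fig3", duration=d + 500.0, segments=[(0.0, 1.0), (d, 4.0)]),
        "fig5a": ScenarioConfig(name="fig5a", duration=4 * d, segments=seg([1.0, 4.0, 1.0, 4.0])),
        "fig5b": ScenarioConfig(name="fig5b", duration=4 * d, segments=[(0.0, 1.0), (3 * d, 4.0)]),
        "fig5c": ScenarioConfig(name="fig5c", duration=4 * d, segments=seg([1.0, 2.0, 1.0, 4.0])),
        "fig5d": ScenarioConfig(name="fig5d", duration=4 * d, segments=seg([1.0, 0.5, 1.0, 4.0])),
        "fig7": ScenarioConfig(name="fig7", duration=1.5 * d, segments=[(0.0, 1.0), (0.5 * d, 4.0)]),
    }


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_ENGINE_KEYS = {f.name for f in dataclasses.fields(EngineConfig)}
_OBSERVER_KEYS = {f.name for f in dataclasses.fields(ObserverParams)}
_GRID_KEYS = {f.name for f in dataclasses.fields(GravityGrid)}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path: str | Path) -> tuple[ScenarioConfig, EngineConfig]:
    """Read a YAML/JSON scenario+engine config; unknown keys are rejected
    with the offending section named, and every default is materialized in
    the returned objects."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, {"scenario", "engine"}, "config root")
    sc_raw = dict(raw.get("scenario", {}))
    en_raw = dict(raw.get("engine", {}))
    _check_keys(sc_raw, _SCENARIO_KEYS, "scenario")
    _check_keys(en_raw, _ENGINE_KEYS, "engine")
    if "segments" in sc_raw:
        sc_raw["segments"] = [tuple(seg) for seg in sc_raw["segments"]]
    ob_raw = dict(en_raw.pop("observer", {}) or {})
    _check_keys(ob_raw, _OBSERVER_KEYS, "engine.observer")
    if "oto_weights" in ob_raw:
        ob_raw["oto_weights"] = tuple(ob_raw["oto_weights"])
    gr_raw = dict(en_raw.pop("grid", {}) or {})
    _check_keys(gr_raw, _GRID_KEYS, "engine.grid")
    cov = en_raw.pop("noise_cov", None)
    scenario = ScenarioConfig(**sc_raw)
    if "dt_sim" not in ob_raw:
        ob_raw["dt_sim"] = scenario.dt_sim
    engine = EngineConfig(
        observer=ObserverParams(**ob_raw),
        grid=GravityGrid(**gr_raw),
        noise_cov=NoiseCovariance(np.asarray(cov)) if cov is not None else NoiseCovariance(),
        **en_raw,
    )
    return scenario, engine


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(scenario: ScenarioConfig, engine: EngineConfig, path: str | Path) -> None:
    """Write the fully materialized configuration (defaults included)."""
    payload = _to_builtin({"scenario": scenario.to_dict(), "engine": engine.to_dict()})
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(
    result: SimulationResult,
    out_dir: str | Path,
    scenario: ScenarioConfig | None = None,
    ltm_density_csv: bool = False,
) -> None:
    """Write per-step CSV, per-substep perception CSV, and a JSON metadata
    sidecar (full config echo including seeds) to ``out_dir``; optionally a
    sparse per-step LTM-density table (step, time, grid value, mass)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ltm_density_csv:
        ks, bins = np.nonzero(result.ltm_mass)
        grid = result.metadata.get("config", {}).get("grid", {})
        g0, dg = grid.get("g_min", 0.05), grid.get("step", 0.01)
        pd.DataFrame(
            {
                "step": ks,
                "t": result.t_step[ks],
                "g": g0 + dg * bins,
                "mass": result.ltm_mass[ks, bins],
            }
        ).to_csv(out / "ltm_density.csv", index=False)
    steps = pd.DataFrame(
        {
            "t": result.t_step,
            "map_g": result.map_g,
            "g_true": result.g_true_step,
            "central_nis": result.central_nis,
            "hml": result.hml,
            "sigma_jitter": result.sigma,
            "W": result.W,
            "max_lik": result.max_lik,
            "ltm_total_mass": result.ltm_mass.sum(axis=1),
        }
    )
    steps.to_csv(out / "steps.csv", index=False)
    pd.DataFrame(
        {
            "t": result.t_sim,
            "central_roll_deg": np.degrees(result.central_roll),
            "actual_roll_deg": np.degrees(result.actual_roll),
        }
    ).to_csv(out / "perception.csv", index=False)
    meta = dict(result.metadata)
    if scenario is not None:
        meta["scenario"] = scenario.to_dict()
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Round-trip companion of :func:`write_results`."""
    out = Path(out_dir)
    steps = pd.read_csv(out / "steps.csv")
    perception = pd.read_csv(out / "perception.csv")
    meta = json.loads((out / "metadata.json").read_text())
    return steps, perception, meta
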