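"""Summary metrics over simulation results: adaptation speed, paired
LTM-advantage comparisons, and tilt-perception (G-excess) ratios."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .engine import EngineConfig, SimulationResult, run_simulation
from .scenarios import ScenarioConfig, build_motion

__all__ = [
    "steps_to_adapt",
    "paired_ltm_runs",
    "sign_test",
    "peak_roll_ratio",
]


def steps_to_adapt(
    result: SimulationResult, t_transition: float, target: float, tol: float = 0.05
) -> int:
    """Filter steps from the transition until the MAP first enters the
    ``target +- tol`` band."""
    return result.steps_to_adapt(t_transition, target, tol)


def paired_ltm_runs(
    scenario: ScenarioConfig, config: EngineConfig, seeds: list[int]
) -> list[tuple[SimulationResult, SimulationResult]]:
    """Run the scenario once with and once without LTM per seed, holding the
    noise realization fixed (the named RNG streams make the pair share it)."""
    import dataclasses

    motion = build_motion(scenario)
    pairs = []
    for seed in seeds:
        with_ltm = run_simulation(
            motion, dataclasses.replace(config, seed=seed, ltm_enabled=True)
        )
        without = run_simulation(
            motion, dataclasses.replace(config, seed=seed, ltm_enabled=False)
        )
        pairs.append((with_ltm, without))
    return pairs


def sign_test(diffs: np.ndarray) -> float:
    """Two-sided exact sign test p-value on paired differences (ties
    dropped); p = 1 when every pair ties."""
    d = np.asarray(diffs)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    return float(stats.binomtest(int((d > 0).sum()), int(d.size), 0.5).pvalue)


def peak_roll_ratio(
    result: SimulationResult, t_start: float, t_stop: float
) -> float:
    """Peak perceived over peak actual roll magnitude within a time window of
    the per-substep perception trace."""
    mask = (result.t_sim >= t_start) & (result.t_sim < t_stop)
    if not np.any(mask):
        raise ValueError("empty window")
    actual = np.max(np.abs(result.actual_roll[mask]))
    if actual <= 0:
        raise ValueError("no actual tilt in window")
    return float(np.max(np.abs(result.central_roll[mask])) / actual)
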