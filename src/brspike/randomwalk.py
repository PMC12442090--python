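"""Random-walk spatialization of spike sequences and effective diffusion.

Each detected spike event becomes one step of a 2D walk: the step length is
the event amplitude (mV-scaled virtual displacement) and the direction
theta comes either from the instantaneous (analytic-signal) phase of a
reference channel at the event time or from a seeded uniform distribution.
The cumulative displacement D(t) = |r(t) - r(0)| and the Einstein-relation
estimator D_eff = <D(t)^2> / (4 t) summarise how far the activity spreads
per unit time, letting per-wavelength responses be compared as diffusion
processes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.signal import hilbert

from .exceptions import InputError
from .synthdata import Recording


@dataclass(frozen=True)
class WalkTrajectory:
    condition: str
    step_times: np.ndarray  # s, one per step
    positions: np.ndarray  # (n_steps + 1, 2), origin-anchored
    step_amplitudes: np.ndarray  # mV
    theta: np.ndarray  # radians per step

    @property
    def n_steps(self) -> int:
        return int(self.step_amplitudes.size)


@dataclass(frozen=True)
class DiffusionResult:
    D_eff: float  # amplitude^2 per unit time
    n_walks: int
    displacement_curve: np.ndarray  # ensemble-mean D at each step index (D[0] = 0)
    ballistic: bool = False  # raised when mean-squared displacement grows ~t^2


def uniform_angles(n: int, seed: int) -> np.ndarray:
    """n i.i.d. directions uniform on [0, 2*pi)."""
    return np.random.default_rng(seed).uniform(0.0, 2 * np.pi, size=n)


def hilbert_phase_angles(reference: Recording, times: Sequence[float]) -> np.ndarray:
    """Instantaneous phase of the reference channel's analytic signal at ``times``."""
    x = reference.voltages - np.mean(reference.voltages)
    phase = np.angle(hilbert(x))
    t = np.asarray(times, dtype=float)
    return np.interp(t, reference.times, phase)


def build_walk(amplitudes: Sequence[float],
               theta: Sequence[float] | None = None,
               *,
               step_times: Sequence[float] | None = None,
               reference: Recording | None = None,
               seed: int | None = None,
               condition: str = "") -> WalkTrajectory:
    """Build a 2D walk: r(t+dt) = r(t) + A * (cos theta, sin theta).

    Direction source (exactly one of):
    ``theta`` — explicit per-step angles;
    ``reference`` — analytic-signal instantaneous phase of a reference
    recording evaluated at ``step_times`` (required then);
    ``seed`` — seeded uniform angles.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size == 0:
        raise InputError("need at least one step")
    if np.any(amps < 0):
        raise InputError("step amplitudes must be >= 0")
    if step_times is None:
        step_times = np.arange(1.0, amps.size + 1)
    step_times = np.asarray(step_times, dtype=float)
    if step_times.size != amps.size:
        raise InputError("step_times and amplitudes must have equal length")

    if theta is not None:
        ang = np.asarray(theta, dtype=float)
        if ang.size != amps.size:
            raise InputError("theta and amplitudes must have equal length")
    elif reference is not None:
        ang = hilbert_phase_angles(reference, step_times)
    elif seed is not None:
        ang = uniform_angles(amps.size, seed)
    else:
        raise InputError("provide theta, a reference Recording, or a seed")

    steps = np.column_stack([amps * np.cos(ang), amps * np.sin(ang)])
    positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return WalkTrajectory(condition=condition, step_times=step_times,
                          positions=positions, step_amplitudes=amps, theta=ang)


def displacement(traj: WalkTrajectory) -> np.ndarray:
    """Cumulative displacement D(t): Euclidean distance from origin at every step."""
    return np.hypot(traj.positions[:, 0], traj.positions[:, 1])


def effective_diffusion(walks: list[WalkTrajectory],
                        time_per_step: float = 1.0) -> DiffusionResult:
    """Einstein-relation effective diffusion over an ensemble of walks.

    D_eff = <D(t)^2> / (4 t) evaluated at the final common step count (walks
    of unequal length are truncated to the shortest, with a warning).  The
    per-step ensemble-mean displacement curve is returned alongside; a
    ballistic flag is raised when the mean-squared displacement grows
    super-diffusively (log-log slope > 1.5), as for straight-line walks.
    """
    if not walks:
        raise InputError("need at least one walk")
    n_steps = [w.n_steps for w in walks]
    if min(n_steps) < 10:
        raise InputError("each walk needs >= 10 steps")
    n = min(n_steps)
    if max(n_steps) != n:
        warnings.warn(f"walks have unequal step counts; truncating to {n}",
                      stacklevel=2)
    D = np.stack([displacement(w)[:n + 1] for w in walks])  # (n_walks, n+1)
    curve = D.mean(axis=0)
    msd = (D ** 2).mean(axis=0)  # mean squared displacement per step index
    t_final = n * time_per_step
    d_eff = float(msd[-1] / (4.0 * t_final))

    # super-diffusion check on the second half of the msd curve
    k = np.arange(1, n + 1)
    half = n // 2
    slope = np.polyfit(np.log(k[half:]), np.log(np.maximum(msd[1:][half:], 1e-300)), 1)[0]
    return DiffusionResult(D_eff=d_eff, n_walks=len(walks),
                           displacement_curve=curve, ballistic=bool(slope > 1.5))


@dataclass(frozen=True)
class ConditionRanking:
    """Per-condition mean final displacement and D_eff, ranked."""

    order: list[str]  # conditions by descending mean final displacement
    mean_final_displacement: dict[str, float]
    d_eff: dict[str, float]
    ties: list[tuple[str, str]]


def compare_conditions(per_condition: dict[str, list[WalkTrajectory]],
                       time_per_step: float = 1.0,
                       tie_rtol: float = 1e-9) -> ConditionRanking:
    """Rank conditions by mean final displacement (D_eff reported alongside)."""
    if len(per_condition) < 2:
        raise InputError("need >= 2 conditions to compare")
    counts = {c: min(w.n_steps for w in ws) for c, ws in per_condition.items()}
    n = min(counts.values())
    if len(set(counts.values())) > 1:
        warnings.warn(f"conditions have unequal step counts; truncating to {n}",
                      stacklevel=2)
    finals: dict[str, float] = {}
    d_effs: dict[str, float] = {}
    for cond, ws in per_condition.items():
        D = np.stack([displacement(w)[:n + 1] for w in ws])
        finals[cond] = float(D[:, -1].mean())
        d_effs[cond] = effective_diffusion(ws, time_per_step).D_eff
    order = sorted(finals, key=lambda c: -finals[c])
    ties = [(a, b) for i, a in enumerate(order) for b in order[i + 1:]
            if np.isclose(finals[a], finals[b], rtol=tie_rtol)]
    return ConditionRanking(order=order, mean_final_displacement=finals,
                            d_eff=d_effs, ties=ties)
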