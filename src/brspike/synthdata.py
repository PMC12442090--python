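"""Synthetic multi-channel voltage recordings with the statistical structure of
proteinoid-bacteriorhodopsin spiking measurements.

Proteinoid microspheres coupled with bacteriorhodopsin show slow spontaneous
voltage oscillations (periods of hundreds to thousands of seconds, millivolt
amplitudes) that are strongly modulated by the wavelength of illumination:
green light produces the largest, most coherent oscillations, blue and yellow
intermediate ones, red the weakest, and pure proteinoids barely respond to
light at all. The generator emulates a recording as

    V(t) = A_k * sin(2*pi*(t - t_k)/P_k + phi) + eta(t)

where the amplitude A_k and period P_k are redrawn once per oscillation cycle
(events are what the downstream statistics summarise), eta is white Gaussian
noise whose variance depends on the light condition, and rare high-amplitude
outlier pulses can be injected to mimic occasional large transients seen on
individual channels.

Per-condition parameter presets carry the published per-group mean/SD values
for amplitude and period; they are package defaults and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigError, ParameterError

CONDITIONS = ("dark", "green", "blue", "yellow", "red")
GROUPS = ("proteinoid", "complex")

#: Per-(condition, group) presets: amplitude mean/SD (mV), period mean/SD (s),
#: noise SD (mV).  Amplitude and period values follow the published
#: per-condition summary statistics for proteinoid channels and
#: proteinoid-bacteriorhodopsin ("complex") channels; noise SDs encode the
#: observed ordering (green quietest, dark noisiest).
CONDITION_PRESETS: dict[tuple[str, str], dict[str, float]] = {
    ("dark", "proteinoid"): dict(amplitude_mean=4.34, amplitude_sd=4.47,
                                 period_mean=2522.85, period_sd=30.91, noise_sd=1.5),
    ("dark", "complex"): dict(amplitude_mean=10.77, amplitude_sd=2.21,
                              period_mean=2641.80, period_sd=88.76, noise_sd=1.5),
    ("green", "proteinoid"): dict(amplitude_mean=0.22, amplitude_sd=0.17,
                                  period_mean=606.56, period_sd=9.55, noise_sd=0.3),
    ("green", "complex"): dict(amplitude_mean=7.31, amplitude_sd=1.49,
                               period_mean=645.23, period_sd=16.32, noise_sd=0.3),
    ("blue", "proteinoid"): dict(amplitude_mean=0.33, amplitude_sd=0.28,
                                 period_mean=622.92, period_sd=151.24, noise_sd=0.8),
    ("blue", "complex"): dict(amplitude_mean=3.64, amplitude_sd=2.69,
                              period_mean=647.23, period_sd=14.38, noise_sd=0.8),
    ("yellow", "proteinoid"): dict(amplitude_mean=0.33, amplitude_sd=0.17,
                                   period_mean=627.74, period_sd=9.45, noise_sd=0.8),
    ("yellow", "complex"): dict(amplitude_mean=3.99, amplitude_sd=2.25,
                                period_mean=662.48, period_sd=11.60, noise_sd=0.8),
    ("red", "proteinoid"): dict(amplitude_mean=0.21, amplitude_sd=0.13,
                                period_mean=711.86, period_sd=157.17, noise_sd=0.8),
    ("red", "complex"): dict(amplitude_mean=1.68, amplitude_sd=1.06,
                             period_mean=649.61, period_sd=11.47, noise_sd=0.8),
}

#: Width of an injected outlier pulse, seconds (isolated half-sine).
OUTLIER_WIDTH_S = 60.0


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of one synthetic recording.

    Amplitudes are in millivolts, periods and durations in seconds,
    sampling_rate in hertz.  ``outlier_rate`` is the expected number of
    outlier pulses per recording (Poisson); ``outlier_amplitude`` their
    height in mV.
    """

    condition: str = "dark"
    group: str = "complex"
    amplitude_mean: float = 10.77
    amplitude_sd: float = 2.21
    period_mean: float = 2641.80
    period_sd: float = 88.76
    noise_sd: float = 1.5
    phase: float = 0.0
    outlier_rate: float = 0.0
    outlier_amplitude: float = 100.0
    duration: float = 86_400.0
    sampling_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ParameterError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.amplitude_mean < 0:
            raise ParameterError(f"amplitude_mean must be >= 0, got {self.amplitude_mean}")
        if self.period_mean <= 0:
            raise ParameterError(f"period_mean must be > 0, got {self.period_mean}")
        if self.sampling_rate <= 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude_sd < 0:
            raise ParameterError(f"amplitude_sd must be >= 0, got {self.amplitude_sd}")
        if self.period_sd < 0:
            raise ParameterError(f"period_sd must be >= 0, got {self.period_sd}")
        if self.outlier_rate < 0:
            raise ParameterError(f"outlier_rate must be >= 0, got {self.outlier_rate}")
        if self.duration < 2 * self.period_mean:
            raise ParameterError(
                f"duration must cover at least two mean periods "
                f"(duration={self.duration}, 2*period_mean={2 * self.period_mean})"
            )


@dataclass(frozen=True)
class Recording:
    """One channel's uniformly sampled voltage trace with condition metadata."""

    channel_id: str
    condition: str
    group: str
    times: np.ndarray  # seconds, uniform grid
    voltages: np.ndarray  # millivolts

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ParameterError("times and voltages must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ParameterError("times must be strictly increasing on a uniform grid")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise ParameterError("times and voltages must be finite (no missing values)")

    @property
    def sampling_rate(self) -> float:
        if self.times.size < 2:
            raise ParameterError("need >= 2 samples to define a sampling rate")
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def preset_params(condition: str, group: str, *, duration: float = 86_400.0,
                  seed: int = 0, **overrides) -> GenerationParams:
    """Return the default GenerationParams for a (condition, group) pair."""
    key = (condition, group)
    if key not in CONDITION_PRESETS:
        raise ConfigError(f"unknown condition/group pair {key!r}")
    kw = dict(CONDITION_PRESETS[key])
    kw.update(condition=condition, group=group, duration=duration, seed=seed)
    kw.update(overrides)
    return GenerationParams(**kw)


def _draw_cycles(rng: np.random.Generator, params: GenerationParams,
                 total: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-cycle (start, period, amplitude) covering [0, total].

    Periods are Normal(period_mean, period_sd) truncated below at half the
    mean period; amplitudes Normal(amplitude_mean, amplitude_sd) truncated
    at zero.  Redrawing on truncation keeps the draws i.i.d. from the
    truncated distribution.
    """
    starts, periods, amps = [], [], []
    t = 0.0
    p_floor = 0.5 * params.period_mean
    while t <= total:
        p = rng.normal(params.period_mean, params.period_sd) if params.period_sd > 0 \
            else params.period_mean
        while p < p_floor:
            p = rng.normal(params.period_mean, params.period_sd)
        a = rng.normal(params.amplitude_mean, params.amplitude_sd) if params.amplitude_sd > 0 \
            else params.amplitude_mean
        while a < 0:
            a = rng.normal(params.amplitude_mean, params.amplitude_sd)
        starts.append(t)
        periods.append(p)
        amps.append(a)
        t += p
    return np.asarray(starts), np.asarray(periods), np.asarray(amps)


def generate_recording(params: GenerationParams, channel_id: str = "F") -> Recording:
    """Generate one synthetic recording.

    The trace is a cycle-wise sinusoid: within cycle k (spanning one full
    period P_k starting at t_k) the voltage is
    ``A_k * sin(2*pi*(t - t_k)/P_k + phase)``, so consecutive cycle
    boundaries are exactly one period apart and, at phase 0, the waveform
    stitches continuously through zero.  White Gaussian noise of SD
    ``noise_sd`` is added samplewise, and ``outlier_rate`` Poisson-placed
    half-sine pulses of height ``outlier_amplitude`` and width 60 s are
    superimposed.  Identical params (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n, dtype=float) / params.sampling_rate

    starts, periods, amps = _draw_cycles(rng, params, t[-1] if n else 0.0)
    edges = np.concatenate([starts, [starts[-1] + periods[-1]]])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(starts) - 1)
    local = (t - starts[idx]) / periods[idx]
    v = amps[idx] * np.sin(2 * np.pi * local + params.phase)

    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=n)

    if params.outlier_rate > 0:
        n_out = rng.poisson(params.outlier_rate)
        width = OUTLIER_WIDTH_S
        for _ in range(n_out):
            t0 = rng.uniform(0.0, max(t[-1] - width, 0.0))
            mask = (t >= t0) & (t < t0 + width)
            v[mask] += params.outlier_amplitude * np.sin(np.pi * (t[mask] - t0) / width)

    return Recording(channel_id=channel_id, condition=params.condition,
                     group=params.group, times=t, voltages=v)


@dataclass(frozen=True)
class ExperimentConfig:
    """Channel counts per (condition, group) plus preset overrides.

    ``channels`` maps a condition name to ``{"proteinoid": n, "complex": m}``
    (either key may be absent).  ``duration`` applies to every recording.
    ``overrides`` maps (condition, group) to GenerationParams field overrides.
    """

    channels: Mapping[str, Mapping[str, int]]
    duration: float = 86_400.0
    seed: int = 0
    overrides: Mapping[tuple[str, str], Mapping[str, float]] = field(default_factory=dict)


def generate_condition_set(config: ExperimentConfig, seed: int | None = None) -> list[Recording]:
    """Generate one Recording per (channel, condition) in the configured design.

    A master seed deterministically derives an independent seed per channel
    (via `numpy.random.SeedSequence.spawn`), so the full file set is
    reproducible and any single channel can be regenerated in isolation.
    """
    if not config.channels:
        raise ConfigError("config must name at least one condition")
    for cond in config.channels:
        if cond not in CONDITIONS:
            raise ConfigError(f"unknown condition label {cond!r}; expected one of {CONDITIONS}")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)

    jobs: list[tuple[str, str, str]] = []
    for cond in config.channels:
        for group in GROUPS:
            count = int(config.channels[cond].get(group, 0))
            for i in range(count):
                label = f"{group[0].upper()}{i:02d}"
                jobs.append((cond, group, label))

    children = ss.spawn(len(jobs))
    out: list[Recording] = []
    for (cond, group, label), child in zip(jobs, children):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        overrides = dict(config.overrides.get((cond, group), {}))
        params = preset_params(cond, group, duration=config.duration,
                               seed=child_seed, **overrides)
        out.append(generate_recording(params, channel_id=f"{cond}-{label}"))
    return out


def pure_sinusoid(amplitude: float, period: float, duration: float,
                  sampling_rate: float = 1.0, phase: float = 0.0,
                  channel_id: str = "synth") -> Recording:
    """Noiseless single-frequency Recording (closed-form reference signal)."""
    params = GenerationParams(amplitude_mean=amplitude, amplitude_sd=0.0,
                              period_mean=period, period_sd=0.0, noise_sd=0.0,
                              phase=phase, duration=duration,
                              sampling_rate=sampling_rate)
    return generate_recording(params, channel_id=channel_id)
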