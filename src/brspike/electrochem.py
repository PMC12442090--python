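"""Cyclic-voltammetry peak analysis and equivalent-circuit impedance modelling.

Cyclic voltammetry: each cycle sweeps the potential up then down; the anodic
peak current i_pa (forward maximum), cathodic peak current i_pc (reverse
minimum) and the current at the switching potential i_sp feed the Nicholson
reversibility relation

    i_pc/i_pa = (i_pc)_0/i_pa + 0.485 (i_sp)_0/i_pa + 0.086

whose right-hand side is exposed here as a current-ratio reversibility
indicator (subscript 0 = baseline-referenced).

Impedance: the spectrum is modelled by a series resistance R1, two parallel
R||CPE blocks (interface charge transfer and bulk transport) and a Warburg
diffusion tail:

    Z(w) = R1 + R2||Z_CPE2 + R3||Z_CPE3 + sigma_w / sqrt(j w)

with Z_CPE = 1/(Q (j w)^n).  Fitting minimises the stacked real/imaginary
residuals weighted by 1/|Z|.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (FitConvergenceError, InputError,
                         InsufficientEventsError, ParameterError)


@dataclass(frozen=True)
class Voltammogram:
    """One CV cycle: potential/current pairs at a fixed scan rate."""

    potential: np.ndarray  # V vs Ag/AgCl
    current: np.ndarray  # uA
    cycle_index: int = 0
    scan_rate: float = 100.0  # mV/s

    def __post_init__(self) -> None:
        p = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "potential", p)
        object.__setattr__(self, "current", i)
        if p.size != i.size or p.size < 8:
            raise InputError("potential and current must be equal-length (>= 8 points)")


@dataclass(frozen=True)
class CvPeaks:
    i_pa: float  # uA, anodic (forward) peak
    i_pc: float  # uA, cathodic (reverse) peak, negative
    i_sp: float  # uA, current at the switching potential
    i_pc0: float  # uA, cathodic peak relative to the extrapolated baseline
    i_sp0: float  # uA, switching current relative to the extrapolated baseline


@dataclass(frozen=True)
class ImpedanceSpectrum:
    frequency: np.ndarray  # Hz, positive
    z_real: np.ndarray  # Ohm
    z_imag: np.ndarray  # Ohm

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        zr = np.asarray(self.z_real, dtype=float)
        zi = np.asarray(self.z_imag, dtype=float)
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "z_real", zr)
        object.__setattr__(self, "z_imag", zi)
        if not (f.size == zr.size == zi.size) or f.size == 0:
            raise InputError("frequency, z_real, z_imag must be equal-length and non-empty")
        if np.any(f <= 0):
            raise InputError("frequencies must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.z_real, self.z_imag)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.z_imag, self.z_real))

    @property
    def z(self) -> np.ndarray:
        return self.z_real + 1j * self.z_imag


@dataclass(frozen=True)
class CircuitParams:
    """R1 + (R2 || CPE2) + (R3 || CPE3) + Warburg equivalent circuit."""

    R1: float  # Ohm, series resistance
    R2: float  # Ohm
    Q2: float  # S * s^n
    n2: float  # CPE ideality, 0..1
    R3: float  # Ohm
    Q3: float
    n3: float
    sigma_w: float  # Ohm / s^-1/2, Warburg coefficient

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("Q2", "Q3", "sigma_w"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("n2", "n3"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.R1, self.R2, self.Q2, self.n2,
                         self.R3, self.Q3, self.n3, self.sigma_w])

    @classmethod
    def from_array(cls, a) -> "CircuitParams":
        return cls(*(float(v) for v in a))


def split_sweep(vg: Voltammogram) -> tuple[slice, slice, int]:
    """Split a cycle into forward/reverse sweeps at the switching potential."""
    k = int(np.argmax(vg.potential))
    if k < 3 or k > vg.potential.size - 4:
        raise InputError("cycle must contain a full forward and reverse sweep "
                         "(monotone-only sweep?)")
    return slice(0, k + 1), slice(k, vg.potential.size), k


def extract_cv_peaks(vg: Voltammogram, min_peak_fraction: float = 0.05) -> CvPeaks:
    """Extract anodic/cathodic peak currents and the switching-potential current.

    i_pa is the forward-sweep maximum, i_pc the reverse-sweep minimum, i_sp
    the current at the switching potential.  Baseline-referenced variants
    subtract a linear baseline extrapolated from the first 10% of the
    forward sweep.  A sweep whose forward "peak" does not rise above that
    baseline by at least ``min_peak_fraction`` of the current range (e.g. a
    pure capacitive box) raises an error: there is no faradaic peak.
    """
    fwd, rev, k = split_sweep(vg)
    p, i = vg.potential, vg.current
    i_pa_idx = fwd.start + int(np.argmax(i[fwd]))
    i_pa = float(i[i_pa_idx])
    i_pc = float(np.min(i[rev]))
    i_sp = float(i[k])

    # linear baseline from the first 10% of the forward sweep
    nb = max(2, (k + 1) // 10)
    coef = np.polyfit(p[:nb], i[:nb], 1)
    baseline = np.polyval(coef, p)

    i_range = float(np.ptp(i))
    if i_range == 0 or (i_pa - baseline[i_pa_idx]) < min_peak_fraction * i_range:
        raise InputError("no faradaic anodic peak above the capacitive baseline")
    if i_pa <= 0:
        raise InputError(f"anodic peak current must be > 0, got {i_pa}")
    if i_pc >= 0:
        raise InputError(f"cathodic peak current must be < 0, got {i_pc}")

    rev_min_idx = rev.start + int(np.argmin(i[rev]))
    return CvPeaks(i_pa=i_pa, i_pc=i_pc, i_sp=i_sp,
                   i_pc0=float(i[rev_min_idx] - baseline[rev_min_idx]),
                   i_sp0=float(i_sp - baseline[k]))


def nicholson_ratio(ipc0_over_ipa: float, isp0_over_ipa: float) -> float:
    """Nicholson peak-current-ratio correction.

    Affine form ``ipc0/ipa + 0.485 * isp0/ipa + 0.086`` estimating
    |i_pc/i_pa| from baseline-referenced currents; a value near 1 indicates
    reversible electron transfer.  This is the raw current ratio — not the
    kinetic Psi parameter sometimes tabulated alongside it.
    """
    if not (np.isfinite(ipc0_over_ipa) and np.isfinite(isp0_over_ipa)):
        raise ParameterError("inputs must be finite")
    return ipc0_over_ipa + 0.485 * isp0_over_ipa + 0.086


@dataclass(frozen=True)
class CycleStats:
    n_cycles: int
    i_pa_mean: float
    i_pa_sd: float
    i_pc_mean: float
    i_pc_sd: float
    ratio_mean: float
    ratio_sd: float


def summarize_cycles(peaks: list[CvPeaks]) -> CycleStats:
    """Mean +/- sample SD of peak currents and the Nicholson ratio across cycles."""
    if len(peaks) < 2:
        raise InsufficientEventsError(f"need >= 2 cycles, got {len(peaks)}")
    i_pa = np.array([p.i_pa for p in peaks])
    i_pc = np.array([p.i_pc for p in peaks])
    ratio = np.array([nicholson_ratio(p.i_pc0 / p.i_pa, p.i_sp0 / p.i_pa)
                      for p in peaks])
    return CycleStats(
        n_cycles=len(peaks),
        i_pa_mean=float(i_pa.mean()), i_pa_sd=float(i_pa.std(ddof=1)),
        i_pc_mean=float(i_pc.mean()), i_pc_sd=float(i_pc.std(ddof=1)),
        ratio_mean=float(ratio.mean()), ratio_sd=float(ratio.std(ddof=1)))


def cpe_impedance(Q: float, n: float, omega: np.ndarray) -> np.ndarray:
    """Constant-phase-element impedance 1/(Q (j w)^n)."""
    return 1.0 / (Q * (1j * omega) ** n)


def warburg_impedance(sigma_w: float, omega: np.ndarray) -> np.ndarray:
    """Semi-infinite Warburg impedance sigma/sqrt(j w) (principal branch).

    Equivalent to sigma (1 - j)/sqrt(2 w): magnitude ~ 1/sqrt(w), phase -45 deg.
    """
    return sigma_w / np.sqrt(1j * omega)


def circuit_impedance(params: CircuitParams, frequency: float | np.ndarray) -> np.ndarray:
    """Model impedance of R1 + (R2||CPE2) + (R3||CPE3) + Warburg at given Hz."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ParameterError("frequency must be > 0")
    omega = 2 * np.pi * f
    z = np.full(f.shape, params.R1, dtype=complex)
    for R, Q, n in ((params.R2, params.Q2, params.n2),
                    (params.R3, params.Q3, params.n3)):
        z_cpe = cpe_impedance(Q, n, omega)
        if R > 0:
            z += 1.0 / (1.0 / R + 1.0 / z_cpe)
        # R = 0 shorts the block
    z += warburg_impedance(params.sigma_w, omega)
    return z if z.shape else complex(z)


@dataclass(frozen=True)
class CircuitFit:
    params: CircuitParams
    residual_norm: float
    converged: bool
    n_points: int
    at_bounds: tuple[str, ...] = ()


_PARAM_NAMES = ("R1", "R2", "Q2", "n2", "R3", "Q3", "n3", "sigma_w")


def fit_circuit(spectrum: ImpedanceSpectrum, init: CircuitParams) -> CircuitFit:
    """Least-squares circuit fit on stacked (Re, Im) residuals weighted by 1/|Z|.

    Bounds enforce passivity (R >= 0, Q/sigma > 0, 0 <= n <= 1).  The fit is
    deterministic given ``init``.  Elements pinned at a bound are reported in
    ``at_bounds`` with a warning (typical for degenerate, e.g. purely
    resistive, data).  Non-convergence raises, carrying the last iterate.
    """
    f = spectrum.frequency
    if f.size < 10:
        raise InputError(f"need >= 10 frequencies, got {f.size}")
    if np.log10(f.max() / f.min()) < 2:
        raise InputError("spectrum must span >= 2 decades of frequency")
    z_meas = spectrum.z
    w = 1.0 / np.maximum(np.abs(z_meas), 1e-300)

    lb = np.array([0.0, 0.0, 1e-15, 0.0, 0.0, 1e-15, 0.0, 1e-15])
    ub = np.array([np.inf, np.inf, np.inf, 1.0, np.inf, np.inf, 1.0, np.inf])

    def residuals(x):
        z = circuit_impedance(CircuitParams.from_array(x), f)
        return np.concatenate([(z.real - z_meas.real) * w,
                               (z.imag - z_meas.imag) * w])

    x0 = np.clip(init.as_array(), lb, ub)
    res = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20_000)
    fitted = CircuitParams.from_array(res.x)
    if not res.success:
        raise FitConvergenceError(f"circuit fit did not converge: {res.message}",
                                  last_params=fitted)
    finite_ub = np.where(np.isfinite(ub), ub, np.inf)
    pinned = tuple(name for name, v, lo, hi in
                   zip(_PARAM_NAMES, res.x, lb, finite_ub)
                   if np.isclose(v, lo, rtol=1e-6, atol=1e-12)
                   or (np.isfinite(hi) and np.isclose(v, hi, rtol=1e-6)))
    if pinned:
        warnings.warn(f"fitted parameters pinned at bounds: {pinned}", stacklevel=2)
    return CircuitFit(params=fitted, residual_norm=float(np.linalg.norm(res.fun)),
                      converged=True, n_points=int(f.size), at_bounds=pinned)


@dataclass(frozen=True)
class SpectrumStats:
    label: str
    z_real_range: tuple[float, float]
    z_imag_range: tuple[float, float]
    mean_magnitude: float
    max_magnitude: float
    min_magnitude: float
    mean_phase_deg: float


@dataclass(frozen=True)
class SpectrumComparison:
    per_label: dict[str, SpectrumStats]
    percent_difference: float | None  # 100*(mean2 - mean1)/mean1 for two labels


def summarize_spectrum(spectra: dict[str, ImpedanceSpectrum]) -> SpectrumComparison:
    """Per-label impedance summary; percent |Z| difference for exactly two labels.

    The first label (insertion order) is the reference; percent difference is
    100 * (mean|Z|_2 - mean|Z|_1) / mean|Z|_1.
    """
    if not spectra:
        raise InputError("need at least one spectrum")
    stats: dict[str, SpectrumStats] = {}
    for label, sp in spectra.items():
        mag = sp.magnitude
        stats[label] = SpectrumStats(
            label=label,
            z_real_range=(float(sp.z_real.min()), float(sp.z_real.max())),
            z_imag_range=(float(sp.z_imag.min()), float(sp.z_imag.max())),
            mean_magnitude=float(mag.mean()),
            max_magnitude=float(mag.max()),
            min_magnitude=float(mag.min()),
            mean_phase_deg=float(sp.phase_deg.mean()))
    pct = None
    if len(stats) == 2:
        (_, ref), (_, other) = stats.items()
        pct = 100.0 * (other.mean_magnitude - ref.mean_magnitude) / ref.mean_magnitude
    return SpectrumComparison(per_label=stats, percent_difference=pct)


def synthesize_voltammogram(n_points: int = 400, e_min: float = -5.0,
                            e_max: float = 5.0, i_pa: float = 285.0,
                            e_peak: float = 1.5, width: float = 0.8,
                            capacitive: float = 20.0, noise_sd: float = 0.0,
                            seed: int = 0, cycle_index: int = 0,
                            scan_rate: float = 100.0) -> Voltammogram:
    """Synthetic single-cycle voltammogram with Gaussian faradaic peaks.

    Forward sweep carries a Gaussian anodic peak of height ``i_pa`` at
    ``e_peak``; the reverse sweep mirrors it as a cathodic peak; a constant
    capacitive offset of +/- ``capacitive`` uA follows the sweep direction.
    Synthetic stand-in for instrument cycles, used for testing and the
    cycle-statistics pipeline.
    """
    rng = np.random.default_rng(seed)
    half = n_points // 2
    up = np.linspace(e_min, e_max, half)
    down = np.linspace(e_max, e_min, n_points - half + 1)[1:]
    p = np.concatenate([up, down])
    i = np.empty_like(p)
    gauss = lambda e, mu: np.exp(-((e - mu) ** 2) / (2 * width ** 2))
    i[:half] = capacitive + i_pa * gauss(up, e_peak)
    i[half:] = -capacitive - i_pa * gauss(down, -e_peak)
    if noise_sd > 0:
        i = i + rng.normal(0, noise_sd, size=i.size)
    return Voltammogram(potential=p, current=i, cycle_index=cycle_index,
                        scan_rate=scan_rate)
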