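"""Wavelength-dependent photoresponse modelling.

Bacteriorhodopsin's retinal chromophore absorbs maximally near green
wavelengths; absorbing a photon stores the photon energy minus the
retinal isomerization cost (about 20 kcal/mol) and drives the proton
pumping that produces the measured voltage response.  The per-wavelength
response amplitude is modelled as a Gaussian sensitivity curve

    S(lambda) = A0 * exp(-(lambda - lambda_max)^2 / (2 sigma^2))

and the amplitude hierarchy check verifies the characteristic ordering
green > blue ~ yellow > red.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InputError, NonIdentifiableError, ParameterError

# CODATA constants; thermochemical calorie.
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s
AVOGADRO = 6.02214076e23  # 1/mol
JOULE_PER_KCAL = 4184.0

#: Default retinal 11-cis -> all-trans isomerization energy, kcal/mol.
ISOMERIZATION_KCAL_MOL = 20.0


@dataclass(frozen=True)
class EnergyResult:
    wavelength: float  # nm
    photon_energy: float  # kcal/mol
    isomerization_energy: float  # kcal/mol
    stored_energy: float  # kcal/mol
    negative_stored: bool = False  # flagged when photon < isomerization


@dataclass(frozen=True)
class SensitivityModel:
    """Gaussian wavelength-sensitivity curve S(lambda)."""

    A0: float  # mV, peak response
    lambda_max: float  # nm, peak sensitivity wavelength
    sigma: float  # nm, curve width
    rss: float = 0.0  # residual sum of squares of the fit

    def __call__(self, wavelength: float | np.ndarray) -> float | np.ndarray:
        lam = np.asarray(wavelength, dtype=float)
        out = self.A0 * np.exp(-((lam - self.lambda_max) ** 2) / (2 * self.sigma ** 2))
        return float(out) if np.isscalar(wavelength) else out


def photon_energy(wavelength: float, rounded: bool = False) -> float:
    """Molar photon energy h*c*N_A/lambda in kcal/mol (wavelength in nm).

    ``rounded=True`` rounds to the nearest integer kcal/mol, matching the
    convention of quoting green-light photons as ~55 kcal/mol.
    """
    if wavelength <= 0:
        raise ParameterError(f"wavelength must be > 0 nm, got {wavelength}")
    e = PLANCK_H * SPEED_OF_LIGHT * AVOGADRO / (wavelength * 1e-9) / JOULE_PER_KCAL
    return float(round(e)) if rounded else e


def stored_energy(wavelength: float,
                  isomerization: float = ISOMERIZATION_KCAL_MOL,
                  rounded: bool = False) -> EnergyResult:
    """Energy stored after photoisomerization: photon minus isomerization cost.

    With ``rounded=True`` the photon energy is first rounded to integer
    kcal/mol (so 520 nm gives exactly 55 - 20 = 35); the default keeps full
    precision (54.98 - 20 = 34.98, a 0.02 kcal/mol difference from the
    rounded figure).  A negative balance is allowed but flagged.
    """
    if isomerization < 0:
        raise ParameterError(f"isomerization energy must be >= 0, got {isomerization}")
    e_photon = photon_energy(wavelength, rounded=rounded)
    stored = e_photon - isomerization
    return EnergyResult(wavelength=wavelength, photon_energy=e_photon,
                        isomerization_energy=isomerization, stored_energy=stored,
                        negative_stored=stored < 0)


def fit_sensitivity(points: list[tuple[float, float]]) -> SensitivityModel:
    """Least-squares Gaussian fit to (wavelength nm, amplitude mV) points.

    Deterministic initializer: A0 = max amplitude, lambda_max = wavelength of
    the max amplitude, sigma = half the wavelength span.  Requires >= 3
    distinct wavelengths and positive amplitudes; all-equal amplitudes are
    rejected as non-identifiable (any sufficiently wide Gaussian fits).
    """
    pts = [(float(l), float(a)) for l, a in points]
    lams = np.array([p[0] for p in pts])
    amps = np.array([p[1] for p in pts])
    if len(set(lams.tolist())) < 3:
        raise InputError(f"need >= 3 distinct wavelengths, got {len(set(lams.tolist()))}")
    if np.any(amps <= 0):
        raise InputError("amplitudes must be > 0")
    if np.allclose(amps, amps[0]):
        raise NonIdentifiableError("all amplitudes equal; Gaussian width not identifiable")

    i_max = int(np.argmax(amps))
    span = float(lams.max() - lams.min())
    p0 = [float(amps[i_max]), float(lams[i_max]), span / 2.0]

    def model(lam, a0, lmax, sig):
        return a0 * np.exp(-((lam - lmax) ** 2) / (2 * sig ** 2))

    import warnings as _warnings
    from scipy.optimize import OptimizeWarning
    with _warnings.catch_warnings():
        # with 3 points the fit is exact and the covariance is singular
        _warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(model, lams, amps, p0=p0,
                            bounds=([1e-12, lams.min() - 10 * span, 1e-6],
                                    [np.inf, lams.max() + 10 * span, np.inf]),
                            maxfev=20_000)
    a0, lmax, sig = (float(v) for v in popt)
    rss = float(np.sum((model(lams, a0, lmax, sig) - amps) ** 2))
    return SensitivityModel(A0=a0, lambda_max=lmax, sigma=abs(sig), rss=rss)


def check_hierarchy(amplitudes: dict[str, float],
                    tolerance: float = 0.20) -> tuple[list[str], bool]:
    """Check the green > blue ~ yellow > red amplitude hierarchy.

    Returns the conditions sorted by descending amplitude and a boolean that
    is true iff green exceeds both blue and yellow, blue and yellow agree
    within ``tolerance`` (relative to their larger value), and red is below
    both blue and yellow.
    """
    required = {"green", "blue", "yellow", "red"}
    missing = required - set(amplitudes)
    if missing:
        raise InputError(f"missing condition(s): {sorted(missing)}")
    g, b, y, r = (amplitudes[c] for c in ("green", "blue", "yellow", "red"))
    order = sorted(required, key=lambda c: -amplitudes[c])
    close = abs(b - y) <= tolerance * max(abs(b), abs(y))
    ok = (g > b) and (g > y) and close and (r < b) and (r < y)
    return order, ok
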