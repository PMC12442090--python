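"""Boolean classification of light responses and the optimal-light decision
hierarchy.

Per-condition response statistics (mean amplitude A, amplitude SD sigma_A,
mean period P, period SD sigma_P) are reduced to boolean predicates:

* response strength — strong (A >= theta_H), medium (theta_L <= A < theta_H)
  or weak (A < theta_L); exactly one holds;
* period stability — (P < P_threshold) AND (sigma_P < sigma_P_max);
* complex pattern — (A > theta_L) AND (sigma_A < sigma_A_factor * A)
  AND (P < P_threshold).

The optimal-light selector maps the four per-wavelength response bits to a
single label by a fixed priority: Green if green responds at all; else
Blue-Yellow if both blue and yellow respond; else Blue; else Yellow; else
Red.  Enumerating all 2^4 input combinations yields the 16-row truth table
in which Green is optimal in 8 cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .exceptions import InputError, ParameterError

OPTIMAL_LABELS = ("Green", "Blue-Yellow", "Blue", "Yellow", "Red")


@dataclass(frozen=True)
class BooleanConfig:
    """Thresholds for the boolean predicates (defaults are the published ones)."""

    theta_H: float = 5.0  # mV, strong-response threshold
    theta_L: float = 1.0  # mV, medium/weak boundary
    P_threshold: float = 650.0  # s, period-stability bound
    sigma_P_max: float = 20.0  # s, period-SD bound
    sigma_A_factor: float = 0.3  # dimensionless, amplitude-SD bound factor
    #: How the per-wavelength response bit R_x is derived from an amplitude:
    #: "medium_or_strong" (A >= theta_L, the default) or "strong" (A >= theta_H).
    response_bit_rule: str = "medium_or_strong"

    def __post_init__(self) -> None:
        if not (self.theta_H > self.theta_L > 0):
            raise ParameterError(
                f"require theta_H > theta_L > 0, got ({self.theta_H}, {self.theta_L})")
        if self.P_threshold <= 0:
            raise ParameterError(f"P_threshold must be > 0, got {self.P_threshold}")
        if self.response_bit_rule not in ("medium_or_strong", "strong"):
            raise ParameterError(f"unknown response_bit_rule {self.response_bit_rule!r}")


@dataclass(frozen=True)
class ConditionFlags:
    condition: str
    strong: bool
    medium: bool
    weak: bool
    stable: bool
    complex: bool

    def __post_init__(self) -> None:
        if sum((self.strong, self.medium, self.weak)) != 1:
            raise ParameterError("exactly one of strong/medium/weak must hold")


@dataclass(frozen=True)
class TruthTable:
    """All 16 (green, blue, yellow, red) bit combinations with optimal labels."""

    rows: tuple[tuple[int, int, int, int, str], ...]


def classify_amplitude(amplitude: float, cfg: BooleanConfig = BooleanConfig()) -> str:
    """Classify a response amplitude as 'strong', 'medium' or 'weak'."""
    if amplitude < 0:
        raise InputError(f"amplitude must be >= 0, got {amplitude}")
    if amplitude >= cfg.theta_H:
        return "strong"
    if amplitude >= cfg.theta_L:
        return "medium"
    return "weak"


def is_stable(period: float, sigma_P: float,
              cfg: BooleanConfig = BooleanConfig()) -> bool:
    """Period stability: (P < P_threshold) AND (sigma_P < sigma_P_max), both strict."""
    return (period < cfg.P_threshold) and (sigma_P < cfg.sigma_P_max)


def is_complex(amplitude: float, sigma_A: float, period: float,
               cfg: BooleanConfig = BooleanConfig()) -> bool:
    """Complex pattern: (A > theta_L) AND (sigma_A < factor*A) AND (P < P_threshold)."""
    return (amplitude > cfg.theta_L) and (sigma_A < cfg.sigma_A_factor * amplitude) \
        and (period < cfg.P_threshold)


def optimal_light(green: int, blue: int, yellow: int, red: int) -> str:
    """Hierarchical optimal-light decision on the four response bits.

    Green dominates whenever present; blue AND yellow together form the
    combined Blue-Yellow optimum; then blue alone, yellow alone, and Red as
    the default (including the all-zero row).
    """
    if green:
        return "Green"
    if blue and yellow:
        return "Blue-Yellow"
    if blue:
        return "Blue"
    if yellow:
        return "Yellow"
    return "Red"


def truth_table(cfg: BooleanConfig = BooleanConfig()) -> TruthTable:
    """Enumerate all 2^4 response-bit combinations in ascending binary order."""
    rows = tuple((g, b, y, r, optimal_light(g, b, y, r))
                 for g, b, y, r in product((0, 1), repeat=4))
    return TruthTable(rows=rows)


def response_bit(amplitude: float, cfg: BooleanConfig = BooleanConfig()) -> int:
    """Per-wavelength response bit R_x from a mean amplitude (see config rule)."""
    if cfg.response_bit_rule == "strong":
        return int(amplitude >= cfg.theta_H)
    return int(amplitude >= cfg.theta_L)


def classify_all(summaries: dict[str, tuple[float, float, float, float]],
                 cfg: BooleanConfig = BooleanConfig()) -> list[ConditionFlags]:
    """Apply all three predicates to per-condition (A, sigma_A, P, sigma_P) stats."""
    if not summaries:
        raise InputError("need at least one condition")
    out: list[ConditionFlags] = []
    for cond, stats in summaries.items():
        if len(stats) != 4 or any(s is None for s in stats):
            raise InputError(f"condition {cond!r} must supply (A, sigma_A, P, sigma_P)")
        A, sA, P, sP = (float(s) for s in stats)
        tier = classify_amplitude(A, cfg)
        out.append(ConditionFlags(
            condition=cond,
            strong=tier == "strong", medium=tier == "medium", weak=tier == "weak",
            stable=is_stable(P, sP, cfg),
            complex=is_complex(A, sA, P, cfg)))
    return out
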