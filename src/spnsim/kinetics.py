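"""Rate-law primitives: guarded exponentiation, Hill activation/repression,
the inducer-repressor transcription law, and first-order linear terms.

The Hill-type laws evaluate ``base ** exponent`` with state-dependent bases.
In IEEE arithmetic that expression is computed as exp(exponent * log(base))
for non-integer exponents, so an integrator overshooting a concentration to a
slightly negative value yields NaN and kills the run.  The guarded variant
replaces every state-dependent base by ``max(eps, base)`` (default
eps = 1e-80), which makes all primitives total functions of finite inputs.
Bases that are strictly positive constants (the half-saturation constants)
are never guarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GuardConfig",
    "RegulatorSpec",
    "pow_guarded",
    "hill_activation",
    "hill_repression",
    "transcription_inducer_repressor",
    "linear_rate",
    "LN2",
]

LN2 = math.log(2.0)

_LINEAR_KINDS = ("translation", "decay", "transfer", "conversion")


@dataclass(frozen=True)
class GuardConfig:
    """Guard floor for state-dependent exponentiation bases."""

    epsilon: float = 1e-80
    enabled: bool = True

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError(f"guard epsilon must be positive, got {self.epsilon}")


#: guards enabled with the default floor
GUARD_DEFAULT = GuardConfig()
#: unguarded evaluation, reproducing the raw IEEE failure mode
GUARD_OFF = GuardConfig(enabled=False)


@dataclass(frozen=True)
class RegulatorSpec:
    """One regulator edge: half-saturation ``kappa``, cooperativity ``nu``."""

    species: str
    kappa: float
    nu: float
    mode: str = "activator"

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not self.nu >= 1:
            raise ValueError(f"nu must be >= 1, got {self.nu}")
        if self.mode not in ("activator", "repressor"):
            raise ValueError(f"unknown regulator mode {self.mode!r}")


def _raw_pow(base: float, exponent: float) -> float:
    """IEEE semantics of base**exponent: NaN for negative base, fractional exponent."""
    if base >= 0.0:
        return base ** exponent
    if exponent == math.floor(exponent):
        return base ** exponent
    return math.nan


def pow_guarded(base: float, exponent: float, guard: GuardConfig = GUARD_DEFAULT) -> float:
    """``max(eps, base) ** exponent`` when guarded, plain power otherwise."""
    if guard.enabled:
        return max(guard.epsilon, base) ** exponent
    return _raw_pow(base, exponent)


def hill_activation(
    x: float, kappa: float, nu: float, guard: GuardConfig = GUARD_DEFAULT
) -> float:
    """Activating Hill function phi(x) = x^nu / (kappa^nu + x^nu), in [0, 1].

    The half-saturation constant ``kappa`` is a positive constant and its
    power is never guarded; only the state-dependent base ``x`` is.
    """
    xn = pow_guarded(x, nu, guard)
    return xn / (kappa ** nu + xn)


def hill_repression(
    x: float, kappa: float, nu: float, guard: GuardConfig = GUARD_DEFAULT
) -> float:
    """Repressing Hill function psi(x) = 1 - phi(x).

    The guarded variant clamps the outer factor to >= eps as well, so the
    result can never go negative from accumulated round-off.
    """
    r = 1.0 - hill_activation(x, kappa, nu, guard)
    if guard.enabled:
        return max(guard.epsilon, r)
    return r


def transcription_inducer_repressor(
    V: float,
    I: float,
    R: float,
    inducer: RegulatorSpec,
    repressor: RegulatorSpec,
    guard: GuardConfig = GUARD_DEFAULT,
) -> float:
    """Transcription rate for an inducer-repressor pair.

    The repressor attenuates the inducer multiplicatively: the effective
    inducer is Ibar = I * psi(R), and the rate is

        V * Ibar^h1 / (k1^h1 + Ibar^h1)

    with every base that can approach zero wrapped by max(eps, .) and the
    constant bases k1, k2 left bare.
    """
    if V < 0:
        raise ValueError(f"maximum rate must be non-negative, got {V}")
    psi = hill_repression(R, repressor.kappa, repressor.nu, guard)
    ibar = I * psi
    num = pow_guarded(ibar, inducer.nu, guard)
    return V * num / (inducer.kappa ** inducer.nu + num)


def linear_rate(kind: str, rate_constant: float, x: float) -> float:
    """First-order mass-action term ``rate_constant * x``.

    For decay parameterized by a half-life H, pass ``rate_constant = ln(2)/H``
    (see :func:`decay_constant`).
    """
    if kind not in _LINEAR_KINDS:
        raise ValueError(f"unknown linear rate kind {kind!r}")
    if rate_constant < 0:
        raise ValueError(f"rate constant must be non-negative, got {rate_constant}")
    return rate_constant * x


def decay_constant(half_life: float) -> float:
    """First-order rate constant ln(2)/H for a species with half-life H."""
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return LN2 / half_life
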