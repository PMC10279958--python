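"""Rate-law primitives: guard semantics, Hill laws, monotonicity, fuzzing."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from spnsim.kinetics import (
    GuardConfig,
    RegulatorSpec,
    decay_constant,
    hill_activation,
    hill_repression,
    linear_rate,
    pow_guarded,
    transcription_inducer_repressor,
)

GUARD = GuardConfig()
OFF = GuardConfig(enabled=False)

conc = st.floats(min_value=-1e-6, max_value=2.0, allow_nan=False)
kappas = st.floats(min_value=1e-3, max_value=1.0)
nus = st.floats(min_value=1.0, max_value=10.0)


class TestPowGuarded:
    @pytest.mark.parametrize(
        "base,expo,expected",
        [
            (0.5, 2.0, 0.25),            # guard inactive for positive base
            (-1e-12, 2.5, 1e-200),       # max(eps, base) = eps, eps**2.5
            (0.0, 0.5, 1e-40),           # eps**0.5
        ],
    )
    def test_guarded_values(self, base, expo, expected):
        assert pow_guarded(base, expo, GUARD) == pytest.approx(expected, rel=1e-12)

    def test_unguarded_negative_base_fractional_exponent_is_nan(self):
        assert math.isnan(pow_guarded(-1e-12, 2.5, OFF))

    def test_unguarded_integer_exponent_is_plain_power(self):
        assert pow_guarded(-2.0, 2.0, OFF) == 4.0

    def test_zero_epsilon_rejected(self):
        with pytest.raises(ValueError):
            GuardConfig(epsilon=0.0)


class TestHill:
    @given(kappa=kappas, nu=nus)
    def test_half_saturation_point(self, kappa, nu):
        assert hill_activation(kappa, kappa, nu, GUARD) == pytest.approx(0.5)
        assert hill_repression(kappa, kappa, nu, GUARD) == pytest.approx(0.5)

    def test_zero_inducer_is_essentially_off(self):
        assert hill_activation(0.0, 0.1, 2.0, GUARD) == pytest.approx(0.0, abs=1e-100)

    def test_unguarded_direct_value(self):
        assert hill_activation(1.0, 0.5, 1.0, OFF) == pytest.approx(1.0 / 1.5)

    def test_repression_limits(self):
        assert hill_repression(0.0, 0.1, 2.0, GUARD) == pytest.approx(1.0)
        big = hill_repression(1e12, 0.1, 2.0, GUARD)
        assert big == GUARD.epsilon  # clamped, never negative or NaN

    @given(x=st.floats(min_value=0, max_value=10), kappa=kappas, nu=nus)
    def test_activation_within_unit_interval_and_monotone(self, x, kappa, nu):
        lo = hill_activation(x, kappa, nu, GUARD)
        hi = hill_activation(x + 0.1, kappa, nu, GUARD)
        assert 0.0 <= lo <= 1.0
        assert hi >= lo - 1e-15


class TestTranscriptionLaw:
    def kI(self, kappa=1.0, nu=1.0):
        return RegulatorSpec("I", kappa, nu, "activator")

    def kR(self, kappa=1.0, nu=1.0):
        return RegulatorSpec("R", kappa, nu, "repressor")

    def test_michaelis_form_without_repressor(self):
        rate = transcription_inducer_repressor(
            2.0, 1.0, 0.0, self.kI(kappa=0.5), self.kR(), GUARD
        )
        assert rate == pytest.approx(2.0 * 1.0 / (0.5 + 1.0))

    def test_zero_inducer_is_essentially_zero(self):
        rate = transcription_inducer_repressor(1.0, 0.0, 0.3, self.kI(), self.kR(), GUARD)
        assert rate <= 1e-79

    def test_hand_evaluated_value(self):
        # V=1, I=1, R=k2, h1=h2=1, k1=1: psi=0.5, Ibar=0.5, rate=1/3
        rate = transcription_inducer_repressor(
            1.0, 1.0, 0.7, self.kI(), self.kR(kappa=0.7), GUARD
        )
        assert rate == pytest.approx(1.0 / 3.0)

    @given(I=st.floats(0, 2), R=st.floats(0, 2))
    def test_monotone_in_inducer_and_repressor(self, I, R):
        kI, kR = self.kI(0.3, 2.0), self.kR(0.2, 3.0)
        base = transcription_inducer_repressor(1.0, I, R, kI, kR, GUARD)
        more_i = transcription_inducer_repressor(1.0, I + 0.1, R, kI, kR, GUARD)
        more_r = transcription_inducer_repressor(1.0, I, R + 0.1, kI, kR, GUARD)
        assert more_i >= base - 1e-15
        assert more_r <= base + 1e-15

    def test_unguarded_negative_inducer_gives_nan(self):
        rate = transcription_inducer_repressor(
            1.0, -1e-9, 0.0, self.kI(nu=2.5), self.kR(), OFF
        )
        assert math.isnan(rate)


class TestGuardProperties:
    @given(x=conc, kappa=kappas, nu=nus)
    def test_guarded_primitives_always_finite(self, x, kappa, nu):
        for fn in (hill_activation, hill_repression):
            assert math.isfinite(fn(x, kappa, nu, GUARD))
        kI = RegulatorSpec("I", kappa, nu)
        kR = RegulatorSpec("R", kappa, max(nu / 2, 1.0))
        assert math.isfinite(
            transcription_inducer_repressor(1.0, x, x, kI, kR, GUARD)
        )

    @given(x=st.floats(min_value=1e-6, max_value=2.0), kappa=kappas, nu=nus)
    def test_guard_transparent_for_healthy_concentrations(self, x, kappa, nu):
        for fn in (hill_activation, hill_repression):
            a, b = fn(x, kappa, nu, GUARD), fn(x, kappa, nu, OFF)
            assert a == pytest.approx(b, rel=1e-12)


class TestLinearRate:
    def test_half_life_decay_constant(self):
        assert linear_rate("decay", decay_constant(5.0), 1.0) == pytest.approx(
            math.log(2) / 5
        )

    def test_zero_rate_and_zero_substrate(self):
        assert linear_rate("transfer", 0.0, 1.23) == 0.0
        assert linear_rate("translation", 2.0, 0.0) == 0.0

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            linear_rate("decay", -0.1, 1.0)
        with pytest.raises(ValueError):
            linear_rate("unknown-kind", 0.1, 1.0)
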