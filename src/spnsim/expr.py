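"""Tiny expression AST for kinetic rate laws.

Rate laws live in three places that must agree exactly: the compiled ODE
kernel, the reaction registry used for generic evaluation, and the MathML
inside exported SBML.  This module is the single algebraic representation
behind the latter two; tests assert its evaluation matches the kernel.

Node types: Num, Sym (a species, parameter, or derived-total identifier),
Add, Mul, Sub, Div, Pow, Max.  ``Max`` encodes the guard max(eps, x); SBML
L3V1 has no max operator so it is serialized as piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Num", "Sym", "Add", "Mul", "Sub", "Div", "Pow", "Max", "Expr"]


class Expr:
    def ev(self, env: dict) -> float:
        raise NotImplementedError

    def symbols(self) -> set:
        raise NotImplementedError

    # operator sugar keeps the builder readable
    def __add__(self, other):
        return Add(self, _wrap(other))

    def __radd__(self, other):
        return Add(_wrap(other), self)

    def __mul__(self, other):
        return Mul(self, _wrap(other))

    def __rmul__(self, other):
        return Mul(_wrap(other), self)

    def __sub__(self, other):
        return Sub(self, _wrap(other))

    def __rsub__(self, other):
        return Sub(_wrap(other), self)

    def __truediv__(self, other):
        return Div(self, _wrap(other))

    def __rtruediv__(self, other):
        return Div(_wrap(other), self)

    def __pow__(self, other):
        return Pow(self, _wrap(other))


def _wrap(x) -> Expr:
    return x if isinstance(x, Expr) else Num(float(x))


@dataclass(frozen=True)
class Num(Expr):
    value: float

    def ev(self, env):
        return self.value

    def symbols(self):
        return set()


@dataclass(frozen=True)
class Sym(Expr):
    name: str

    def ev(self, env):
        return env[self.name]

    def symbols(self):
        return {self.name}


class _Bin(Expr):
    def __init__(self, a: Expr, b: Expr):
        self.a = _wrap(a)
        self.b = _wrap(b)

    def symbols(self):
        return self.a.symbols() | self.b.symbols()

    def __repr__(self):
        return f"{type(self).__name__}({self.a!r}, {self.b!r})"


class Add(_Bin):
    def ev(self, env):
        return self.a.ev(env) + self.b.ev(env)


class Mul(_Bin):
    def ev(self, env):
        return self.a.ev(env) * self.b.ev(env)


class Sub(_Bin):
    def ev(self, env):
        return self.a.ev(env) - self.b.ev(env)


class Div(_Bin):
    def ev(self, env):
        return self.a.ev(env) / self.b.ev(env)


class Pow(_Bin):
    def ev(self, env):
        import math

        base = self.a.ev(env)
        expo = self.b.ev(env)
        if base < 0 and expo != math.floor(expo):
            return math.nan
        return base ** expo


class Max(_Bin):
    def ev(self, env):
        return max(self.a.ev(env), self.b.ev(env))
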