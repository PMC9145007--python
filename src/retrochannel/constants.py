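"""Closed-form retroactivity constants for the five circuit topologies.

Each constant is the erasure probability A = P(Z1(ts) = 0 | I1(t0) = 1) of
the Z-channel induced by one circuit:

* ``a0``      -- isolated SISO:            A0 = (1+k0) c2 / (c1 + (1+k0) c2)
* ``aN``      -- SISO with N sites:        AN = 1 - c1 / [(1+k0) c2 + (1 + sum_j 1/k3j) c1]
* ``aN_noncyclic`` -- the c2 = 0 variant:  AN = 1 - 1 / (1 + sum_j 1/k3j)
* ``b_const`` -- MIMO cross-branch term B (fast-binding closed form)
* ``a0_mimo`` -- isolated MIMO mixture:    A0 * P02 + B * P12
* ``aN_mimo`` -- loaded MIMO mixture:      AN * P02 + G * P12
* ``aQ_mac``  -- two SISO sharing sites:   the AN form with Q of the N terms

with volume-scaled dissociation constants k0 = k0- * omega / k0+ and
k3j = k3j- * omega / k3j+.  The parse of the flattened fractions is pinned
by four limit facts, all asserted in the test suite: A0(c2=0) = 0;
A0, AN -> 1 as c2 -> inf; AN(N=0) = A0; AN -> 1 as N -> inf with equal k3.

The closed forms agree with the exact CME channel in the fast-binding
regime k0+, k0- >> c1, c2; outside it they are asymptotic, and ``b_const``
emits a ``RegimeWarning``.  No closed form exists for G; it is extracted
numerically from the CME (``g_const_numeric``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import sympy

from . import cme
from .networks import RateParameters, Topology, build_model

__all__ = [
    "AConstant",
    "RegimeWarning",
    "a0",
    "aN",
    "aN_noncyclic",
    "b_const",
    "a0_mimo",
    "g_const_numeric",
    "b_const_numeric",
    "aN_mimo",
    "aQ_mac",
    "a0_limit_c2_to_inf",
    "aN_limit_n_to_inf",
]

#: b_const warns when min(k0+, k0-) falls below this multiple of c.
FAST_BINDING_FACTOR = 100.0


class RegimeWarning(UserWarning):
    """A closed form was evaluated outside its validity regime."""


@dataclass(frozen=True)
class AConstant:
    """A retroactivity constant with its provenance.

    ``regime`` is ``"generic"`` for exact-in-regime closed forms,
    ``"fast-binding-asymptotic"`` for forms valid only when binding dwarfs
    catalysis, and ``"cme-numeric"`` for values extracted from the exact
    stationary CME.
    """

    value: float
    model: str
    regime: str
    inputs: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if not -1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"A constant {self.value} outside [0, 1]")
        object.__setattr__(self, "value", min(max(self.value, 0.0), 1.0))

    def __float__(self) -> float:
        return self.value


def _inputs(**kw) -> tuple[tuple[str, object], ...]:
    return tuple(sorted(kw.items()))


def a0(k0: float, c1: float, c2: float) -> AConstant:
    """Isolated-SISO constant A0 = (1+k0) c2 / (c1 + (1+k0) c2)."""
    if k0 < 0 or c1 < 0 or c2 < 0:
        raise ValueError("rates must be non-negative")
    denom = c1 + (1.0 + k0) * c2
    if denom == 0.0:
        raise ValueError("A0 undefined when c1 and c2 are both zero")
    return AConstant(
        (1.0 + k0) * c2 / denom,
        "ISOLATED_SISO",
        "generic",
        _inputs(k0=k0, c1=c1, c2=c2),
    )


def _load_sum(k3_list) -> float:
    k3_list = tuple(float(k) for k in k3_list)
    if any(k3 <= 0 for k3 in k3_list):
        raise ValueError("k3 must be positive (k3 = 0 is an infinite-affinity site)")
    return sum(1.0 / k3 for k3 in k3_list)


def aN(k0: float, c1: float, c2: float, k3_list) -> AConstant:
    """Downstream-loaded constant AN = 1 - c1 / [(1+k0) c2 + (1 + sum 1/k3j) c1]."""
    if k0 < 0 or c1 < 0 or c2 < 0:
        raise ValueError("rates must be non-negative")
    load = _load_sum(k3_list)
    denom = (1.0 + k0) * c2 + (1.0 + load) * c1
    if denom == 0.0:
        raise ValueError("AN undefined when all rates vanish")
    return AConstant(
        1.0 - c1 / denom,
        "SISO_N_DOWNSTREAM",
        "generic",
        _inputs(k0=k0, c1=c1, c2=c2, k3=tuple(k3_list)),
    )


def aN_noncyclic(c1: float, k3_list) -> AConstant:
    """The non-cyclic (c2 = 0) load constant, sum(1/k3j) / (1 + sum(1/k3j))."""
    if c1 <= 0:
        raise ValueError("c1 must be positive")
    load = _load_sum(k3_list)
    return AConstant(
        load / (1.0 + load),
        "SISO_N_DOWNSTREAM",
        "generic",
        _inputs(c1=c1, k3=tuple(k3_list), c2=0.0),
    )


def b_const(
    k0_plus: float, k0_minus: float, c: float, omega: float = 1.0
) -> AConstant:
    """The MIMO cross-branch constant B (equal catalytic rates c1 = c2 = c).

    B = (3 kp^2 + km^2 + 4 km kp + 3 km c + 6 kp c)
      / (5 kp^2 + km^2 + 5 km kp + 3 km c + 8 kp c),  kp = k0+ / omega.

    Valid for fast binding, k0+, k0- >> c; outside that regime a
    ``RegimeWarning`` is emitted and the value is only approximate.
    """
    if k0_plus <= 0 or k0_minus < 0 or c < 0:
        raise ValueError("need k0_plus > 0 and non-negative k0_minus, c")
    kp = k0_plus / omega
    km = k0_minus
    if c > 0 and min(kp, km) < FAST_BINDING_FACTOR * c:
        ratio = min(kp, km) / c
        warnings.warn(
            f"B evaluated outside its fast-binding regime: min(k0+/omega, k0-)/c "
            f"= {ratio:.3g} < {FAST_BINDING_FACTOR:g}",
            RegimeWarning,
            stacklevel=2,
        )
    num = 3 * kp**2 + km**2 + 4 * km * kp + 3 * km * c + 6 * kp * c
    den = 5 * kp**2 + km**2 + 5 * km * kp + 3 * km * c + 8 * kp * c
    return AConstant(
        num / den,
        "ISOLATED_MIMO",
        "fast-binding-asymptotic",
        _inputs(k0_plus=k0_plus, k0_minus=k0_minus, c=c, omega=omega),
    )


def _check_priors(p02: float, p12: float) -> None:
    if p02 < 0 or p12 < 0 or abs(p02 + p12 - 1.0) > 1e-9:
        raise ValueError("(P02, P12) must be a valid binary pmf")


def a0_mimo(a0_value: float, b_value: float, p02: float, p12: float) -> AConstant:
    """Isolated-MIMO constant A0,MIMO = A0 * P02 + B * P12."""
    _check_priors(p02, p12)
    return AConstant(
        float(a0_value) * p02 + float(b_value) * p12,
        "ISOLATED_MIMO",
        "mixture",
        _inputs(a0=float(a0_value), b=float(b_value), p02=p02, p12=p12),
    )


def aN_mimo(aN_value: float, g_value: float, p02: float, p12: float) -> AConstant:
    """Loaded-MIMO constant AN,MIMO = AN * P02 + G * P12."""
    _check_priors(p02, p12)
    return AConstant(
        float(aN_value) * p02 + float(g_value) * p12,
        "MIMO_N_DOWNSTREAM",
        "mixture",
        _inputs(aN=float(aN_value), g=float(g_value), p02=p02, p12=p12),
    )


def aQ_mac(k0: float, c1: float, c2: float, k3_list, q: int) -> AConstant:
    """MAC constant: the AN form keeping only the Q sites bound to branch 1.

    AQ,MAC = 1 - c1 / [(1+k0) c2 + (1 + sum_{j<=Q} 1/k3j) c1]; reduces to A0
    at Q = 0 and to AN at Q = N.
    """
    k3_list = tuple(k3_list)
    if not 0 <= q <= len(k3_list):
        raise ValueError(f"need 0 <= Q <= N = {len(k3_list)}")
    a = aN(k0, c1, c2, k3_list[:q]) if q > 0 else a0(k0, c1, c2)
    return AConstant(
        a.value,
        "TWO_SISO_MAC",
        "generic",
        _inputs(k0=k0, c1=c1, c2=c2, k3=k3_list, q=q),
    )


@lru_cache(maxsize=512)
def _cme_branch_conditional(
    topology: str,
    k0_plus: float,
    k0_minus: float,
    c1: float,
    c2: float,
    k3_plus: tuple[float, ...],
    k3_minus: tuple[float, ...],
    omega: float,
) -> float:
    rates = RateParameters(k0_plus, k0_minus, c1, c2, k3_plus, k3_minus, omega)
    model = build_model(Topology(topology), rates, n_downstream=len(k3_plus))
    return cme.prob_z1_zero(model, 1, 1)


def b_const_numeric(rates: RateParameters) -> AConstant:
    """B extracted exactly from the CME: P(Z1=0 | i1=1, i2=1), isolated MIMO."""
    val = _cme_branch_conditional(
        Topology.ISOLATED_MIMO.value,
        rates.k0_plus,
        rates.k0_minus,
        rates.c1,
        rates.c2,
        (),
        (),
        rates.omega,
    )
    return AConstant(val, "ISOLATED_MIMO", "cme-numeric")


def g_const_numeric(rates: RateParameters, n_downstream: int | None = None) -> AConstant:
    """G extracted from the CME: P(Z1=0 | i1=1, i2=1) in the loaded MIMO.

    No closed form exists for G; it depends on both the upstream rates and
    the downstream binding rates.  With no downstream sites it collapses to
    the CME-extracted B.  Values are cached per parameter set.
    """
    n = rates.n_sites if n_downstream is None else n_downstream
    val = _cme_branch_conditional(
        Topology.MIMO_N_DOWNSTREAM.value,
        rates.k0_plus,
        rates.k0_minus,
        rates.c1,
        rates.c2,
        rates.k3_plus[:n],
        rates.k3_minus[:n],
        rates.omega,
    )
    return AConstant(val, "MIMO_N_DOWNSTREAM", "cme-numeric")


# -- symbolic limits --------------------------------------------------------

def a0_limit_c2_to_inf(k0: float, c1: float) -> float:
    """lim_{c2 -> inf} A0, evaluated symbolically (equals 1)."""
    c2 = sympy.Symbol("c2", positive=True)
    expr = (1 + k0) * c2 / (c1 + (1 + k0) * c2)
    return float(sympy.limit(expr, c2, sympy.oo))


def aN_limit_n_to_inf(k0: float, c1: float, c2: float, k3: float) -> float:
    """lim_{N -> inf} AN with equal site constants k3 (equals 1)."""
    n = sympy.Symbol("N", positive=True)
    expr = 1 - c1 / ((1 + k0) * c2 + (1 + n / k3) * c1)
    return float(sympy.limit(expr, n, sympy.oo))


def aN_limit_c2_to_inf(k0: float, c1: float, k3_list) -> float:
    """lim_{c2 -> inf} AN (equals 1)."""
    c2 = sympy.Symbol("c2", positive=True)
    load = sum(sympy.Rational(1) / sympy.nsimplify(k3) for k3 in k3_list)
    expr = 1 - c1 / ((1 + k0) * c2 + (1 + load) * c1)
    return float(sympy.limit(expr, c2, sympy.oo))
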