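"""Synthetic parameter sets, symbol ensembles, and canonical test fixtures.

The analysis has no external datasets: its inputs are rate-constant sets in
the regimes the closed-form constants assume, together with binary
concentration on-off-keying symbol priors.  This module draws both, seeded
and reproducibly, so every downstream stage is testable end to end.

Rate regimes:

* ``generic``      -- all rates log-uniform over [1e-2, 1e2] (per base time
  unit); no relation imposed between binding and catalysis.
* ``fast_binding`` -- binding dominates catalysis, min(k0+, k0-) >=
  100 * max(c1, c2); the validity regime of the closed-form constants.
* ``noncyclic``    -- c2 = 0 (no recycling; the upstream loses its cycle).
* ``large_c2``     -- recycling dominates, c2 >= 1e6 * c1 (output instantly
  reconverted; the A -> 1 regime).

Log-uniform sampling is used because the limiting claims span rate ratios
over many orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import RateParameters

__all__ = [
    "ParameterDraw",
    "SymbolPriors",
    "Fixture",
    "sample_rates",
    "symbol_ensemble",
    "prior_grid",
    "fixture_suite",
]

REGIMES = ("generic", "fast_binding", "noncyclic", "large_c2")

#: log10 range for catalytic and binding rates in generic draws.
CATALYTIC_RANGE = (-2.0, 2.0)
#: log10 range of the binding/catalysis ratio in fast-binding draws.
FAST_RATIO_RANGE = (2.0, 3.5)

FAST_BINDING_FACTOR = 100.0


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled rate set with its regime tag and seed."""

    rates: RateParameters
    regime: str
    seed: int

    def __post_init__(self) -> None:
        if not self.satisfies_regime():
            raise ValueError(f"draw violates its {self.regime!r} regime constraint")

    def satisfies_regime(self) -> bool:
        r = self.rates
        if self.regime == "fast_binding":
            c = max(r.c1, r.c2)
            return min(r.k0_plus, r.k0_minus) >= FAST_BINDING_FACTOR * c
        if self.regime == "noncyclic":
            return r.c2 == 0.0
        if self.regime == "large_c2":
            return r.c2 >= 1e6 * r.c1
        return self.regime == "generic"


def _loguniform(rng: np.random.Generator, lo10: float, hi10: float, size=None):
    return 10.0 ** rng.uniform(lo10, hi10, size)


def sample_rates(
    regime: str,
    n_draws: int,
    seed: int,
    n_sites: int = 1,
    omega: float = 1.0,
    equal_catalytic: bool = False,
) -> list[ParameterDraw]:
    """Draw ``n_draws`` rate sets in the given regime, reproducibly by seed.

    ``equal_catalytic`` forces c1 = c2 = c (the extra assumption behind the
    MIMO cross-branch constant B).  Downstream binding pairs are drawn in the
    same regime-appropriate range as the upstream pair.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = CATALYTIC_RANGE
    draws: list[ParameterDraw] = []
    for _ in range(n_draws):
        c1 = float(_loguniform(rng, lo, hi))
        c2 = c1 if equal_catalytic else float(_loguniform(rng, lo, hi))
        if regime == "noncyclic":
            c2 = 0.0
        elif regime == "large_c2":
            c2 = c1 * float(_loguniform(rng, 6.0, 9.0))
        cmax = max(c1, c2)
        if regime == "fast_binding":
            k0p = cmax * float(_loguniform(rng, *FAST_RATIO_RANGE))
            k0m = cmax * float(_loguniform(rng, *FAST_RATIO_RANGE))
            k3p = tuple(
                cmax * float(_loguniform(rng, *FAST_RATIO_RANGE))
                for _ in range(n_sites)
            )
            k3m = tuple(
                cmax * float(_loguniform(rng, *FAST_RATIO_RANGE))
                for _ in range(n_sites)
            )
        else:
            k0p = float(_loguniform(rng, lo, hi))
            k0m = float(_loguniform(rng, lo, hi))
            k3p = tuple(float(_loguniform(rng, lo, hi)) for _ in range(n_sites))
            k3m = tuple(float(_loguniform(rng, lo, hi)) for _ in range(n_sites))
        rates = RateParameters(k0p, k0m, c1, c2, k3p, k3m, omega)
        draws.append(ParameterDraw(rates=rates, regime=regime, seed=seed))
    return draws


@dataclass(frozen=True)
class SymbolPriors:
    """Concentration on-off-keying priors for the two input streams."""

    p01: float
    p11: float
    p02: float
    p12: float

    @property
    def degenerate(self) -> bool:
        """True when an input is deterministic (its MI contribution is 0)."""
        return self.p01 in (0.0, 1.0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p01, self.p11, self.p02, self.p12)


def symbol_ensemble(p01: float = 0.5, p02: float = 0.5) -> SymbolPriors:
    """Complete, normalized prior record for the binary on-off alphabet."""
    for name, p in (("P01", p01), ("P02", p02)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return SymbolPriors(p01, 1.0 - p01, p02, 1.0 - p02)


def prior_grid(n_points: int = 101) -> np.ndarray:
    """Uniform grid of P01 values on [0, 1] for capacity searches."""
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(0.0, 1.0, n_points)


@dataclass(frozen=True)
class Fixture:
    """A named fixture with embedded expected values and their provenance."""

    name: str
    description: str
    rates: RateParameters
    expected: dict = field(default_factory=dict)
    provenance: str = ""


def fixture_suite() -> dict[str, Fixture]:
    """The canonical hand-checkable fixtures consumed by the test suite."""
    unit = RateParameters(1.0, 1.0, 1.0, 1.0)
    fixtures = {
        "siso_unit_rates": Fixture(
            name="siso_unit_rates",
            description=(
                "Isolated SISO at unit rates and unit totals: 3-state chain "
                "I+E -> M -> E+Z -> I+E with hand-solved balance equations."
            ),
            rates=unit,
            expected={
                "n_states": 3,
                "pi": (0.5, 0.25, 0.25),
                "a_hat": 0.75,
            },
            provenance="hand-solved detailed balance of the 3-state cycle",
        ),
        "mimo_statespace": Fixture(
            name="mimo_statespace",
            description=(
                "Isolated MIMO, both symbols 1, one shared enzyme: each branch "
                "occupies {I, M, Z} but the two M states exclude each other."
            ),
            rates=unit,
            expected={"n_states": 8},
            provenance="exhaustive enumeration; 3*3 minus the (M1, M2) clash",
        ),
        "fastbinding_ladder": Fixture(
            name="fastbinding_ladder",
            description=(
                "Unit catalytic rates with binding scaled by 10, 100, 1000 "
                "at fixed dissociation constant k0 = 1: the CME channel "
                "constant converges to the closed form along the ladder."
            ),
            rates=unit,
            expected={
                "scales": (10.0, 100.0, 1000.0),
                "monotone_error": True,
                "top_rung_tol": 1e-3,
            },
            provenance="fast-binding asymptotics of the closed-form constants",
        ),
    }
    return fixtures


def ladder_rates(
    scale: float, c: float = 1.0, n_sites: int = 0, omega: float = 1.0
) -> RateParameters:
    """Rates for one rung of the fast-binding ladder: k0+ = k0- = scale * c.

    The dissociation constant k0 = 1 is held fixed while binding speeds up,
    so the closed-form constants stay put and only the CME value moves.
    """
    k = scale * c
    return RateParameters(k, k, c, c, (k,) * n_sites, (k,) * n_sites, omega)
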