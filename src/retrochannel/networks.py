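"""Mass-action reaction networks for the five signaling-circuit topologies.

Each circuit couples a two-step cyclic enzymatic upstream system

    I + E <=> M -> E + Z,   Z -> I

to zero or more downstream binding sites

    Z + Dj <=> Cj

which sequester the output Z and thereby exert retroactivity (load) on the
upstream system.  Five topologies are supported, mirroring standard
telecommunication channel models:

* ``ISOLATED_SISO``     -- one upstream system, no downstream sites.
* ``SISO_N_DOWNSTREAM`` -- one upstream system broadcasting to N sites (BC).
* ``ISOLATED_MIMO``     -- two upstream branches sharing one enzyme pool.
* ``MIMO_N_DOWNSTREAM`` -- the MIMO circuit with branch-1 output loaded by
  N sites.
* ``TWO_SISO_MAC``      -- two fully independent upstream systems (separate
  enzymes) sharing a pool of N sites, Q of which bind Z1 and N-Q bind Z2
  (multiple-access channel); a site holds at most one complex at a time.

Species are molecule counts in CME mode; dividing by the volume ``omega``
gives the concentrations used by the LNA engine.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Topology",
    "RateParameters",
    "Totals",
    "Reaction",
    "ModelSpec",
    "ConservationLaw",
    "build_model",
    "conservation_laws",
    "sample_mac_allocation",
]


class Topology(str, enum.Enum):
    ISOLATED_SISO = "ISOLATED_SISO"
    SISO_N_DOWNSTREAM = "SISO_N_DOWNSTREAM"
    ISOLATED_MIMO = "ISOLATED_MIMO"
    MIMO_N_DOWNSTREAM = "MIMO_N_DOWNSTREAM"
    TWO_SISO_MAC = "TWO_SISO_MAC"


_TWO_INPUT = {Topology.ISOLATED_MIMO, Topology.MIMO_N_DOWNSTREAM, Topology.TWO_SISO_MAC}
_ISOLATED = {Topology.ISOLATED_SISO, Topology.ISOLATED_MIMO}


@dataclass(frozen=True)
class RateParameters:
    """Mass-action rate constants for one circuit.

    ``k0_plus`` is the I+E association rate (its propensity is scaled by
    1/omega), ``k0_minus`` the M dissociation rate, ``c1`` the catalytic rate
    M -> E + Z, ``c2`` the recycling rate Z -> I.  ``k3_plus``/``k3_minus``
    hold one association/dissociation pair per downstream site.
    """

    k0_plus: float
    k0_minus: float
    c1: float
    c2: float
    k3_plus: tuple[float, ...] = ()
    k3_minus: tuple[float, ...] = ()
    omega: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "k3_plus", tuple(float(x) for x in self.k3_plus))
        object.__setattr__(self, "k3_minus", tuple(float(x) for x in self.k3_minus))
        for name in ("k0_plus", "k0_minus", "c1", "c2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(x < 0 for x in self.k3_plus + self.k3_minus):
            raise ValueError("k3 rates must be non-negative")
        if len(self.k3_plus) != len(self.k3_minus):
            raise ValueError("k3_plus and k3_minus must have the same length")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.k3_plus)

    @property
    def k0(self) -> float:
        """Volume-scaled dissociation constant k0_minus * omega / k0_plus."""
        if self.k0_plus <= 0:
            raise ZeroDivisionError("k0 undefined for k0_plus = 0")
        return self.k0_minus * self.omega / self.k0_plus

    @property
    def k3(self) -> tuple[float, ...]:
        """Per-site dissociation constants k3_minus * omega / k3_plus."""
        if any(kp <= 0 for kp in self.k3_plus):
            raise ZeroDivisionError("k3 undefined for k3_plus = 0")
        return tuple(km * self.omega / kp for kp, km in zip(self.k3_plus, self.k3_minus))

    @classmethod
    def uniform(
        cls,
        k0_plus: float,
        k0_minus: float,
        c1: float,
        c2: float,
        k3_plus: float = 1.0,
        k3_minus: float = 1.0,
        n_sites: int = 0,
        omega: float = 1.0,
    ) -> "RateParameters":
        """Convenience constructor with identical rates for all sites."""
        return cls(
            k0_plus,
            k0_minus,
            c1,
            c2,
            (k3_plus,) * n_sites,
            (k3_minus,) * n_sites,
            omega,
        )


@dataclass(frozen=True)
class Totals:
    """Conserved molecule totals (counts in CME mode).

    Input totals Itot1/Itot2 are fixed by the transmitted symbols at t0 and
    are therefore supplied at enumeration time rather than stored here.
    """

    etot: int = 1
    etot2: int = 1
    dtot: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dtot", tuple(int(x) for x in self.dtot))
        if self.etot < 0 or self.etot2 < 0 or any(d < 0 for d in self.dtot):
            raise ValueError("totals must be non-negative")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    Propensity in counts ``x``: ``rate * x_a`` (unimolecular) or
    ``rate * x_a * x_b / omega`` (bimolecular, distinct reactants).
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate: float
    bimolecular: bool = False

    @property
    def net(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for sp, n in self.products.items():
            delta[sp] = delta.get(sp, 0) + n
        for sp, n in self.reactants.items():
            delta[sp] = delta.get(sp, 0) - n
        return {sp: d for sp, d in delta.items() if d != 0}

    def propensity(self, counts: dict[str, int], omega: float) -> float:
        a = self.rate
        for sp, n in self.reactants.items():
            if n != 1:  # no multi-copy reactants occur in these circuits
                raise NotImplementedError("stoichiometry > 1 not supported")
            a *= counts.get(sp, 0)
        if self.bimolecular:
            a /= omega
        return a


#: A linear invariant: sum_i coeffs[sp_i] * x[sp_i] == total for every
#: reachable state.  ``total_key`` names the conserved quantity.
@dataclass(frozen=True)
class ConservationLaw:
    total_key: str
    coeffs: dict[str, int]

    def evaluate(self, counts: dict[str, int]) -> int:
        return sum(c * counts.get(sp, 0) for sp, c in self.coeffs.items())


@dataclass(frozen=True)
class ModelSpec:
    topology: Topology
    rates: RateParameters
    totals: Totals
    n_downstream: int = 0
    q_connected: int | None = None
    species: tuple[str, ...] = field(default_factory=tuple)
    reactions: tuple[Reaction, ...] = field(default_factory=tuple)
    laws: tuple[ConservationLaw, ...] = field(default_factory=tuple)

    @property
    def two_input(self) -> bool:
        return self.topology in _TWO_INPUT

    def with_rates(self, rates: RateParameters) -> "ModelSpec":
        """Rebuild the model with a different rate set (topology unchanged)."""
        return build_model(
            self.topology,
            rates,
            n_downstream=self.n_downstream,
            q_connected=self.q_connected,
            totals=self.totals,
        )

    # -- plain-text serialization ------------------------------------------

    def to_config(self) -> str:
        cfg = {
            "topology": self.topology.value,
            "n_downstream": self.n_downstream,
            "q_connected": self.q_connected,
            "totals": {
                "etot": self.totals.etot,
                "etot2": self.totals.etot2,
                "dtot": list(self.totals.dtot),
            },
            "rates": {
                "k0_plus": self.rates.k0_plus,
                "k0_minus": self.rates.k0_minus,
                "c1": self.rates.c1,
                "c2": self.rates.c2,
                "k3_plus": list(self.rates.k3_plus),
                "k3_minus": list(self.rates.k3_minus),
                "omega": self.rates.omega,
            },
        }
        return yaml.safe_dump(cfg, sort_keys=True)

    @classmethod
    def from_config(cls, text: str) -> "ModelSpec":
        cfg = yaml.safe_load(text)
        rates = RateParameters(
            cfg["rates"]["k0_plus"],
            cfg["rates"]["k0_minus"],
            cfg["rates"]["c1"],
            cfg["rates"]["c2"],
            tuple(cfg["rates"]["k3_plus"]),
            tuple(cfg["rates"]["k3_minus"]),
            cfg["rates"]["omega"],
        )
        totals = Totals(
            cfg["totals"]["etot"], cfg["totals"]["etot2"], tuple(cfg["totals"]["dtot"])
        )
        return build_model(
            Topology(cfg["topology"]),
            rates,
            n_downstream=cfg["n_downstream"],
            q_connected=cfg["q_connected"],
            totals=totals,
        )

    def reaction_table(self) -> str:
        """Human-readable TSV listing of the reaction scheme."""
        buf = io.StringIO()
        buf.write("name\treactants\tproducts\trate\tbimolecular\n")
        for r in self.reactions:
            rs = " + ".join(sorted(r.reactants)) or "0"
            ps = " + ".join(sorted(r.products)) or "0"
            buf.write(f"{r.name}\t{rs}\t{ps}\t{r.rate!r}\t{int(r.bimolecular)}\n")
        return buf.getvalue()


def _upstream_branch(
    rates: RateParameters, branch: int, enzyme: str
) -> list[Reaction]:
    b = str(branch)
    return [
        Reaction(f"bind{b}", {f"I{b}": 1, enzyme: 1}, {f"M{b}": 1}, rates.k0_plus, True),
        Reaction(f"unbind{b}", {f"M{b}": 1}, {f"I{b}": 1, enzyme: 1}, rates.k0_minus),
        Reaction(f"catalyze{b}", {f"M{b}": 1}, {enzyme: 1, f"Z{b}": 1}, rates.c1),
        Reaction(f"recycle{b}", {f"Z{b}": 1}, {f"I{b}": 1}, rates.c2),
    ]


def _downstream_site(
    rates: RateParameters, j: int, z: str, complex_name: str
) -> list[Reaction]:
    kp = rates.k3_plus[j - 1]
    km = rates.k3_minus[j - 1]
    return [
        Reaction(f"bind_{complex_name}", {z: 1, f"D{j}": 1}, {complex_name: 1}, kp, True),
        Reaction(f"unbind_{complex_name}", {complex_name: 1}, {z: 1, f"D{j}": 1}, km),
    ]


def build_model(
    topology: Topology | str,
    rates: RateParameters,
    n_downstream: int = 0,
    q_connected: int | None = None,
    totals: Totals | None = None,
) -> ModelSpec:
    """Assemble the reaction network for one of the five topologies.

    ``n_downstream`` is the number of binding sites N (must be 0 for the
    isolated topologies); ``q_connected`` is the MAC split Q (sites 1..Q bind
    Z1, sites Q+1..N bind Z2) and defaults to N//2 for the MAC topology.
    Both MIMO branches use the same rate constants (the second circuit is a
    replica of the first); pass a distinct ``RateParameters`` and rebuild to
    override.
    """
    topology = Topology(topology)
    n = int(n_downstream)
    if n < 0:
        raise ValueError("n_downstream must be >= 0")
    if topology in _ISOLATED and n != 0:
        raise ValueError(f"{topology.value} takes no downstream systems")
    if rates.n_sites < n:
        raise ValueError(f"rates carry {rates.n_sites} k3 pairs but N={n}")
    if topology is Topology.TWO_SISO_MAC:
        q = n // 2 if q_connected is None else int(q_connected)
        if not 0 <= q <= n:
            raise ValueError("need 0 <= Q <= N")
    else:
        if q_connected not in (None, n):
            raise ValueError("q_connected only applies to TWO_SISO_MAC")
        q = None
    if totals is None:
        totals = Totals(dtot=(1,) * n)
    if len(totals.dtot) != n:
        raise ValueError(f"totals.dtot has {len(totals.dtot)} entries but N={n}")

    species: list[str] = []
    reactions: list[Reaction] = []
    laws: list[ConservationLaw] = []

    def upstream(branch: int, enzyme: str) -> None:
        b = str(branch)
        for sp in (f"I{b}", f"M{b}", f"Z{b}"):
            species.append(sp)
        if enzyme not in species:
            species.append(enzyme)
        reactions.extend(_upstream_branch(rates, branch, enzyme))

    if topology in (Topology.ISOLATED_SISO, Topology.SISO_N_DOWNSTREAM):
        upstream(1, "E")
        laws.append(ConservationLaw("Etot", {"E": 1, "M1": 1}))
        itot1 = {"I1": 1, "M1": 1, "Z1": 1}
        for j in range(1, n + 1):
            species += [f"D{j}", f"C{j}"]
            reactions += _downstream_site(rates, j, "Z1", f"C{j}")
            laws.append(ConservationLaw(f"Dtot{j}", {f"D{j}": 1, f"C{j}": 1}))
            itot1[f"C{j}"] = 1
        laws.append(ConservationLaw("Itot1", itot1))

    elif topology in (Topology.ISOLATED_MIMO, Topology.MIMO_N_DOWNSTREAM):
        upstream(1, "E")
        upstream(2, "E")
        laws.append(ConservationLaw("Etot", {"E": 1, "M1": 1, "M2": 1}))
        itot1 = {"I1": 1, "M1": 1, "Z1": 1}
        for j in range(1, n + 1):
            species += [f"D{j}", f"C{j}"]
            reactions += _downstream_site(rates, j, "Z1", f"C{j}")
            laws.append(ConservationLaw(f"Dtot{j}", {f"D{j}": 1, f"C{j}": 1}))
            itot1[f"C{j}"] = 1
        laws.append(ConservationLaw("Itot1", itot1))
        laws.append(ConservationLaw("Itot2", {"I2": 1, "M2": 1, "Z2": 1}))

    elif topology is Topology.TWO_SISO_MAC:
        upstream(1, "E")
        upstream(2, "E2")
        laws.append(ConservationLaw("Etot", {"E": 1, "M1": 1}))
        laws.append(ConservationLaw("Etot2", {"E2": 1, "M2": 1}))
        itot1 = {"I1": 1, "M1": 1, "Z1": 1}
        itot2 = {"I2": 1, "M2": 1, "Z2": 1}
        for j in range(1, n + 1):
            # A site is bound by exactly one branch at a time; the Dtot law
            # over the site and its complexes enforces exclusivity.
            species.append(f"D{j}")
            law = {f"D{j}": 1}
            if j <= q:
                cname = f"C{j}_1"
                species.append(cname)
                reactions += _downstream_site(rates, j, "Z1", cname)
                itot1[cname] = 1
            else:
                cname = f"C{j}_2"
                species.append(cname)
                reactions += _downstream_site(rates, j, "Z2", cname)
                itot2[cname] = 1
            law[cname] = 1
            laws.append(ConservationLaw(f"Dtot{j}", law))
        laws.append(ConservationLaw("Itot1", itot1))
        laws.append(ConservationLaw("Itot2", itot2))
    else:  # pragma: no cover - Topology() already validates
        raise ValueError(f"unknown topology {topology!r}")

    return ModelSpec(
        topology=topology,
        rates=rates,
        totals=totals,
        n_downstream=n,
        q_connected=q,
        species=tuple(species),
        reactions=tuple(reactions),
        laws=tuple(laws),
    )


def conservation_laws(model: ModelSpec) -> tuple[ConservationLaw, ...]:
    """The linear invariants of ``model``.

    Every law ``v`` satisfies ``v . net(r) == 0`` for every reaction ``r``
    (exact integer arithmetic); this is asserted by the test suite.
    """
    return model.laws


def total_values(model: ModelSpec, i1: int, i2: int = 0) -> dict[str, int]:
    """Numeric conserved totals for input symbols (i1, i2).

    The input totals at transmission start are the symbols themselves:
    Itot1(t0) = i1 and Itot2(t0) = i2 (no complexes or output present
    before t0).
    """
    vals: dict[str, int] = {}
    for law in model.laws:
        if law.total_key == "Itot1":
            vals[law.total_key] = int(i1)
        elif law.total_key == "Itot2":
            vals[law.total_key] = int(i2)
        elif law.total_key == "Etot":
            vals[law.total_key] = model.totals.etot
        elif law.total_key == "Etot2":
            vals[law.total_key] = model.totals.etot2
        elif law.total_key.startswith("Dtot"):
            j = int(law.total_key[4:])
            vals[law.total_key] = model.totals.dtot[j - 1]
        else:  # pragma: no cover
            raise KeyError(law.total_key)
    return vals


def initial_state(model: ModelSpec, i1: int, i2: int = 0) -> dict[str, int]:
    """The t0 microstate: free inputs, free enzymes, free sites, nothing else."""
    counts = {sp: 0 for sp in model.species}
    counts["I1"] = int(i1)
    if "I2" in counts:
        counts["I2"] = int(i2)
    counts["E"] = model.totals.etot
    if "E2" in counts:
        counts["E2"] = model.totals.etot2
    for j in range(1, model.n_downstream + 1):
        counts[f"D{j}"] = model.totals.dtot[j - 1]
    return counts


def sample_mac_allocation(n: int, rng) -> int:
    """Draw a MAC split Q ~ Binomial(N, 1/2) for ensemble studies.

    The two upstream systems emit symmetrically, so a site is equally likely
    to be captured by either branch; on average Q = N/2.
    """
    return int(rng.binomial(n, 0.5))
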