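"""Steady-state chemical master equation engine.

With molecule totals of order one the state space of each circuit is small
enough to enumerate exactly.  The stationary distribution of the resulting
continuous-time Markov chain is obtained by a dense linear solve restricted
to the closed communicating class reachable from the t0 microstate; the
reachability restriction matters because the i1 = 0 symbol yields a trivial
one-state class and the non-cyclic (c2 = 0) circuits are absorbing.

The input/output channel between the transmitted symbol I1(t0) and the
steady-state output Z1(ts) is a Z-channel: an empty input class can never
produce output (P(Z1 >= 1 | i1 = 0) = 0 by conservation), while symbol 1
is erased with probability A = P(Z1(ts) = 0 | i1 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .info import ZChannel, mutual_information
from .networks import ModelSpec, initial_state, total_values

__all__ = [
    "StationaryDistribution",
    "enumerate_states",
    "build_generator",
    "stationary_distribution",
    "solve_model",
    "prob_z1_zero",
    "a_hat",
    "channel_from_cme",
    "mi_from_cme",
]

#: Guard against accidental enumeration of huge conservation classes.
MAX_STATES = 200_000

#: Residual tolerance for the stationary solve, ||pi^T Q||_inf.
STATIONARY_TOL = 1e-10


class NonErgodicError(RuntimeError):
    """Raised when the reachable state set holds several closed classes."""


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary law over enumerated microstates for one symbol condition."""

    species: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]
    probs: np.ndarray
    condition: tuple[int, int]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if abs(p.sum() - 1.0) > 1e-10 or (p < -1e-14).any():
            raise ValueError("probs must be a normalized pmf")

    def marginal(self, species: str) -> dict[int, float]:
        """Marginal pmf of one species' copy number."""
        idx = self.species.index(species)
        out: dict[int, float] = {}
        for state, p in zip(self.states, self.probs):
            out[state[idx]] = out.get(state[idx], 0.0) + float(p)
        return out

    def expectation(self, species: str) -> float:
        return sum(k * p for k, p in self.marginal(species).items())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(list(self.states), columns=list(self.species))
        df["prob"] = self.probs
        return df


def enumerate_states(
    model: ModelSpec, initial_symbols: tuple[int, int] | int, max_states: int = MAX_STATES
) -> list[tuple[int, ...]]:
    """All non-negative integer microstates satisfying the conservation laws.

    ``initial_symbols`` is ``(i1, i2)`` (a bare int is taken as ``i1``); each
    symbol fixes the corresponding input total at t0.  States are returned as
    count tuples in the model's species order, sorted lexicographically so the
    ordering is canonical.
    """
    if isinstance(initial_symbols, int):
        initial_symbols = (initial_symbols, 0)
    i1, i2 = initial_symbols
    if i1 < 0 or i2 < 0:
        raise ValueError("input symbols must be non-negative counts")
    totals = total_values(model, i1, i2)

    species = model.species
    laws = [(law, totals[law.total_key]) for law in model.laws]
    # Upper bound per species from the tightest law that contains it.
    bounds = []
    for sp in species:
        b = None
        for law, tot in laws:
            c = law.coeffs.get(sp, 0)
            if c > 0:
                ub = tot // c
                b = ub if b is None else min(b, ub)
        if b is None:  # species in no law -- cannot happen for these circuits
            raise ValueError(f"species {sp} unconstrained by any conservation law")
        bounds.append(b)

    # Depth-first assignment with residual pruning.  law_resid[k] tracks the
    # amount of law k's total not yet allocated to assigned species.
    remaining_weight = []  # max contribution of species i.. to each law
    nlaws = len(laws)
    weights = np.zeros((len(species), nlaws), dtype=np.int64)
    for i, sp in enumerate(species):
        for k, (law, _) in enumerate(laws):
            weights[i, k] = law.coeffs.get(sp, 0)
    suffix_max = np.zeros((len(species) + 1, nlaws), dtype=np.int64)
    for i in range(len(species) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + weights[i] * bounds[i]

    out: list[tuple[int, ...]] = []
    state = [0] * len(species)
    resid = np.array([tot for _, tot in laws], dtype=np.int64)

    def rec(i: int) -> None:
        if len(out) > max_states:
            raise MemoryError(
                f"conservation class exceeds the {max_states}-state enumeration cap"
            )
        if i == len(species):
            if (resid == 0).all():
                out.append(tuple(state))
            return
        w = weights[i]
        hi = bounds[i]
        for k in range(nlaws):
            if w[k] > 0:
                hi = min(hi, resid[k] // w[k])
        for x in range(hi + 1):
            state[i] = x
            resid2 = resid - x * w
            if (resid2 <= suffix_max[i + 1]).all():
                resid_save = resid.copy()
                resid[:] = resid2
                rec(i + 1)
                resid[:] = resid_save
        state[i] = 0

    rec(0)
    out.sort()
    return out


def build_generator(
    model: ModelSpec, states: list[tuple[int, ...]]
) -> np.ndarray:
    """Dense CTMC generator over ``states`` (rows sum to zero).

    Off-diagonal entry (i, j) is the propensity of the reaction carrying
    state i to state j; a transition leaving the enumerated set signals an
    enumeration bug and raises ``KeyError``.
    """
    species = model.species
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    nets = [
        (r, tuple(r.net.get(sp, 0) for sp in species)) for r in model.reactions
    ]
    for i, s in enumerate(states):
        counts = dict(zip(species, s))
        for r, net in nets:
            a = r.propensity(counts, model.rates.omega)
            if a <= 0.0:
                continue
            target = tuple(x + d for x, d in zip(s, net))
            j = index.get(target)
            if j is None:
                raise KeyError(
                    f"reaction {r.name} maps state {s} outside the enumerated set"
                )
            Q[i, j] += a
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


def _closed_class(Q: np.ndarray, start: int) -> list[int]:
    """Indices of the unique closed communicating class reachable from start."""
    n = Q.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    src, dst = np.nonzero(Q > 0)
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    reachable = nx.descendants(G, start) | {start}
    H = G.subgraph(reachable)
    cond = nx.condensation(H)
    terminal = [c for c in cond.nodes if cond.out_degree(c) == 0]
    if len(terminal) != 1:
        raise NonErgodicError(
            f"{len(terminal)} closed classes reachable from the initial state; "
            "stationary law is ambiguous"
        )
    members = sorted(cond.nodes[terminal[0]]["members"])
    return members


def stationary_distribution(Q: np.ndarray, start: int = 0) -> np.ndarray:
    """Stationary pmf of the CTMC with generator ``Q``.

    Probability mass is supported on the closed communicating class reachable
    from ``start``; all transient states get probability zero.  The solve is
    dense: one balance equation is replaced by the normalization row.
    """
    n = Q.shape[0]
    members = _closed_class(Q, start)
    sub = Q[np.ix_(members, members)]
    m = len(members)
    if m == 1:
        pi_sub = np.array([1.0])
    else:
        A = sub.T.copy()
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        pi_sub = np.linalg.solve(A, b)
    pi = np.zeros(n)
    pi[members] = pi_sub
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(pi @ Q).max()
    if resid > STATIONARY_TOL:
        raise RuntimeError(f"stationary residual {resid:.2e} exceeds {STATIONARY_TOL}")
    return pi


def solve_model(
    model: ModelSpec, i1: int, i2: int = 0
) -> StationaryDistribution:
    """Enumerate, build the generator, and solve one symbol condition."""
    states = enumerate_states(model, (i1, i2))
    Q = build_generator(model, states)
    start = states.index(tuple(initial_state(model, i1, i2)[sp] for sp in model.species))
    pi = stationary_distribution(Q, start)
    return StationaryDistribution(
        species=model.species, states=tuple(states), probs=pi, condition=(i1, i2)
    )


def prob_z1_zero(model: ModelSpec, i1: int, i2: int = 0) -> float:
    """P(Z1(ts) = 0 | I1(t0) = i1, I2(t0) = i2) under the stationary CME."""
    dist = solve_model(model, i1, i2)
    return dist.marginal("Z1").get(0, 0.0)


def a_hat(
    model: ModelSpec, second_input_priors: tuple[float, float] = (0.5, 0.5)
) -> float:
    """The Z-channel erasure constant A = P(Z1(ts) = 0 | I1(t0) = 1).

    For two-input topologies the second symbol is marginalized with priors
    ``(P02, P12)``; single-input topologies ignore them.
    """
    if not model.two_input:
        return prob_z1_zero(model, 1, 0)
    p02, p12 = second_input_priors
    if p02 < 0 or p12 < 0 or abs(p02 + p12 - 1.0) > 1e-9:
        raise ValueError("second-input priors must be a valid binary pmf")
    a = 0.0
    if p02 > 0:
        a += p02 * prob_z1_zero(model, 1, 0)
    if p12 > 0:
        a += p12 * prob_z1_zero(model, 1, 1)
    return a


def channel_from_cme(
    model: ModelSpec,
    p01: float = 0.5,
    second_input_priors: tuple[float, float] = (0.5, 0.5),
) -> ZChannel:
    """The exact binary channel I1(t0) -> 1{Z1(ts) >= 1}.

    The zero symbol has an empty conservation class, so its row of the joint
    pmf is (P01, 0) exactly; the one symbol is thinned by A.
    """
    return ZChannel(a_hat(model, second_input_priors), p01)


def mi_from_cme(
    model: ModelSpec,
    priors: tuple[float, float, float, float] = (0.5, 0.5, 0.5, 0.5),
) -> float:
    """Mutual information (nats) between I1(t0) and Z1(ts).

    ``priors`` is (P01, P11, P02, P12); the second pair is only used by
    two-input topologies.
    """
    p01, p11, p02, p12 = priors
    if abs(p01 + p11 - 1.0) > 1e-9:
        raise ValueError("first-input priors must sum to 1")
    ch = channel_from_cme(model, p01, (p02, p12))
    return mutual_information(ch.joint)
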