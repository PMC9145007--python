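"""Exact stochastic simulation (Gillespie direct method) oracle.

Used to validate the stationary CME solver: for an ergodic class the
time-averaged occupancy of a single long trajectory converges to the
stationary pmf, with a batch-means standard error.  Random-number usage
order is fixed -- exponential waiting time first, then reaction selection --
so identical seeds give identical event paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import ModelSpec, initial_state

__all__ = ["EventPath", "TrajectorySummary", "gillespie", "occupancy_pmf"]


@dataclass(frozen=True)
class EventPath:
    """A jump path: state ``states[k]`` holds on [times[k], times[k+1])."""

    species: tuple[str, ...]
    times: np.ndarray
    states: tuple[tuple[int, ...], ...]
    t_end: float
    seed: int
    absorbed: bool

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class TrajectorySummary:
    """Time-averaged occupancy after burn-in, with batch-means errors."""

    species: tuple[str, ...]
    pmf: dict[tuple[int, ...], float]
    stderr: dict[tuple[int, ...], float]
    total_time: float
    burn_in: float
    seed: int

    def prob(self, state: tuple[int, ...]) -> float:
        return self.pmf.get(state, 0.0)


def gillespie(
    model: ModelSpec,
    initial: dict[str, int] | None = None,
    t_end: float = 1000.0,
    seed: int = 0,
    i1: int = 1,
    i2: int = 0,
    max_events: int = 10_000_000,
) -> EventPath:
    """Simulate one exact trajectory of the reaction network CTMC.

    ``initial`` defaults to the t0 microstate for symbols (i1, i2).  If the
    total propensity hits zero the path ends in the absorbing state (valid
    for non-cyclic c2 = 0 circuits).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        initial = initial_state(model, i1, i2)
    species = model.species
    rng = np.random.default_rng(seed)
    omega = model.rates.omega
    nets = [
        (r, tuple(r.net.get(sp, 0) for sp in species)) for r in model.reactions
    ]
    state = tuple(int(initial.get(sp, 0)) for sp in species)
    t = 0.0
    times = [0.0]
    states = [state]
    absorbed = False
    for _ in range(max_events):
        counts = dict(zip(species, state))
        props = np.array([r.propensity(counts, omega) for r, _ in nets])
        total = props.sum()
        if total <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        k = int(np.searchsorted(np.cumsum(props), rng.random() * total))
        state = tuple(x + d for x, d in zip(state, nets[k][1]))
        times.append(t)
        states.append(state)
    else:
        raise RuntimeError(f"exceeded {max_events} events before t_end")
    return EventPath(
        species=species,
        times=np.asarray(times),
        states=tuple(states),
        t_end=t_end,
        seed=seed,
        absorbed=absorbed,
    )


def occupancy_pmf(
    path: EventPath, burn_in: float | None = None, n_batches: int = 20
) -> TrajectorySummary:
    """Time-weighted state occupancy after burn-in.

    ``burn_in`` defaults to 10% of the path duration.  Standard errors come
    from batch means: the post-burn-in window is split into ``n_batches``
    equal slices and the across-batch spread of each state's occupancy gives
    its standard error.
    """
    if burn_in is None:
        burn_in = 0.1 * path.t_end
    if burn_in >= path.t_end:
        raise ValueError("burn_in must be smaller than the path duration")
    edges = np.append(path.times, path.t_end)
    starts = np.maximum(edges[:-1], burn_in)
    ends = edges[1:]
    durs = np.clip(ends - starts, 0.0, None)
    window = path.t_end - burn_in
    if window <= 0 or durs.sum() <= 0:
        raise ValueError("empty post-burn-in window")

    keys = sorted(set(path.states))
    index = {s: i for i, s in enumerate(keys)}
    occ = np.zeros(len(keys))
    for s, d in zip(path.states, durs):
        if d > 0:
            occ[index[s]] += d
    pmf_vec = occ / occ.sum()

    # batch means over equal time slices of the post-burn-in window
    bounds = np.linspace(burn_in, path.t_end, n_batches + 1)
    batch = np.zeros((n_batches, len(keys)))
    for b in range(n_batches):
        lo, hi = bounds[b], bounds[b + 1]
        seg = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)
        tot = seg.sum()
        if tot > 0:
            for s, d in zip(path.states, seg):
                if d > 0:
                    batch[b, index[s]] += d
            batch[b] /= tot
    se = batch.std(axis=0, ddof=1) / np.sqrt(n_batches)

    return TrajectorySummary(
        species=path.species,
        pmf={s: float(pmf_vec[i]) for s, i in index.items()},
        stderr={s: float(se[i]) for s, i in index.items()},
        total_time=path.t_end,
        burn_in=burn_in,
        seed=path.seed,
    )
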