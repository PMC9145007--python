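"""Entropy, mutual information, and Z-channel capacity with bounds.

The input/output pair (symbol at t0, presence of output at steady state)
forms a Z-channel: symbol 0 is received noiselessly, symbol 1 is flipped to
0 with probability A.  Its joint pmf is

    [[P01,      0       ],
     [A * P11,  (1-A) * P11]]

with rows indexed by the input symbol and columns by the output.  All
quantities default to nats; capacity utilities take a ``units`` toggle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "entropy",
    "mutual_information",
    "ZChannel",
    "z_channel_joint",
    "mi_z_channel",
    "mi_z_channel_closed_form",
    "z_channel_capacity",
    "z_channel_optimal_prior",
    "blahut_arimoto",
    "capacity_upper_bound",
    "bound_surface",
    "CapacityCurve",
]

LN2 = math.log(2.0)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0 * ln 0 := 0 continuity convention."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def _check_pmf(p: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < -1e-12).any():
        raise ValueError("pmf entries must be non-negative")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"pmf sums to {p.sum()!r}, not 1")
    return np.clip(p, 0.0, None)


def entropy(p, units: str = "nats") -> float:
    """Shannon entropy of a discrete pmf."""
    p = _check_pmf(p)
    h = -float(_xlogx(p).sum())
    return h / LN2 if units == "bits" else h


def mutual_information(joint: np.ndarray, units: str = "nats") -> float:
    """Mutual information of a joint pmf matrix, I(X;Y) = H(X) - H(X|Y)."""
    j = _check_pmf(np.asarray(joint, dtype=float))
    px = j.sum(axis=1)
    py = j.sum(axis=0)
    mi = float(_xlogx(j).sum() - _xlogx(px).sum() - _xlogx(py).sum())
    mi = max(mi, 0.0)
    return mi / LN2 if units == "bits" else mi


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


@dataclass(frozen=True)
class ZChannel:
    """The binary asymmetric channel with a noiseless zero symbol.

    ``a`` is the flip probability P(Y=0 | X=1); ``p01`` the prior of
    symbol 0.
    """

    a: float
    p01: float

    def __post_init__(self) -> None:
        _check_prob(self.a, "a")
        _check_prob(self.p01, "p01")

    @property
    def p11(self) -> float:
        return 1.0 - self.p01

    @property
    def joint(self) -> np.ndarray:
        return z_channel_joint(self.a, self.p01)

    @property
    def conditional(self) -> np.ndarray:
        return np.array([[1.0, 0.0], [self.a, 1.0 - self.a]])

    def mutual_information(self, units: str = "nats") -> float:
        return mutual_information(self.joint, units)


def z_channel_joint(a: float, p01: float) -> np.ndarray:
    """Joint pmf of input symbol (rows) and output symbol (columns)."""
    _check_prob(a, "a")
    _check_prob(p01, "p01")
    p11 = 1.0 - p01
    return np.array([[p01, 0.0], [a * p11, (1.0 - a) * p11]])


def mi_z_channel(a: float, p01: float, units: str = "nats") -> float:
    """I(X;Y) of the Z-channel, computed from the joint pmf.

    This is the canonical definition H(X) - H(X|Y); the algebraic expansion
    ``mi_z_channel_closed_form`` agrees with it identically.
    """
    return mutual_information(z_channel_joint(a, p01), units)


def mi_z_channel_closed_form(a: float, p01: float, units: str = "nats") -> float:
    """Algebraic expansion of the Z-channel mutual information.

    I = H(X) - (P01 + A*P11) * h(P01 / (P01 + A*P11)) where h is the binary
    entropy; used as an independent transcription check of the joint-based
    computation.
    """
    a = _check_prob(a, "a")
    p01 = _check_prob(p01, "p01")
    p11 = 1.0 - p01
    hx = entropy([p01, p11])
    py0 = p01 + a * p11
    h_cond = 0.0
    if py0 > 0:
        q = p01 / py0
        h_cond = py0 * entropy([q, 1.0 - q])
    mi = max(hx - h_cond, 0.0)
    return mi / LN2 if units == "bits" else mi


def z_channel_capacity(a: float, units: str = "nats") -> float:
    """Capacity of the Z-channel with flip probability ``a``.

    Closed form: C = ln(1 + (1-A) * A^(A/(1-A))) nats; degenerates to ln 2
    at A = 0 and to 0 at A = 1.
    """
    a = _check_prob(a, "a")
    if a >= 1.0:
        c = 0.0
    elif a <= 0.0:
        c = LN2
    else:
        c = math.log1p((1.0 - a) * a ** (a / (1.0 - a)))
    return c / LN2 if units == "bits" else c


def z_channel_optimal_prior(a: float) -> float:
    """The input prior P01 maximizing the Z-channel mutual information."""
    a = _check_prob(a, "a")
    if a >= 1.0:
        return 0.5  # MI is identically zero; return the symmetric prior
    res = minimize_scalar(
        lambda p: -mi_z_channel(a, p),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def blahut_arimoto(
    conditional: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    units: str = "nats",
) -> tuple[float, np.ndarray]:
    """Capacity of a discrete memoryless channel by Blahut-Arimoto iteration.

    ``conditional`` is the row-stochastic matrix W(y|x).  Returns the
    capacity and the optimizing input distribution.  The iteration maintains
    lower/upper capacity bounds and stops when their gap falls below ``tol``
    (in nats); non-convergence raises ``RuntimeError``.
    """
    W = np.asarray(conditional, dtype=float)
    if (W < 0).any() or not np.allclose(W.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("conditional must be row-stochastic")
    nx = W.shape[0]
    r = np.full(nx, 1.0 / nx)
    logW = np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), 0.0)
    for _ in range(max_iter):
        q = r @ W  # output distribution
        # D(W_x || q) for each input x
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), -np.inf)
        d = np.array(
            [float(np.sum(W[x][W[x] > 0] * (logW[x][W[x] > 0] - logq[W[x] > 0]))) for x in range(nx)]
        )
        lower = float(r @ d)
        upper = float(d.max())
        if upper - lower < tol:
            c = lower
            return (c / LN2 if units == "bits" else c), r
        r = r * np.exp(d - d.max())
        r /= r.sum()
    raise RuntimeError(f"Blahut-Arimoto did not converge in {max_iter} iterations")


def capacity_upper_bound(a: float, q, units: str = "nats") -> float:
    """Dual (KL-divergence) capacity bound of the Z-channel.

    For any output distribution q, C <= max_x D(W(.|x) || q); the bound is
    tight when q is the capacity-achieving output distribution.
    """
    a = _check_prob(a, "a")
    q = _check_pmf(np.asarray(q, dtype=float))
    W = np.array([[1.0, 0.0], [a, 1.0 - a]])
    best = -math.inf
    for row in W:
        d = 0.0
        for w, qq in zip(row, q):
            if w > 0:
                if qq <= 0:
                    d = math.inf
                    break
                d += w * math.log(w / qq)
        best = max(best, d)
    return best / LN2 if units == "bits" else best


@dataclass(frozen=True)
class CapacityCurve:
    a_grid: np.ndarray
    capacity: np.ndarray
    optimal_p01: np.ndarray
    units: str = "nats"


def capacity_curve(a_grid, units: str = "nats") -> CapacityCurve:
    a_grid = np.asarray(a_grid, dtype=float)
    cap = np.array([z_channel_capacity(a, units) for a in a_grid])
    popt = np.array([z_channel_optimal_prior(a) for a in a_grid])
    return CapacityCurve(a_grid, cap, popt, units)


def bound_surface(a_grid, p01_grid, units: str = "nats"):
    """Lower bound (MI), capacity, and dual upper bound over an (A, P01) grid.

    Returns a DataFrame with columns (A, P01, lower, capacity, upper).  For
    each A the upper bound is minimized over output distributions q with
    q(0) swept on ``p01_grid``; as the grids refine, max_P01 lower, the
    capacity, and min_q upper coincide.
    """
    import pandas as pd

    a_grid = np.asarray(a_grid, dtype=float)
    p01_grid = np.asarray(p01_grid, dtype=float)
    rows = []
    for a in a_grid:
        cap = z_channel_capacity(a, units)
        ub = min(
            capacity_upper_bound(a, [q0, 1.0 - q0], units)
            for q0 in p01_grid
        )
        for p01 in p01_grid:
            rows.append(
                {
                    "A": a,
                    "P01": p01,
                    "lower": mi_z_channel(a, p01, units),
                    "capacity": cap,
                    "upper": ub,
                }
            )
    return pd.DataFrame(rows)
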