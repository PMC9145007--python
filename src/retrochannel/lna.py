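"""Linear-noise-approximation engine for the high-molecular-count regime.

Species are concentrations (counts / omega).  Deterministic steady states
come from the reaction rate equations; fluctuations around them are
Gaussian with a covariance solving the stationary Lyapunov equation

    A Sigma + Sigma A^T + B B^T = 0,

where A is the Jacobian of the rate equations at the fixed point and
B B^T is the diffusion matrix, sum_r nu_r nu_r^T a_r(x*) / omega over
reactions.  With channel noise fixed at unit variance the resulting
Gaussian channel has capacity 0.5 * ln(1 + sigma_signal^2 / sigma_noise^2).

For a single upstream system the circuit is reduced to a one-step cyclic
enzymatic reaction I + E -> E + Z, Z -> I.  At the fixed point the
downstream binding and unbinding fluxes cancel identically once each
complex sits at its quasi-equilibrium Cj = Z * Dtot / (k3 + Z), so the
free-output mean is unshifted by the load: mu_N = mu_0.  (This treats the
input pool as unsequestered by the sites -- the natural high-count limit,
where site concentrations Dtot/omega are vanishingly small against the
input pool; ``account_sequestration=True`` keeps the sequestered term
I = Itot - Z - sum_j Cj for finite-site studies, where the mean does shift.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import brentq, least_squares

__all__ = [
    "LNASteadyState",
    "GaussianChannel",
    "siso_reduced_mean",
    "siso_reduced_variance",
    "downstream_complex_steady",
    "siso_downstream_mean",
    "siso_downstream_covariance",
    "mimo_steady_state",
    "mimo_downstream_steady_state",
    "lyapunov_covariance",
    "awgn_capacity",
]

ROOT_TOL = 1e-12
LYAP_TOL = 1e-10


class NotHurwitzError(RuntimeError):
    """The Jacobian has an eigenvalue with non-negative real part."""


@dataclass(frozen=True)
class LNASteadyState:
    """Deterministic means and Gaussian covariance at steady state."""

    species: tuple[str, ...]
    means: np.ndarray
    covariance: np.ndarray
    omega: float

    def mean(self, sp: str) -> float:
        return float(self.means[self.species.index(sp)])

    def variance(self, sp: str) -> float:
        i = self.species.index(sp)
        return float(self.covariance[i, i])


@dataclass(frozen=True)
class GaussianChannel:
    """AWGN channel carrying the steady-state output concentration."""

    signal_variance: float
    noise_variance: float = 1.0

    def capacity(self, units: str = "nats") -> float:
        return awgn_capacity(self.signal_variance, self.noise_variance, units)


def siso_reduced_mean(c1: float, e: float, itot1: float, c2: float) -> float:
    """Steady-state output mean of the reduced SISO, mu0 = c1 E Itot / (c2 + c1 E)."""
    denom = c2 + c1 * e
    if denom <= 0:
        raise ValueError("need c2 + c1*E > 0")
    mu = c1 * e * itot1 / denom
    return mu


def siso_reduced_variance(
    c1: float, e: float, itot1: float, c2: float, omega: float
) -> float:
    """Stationary output variance of the reduced SISO.

    sigma0^2 = c1 E Itot c2 / (omega (c1 E + c2)^2), the scalar Lyapunov
    solution; scales as 1/omega.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    denom = c1 * e + c2
    if denom <= 0:
        raise ValueError("need c1*E + c2 > 0")
    return c1 * e * itot1 * c2 / (omega * denom**2)


def downstream_complex_steady(z1: float, dtot: float, k3: float) -> float:
    """Quasi-equilibrium complex concentration Cj = Z1 Dtot / (k3 + Z1)."""
    if k3 <= 0:
        raise ValueError("k3 must be positive")
    if z1 < 0:
        raise ValueError("Z1 must be non-negative")
    return z1 * dtot / (k3 + z1)


def _siso_downstream_rhs(
    z: float,
    c1: float,
    e: float,
    itot1: float,
    c2: float,
    k3: float,
    dtot: float,
    n: int,
    account_sequestration: bool,
) -> float:
    c = downstream_complex_steady(z, dtot, k3)
    free_input = itot1 - z - (n * c if account_sequestration else 0.0)
    # binding/unbinding fluxes cancel identically at Cj = Z Dtot/(k3+Z):
    # k3- * n * c - k3+ * z * n * (dtot - c) == 0 for every z.
    return c1 * e * free_input - c2 * z


def siso_downstream_mean(
    c1: float,
    e: float,
    itot1: float,
    c2: float,
    k3: float,
    dtot: float,
    n: int,
    account_sequestration: bool = False,
) -> float:
    """Steady-state free-output mean of the SISO loaded by N identical sites.

    Solves the reduced rate equation with each complex at quasi-equilibrium.
    The binding/unbinding flux terms cancel at the fixed point, so by default
    (no input sequestration) the root is exactly mu0: the load leaves the
    mean untouched.  The MAC circuit reuses this with Q in place of N.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = 0.0, itot1
    f = lambda z: _siso_downstream_rhs(
        z, c1, e, itot1, c2, k3, dtot, n, account_sequestration
    )
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return 0.0
    if f_hi == 0.0:
        return itot1
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no steady state bracketed in [0, Itot1]: f(0)={f_lo}, f(Itot1)={f_hi}"
        )
    z = brentq(f, lo, hi, xtol=ROOT_TOL, rtol=8.9e-16)
    if abs(f(z)) > 1e-10 * max(1.0, c1 * e * itot1):
        raise RuntimeError(f"root residual {f(z):.2e} too large")
    return z


def lyapunov_covariance(jacobian: np.ndarray, diffusion: np.ndarray) -> np.ndarray:
    """Stationary covariance Sigma solving A Sigma + Sigma A^T + BB^T = 0.

    ``jacobian`` must be Hurwitz (all eigenvalues in the open left half
    plane) and ``diffusion`` symmetric PSD; the residual is checked against
    ``LYAP_TOL`` and the result symmetrized.
    """
    A = np.atleast_2d(np.asarray(jacobian, dtype=float))
    D = np.atleast_2d(np.asarray(diffusion, dtype=float))
    eigs = np.linalg.eigvals(A)
    if (eigs.real >= 0).any():
        raise NotHurwitzError(
            f"Jacobian eigenvalues {eigs} are not all in the open left half plane"
        )
    sigma = solve_continuous_lyapunov(A, -D)
    sigma = 0.5 * (sigma + sigma.T)
    resid = np.abs(A @ sigma + sigma @ A.T + D).max()
    scale = max(1.0, np.abs(D).max())
    if resid > LYAP_TOL * scale:
        raise RuntimeError(f"Lyapunov residual {resid:.2e} exceeds tolerance")
    return sigma


def siso_reduced_lna(
    c1: float, e: float, itot1: float, c2: float, omega: float
) -> LNASteadyState:
    """Full LNA record for the reduced isolated SISO (one tracked species, Z1)."""
    mu = siso_reduced_mean(c1, e, itot1, c2)
    A = np.array([[-(c1 * e + c2)]])
    # production c1*E*I and degradation c2*Z fluxes at the fixed point
    D = np.array([[(c1 * e * (itot1 - mu) + c2 * mu) / omega]])
    sigma = lyapunov_covariance(A, D)
    return LNASteadyState(("Z1",), np.array([mu]), sigma, omega)


def siso_downstream_covariance(
    c1: float,
    e: float,
    itot1: float,
    c2: float,
    k3_plus: float,
    k3_minus: float,
    dtot: float,
    n: int,
    omega: float,
    account_sequestration: bool = True,
) -> LNASteadyState:
    """Numeric LNA for the reduced SISO plus N identical downstream sites.

    State (Z1, C1..CN); no closed form is attempted.  Used to probe how the
    load reshapes the output variance relative to sigma0^2 (the mean is
    already known to be load-free when sequestration is negligible).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    k3 = k3_minus / k3_plus
    z = siso_downstream_mean(
        c1, e, itot1, c2, k3, dtot, n, account_sequestration=account_sequestration
    )
    c = downstream_complex_steady(z, dtot, k3)
    dim = 1 + n
    means = np.array([z] + [c] * n)
    A = np.zeros((dim, dim))
    D = np.zeros((dim, dim))
    seq = 1.0 if account_sequestration else 0.0
    # dZ/dt = c1 E (Itot - Z - seq*sum C) - c2 Z - k3+ Z sum(Dtot - Cj) + k3- sum Cj
    A[0, 0] = -(c1 * e + c2) - k3_plus * n * (dtot - c)
    for j in range(1, dim):
        A[0, j] = -seq * c1 * e + k3_plus * z + k3_minus
        A[j, 0] = k3_plus * (dtot - c)
        A[j, j] = -(k3_plus * z + k3_minus)
    # reaction fluxes at the fixed point
    prod = c1 * e * (itot1 - z - seq * n * c)
    deg = c2 * z
    bind = k3_plus * z * (dtot - c)
    unbind = k3_minus * c
    D[0, 0] = (prod + deg + n * (bind + unbind)) / omega
    for j in range(1, dim):
        D[0, j] = D[j, 0] = -(bind + unbind) / omega
        D[j, j] = (bind + unbind) / omega
    sigma = lyapunov_covariance(A, D)
    species = ("Z1",) + tuple(f"C{j}" for j in range(1, n + 1))
    return LNASteadyState(species, means, sigma, omega)


def _mimo_residuals(
    x: np.ndarray,
    k0_plus: float,
    k0_minus: float,
    c1: float,
    c2: float,
    etot: float,
    itot1: float,
    itot2: float,
    n: int,
    k3_plus: float,
    k3_minus: float,
    dtot: float,
) -> np.ndarray:
    z1, m1, z2, m2 = x
    k3 = k3_minus / k3_plus if n else 1.0
    c = downstream_complex_steady(max(z1, 0.0), dtot, k3) if n else 0.0
    e = etot - m1 - m2
    i1 = itot1 - m1 - z1 - n * c
    i2 = itot2 - m2 - z2
    return np.array(
        [
            c1 * m1 + k3_minus * n * c - z1 * (c2 + k3_plus * n * (dtot - c)),
            k0_plus * e * i1 - (k0_minus + c1) * m1,
            c1 * m2 - c2 * z2,
            k0_plus * e * i2 - (k0_minus + c1) * m2,
        ]
    )


def _solve_mimo(
    k0_plus: float,
    k0_minus: float,
    c1: float,
    c2: float,
    etot: float,
    itot1: float,
    itot2: float,
    n: int = 0,
    k3_plus: float = 1.0,
    k3_minus: float = 1.0,
    dtot: float = 0.0,
) -> dict[str, float]:
    ub = np.array(
        [itot1, min(etot, itot1), itot2, min(etot, itot2)], dtype=float
    )
    x0 = 0.5 * np.where(ub > 0, ub, 1.0) * (ub > 0)
    res = least_squares(
        _mimo_residuals,
        x0,
        bounds=(np.zeros(4), np.where(ub > 0, ub, 1e-12)),
        args=(k0_plus, k0_minus, c1, c2, etot, itot1, itot2, n, k3_plus, k3_minus, dtot),
        xtol=3e-16,
        ftol=3e-16,
        gtol=3e-16,
    )
    resid = np.abs(res.fun).max()
    scale = max(1.0, k0_plus * etot * max(itot1, itot2), c1, c2)
    if resid > 1e-10 * scale:
        raise RuntimeError(
            f"MIMO steady-state solve did not converge: residuals {res.fun}"
        )
    z1, m1, z2, m2 = res.x
    return {"Z1": z1, "M1": m1, "Z2": z2, "M2": m2}


def mimo_steady_state(
    k0_plus: float,
    k0_minus: float,
    c1: float,
    c2: float,
    etot: float,
    itot1: float,
    itot2: float,
) -> dict[str, float]:
    """Deterministic steady state of the isolated MIMO circuit.

    Solves the four coupled rate equations for (Z1, M1, Z2, M2) with the
    conservation substitutions I_b = Itot_b - M_b - Z_b and
    E = Etot - M1 - M2; residuals are checked to 1e-10 (relative).
    """
    return _solve_mimo(k0_plus, k0_minus, c1, c2, etot, itot1, itot2)


def mimo_downstream_steady_state(
    k0_plus: float,
    k0_minus: float,
    c1: float,
    c2: float,
    etot: float,
    itot1: float,
    itot2: float,
    n: int,
    k3_plus: float,
    k3_minus: float,
    dtot: float,
) -> dict[str, float]:
    """Steady state of the MIMO circuit with branch-1 output loaded by N sites.

    Each complex is held at its quasi-equilibrium Cj = Z1 Dtot / (k3 + Z1);
    the sites sequester branch-1 input (I1 = Itot1 - M1 - Z1 - sum Cj).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return _solve_mimo(
        k0_plus, k0_minus, c1, c2, etot, itot1, itot2, n, k3_plus, k3_minus, dtot
    )


def awgn_capacity(
    signal_variance: float, noise_variance: float = 1.0, units: str = "nats"
) -> float:
    """Shannon capacity 0.5 * ln(1 + S/N) of the additive Gaussian channel."""
    if signal_variance < 0 or noise_variance <= 0:
        raise ValueError("variances must be non-negative (noise positive)")
    c = 0.5 * math.log1p(signal_variance / noise_variance)
    return c / math.log(2.0) if units == "bits" else c
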