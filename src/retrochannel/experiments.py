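"""End-to-end analyses: load sweeps, MIMO mitigation, capacity bounds, LNA.

Each ``run_*`` function is pure given its :class:`ExperimentConfig` and
returns pandas DataFrames; the CLI layer writes them to disk together with
a manifest (config hash, seed, version) sufficient to reproduce the outputs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import yaml

from . import __version__, cme, constants, info, lna
from .networks import RateParameters, Topology, build_model
from .synthetic import ladder_rates, sample_rates

__all__ = [
    "ExperimentConfig",
    "manifest",
    "run_mi_vs_load",
    "run_mimo_mitigation",
    "run_capacity_bounds",
    "run_lna_suite",
    "run_validation",
]

#: |A_cme - A_analytic| tolerance per fast-binding ladder rung (scale -> tol).
REGIME_TOLERANCES = {10.0: 2e-2, 100.0: 2e-3, 1000.0: 2e-4}


@dataclass(frozen=True)
class ExperimentConfig:
    """Serializable description of one experiment run."""

    seed: int = 0
    units: str = "nats"
    p01: float = 0.5
    p02: float = 0.5
    n_max: int = 10
    n_draws: int = 100
    grid_points: int = 101
    omega_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    rates: dict = field(
        default_factory=lambda: {
            "k0_plus": 1.0,
            "k0_minus": 1.0,
            "c1": 1.0,
            "c2": 1.0,
            "k3_plus": 1.0,
            "k3_minus": 1.0,
            "omega": 1.0,
        }
    )

    def rate_parameters(self, n_sites: int = 0) -> RateParameters:
        r = self.rates
        return RateParameters.uniform(
            r["k0_plus"],
            r["k0_minus"],
            r["c1"],
            r["c2"],
            r["k3_plus"],
            r["k3_minus"],
            n_sites,
            r["omega"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        data = yaml.safe_load(text) or {}
        if "omega_grid" in data:
            data["omega_grid"] = tuple(data["omega_grid"])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def manifest(config: ExperimentConfig) -> dict:
    return {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
    }


def run_mi_vs_load(config: ExperimentConfig) -> pd.DataFrame:
    """A, MI, and capacity as the downstream load N grows.

    Sweeps the broadcast circuit over N = 0..n_max and the MAC circuit over
    Q = 0..n_max at N = n_max; MI is non-increasing in the load, and the MAC
    rows interpolate between the isolated and fully loaded broadcast rows.
    """
    rows = []
    u = config.units
    for n in range(config.n_max + 1):
        rates = config.rate_parameters(n)
        topo = Topology.SISO_N_DOWNSTREAM if n else Topology.ISOLATED_SISO
        model = build_model(topo, rates, n_downstream=n)
        a_cme = cme.a_hat(model)
        a_ana = (
            constants.aN(rates.k0, rates.c1, rates.c2, rates.k3).value
            if n
            else constants.a0(rates.k0, rates.c1, rates.c2).value
        )
        rows.append(
            {
                "topology": topo.value,
                "N": n,
                "Q": n,
                "A_analytic": a_ana,
                "A_cme": a_cme,
                "MI": info.mi_z_channel(a_cme, config.p01, u),
                "capacity": info.z_channel_capacity(a_cme, u),
            }
        )
    n = config.n_max
    for q in range(n + 1):
        rates = config.rate_parameters(n)
        model = build_model(Topology.TWO_SISO_MAC, rates, n_downstream=n, q_connected=q)
        a_cme = cme.a_hat(model, (config.p02, 1.0 - config.p02))
        a_ana = constants.aQ_mac(rates.k0, rates.c1, rates.c2, rates.k3, q).value
        rows.append(
            {
                "topology": Topology.TWO_SISO_MAC.value,
                "N": n,
                "Q": q,
                "A_analytic": a_ana,
                "A_cme": a_cme,
                "MI": info.mi_z_channel(a_cme, config.p01, u),
                "capacity": info.z_channel_capacity(a_cme, u),
            }
        )
    return pd.DataFrame(rows)


def run_mimo_mitigation(config: ExperimentConfig) -> pd.DataFrame:
    """Does a second upstream branch mitigate retroactivity?

    The loaded-MIMO constant AN,MIMO = AN * P02 + G * P12 drops below AN
    exactly when G < AN.  Each fast-binding draw is classified by that
    criterion and the induced MI of the loaded MIMO is compared with the
    loaded SISO at matched rates.
    """
    draws = sample_rates(
        "fast_binding", config.n_draws, config.seed, n_sites=1, equal_catalytic=True
    )
    p02, p12 = config.p02, 1.0 - config.p02
    rows = []
    for k, draw in enumerate(draws):
        r = draw.rates
        an = constants.aN(r.k0, r.c1, r.c2, r.k3).value
        g = constants.g_const_numeric(r).value
        an_mimo = constants.aN_mimo(an, g, p02, p12).value
        rows.append(
            {
                "draw": k,
                "AN": an,
                "G": g,
                "AN_mimo": an_mimo,
                "mitigates": g < an,
                "MI_siso_loaded": info.mi_z_channel(an, config.p01, config.units),
                "MI_mimo_loaded": info.mi_z_channel(an_mimo, config.p01, config.units),
            }
        )
    return pd.DataFrame(rows)


def run_capacity_bounds(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The bound-surface study: lower bound (MI), capacity, dual upper bound.

    Returns (surface, curve): the (A, P01) surface table and the per-A
    capacity curve with its optimizing prior.  At every A the maximum of the
    lower bound, the capacity, and the minimum of the upper bound coincide
    up to grid resolution.
    """
    grid = np.linspace(0.0, 1.0, config.grid_points)
    surface = info.bound_surface(grid, grid, config.units)
    curve = info.capacity_curve(grid, config.units)
    curve_df = pd.DataFrame(
        {"A": curve.a_grid, "capacity": curve.capacity, "optimal_P01": curve.optimal_p01}
    )
    return surface, curve_df


def run_lna_suite(config: ExperimentConfig) -> pd.DataFrame:
    """High-count steady states, variances, and AWGN capacities.

    For each volume in the omega grid: the reduced SISO mean/variance, the
    load-free identity mu_N = mu_0, the 1/omega variance scaling, and the
    numerically Lyapunov-solved loaded variance sigma_N^2 (recording the
    sign of sigma_0^2 - sigma_N^2, an exploratory probe of whether load can
    only shrink the output variance).
    """
    r = config.rates
    c1, c2 = r["c1"], r["c2"]
    e, itot1, dtot = 1.0, 10.0, 1.0
    k3p, k3m = r["k3_plus"], r["k3_minus"]
    k3 = k3m / k3p
    n = max(config.n_max, 1)
    rows = []
    for omega in config.omega_grid:
        mu0 = lna.siso_reduced_mean(c1, e, itot1, c2)
        var0 = lna.siso_reduced_variance(c1, e, itot1, c2, omega)
        mu_n = lna.siso_downstream_mean(c1, e, itot1, c2, k3, dtot, n)
        state = lna.siso_downstream_covariance(
            c1, e, itot1, c2, k3p, k3m, dtot, n, omega
        )
        var_n = state.variance("Z1")
        rows.append(
            {
                "omega": omega,
                "N": n,
                "mu0": mu0,
                "muN": mu_n,
                "sigma0_sq": var0,
                "sigmaN_sq": var_n,
                "load_shrinks_variance": var_n < var0,
                "capacity0": lna.awgn_capacity(var0, 1.0, config.units),
                "capacityN": lna.awgn_capacity(var_n, 1.0, config.units),
            }
        )
    return pd.DataFrame(rows)


def run_validation(config: ExperimentConfig) -> pd.DataFrame:
    """Cross-engine consistency battery.

    Along the fast-binding ladder the exact CME constant must approach the
    closed form within the regime tolerance ladder; violations raise.
    """
    rows = []
    for scale, tol in REGIME_TOLERANCES.items():
        for n in (0, 2):
            rates = ladder_rates(scale, n_sites=n)
            topo = Topology.SISO_N_DOWNSTREAM if n else Topology.ISOLATED_SISO
            model = build_model(topo, rates, n_downstream=n)
            a_cme = cme.a_hat(model)
            a_ana = (
                constants.aN(rates.k0, rates.c1, rates.c2, rates.k3).value
                if n
                else constants.a0(rates.k0, rates.c1, rates.c2).value
            )
            err = abs(a_cme - a_ana)
            if err > tol:
                raise RuntimeError(
                    f"cross-engine disagreement at scale {scale}, N={n}: "
                    f"|{a_cme} - {a_ana}| = {err:.3g} > {tol}"
                )
            rows.append(
                {
                    "scale": scale,
                    "N": n,
                    "n_states": len(cme.enumerate_states(model, (1, 0))),
                    "A_cme": a_cme,
                    "A_analytic": a_ana,
                    "abs_error": err,
                    "tolerance": tol,
                }
            )
    return pd.DataFrame(rows)
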