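"""Shared fixtures: the fast-limit Poisson simulation ladder.

The ladder runs the Poisson-division model at a fixed characteristic length
(lam = 41.74 um) for three (D, k) pairs spanning two decades of reaction-
diffusion speed, five seeds each, on a desk-scale strip.  Two acceptance
checks share these runs: agreement of the simulated recruitment limit with
the closed-form fast-limit theory (fastest two pairs), and the decrease of
the simulation-vs-theory error with increasing D.
"""

import numpy as np
import pytest

from axoregen.engine import SimulationConfig, run_simulation
from axoregen.theory import TheoryParams, population_lengths

LAM_FAST = 41.74  # um
K_LADDER_PER_DAY = (1.0, 10.0, 100.0)
LADDER_SEEDS = (0, 1, 2, 3, 4)
NU_SLOW = np.log(2.0) / 340.0
NU_FAST = np.log(2.0) / 119.0


def d_for_lambda(lam_um: float, k_per_day: float) -> float:
    """Diffusion coefficient (um^2/s) pairing with k (1/day) at fixed lam."""
    return lam_um**2 * (k_per_day / 24.0) / 3600.0


def poisson_config(D, k, seed, **kw):
    base = dict(
        D=D,
        k=k,
        rho0=20.0,
        rhosmin=1.0,
        particle_mass=80.0,
        R_um=7.0,
        L0_um=400.0,
        ymax_um=56.0,
        t_end_days=8.0,
        seed=seed,
        division_model="poisson",
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def fast_limit_ladder():
    """dict: k (1/day) -> list over seeds of (observables, theory curves)."""
    out = {}
    for k in K_LADDER_PER_DAY:
        D = d_for_lambda(LAM_FAST, k)
        runs = []
        for seed in LADDER_SEEDS:
            obs = run_simulation(poisson_config(D, k, seed)).observables
            L0_eff = float(obs["L_um"].iloc[0])
            p = TheoryParams(
                lam=LAM_FAST,
                rho0=20.0,
                rhosmin=1.0,
                nu_slow=NU_SLOW,
                nu_fast=NU_FAST,
                L0=L0_eff,
            )
            t_h = obs["t_days"].to_numpy() * 24.0
            Ls_th, Lf_th = population_lengths(t_h, p)
            runs.append({"obs": obs, "Ls_th": Ls_th, "Lf_th": Lf_th, "L0_eff": L0_eff})
        out[k] = runs
    return out
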