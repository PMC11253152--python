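"""Closed-form theory of regenerative outgrowth in the fast reaction-diffusion limit.

When signal diffusion and degradation are much faster than cell division, the
signal density relaxes instantaneously to the steady state of

    D rho'' = k rho   on [0, L(t)],   rho(0) = 0,  rho(L) = rho0,

whose solution is ``rho(x) = rho0 * sinh(x/lam) / sinh(L/lam)`` with the
characteristic length ``lam = sqrt(D/k)``.  Cells posterior to the position
``x*`` where the profile crosses the recruitment threshold ``rhosmin`` are
recruited to the fast-cycling program.  With Poisson division frequencies
``nu_slow < nu_fast`` the two population zones then grow exponentially,

    Ls(t) = (xi0 + L0) e^{nu_slow t},    Lf(t) = -xi0 e^{nu_fast t},

where ``xi0 = x*(L0) - L0 <= 0`` is the initial recruitment limit in
amputation-plane coordinates.  These expressions are exact whenever the
recruitment position stays inside the already-recruited zone for all times,
which holds under the initial-condition inequality of
:func:`proposition1_condition`.

All lengths are in micrometres.  Functions in this module take time in hours
and rates in 1/hour; the only exception is :func:`characteristic_length`,
which accepts the bench units used throughout the package configuration
surface (D in um^2/s, k in 1/day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "characteristic_length",
    "steady_state_profile",
    "recruitment_position",
    "xi0",
    "population_lengths",
    "outgrowth",
    "recruitment_limit",
    "proposition1_condition",
    "integrate_growth_ode",
]

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0

# switch to log-space evaluation of sinh/cosh ratios above this argument;
# naive sinh overflows float64 near 710
_LOG_SWITCH = 30.0


def _log_sinh(a: np.ndarray | float) -> np.ndarray | float:
    """log(sinh(a)) for a > 0, overflow-safe."""
    a = np.asarray(a, dtype=float)
    return a + np.log1p(-np.exp(-2.0 * a)) - np.log(2.0)


def _log_cosh(a: np.ndarray | float) -> np.ndarray | float:
    a = np.asarray(a, dtype=float)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


def _asinh_exp(log_s: np.ndarray | float) -> np.ndarray | float:
    """asinh(s) given log(s), stable for arbitrarily large s."""
    arr = np.atleast_1d(np.asarray(log_s, dtype=float))
    small = arr < _LOG_SWITCH
    out = np.empty_like(arr)
    out[small] = np.arcsinh(np.exp(arr[small]))
    # asinh(s) = log(2s) + log((1 + sqrt(1 + s^-2)) / 2) -> log(2s) for s >> 1
    out[~small] = arr[~small] + np.log(2.0)
    return float(out[0]) if np.isscalar(log_s) or np.ndim(log_s) == 0 else out


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the fast reaction-diffusion growth theory.

    Attributes
    ----------
    lam : float
        Signal characteristic length sqrt(D/k), um.  Must satisfy
        ``lam < L0`` (the gradient must live inside the tissue).
    rho0 : float
        Signal density imposed at the regenerating front (source).
    rhosmin : float
        Minimal signal density required to recruit a cell.  The cell-to-signal
        sensitivity is ``SR = 1/rhosmin``.  Must not exceed ``rho0``.
    nu_slow, nu_fast : float
        Poisson division frequencies of non-recruited / recruited cells, 1/h,
        with ``nu_fast > nu_slow``.
    L0 : float
        Initial tissue length (distance from the fixed anterior boundary to
        the amputation plane), um.
    """

    lam: float
    rho0: float
    rhosmin: float
    nu_slow: float
    nu_fast: float
    L0: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.L0 <= 0:
            raise ValueError("lam and L0 must be positive")
        if self.lam >= self.L0:
            raise ValueError(
                f"characteristic length lam={self.lam} must be smaller than L0={self.L0}"
            )
        if self.rhosmin > self.rho0:
            raise ValueError(
                f"rhosmin={self.rhosmin} exceeds the front density rho0={self.rho0}: "
                "no cell can ever be recruited"
            )
        if self.rhosmin <= 0 or self.rho0 <= 0:
            raise ValueError("rho0 and rhosmin must be positive")
        if self.nu_fast <= self.nu_slow:
            raise ValueError("nu_fast must exceed nu_slow")


def characteristic_length(D_um2_s: float, k_per_day: float) -> float:
    """Characteristic length lam = sqrt(D/k) in um.

    Parameters are given in the units quoted throughout the package
    configuration: D in um^2/s and k in 1/day.  They are converted to the
    internal hour-based units before taking the square root.
    """
    if D_um2_s <= 0 or k_per_day <= 0:
        raise ValueError("D and k must be positive")
    D_h = D_um2_s * SECONDS_PER_HOUR
    k_h = k_per_day / HOURS_PER_DAY
    return float(np.sqrt(D_h / k_h))


def steady_state_profile(
    x: np.ndarray | float, L: float, lam: float, rho0: float
) -> np.ndarray | float:
    """Steady-state signal density rho0*sinh(x/lam)/sinh(L/lam) on [0, L]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > L):
        raise ValueError("x must lie in [0, L]")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.zeros_like(x)
    pos = x > 0
    # exp-shifted log evaluation; exact ratio for moderate arguments too
    out[pos] = rho0 * np.exp(_log_sinh(x[pos] / lam) - _log_sinh(L / lam))
    return float(out[0]) if scalar else out


def recruitment_position(L: float, params: TheoryParams) -> float:
    """Anterior-most recruited position x* in shifted coordinates.

    Solves ``steady_state_profile(x*, L) = rhosmin``:

        x* = lam * asinh( (rhosmin/rho0) * sinh(L/lam) ).
    """
    p = params
    log_s = np.log(p.rhosmin / p.rho0) + _log_sinh(L / p.lam)
    xstar = float(p.lam * _asinh_exp(log_s))
    return min(xstar, L)


def xi0(params: TheoryParams) -> float:
    """Initial recruitment limit xi(0) = x*(L0) - L0, in amputation-plane
    coordinates (non-positive: anterior of the amputation plane)."""
    return recruitment_position(params.L0, params) - params.L0


def population_lengths(
    t_hours: np.ndarray | float, params: TheoryParams
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Closed-form extents (Ls, Lf) of the slow and fast zones at time t (h)."""
    t = np.asarray(t_hours, dtype=float)
    x0 = xi0(params)
    Ls = (x0 + params.L0) * np.exp(params.nu_slow * t)
    Lf = -x0 * np.exp(params.nu_fast * t)
    return Ls, Lf


def outgrowth(t_hours: np.ndarray | float, params: TheoryParams) -> np.ndarray | float:
    """Tissue outgrowth Ls(t) + Lf(t) - L0 beyond the amputation plane (um)."""
    Ls, Lf = population_lengths(t_hours, params)
    return Ls + Lf - params.L0


def recruitment_limit(t_hours: np.ndarray | float, params: TheoryParams) -> np.ndarray:
    """Theoretical recruitment limit xi(t) = Ls(t) - L0 (um).

    The most anterior recruited cell sits at the interface between the slow
    and fast zones.  In the regime of :func:`proposition1_condition` the
    recruitment position x*(t) stays posterior of that interface, no new
    recruitment occurs, and the interface follows the closed-form slow-zone
    length; xi(0) = x*(L0) - L0 in either case.
    """
    t = np.atleast_1d(np.asarray(t_hours, dtype=float))
    Ls, _ = population_lengths(t, params)
    return Ls - params.L0


def proposition1_condition(
    params: TheoryParams,
    Ls0: float | None = None,
    Lf0: float | None = None,
) -> bool:
    """Initial-condition inequality under which the recruitment position stays
    inside the already-recruited zone for all t > 0 (making the closed-form
    population lengths exact):

        nu_fast * Lf(0) > nu_slow * Ls(0) * sqrt((rho0/rhosmin)^2 - 1) / cosh(L0/lam)

    By default Ls0, Lf0 are the theory's own initial zone extents.
    The inequality is strict; equality returns False.
    """
    p = params
    if Ls0 is None or Lf0 is None:
        x0 = xi0(p)
        Ls0 = x0 + p.L0 if Ls0 is None else Ls0
        Lf0 = -x0 if Lf0 is None else Lf0
    ratio2 = (p.rho0 / p.rhosmin) ** 2 - 1.0
    if ratio2 < 0:
        raise ValueError("rhosmin > rho0: condition undefined")
    if ratio2 == 0.0:  # rhosmin == rho0: RHS vanishes
        return p.nu_fast * Lf0 > 0.0
    if Lf0 <= 0.0:
        return False
    if p.L0 / p.lam < _LOG_SWITCH:  # direct evaluation, exact strictness
        rhs = p.nu_slow * Ls0 * np.sqrt(ratio2) / np.cosh(p.L0 / p.lam)
        return bool(p.nu_fast * Lf0 > rhs)
    log_lhs = np.log(p.nu_fast * Lf0)
    log_rhs = (
        np.log(p.nu_slow * Ls0) + 0.5 * np.log(ratio2) - _log_cosh(p.L0 / p.lam)
    )
    return bool(log_lhs > log_rhs)


def integrate_growth_ode(
    params: TheoryParams,
    Ls0: float | None = None,
    Lf0: float | None = None,
    t_end_hours: float = 192.0,
    dt_hours: float = 0.24,
) -> dict[str, np.ndarray]:
    """Integrate the two-zone growth law with instantaneous recruitment.

    Between recruitment events the zones obey ``Ls' = nu_slow Ls`` and
    ``Lf' = nu_fast Lf`` (so the total length follows
    ``L' = nu_slow Ls + nu_fast Lf``), advanced with fixed-step RK4.  After
    each step the steady-state recruitment position ``x*(L)`` is evaluated;
    if it falls inside the slow zone the intervening cells are recruited
    instantaneously (Ls -> x*, the difference moves to Lf).  Under the
    condition of :func:`proposition1_condition` this projection never fires
    and the trajectories coincide with the closed forms.

    Returns a dict of arrays ``t`` (hours), ``Ls``, ``Lf``, ``L``, ``xstar``.
    """
    p = params
    if Ls0 is None or Lf0 is None:
        x0 = xi0(p)
        Ls0 = x0 + p.L0 if Ls0 is None else Ls0
        Lf0 = -x0 if Lf0 is None else Lf0
    if dt_hours <= 0:
        raise ValueError("dt_hours must be positive")
    if p.nu_fast > 0 and dt_hours > 0.2 / p.nu_fast:
        raise ValueError(
            f"dt_hours={dt_hours} too large relative to 1/nu_fast={1.0 / p.nu_fast:.3g} h"
        )
    n = int(np.ceil(t_end_hours / dt_hours)) + 1
    t = np.minimum(np.arange(n) * dt_hours, t_end_hours)
    Ls = np.empty(n)
    Lf = np.empty(n)
    xs = np.empty(n)
    Ls[0], Lf[0] = Ls0, Lf0
    xs[0] = recruitment_position(Ls0 + Lf0, p)
    for i in range(1, n):
        h = t[i] - t[i - 1]
        # linear decoupled system: RK4 per component
        Ls[i] = _rk4_exp(Ls[i - 1], p.nu_slow, h)
        Lf[i] = _rk4_exp(Lf[i - 1], p.nu_fast, h)
        xstar = recruitment_position(Ls[i] + Lf[i], p)
        if xstar < Ls[i]:  # recruitment wave enters the slow zone
            Lf[i] += Ls[i] - xstar
            Ls[i] = xstar
        xs[i] = xstar
    return {"t": t, "Ls": Ls, "Lf": Lf, "L": Ls + Lf, "xstar": xs}


def _rk4_exp(y: float, nu: float, h: float) -> float:
    """One RK4 step of y' = nu*y."""
    k1 = nu * y
    k2 = nu * (y + 0.5 * h * k1)
    k3 = nu * (y + 0.5 * h * k2)
    k4 = nu * (y + h * k3)
    return y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
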