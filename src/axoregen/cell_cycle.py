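"""Cell-cycle clocks, recruitment-induced cycle shortening, and division.

Each ependymal cell carries a non-Markovian clock: a total cycle length T
drawn from a lognormal distribution and an age C within the cycle.
Non-recruited (slow) cells have mean cycle 340 h (sd 32 h); recruited (fast)
cells have mean 119 h (sd 10 h).  Recruitment is irreversible and heritable,
and shortens the cycle by partially skipping G1 and proportionally mapping
the long S phase onto the short one; time already spent in G2/M is preserved
as time-to-division.

A simplified memoryless variant replaces the clocks with Poisson division at
frequency nu_slow or nu_fast; it underlies the closed-form growth theory.

All times are in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellPopulation, DomainGeometry

__all__ = [
    "CycleParams",
    "CellClock",
    "PHASE_LABELS",
    "sample_cycle_length",
    "sample_initial_age",
    "initialize_clocks",
    "recruit_cells",
    "recruit_cell",
    "advance_and_divide",
    "poisson_divide",
    "phase_of",
    "phase_code",
]

PHASE_LABELS = ("G0/G1", "S", "G2/M")

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CycleParams:
    """Cell-cycle parameters.

    mu/sd are the mean and standard deviation (hours) of the lognormal cycle
    length distributions (converted internally to log-space parameters).
    Phase fractions are the G1 / S / G2+M shares of the total cycle for each
    program; the numeric defaults are documented placeholders, configurable
    because the original supplementary parameter table is not reproduced
    here.  nu_slow/nu_fast are the Poisson-variant division frequencies
    (1/h); the defaults ln2/mu give the same population doubling pace as the
    clock model.  theta_star is the daughter-placement half-angle (rad).
    """

    mu_slow: float = 340.0
    sd_slow: float = 32.0
    mu_fast: float = 119.0
    sd_fast: float = 10.0
    frac_slow: tuple[float, float, float] = (0.45, 0.40, 0.15)
    frac_fast: tuple[float, float, float] = (0.20, 0.60, 0.20)
    nu_slow: float = LN2 / 340.0
    nu_fast: float = LN2 / 119.0
    theta_star: float = np.pi / 8.0

    def __post_init__(self) -> None:
        if min(self.mu_slow, self.sd_slow, self.mu_fast, self.sd_fast) <= 0:
            raise ValueError("lognormal means and sds must be positive")
        if self.mu_fast >= self.mu_slow:
            raise ValueError("fast cycle must be shorter on average than slow")
        for name, fr in (("frac_slow", self.frac_slow), ("frac_fast", self.frac_fast)):
            if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be three positive fractions summing to 1")
        if self.nu_fast <= self.nu_slow:
            raise ValueError("nu_fast must exceed nu_slow")
        if self.sd_slow >= self.mu_slow or self.sd_fast >= self.mu_fast:
            warnings.warn(
                "cycle-length sd is of the order of the mean; check mu/sd ordering",
                stacklevel=2,
            )

    def lognormal_params(self, fast: bool) -> tuple[float, float]:
        """(mu_log, sigma_log) of the underlying normal."""
        m = self.mu_fast if fast else self.mu_slow
        s = self.sd_fast if fast else self.sd_slow
        sigma2 = np.log1p((s / m) ** 2)
        return float(np.log(m) - 0.5 * sigma2), float(np.sqrt(sigma2))

    def fractions(self, fast: bool) -> tuple[float, float, float]:
        return self.frac_fast if fast else self.frac_slow


@dataclass(frozen=True)
class CellClock:
    """Scalar view of one cell's cycle state (T, age, program, recruited)."""

    T: float
    age: float
    fast: bool = False
    recruited: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.age < self.T):
            raise ValueError("age must lie in [0, T)")


def _program_is_fast(program: str | bool) -> bool:
    if isinstance(program, str):
        if program not in ("slow", "fast"):
            raise ValueError("program must be 'slow' or 'fast'")
        return program == "fast"
    return bool(program)


def sample_cycle_length(
    program: str | bool,
    params: CycleParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw cycle length(s) T from the program's lognormal distribution.

    mu/sd parametrize the distribution itself (not log-space), so large
    samples converge to exactly the configured mean and sd.
    """
    mu_log, sd_log = params.lognormal_params(_program_is_fast(program))
    out = rng.lognormal(mu_log, sd_log, size=size)
    return float(out) if size is None else out


def sample_initial_age(
    T: float | np.ndarray, rng: np.random.Generator
) -> float | np.ndarray:
    """Initial age within the cycle for a pre-existing population.

    Ages follow a truncated exponential on [0, T) with rate 2 ln2 / T, i.e.
    density proportional to 2^(-2C/T) (four times more cells at the start of
    the cycle than at its end), normalized to integrate to one and sampled
    by inverse CDF.
    """
    T = np.asarray(T, dtype=float)
    u = rng.uniform(size=T.shape)
    age = -T / (2.0 * LN2) * np.log1p(-0.75 * u)
    return float(age) if age.ndim == 0 else age


def initialize_clocks(
    pop: CellPopulation, params: CycleParams, rng: np.random.Generator
) -> None:
    """Draw slow-program cycle lengths and initial ages for a fresh population."""
    pop.T = np.asarray(
        sample_cycle_length("slow", params, rng, size=pop.n), dtype=float
    )
    pop.age = np.asarray(sample_initial_age(pop.T, rng), dtype=float)
    pop.fast = np.zeros(pop.n, dtype=bool)
    pop.recruited = np.zeros(pop.n, dtype=bool)


def _phase_bounds(T: np.ndarray, fast: np.ndarray, params: CycleParams):
    """(end of G1, end of S) per cell, hours."""
    f_s = np.asarray(params.frac_slow)
    f_f = np.asarray(params.frac_fast)
    g1 = np.where(fast, f_f[0], f_s[0]) * T
    s_end = g1 + np.where(fast, f_f[1], f_s[1]) * T
    return g1, s_end


def phase_code(
    T: np.ndarray, age: np.ndarray, fast: np.ndarray, params: CycleParams
) -> np.ndarray:
    """Phase index per cell: 0 = G0/G1, 1 = S, 2 = G2/M."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    age = np.atleast_1d(np.asarray(age, dtype=float))
    fast = np.atleast_1d(np.asarray(fast, dtype=bool))
    g1, s_end = _phase_bounds(T, fast, params)
    return np.where(age < g1, 0, np.where(age < s_end, 1, 2)).astype(int)


def phase_of(clock: CellClock, params: CycleParams) -> str:
    """Phase label of a single clock."""
    code = phase_code(
        np.array([clock.T]), np.array([clock.age]), np.array([clock.fast]), params
    )[0]
    return PHASE_LABELS[code]


def recruit_cells(
    pop: CellPopulation,
    idx: np.ndarray,
    params: CycleParams,
    rng: np.random.Generator,
) -> None:
    """Switch cells idx to the fast program (idempotent, irreversible).

    The new cycle length is a fresh fast-program draw; the age maps so that
    - in G1: age is preserved, but capped at the end of the (shorter) fast
      G1 (partial G1 skip);
    - in S: the fractional progress through S is preserved;
    - in G2/M: the remaining time to division is preserved.
    """
    idx = np.asarray(idx, dtype=int)
    idx = idx[~pop.recruited[idx]]
    if len(idx) == 0:
        return
    T_old = pop.T[idx]
    age_old = pop.age[idx]
    g1_old, s_end_old = _phase_bounds(T_old, pop.fast[idx], params)
    T_new = np.asarray(sample_cycle_length("fast", params, rng, size=len(idx)))
    fastmask = np.ones(len(idx), dtype=bool)
    g1_new, s_end_new = _phase_bounds(T_new, fastmask, params)

    age_new = np.empty_like(age_old)
    in_g1 = age_old < g1_old
    in_s = (~in_g1) & (age_old < s_end_old)
    in_g2 = ~(in_g1 | in_s)
    age_new[in_g1] = np.minimum(age_old[in_g1], g1_new[in_g1])
    frac = (age_old[in_s] - g1_old[in_s]) / (s_end_old[in_s] - g1_old[in_s])
    age_new[in_s] = g1_new[in_s] + frac * (s_end_new[in_s] - g1_new[in_s])
    remaining = T_old[in_g2] - age_old[in_g2]
    age_new[in_g2] = np.maximum(T_new[in_g2] - remaining, 0.0)

    pop.T[idx] = T_new
    pop.age[idx] = np.minimum(age_new, np.nextafter(T_new, 0.0))
    pop.fast[idx] = True
    pop.recruited[idx] = True


def recruit_cell(
    clock: CellClock, params: CycleParams, rng: np.random.Generator
) -> CellClock:
    """Scalar recruitment; no-op if the clock is already recruited."""
    if clock.recruited:
        return clock
    pop = _singleton_pop(clock)
    recruit_cells(pop, np.array([0]), params, rng)
    return CellClock(
        T=float(pop.T[0]), age=float(pop.age[0]), fast=True, recruited=True
    )


def _singleton_pop(clock: CellClock) -> CellPopulation:
    pop = CellPopulation.from_positions(np.zeros(1), np.zeros(1), 1.0)
    pop.T = np.array([clock.T])
    pop.age = np.array([clock.age])
    pop.fast = np.array([clock.fast])
    pop.recruited = np.array([clock.recruited])
    return pop


def _place_daughters(
    pop: CellPopulation,
    mothers: np.ndarray,
    params: CycleParams,
    rng: np.random.Generator,
    geom: DomainGeometry,
) -> np.ndarray:
    """Append one new cell per mother (the mother stays in place).

    The second daughter lands at a uniform distance in (0, 2R) and an angle
    uniform in (-theta_star, theta_star) off the posterior-pointing AP axis,
    which biases growth toward the free boundary.  Returns the new ids.
    """
    m = len(mothers)
    dist = rng.uniform(0.0, 2.0 * pop.radius, size=m)
    theta = rng.uniform(-params.theta_star, params.theta_star, size=m)
    new_x = np.maximum(pop.x[mothers] + dist * np.cos(theta), 0.0)
    new_y = geom.wrap_y(pop.y[mothers] + dist * np.sin(theta))
    new_ids = np.arange(pop.next_id, pop.next_id + m, dtype=np.int64)
    pop.x = np.concatenate([pop.x, new_x])
    pop.y = np.concatenate([pop.y, new_y])
    pop.recruited = np.concatenate([pop.recruited, pop.recruited[mothers]])
    pop.lineage = np.concatenate([pop.lineage, pop.lineage[mothers]])
    pop.ids = np.concatenate([pop.ids, new_ids])
    pop.fast = np.concatenate([pop.fast, pop.fast[mothers]])
    pop.next_id += m
    return new_ids


def advance_and_divide(
    pop: CellPopulation,
    dt: float,
    params: CycleParams,
    rng: np.random.Generator,
    geom: DomainGeometry,
    t: float = 0.0,
) -> list[dict]:
    """Advance all clocks by dt hours and divide cells reaching T.

    On division both daughters draw a fresh cycle length from their program's
    distribution; the residual age overshoot (age - T at step end) is carried
    into the new cycle to avoid a systematic dt/2 delay.  The recruitment
    flag and lineage are inherited.  Returns division-event records
    (t, mother_id, daughter_ids, recruited).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if pop.n and dt > 0.1 * pop.T.min():
        warnings.warn(
            f"dt={dt} h is large relative to the shortest cycle ({pop.T.min():.1f} h); "
            "division events may be under-resolved",
            stacklevel=2,
        )
    pop.age = pop.age + dt
    mothers = np.flatnonzero(pop.age >= pop.T)
    events: list[dict] = []
    if len(mothers) == 0:
        return events
    residual = pop.age[mothers] - pop.T[mothers]
    new_ids = _place_daughters(pop, mothers, params, rng, geom)
    m = len(mothers)
    fast = pop.fast[mothers]
    T1 = np.where(
        fast,
        np.asarray(sample_cycle_length("fast", params, rng, size=m)),
        np.asarray(sample_cycle_length("slow", params, rng, size=m)),
    )
    T2 = np.where(
        fast,
        np.asarray(sample_cycle_length("fast", params, rng, size=m)),
        np.asarray(sample_cycle_length("slow", params, rng, size=m)),
    )
    pop.T[mothers] = T1
    pop.age[mothers] = np.minimum(residual, np.nextafter(T1, 0.0))
    pop.T = np.concatenate([pop.T, T2])
    pop.age = np.concatenate(
        [pop.age[: pop.n - m], np.minimum(residual, np.nextafter(T2, 0.0))]
    )
    for k, mo in enumerate(mothers):
        events.append(
            {
                "t": t,
                "mother_id": int(pop.ids[mo]),
                "daughter_ids": (int(pop.ids[mo]), int(new_ids[k])),
                "recruited": bool(pop.recruited[mo]),
            }
        )
    return events


def poisson_divide(
    pop: CellPopulation,
    dt: float,
    params: CycleParams,
    rng: np.random.Generator,
    geom: DomainGeometry,
    t: float = 0.0,
) -> list[dict]:
    """Memoryless division variant: each cell divides with probability
    1 - exp(-nu dt), nu chosen by recruitment status.  Clocks are ignored."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    nu = np.where(pop.recruited, params.nu_fast, params.nu_slow)
    if np.any(nu * dt > 0.2):
        warnings.warn(
            "nu*dt > 0.2: the per-step Bernoulli draw is a poor Poisson "
            "approximation; reduce dt",
            stacklevel=2,
        )
    p = -np.expm1(-nu * dt)
    mothers = np.flatnonzero(rng.uniform(size=pop.n) < p)
    events: list[dict] = []
    if len(mothers) == 0:
        return events
    new_ids = _place_daughters(pop, mothers, params, rng, geom)
    pop.T = np.concatenate([pop.T, pop.T[mothers]])
    pop.age = np.concatenate([pop.age, np.zeros(len(mothers))])
    for k, mo in enumerate(mothers):
        events.append(
            {
                "t": t,
                "mother_id": int(pop.ids[mo]),
                "daughter_ids": (int(pop.ids[mo]), int(new_ids[k])),
                "recruited": bool(pop.recruited[mo]),
            }
        )
    return events
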