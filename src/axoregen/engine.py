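"""Operator-splitting driver coupling cells, clocks and signal; observables.

One simulation step applies, in fixed order: signal diffusion, stochastic
degradation, boundary enforcement at the current tissue length, recruitment
of eligible cells (exposure to >= 2 particles and local density above
rhosmin), cell division (clock-based or Poisson variant), hard-disc
relaxation of any division overlaps, and tissue-length / observable updates.
Recruitment precedes division so a cell recruited within a step divides on
the fast program thereafter.

The configuration surface uses bench units (D in um^2/s, k in 1/day,
lengths in um, times in days); everything is converted to um/hours
internally.  A run is fully determined by its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_cycle import (
    CycleParams,
    advance_and_divide,
    initialize_clocks,
    phase_code,
    poisson_divide,
    recruit_cells,
)
from .geometry import (
    CellPopulation,
    DomainGeometry,
    initialize_cells,
    relax_overlaps,
    tissue_length,
)
from .signal_sph import (
    SignalField,
    apply_boundaries,
    choose_timestep,
    degradation_step,
    diffusion_step,
    exposure,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "recruitment_limit",
    "phase_profile",
    "newly_recruited_counts",
    "snapshot_frame",
]

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0
HEX_AREA = 2.0 * np.sqrt(3.0)  # area per disc of unit radius in hex packing


@dataclass
class SimulationConfig:
    """All model parameters, in bench units.

    Signal: D (um^2/s), k (1/day), rho0 and rhosmin (signal-density units),
    rho_star (None -> rho0/100), particle_mass, kernel radius h_um
    (None -> 4R).  Geometry: R_um, L0_um, ymin_um/ymax_um, repulsion kappa.
    Cells: cycle (CycleParams), division_model 'clock' or 'poisson',
    n_throw (None -> hex-packing estimate for the strip).  Run control:
    t_end_days, record_every_days, snapshot_days (phase-profile snapshots),
    seed, cfl_C, dt_cap_hours, degrade_in_source.
    """

    D: float = 1.0
    k: float = 1.0
    rho0: float = 60.0
    rhosmin: float = 3.0
    rho_star: float | None = None
    particle_mass: float = 1.0
    h_um: float | None = None
    R_um: float = 7.0
    L0_um: float = 1000.0
    ymin_um: float = 0.0
    ymax_um: float = 180.0
    kappa: float = 1.0
    cycle: CycleParams = dc_field(default_factory=CycleParams)
    division_model: str = "clock"
    n_throw: int | None = None
    t_end_days: float = 8.0
    record_every_days: float = 0.2
    snapshot_days: tuple[float, ...] = ()
    seed: int = 0
    cfl_C: float = 0.5
    dt_cap_hours: float = 0.5
    degrade_in_source: bool = False
    phase_bin_um: float = 50.0

    def __post_init__(self) -> None:
        if self.division_model not in ("clock", "poisson"):
            raise ValueError("division_model must be 'clock' or 'poisson'")
        if self.rhosmin <= 0 or self.rho0 <= 0:
            raise ValueError("rho0 and rhosmin must be positive")

    # -- derived, internal units ------------------------------------------
    @property
    def D_um2_h(self) -> float:
        return self.D * SECONDS_PER_HOUR

    @property
    def k_per_h(self) -> float:
        return self.k / HOURS_PER_DAY

    @property
    def lam_um(self) -> float:
        return float(np.sqrt(self.D_um2_h / self.k_per_h))

    def geometry(self) -> DomainGeometry:
        return DomainGeometry(L0=self.L0_um, ymin=self.ymin_um, ymax=self.ymax_um)

    def default_n_throw(self) -> int:
        """Overfill the strip slightly beyond hexagonal packing; the relaxing
        cloud expands past L0 and the spill-over is cut, leaving [0, L0] at a
        reproducible near-jammed density so that cell divisions translate
        into tissue extension from the start."""
        area = self.L0_um * (self.ymax_um - self.ymin_um)
        return int(round(1.12 * area / (HEX_AREA * self.R_um**2)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snapshot_days"] = list(self.snapshot_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cycle" in d and isinstance(d["cycle"], dict):
            cyc = dict(d["cycle"])
            for key in ("frac_slow", "frac_fast"):
                if key in cyc:
                    cyc[key] = tuple(cyc[key])
            d["cycle"] = CycleParams(**cyc)
        if "snapshot_days" in d:
            d["snapshot_days"] = tuple(d["snapshot_days"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimulationResult:
    """Observables plus final state and a reproducibility manifest."""

    observables: pd.DataFrame
    division_events: pd.DataFrame
    recruitment_events: pd.DataFrame
    population: CellPopulation
    field: SignalField
    phase_profiles: dict[float, pd.DataFrame]
    manifest: dict

    def write(self, outdir) -> None:
        """Tidy CSV per observable table plus a JSON run manifest."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.observables.to_csv(out / "observables.csv", index=False)
        self.division_events.to_csv(out / "division_events.csv", index=False)
        self.recruitment_events.to_csv(out / "recruitment_events.csv", index=False)
        for day, prof in self.phase_profiles.items():
            prof.to_csv(out / f"phase_profile_day{day:g}.csv", index=False)
        from .signal_sph import particle_frame

        t_end = float(self.observables["t_days"].iloc[-1])
        particle_frame(self.field, t_end).to_csv(
            out / "particles_final.csv", index=False
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def recruitment_limit(pop: CellPopulation, L0: float) -> float:
    """xi = min x over recruited cells, in amputation-plane coordinates
    (x - L0).  NaN when no cell is recruited."""
    if not np.any(pop.recruited):
        return float("nan")
    return float(pop.x[pop.recruited].min() - L0)


def phase_profile(
    pop: CellPopulation,
    params: CycleParams,
    L0: float,
    bin_width: float = 50.0,
) -> pd.DataFrame:
    """Fractions of cells in G0/G1 versus S/G2 per AP-axis bin.

    S, G2 and M are pooled into the S/G2 channel, matching how FUCCI-style
    reporters read out.  Positions are reported at bin centers in
    amputation-plane coordinates.  Empty bins carry NaN fractions.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    codes = phase_code(pop.T, pop.age, pop.fast, params)
    edges = np.arange(0.0, pop.x.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(pop.x, edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    total = np.bincount(idx, minlength=nb).astype(float)
    n_g1 = np.bincount(idx, weights=(codes == 0).astype(float), minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_g1 = np.where(total > 0, n_g1 / total, np.nan)
    return pd.DataFrame(
        {
            "z_um": 0.5 * (edges[:-1] + edges[1:]) - L0,
            "frac_g0g1": frac_g1,
            "frac_sg2": np.where(total > 0, 1.0 - frac_g1, np.nan),
            "n_cells": total.astype(int),
        }
    )


def newly_recruited_counts(
    recruitment_events: pd.DataFrame,
    window_days: float = 0.2,
    t_end_days: float | None = None,
) -> pd.DataFrame:
    """Histogram of signal-induced first-recruitment events per time window.

    Counts only direct recruitment by the signal (inherited recruitment at
    division never enters the event log).  The sum over windows equals the
    number of distinct recruited lineages' founding events.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    times = np.asarray(recruitment_events["t_days"], dtype=float) if len(
        recruitment_events
    ) else np.empty(0)
    t_max = t_end_days if t_end_days is not None else (times.max() if len(times) else window_days)
    edges = np.arange(0.0, t_max + window_days, window_days)
    counts, _ = np.histogram(times, bins=edges)
    return pd.DataFrame(
        {"t_days": 0.5 * (edges[:-1] + edges[1:]), "n_newly_recruited": counts}
    )


def snapshot_frame(
    pop: CellPopulation, geom: DomainGeometry, t_days: float, params: CycleParams
) -> pd.DataFrame:
    """Tabular cell snapshot (shifted and amputation-plane coordinates)."""
    codes = phase_code(pop.T, pop.age, pop.fast, params)
    from .cell_cycle import PHASE_LABELS

    return pd.DataFrame(
        {
            "t": t_days,
            "cell_id": pop.ids,
            "x_shifted": pop.x,
            "z_amputation": pop.x - geom.L0,
            "y": pop.y,
            "recruited": pop.recruited,
            "phase": [PHASE_LABELS[c] for c in codes],
        }
    )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full hybrid simulation described by config.

    Deterministic given config.seed: a single seeded generator drives every
    stochastic draw in a fixed order (initial placement, clocks, signal
    degradation and replenishment, recruitment-remapping draws, division
    placement, relaxation tie-breaks).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry()
    R = cfg.R_um
    h = cfg.h_um if cfg.h_um is not None else 4.0 * R

    n_throw = cfg.n_throw if cfg.n_throw is not None else cfg.default_n_throw()
    pop = initialize_cells(geom, R, n_throw, rng, kappa=cfg.kappa)
    initialize_clocks(pop, cfg.cycle, rng)

    field = SignalField.empty(
        h=h,
        D=cfg.D_um2_h,
        k=cfg.k_per_h,
        rho0=cfg.rho0,
        R=R,
        rho_star=cfg.rho_star,
        m=cfg.particle_mass,
    )
    L = tissue_length(pop, geom)
    apply_boundaries(field, L, geom, rng)

    dt = choose_timestep(
        field.D, field.k, R, C=cfg.cfl_C, cap_hours=cfg.dt_cap_hours
    )
    t_end_h = cfg.t_end_days * HOURS_PER_DAY
    n_steps = int(np.ceil(t_end_h / dt))
    record_every_h = cfg.record_every_days * HOURS_PER_DAY

    records: list[dict] = []
    division_events: list[dict] = []
    recruitment_events: list[dict] = []
    phase_profiles: dict[float, pd.DataFrame] = {}
    snapshot_due = sorted(cfg.snapshot_days)
    next_record = 0.0

    def record(t_h: float) -> None:
        xi = recruitment_limit(pop, geom.L0)
        Ls = xi + geom.L0 if np.isfinite(xi) else L
        records.append(
            {
                "t_days": t_h / HOURS_PER_DAY,
                "xi_um": xi,
                "L_um": L,
                "outgrowth_um": L - geom.L0,
                "Ls_um": Ls,
                "Lf_um": L - Ls,
                "n_cells": pop.n,
                "n_recruited": int(pop.recruited.sum()),
                "n_particles": field.n,
            }
        )

    t_h = 0.0
    record(t_h)
    next_record = record_every_h
    with warnings.catch_warnings():
        # the per-step division warnings are configuration-level diagnostics;
        # raising them once per run is enough
        warnings.simplefilter("once")
        for _ in range(n_steps):
            step_dt = min(dt, t_end_h - t_h)
            if step_dt <= 0:
                break
            diffusion_step(field, step_dt, geom)
            degradation_step(
                field,
                step_dt,
                rng,
                protect_x_min=None if cfg.degrade_in_source else L - 2.0 * R,
            )
            apply_boundaries(field, L, geom, rng)

            candidates = np.flatnonzero(~pop.recruited)
            if len(candidates):
                rho, cnt = exposure(
                    np.column_stack([pop.x[candidates], pop.y[candidates]]),
                    field,
                    geom,
                )
                newly = candidates[(cnt >= 2) & (rho > cfg.rhosmin)]
                if len(newly):
                    t_days_now = (t_h + step_dt) / HOURS_PER_DAY
                    for i in newly:
                        recruitment_events.append(
                            {
                                "t_days": t_days_now,
                                "cell_id": int(pop.ids[i]),
                                "lineage": int(pop.lineage[i]),
                                "z_um": float(pop.x[i] - geom.L0),
                            }
                        )
                    if cfg.division_model == "clock":
                        recruit_cells(pop, newly, cfg.cycle, rng)
                    else:
                        pop.recruited[newly] = True
                        pop.fast[newly] = True

            t_days_now = (t_h + step_dt) / HOURS_PER_DAY
            if cfg.division_model == "clock":
                events = advance_and_divide(
                    pop, step_dt, cfg.cycle, rng, geom, t=t_days_now
                )
            else:
                events = poisson_divide(
                    pop, step_dt, cfg.cycle, rng, geom, t=t_days_now
                )
            if events:
                for ev in events:
                    division_events.append(
                        {
                            "t_days": ev["t"],
                            "mother_id": ev["mother_id"],
                            "daughter1_id": ev["daughter_ids"][0],
                            "daughter2_id": ev["daughter_ids"][1],
                            "recruited": ev["recruited"],
                        }
                    )
                pop.x, pop.y, _ = relax_overlaps(
                    pop.x, pop.y, R, geom, kappa=cfg.kappa, rng=rng
                )
                L = tissue_length(pop, geom)

            t_h += step_dt
            if t_h + 1e-9 >= next_record:
                record(t_h)
                next_record += record_every_h
            while snapshot_due and t_h / HOURS_PER_DAY + 1e-9 >= snapshot_due[0]:
                day = snapshot_due.pop(0)
                phase_profiles[day] = phase_profile(
                    pop, cfg.cycle, geom.L0, cfg.phase_bin_um
                )

    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "code_version": __version__,
        "dt_hours": dt,
        "n_steps": n_steps,
        "final_n_cells": pop.n,
        "final_n_particles": field.n,
    }
    return SimulationResult(
        observables=pd.DataFrame(records),
        division_events=pd.DataFrame(
            division_events,
            columns=["t_days", "mother_id", "daughter1_id", "daughter2_id", "recruited"],
        ),
        recruitment_events=pd.DataFrame(
            recruitment_events, columns=["t_days", "cell_id", "lineage", "z_um"]
        ),
        population=pop,
        field=field,
        phase_profiles=phase_profiles,
        manifest=manifest,
    )
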