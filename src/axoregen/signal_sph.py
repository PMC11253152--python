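"""Particle-based reaction-diffusion solver for the recruitment signal.

The signal density obeys d_t rho = D * Laplacian(rho) - k * rho on the
growing strip occupied by the cells, with density rho0 imposed at the moving
posterior front, an absorbing anterior wall (rho = 0), and periodic y.  It
is discretized by a cloud of equal-mass particles:

* diffusion moves every particle along its regularized density gradient
  (diffusion velocity method), Z <- Z - dt * D * grad(rho) / (rho + rho*),
  with rho and grad(rho) estimated by SPH sums over the 2D Poly6 kernel;
* degradation removes each particle with probability 1 - exp(-k dt)
  (Poisson removal);
* the Dirichlet front condition is enforced discretely by keeping exactly
  NS = round(2R * W * rho0 / m) particles in the source strip
  [L - 2R, L] x [ymin, ymax], and the anterior sink by deleting particles
  that cross x = 0.

Internal units: um, hours.  The configuration surface accepts D in um^2/s
and k in 1/day; conversion happens in the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import cross_density_sorted, self_density_sorted
from .geometry import DomainGeometry

__all__ = [
    "SignalField",
    "poly6",
    "poly6_grad",
    "sph_density",
    "field_density",
    "diffusion_step",
    "degradation_step",
    "apply_boundaries",
    "choose_timestep",
    "exposure",
    "density_profile",
    "simulate_fixed_domain",
]


def poly6(q: np.ndarray, h: float) -> np.ndarray:
    """2D Poly6 kernel W(q, h) = 4/(pi h^8) (h^2 - |q|^2)^3 on |q| <= h.

    q is an (..., 2) displacement array.  Normalized to unit integral over
    the plane; W(0, h) = 4/(pi h^2).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    q = np.asarray(q, dtype=float)
    r2 = np.einsum("...i,...i->...", q, q)
    return _poly6_r2(r2, h)


def _poly6_r2(r2: np.ndarray, h: float) -> np.ndarray:
    d = np.maximum(h * h - r2, 0.0)
    return 4.0 / (np.pi * h**8) * d**3


def poly6_grad(q: np.ndarray, h: float) -> np.ndarray:
    """Gradient of the Poly6 kernel: -24/(pi h^8) (h^2 - |q|^2)^2 * q inside
    the support, zero at q = 0 and outside."""
    if h <= 0:
        raise ValueError("h must be positive")
    q = np.asarray(q, dtype=float)
    r2 = np.einsum("...i,...i->...", q, q)
    d = np.maximum(h * h - r2, 0.0)
    coef = -24.0 / (np.pi * h**8) * d**2
    return coef[..., None] * q


@dataclass
class SignalField:
    """Cloud of equal-mass signalling particles plus the solver parameters.

    D is in um^2/h and k in 1/h (internal units).  rho0 is the Dirichlet
    density at the front; with particle mass m the source strip of width 2R
    holds NS = round(2R * W * rho0 / m) particles (the published scheme is
    the m = 1 case).  rho_star > 0 regularizes the diffusion velocity where
    the density vanishes.
    """

    x: np.ndarray
    y: np.ndarray
    h: float
    D: float
    k: float
    rho0: float
    rho_star: float
    R: float
    m: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.h <= 0 or self.rho_star <= 0 or self.R <= 0 or self.m <= 0:
            raise ValueError("h, rho_star, R and m must be positive")

    @classmethod
    def empty(cls, h, D, k, rho0, R, rho_star=None, m=1.0) -> "SignalField":
        """Field with no particles; rho_star defaults to rho0/100."""
        return cls(
            x=np.empty(0),
            y=np.empty(0),
            h=h,
            D=D,
            k=k,
            rho0=rho0,
            rho_star=rho_star if rho_star is not None else rho0 / 100.0,
            R=R,
            m=m,
        )

    @property
    def n(self) -> int:
        return len(self.x)

    def ns(self, geom: DomainGeometry) -> int:
        """Nominal source-strip particle count NS = round(2R * W * rho0 / m)."""
        return int(round(2.0 * self.R * geom.width * self.rho0 / self.m))

    def ns_effective(self, geom: DomainGeometry, L: float | None = None) -> int:
        """Source-strip count calibrated so the Dirichlet value rho0 sits at
        the front line x = L rather than at the strip's anterior face.

        A uniform strip of width 2R behaves, seen from the interior, like a
        Dirichlet boundary at its anterior face x = L - 2R.  The count is
        therefore scaled by the steady-profile ratio
        sinh((L-2R)/lam)/sinh(L/lam) with lam = sqrt(D/k), which tends to 1
        when lam >> 2R.  Falls back to the nominal NS when k = 0 or L is
        unknown."""
        if L is None or self.k <= 0.0 or self.D <= 0.0:
            return self.ns(geom)
        lam = np.sqrt(self.D / self.k)
        off = 2.0 * self.R
        a = (L - off) / lam
        b = L / lam
        fac = np.exp(a - b) * (-np.expm1(-2.0 * a)) / (-np.expm1(-2.0 * b))
        return int(round(self.ns(geom) * fac))

    @property
    def half_life(self) -> float:
        return np.inf if self.k == 0 else np.log(2.0) / self.k


def sph_density(
    points: np.ndarray,
    field: SignalField,
    geom: DomainGeometry,
    gradients: bool = False,
    counts: bool = False,
):
    """SPH density (optionally gradient and neighbor count) at query points.

    points is an (n, 2) array of (x, y).  Displacements are minimal-image in
    y.  Returns rho, or a tuple with the requested extras appended.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if field.n:
        if geom.width < 2.0 * field.h:
            raise ValueError(
                f"periodic width {geom.width} um < 2h={2 * field.h} um: "
                "minimal-image kernel sums would be wrong"
            )
        order = np.argsort(field.x, kind="stable")
        rho, gx, gy, cnt = cross_density_sorted(
            pts[:, 0],
            np.asarray(geom.wrap_y(pts[:, 1]), dtype=float),
            field.x[order],
            np.asarray(geom.wrap_y(field.y[order]), dtype=float),
            field.h,
            geom.width,
            field.m,
        )
        grad = np.column_stack([gx, gy])
    else:
        rho = np.zeros(n)
        grad = np.zeros((n, 2))
        cnt = np.zeros(n, dtype=np.int64)
    out = [rho]
    if gradients:
        out.append(grad)
    if counts:
        out.append(cnt)
    return rho if len(out) == 1 else tuple(out)


def field_density(
    field: SignalField, geom: DomainGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Density and gradient at every particle's own position (pair sums plus
    the self term m*W(0,h); the self gradient is zero)."""
    n = field.n
    if n < 2:
        return np.full(n, field.m * 4.0 / (np.pi * field.h**2)), np.zeros((n, 2))
    if geom.width < 2.0 * field.h:
        raise ValueError(
            f"periodic width {geom.width} um < 2h={2 * field.h} um: "
            "minimal-image kernel sums would be wrong"
        )
    order = np.argsort(field.x, kind="stable")
    rho_s, gx_s, gy_s = self_density_sorted(
        field.x[order],
        np.asarray(geom.wrap_y(field.y[order]), dtype=float),
        field.h,
        geom.width,
        field.m,
    )
    rho = np.empty(n)
    grad = np.empty((n, 2))
    rho[order] = rho_s
    grad[order, 0] = gx_s
    grad[order, 1] = gy_s
    return rho, grad


def diffusion_step(field: SignalField, dt: float, geom: DomainGeometry) -> None:
    """Move particles along the diffusion velocity -D grad(rho)/(rho + rho*).

    In-place.  Particle count is conserved.  Displacements are bounded by
    dZ* = 2R: the density discontinuity at the vacuum edge of the source
    strip produces occasional velocity spikes there (on particles that the
    boundary step deletes and re-imposes anyway), which are clipped to the
    bound preserving direction.  If more than 1 % of particles need
    clipping the time step is genuinely mis-chosen and a RuntimeError is
    raised.
    """
    if field.n == 0:
        return
    rho, grad = field_density(field, geom)
    # the mirror-image wall correction can leave slightly negative density
    # estimates right at x = 0; the floor keeps the regularized velocity sane
    disp = -dt * field.D * grad / (np.maximum(rho, 0.0) + field.rho_star)[:, None]
    dmag = np.hypot(disp[:, 0], disp[:, 1])
    bound = 2.0 * field.R
    over = dmag > bound
    n_over = int(over.sum())
    if n_over:
        if n_over > max(2, 0.05 * field.n):
            raise RuntimeError(
                f"{n_over}/{field.n} particle displacements exceed the bound "
                f"2R={bound} um (max {dmag.max():.3g} um); dt={dt} h violates "
                "the CFL condition"
            )
        disp[over] *= (bound / dmag[over])[:, None]
    field.x = field.x + disp[:, 0]
    field.y = np.asarray(geom.wrap_y(field.y + disp[:, 1]))


def degradation_step(
    field: SignalField,
    dt: float,
    rng: np.random.Generator,
    protect_x_min: float | None = None,
) -> int:
    """Remove each particle with probability 1 - exp(-k dt).  In-place.

    Particles with x >= protect_x_min (the source strip, whose density is
    re-imposed anyway) are exempted when the threshold is given.  Returns
    the number of particles removed.
    """
    if field.k * dt > 0.1:
        raise ValueError(
            f"k*dt = {field.k * dt:.3g} > 0.1: Poisson removal badly approximated"
        )
    if field.n == 0 or field.k == 0.0:
        return 0
    p = -np.expm1(-field.k * dt)
    gone = rng.uniform(size=field.n) < p
    if protect_x_min is not None:
        gone &= field.x < protect_x_min
    field.x = field.x[~gone]
    field.y = field.y[~gone]
    return int(gone.sum())


def apply_boundaries(
    field: SignalField, L: float, geom: DomainGeometry, rng: np.random.Generator
) -> None:
    """Enforce the absorbing wall and the Dirichlet source strip.  In-place.

    Particles with x < 0 (absorbed anteriorly) or x > L (outside the tissue)
    are deleted; the front strip [L-2R, L] is then topped up or thinned
    uniformly at random so it holds exactly ns_effective(geom, L) particles
    (the nominal NS corrected for the finite strip width).
    """
    if L < 2.0 * field.R:
        raise ValueError(f"tissue length L={L} um shorter than the source strip 2R")
    keep = (field.x >= 0.0) & (field.x <= L)
    x, y = field.x[keep], field.y[keep]
    ns = field.ns_effective(geom, L)
    strip = x >= L - 2.0 * field.R
    n_strip = int(strip.sum())
    if n_strip > ns:
        drop = rng.choice(np.flatnonzero(strip), size=n_strip - ns, replace=False)
        mask = np.ones(len(x), dtype=bool)
        mask[drop] = False
        x, y = x[mask], y[mask]
    elif n_strip < ns:
        n_add = ns - n_strip
        x = np.concatenate([x, rng.uniform(L - 2.0 * field.R, L, size=n_add)])
        y = np.concatenate([y, rng.uniform(geom.ymin, geom.ymax, size=n_add)])
    field.x, field.y = x, y


def choose_timestep(
    D: float, k: float, R: float, C: float = 0.5, cap_hours: float = 0.5
) -> float:
    """Time step dt = min(C (2R)^2 / D, 1/k), further capped so k dt <= 0.1
    and dt <= cap_hours (so cell-scale events stay resolved).  D in um^2/h,
    k in 1/h."""
    if D <= 0 and k <= 0:
        raise ValueError("at least one of D, k must be positive")
    if not 0 < C <= 0.5:
        raise ValueError("CFL constant C must be in (0, 1/2]")
    candidates = [cap_hours]
    if D > 0:
        candidates.append(C * (2.0 * R) ** 2 / D)
    if k > 0:
        candidates.append(1.0 / k)
        candidates.append(0.1 / k)
    return float(min(candidates))


def exposure(
    points: np.ndarray, field: SignalField, geom: DomainGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Local SPH density and particle count within h at cell centers.

    A cell is *exposed* only if at least two signalling particles surround
    it (count >= 2); recruitment eligibility additionally requires the local
    density to exceed the threshold, which the engine checks.
    """
    rho, cnt = sph_density(points, field, geom, counts=True)
    return rho, cnt


def particle_frame(field: SignalField, t_days: float = 0.0):
    """Tabular particle snapshot (t, particle_id, x, y) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": t_days,
            "particle_id": np.arange(field.n),
            "x": field.x,
            "y": field.y,
        }
    )


def density_profile(
    field: SignalField, geom: DomainGeometry, L: float, bin_width: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binned 1D mass-density profile along x: centers, rho (mass/area)."""
    edges = np.arange(0.0, L + bin_width, bin_width)
    counts, _ = np.histogram(field.x, bins=edges)
    rho = field.m * counts / (bin_width * geom.width)
    return 0.5 * (edges[:-1] + edges[1:]), rho


def simulate_fixed_domain(
    field: SignalField,
    L: float,
    geom: DomainGeometry,
    t_end_hours: float,
    rng: np.random.Generator,
    bin_width: float = 20.0,
    average_after: float = 0.5,
    degrade_in_source: bool = False,
) -> tuple[np.ndarray, np.ndarray, SignalField]:
    """Run the signal solver alone on a fixed domain [0, L] and average the
    binned density profile over the final (1 - average_after) of the run.

    This is the validation setting for the scheme: without cell growth, the
    long-time profile must approach rho0 sinh(x/lam)/sinh(L/lam).
    Returns (bin centers, time-averaged rho profile, final field).
    """
    dt = choose_timestep(field.D, field.k, field.R)
    n_steps = int(np.ceil(t_end_hours / dt))
    protect = None if degrade_in_source else L - 2.0 * field.R
    apply_boundaries(field, L, geom, rng)
    acc = None
    n_acc = 0
    for step in range(n_steps):
        diffusion_step(field, dt, geom)
        degradation_step(field, dt, rng, protect_x_min=protect)
        apply_boundaries(field, L, geom, rng)
        if step >= average_after * n_steps:
            centers, prof = density_profile(field, geom, L, bin_width)
            acc = prof if acc is None else acc + prof
            n_acc += 1
    return centers, acc / n_acc, field
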