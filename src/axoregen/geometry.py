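"""Domain geometry, hard-disc mechanics, front detection and tissue length.

The ependymal tube is modelled as a flat strip: the x axis is the
anterior-posterior (AP) axis, the y axis is the arc length along the central
canal circumference and is periodic.  Internally all cell positions use
shifted coordinates x in [0, L(t)] with a fixed wall at x = 0 (the anterior
Dirichlet boundary) and a free boundary at the growing posterior front;
positions are converted to amputation-plane coordinates z = x - L0 only at
the I/O surface.

Cells are hard discs of common radius R.  Non-overlap is enforced by
explicit-Euler descent on a pairwise repulsion potential

    Phi(r) = 2 kappa R^2 (r - 1)^2   for r = dist/(2R) < 1,  else 0,

iterated until the largest pairwise overlap is below one tenth of a cell
diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DomainGeometry",
    "CellPopulation",
    "periodic_distance",
    "periodic_pairs",
    "initialize_cells",
    "relax_overlaps",
    "find_front_cells",
    "tissue_length",
]

#: relaxation stops when max pairwise overlap < EPS_OVERLAP * (2R)
EPS_OVERLAP = 0.1


@dataclass(frozen=True)
class DomainGeometry:
    """Strip geometry: x in [0, L(t)] (shifted coordinates), y periodic.

    L0 is the initial tissue length; ymin/ymax bound the circumference axis.
    Amputation-plane coordinates are z = x - L0.
    """

    L0: float
    ymin: float = 0.0
    ymax: float = 180.0

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.ymax <= self.ymin:
            raise ValueError("ymax must exceed ymin")

    @property
    def width(self) -> float:
        return self.ymax - self.ymin

    def wrap_y(self, y: np.ndarray | float) -> np.ndarray | float:
        """Wrap y into [ymin, ymax)."""
        return self.ymin + np.mod(np.asarray(y, dtype=float) - self.ymin, self.width)

    def min_image_dy(self, dy: np.ndarray | float) -> np.ndarray | float:
        """Minimal-image y difference in (-W/2, W/2]."""
        w = self.width
        return np.asarray(dy, dtype=float) - w * np.round(np.asarray(dy) / w)


@dataclass
class CellPopulation:
    """Positions, shared radius and per-cell state of all ependymal cells.

    The cycle-state arrays (T, age, fast) are owned by the cell_cycle module;
    they travel with the population so that division and recruitment can
    update positions and clocks together.
    """

    x: np.ndarray
    y: np.ndarray
    radius: float
    recruited: np.ndarray  # bool
    lineage: np.ndarray  # founding-ancestor id, inherited on division
    ids: np.ndarray  # unique per cell
    T: np.ndarray  # cycle length, h
    age: np.ndarray  # age within cycle, h
    fast: np.ndarray  # bool: on the fast (recruited) cycling program
    next_id: int = 0

    @classmethod
    def from_positions(cls, x: np.ndarray, y: np.ndarray, radius: float) -> "CellPopulation":
        n = len(x)
        return cls(
            x=np.asarray(x, dtype=float),
            y=np.asarray(y, dtype=float),
            radius=float(radius),
            recruited=np.zeros(n, dtype=bool),
            lineage=np.arange(n, dtype=np.int64),
            ids=np.arange(n, dtype=np.int64),
            T=np.zeros(n),
            age=np.zeros(n),
            fast=np.zeros(n, dtype=bool),
            next_id=n,
        )

    @property
    def n(self) -> int:
        return len(self.x)

    def copy(self) -> "CellPopulation":
        return replace(
            self,
            **{
                name: getattr(self, name).copy()
                for name in ("x", "y", "recruited", "lineage", "ids", "T", "age", "fast")
            },
        )


def periodic_distance(p, q, geom: DomainGeometry) -> float:
    """Euclidean distance with the y difference taken minimal-image."""
    dx = p[0] - q[0]
    dy = geom.min_image_dy(p[1] - q[1])
    return float(np.hypot(dx, dy))


def _build_tree(x: np.ndarray, y: np.ndarray, r: float, geom: DomainGeometry) -> cKDTree:
    """KD-tree on (x, wrapped y) with a periodic y box.

    The x axis is padded so the periodic box never wraps pairs in x.  A query
    radius r larger than half the circumference would require image summation
    beyond the minimal image, which this package does not do; geometries are
    validated against that.
    """
    w = geom.width
    if w < 2.0 * r:
        raise ValueError(
            f"periodic width {w} um is smaller than twice the interaction radius "
            f"{r} um; minimal-image sums would be wrong. Use a wider strip or a "
            "smaller kernel/interaction radius."
        )
    if len(x) and x.min() < 0:
        raise ValueError("negative x encountered (anterior wall violated)")
    bx = (x.max() if len(x) else 0.0) + 2.0 * r + 1.0
    pts = np.column_stack([x, np.mod(y - geom.ymin, w)])
    # guard against y == W from float round-off
    pts[:, 1] = np.where(pts[:, 1] >= w, 0.0, pts[:, 1])
    return cKDTree(pts, boxsize=[bx, w])


def periodic_pairs(
    x: np.ndarray, y: np.ndarray, r: float, geom: DomainGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All unordered pairs closer than r (y periodic).

    Returns (pairs, dx, dy, dist) where pairs is an (m, 2) int array and
    dx, dy are signed displacements from the second to the first member.
    """
    if len(x) < 2:
        return np.empty((0, 2), dtype=int), np.empty(0), np.empty(0), np.empty(0)
    tree = _build_tree(x, y, r, geom)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs) == 0:
        return pairs, np.empty(0), np.empty(0), np.empty(0)
    i, j = pairs[:, 0], pairs[:, 1]
    dx = x[i] - x[j]
    dy = y[i] - y[j]
    # inline minimal image: |dy| < W always holds here, one branch suffices
    w = geom.width
    half = 0.5 * w
    dy = np.where(dy > half, dy - w, np.where(dy < -half, dy + w, dy))
    return pairs, dx, dy, np.hypot(dx, dy)


def relax_overlaps(
    x: np.ndarray,
    y: np.ndarray,
    radius: float,
    geom: DomainGeometry,
    kappa: float = 1.0,
    eps_overlap: float = EPS_OVERLAP,
    max_iter: int = 100_000,
    rng: np.random.Generator | None = None,
    record_energy: bool = False,
) -> tuple[np.ndarray, np.ndarray, int] | tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Drive an overlapping configuration to a hard-disc steady state.

    Explicit-Euler descent on the summed repulsion potential, with the
    anterior wall enforced by clamping x >= 0 after every step and y
    re-wrapped.  Iteration stops once

        max over overlapping pairs of (2R - dist) < eps_overlap * 2R.

    The Euler step is 0.1*R/(4*kappa*R), further shrunk so no cell moves more
    than 0.25 R per iteration.  Raises RuntimeError if the criterion is not
    met within max_iter iterations (reporting the residual overlap and the
    packing fraction, which is the usual culprit).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(geom.wrap_y(y), dtype=float).copy()
    np.clip(x, 0.0, None, out=x)
    two_r = 2.0 * radius
    if geom.width < 2.0 * two_r:
        raise ValueError(
            f"periodic width {geom.width} um < 4R={2 * two_r} um: minimal-image "
            "pair interactions would be wrong"
        )
    if not record_energy:
        # compiled fast path (identical dynamics; the pure-python loop below
        # is kept for the energy audit used in tests)
        from ._kernels import relax_hard_discs

        gen = rng if rng is not None else np.random.default_rng(0)
        angle = gen.uniform(0.0, 2.0 * np.pi)
        jitter_seed = int(gen.integers(2**31))
        y0 = y - geom.ymin
        n_iter, max_ov = relax_hard_discs(
            x, y0, radius, geom.width, kappa, eps_overlap, max_iter, angle,
            jitter_seed,
        )
        if n_iter < 0:
            area = geom.width * max(x.max(), geom.L0)
            phi = len(x) * np.pi * radius**2 / area
            raise RuntimeError(
                f"hard-disc relaxation did not converge in {max_iter} iterations: "
                f"residual overlap {max_ov:.3g} um (criterion "
                f"{eps_overlap * two_r:.3g}); packing fraction ~{phi:.2f} may be "
                "infeasible"
            )
        return x, y0 + geom.ymin, n_iter
    dt0 = 0.1 * radius / (4.0 * kappa * radius)
    energies = []
    n_iter = 0
    while True:
        pairs, dx, dy, dist = periodic_pairs(x, y, two_r, geom)
        if len(pairs):
            overlap = two_r - dist
            max_ov = overlap.max()
        else:
            max_ov = 0.0
        if record_energy:
            r_n = dist / two_r if len(pairs) else np.empty(0)
            energies.append(float(np.sum(2.0 * kappa * radius**2 * (r_n - 1.0) ** 2)))
        if max_ov < eps_overlap * two_r:
            break
        if n_iter >= max_iter:
            area = geom.width * max(x.max(), geom.L0)
            phi = len(x) * np.pi * radius**2 / area
            raise RuntimeError(
                f"hard-disc relaxation did not converge in {max_iter} iterations: "
                f"residual overlap {max_ov:.3g} um (criterion {eps_overlap * two_r:.3g}); "
                f"packing fraction ~{phi:.2f} may be infeasible"
            )
        i, j = pairs[:, 0], pairs[:, 1]
        r_n = dist / two_r
        with np.errstate(invalid="ignore"):
            ux, uy = dx / dist, dy / dist
        coincident = dist == 0.0
        if np.any(coincident):
            gen = rng if rng is not None else np.random.default_rng(0)
            ang = gen.uniform(0.0, 2.0 * np.pi, size=int(coincident.sum()))
            ux[coincident] = np.cos(ang)
            uy[coincident] = np.sin(ang)
        fmag = 2.0 * kappa * radius * (1.0 - r_n)  # repulsive, > 0 for overlap
        nn = len(x)
        fx = np.bincount(i, weights=fmag * ux, minlength=nn) - np.bincount(
            j, weights=fmag * ux, minlength=nn
        )
        fy = np.bincount(i, weights=fmag * uy, minlength=nn) - np.bincount(
            j, weights=fmag * uy, minlength=nn
        )
        fmax = np.hypot(fx, fy).max()
        dt = min(dt0, 0.25 * radius / fmax) if fmax > 0 else dt0
        x += dt * fx
        y += dt * fy
        np.clip(x, 0.0, None, out=x)
        y = geom.wrap_y(y)
        n_iter += 1
    if record_energy:
        return x, y, n_iter, np.asarray(energies)
    return x, y, n_iter


def initialize_cells(
    geom: DomainGeometry,
    radius: float,
    n_throw: int,
    rng: np.random.Generator,
    kappa: float = 1.0,
    max_iter: int = 100_000,
) -> CellPopulation:
    """Random non-overlapping initial configuration filling [0, L0].

    n_throw cells are thrown uniformly at random in [0, L0] x [ymin, ymax],
    the hard-disc dynamics is relaxed to its steady state, and every cell
    pushed beyond L0 is removed.  Cycle clocks are left zeroed for the
    cell_cycle module to initialize.
    """
    if n_throw < 1:
        raise ValueError("n_throw must be >= 1")
    area = geom.L0 * geom.width
    phi = n_throw * np.pi * radius**2 / area
    if phi > 1.05:
        raise ValueError(
            f"packing fraction {phi:.2f} for n_throw={n_throw} discs of radius "
            f"{radius} um in a {geom.L0} x {geom.width} um strip is infeasible"
        )
    x = rng.uniform(0.0, geom.L0, size=n_throw)
    y = rng.uniform(geom.ymin, geom.ymax, size=n_throw)
    if n_throw > 1:
        x, y, _ = relax_overlaps(
            x, y, radius, geom, kappa=kappa, max_iter=max_iter, rng=rng
        )
    keep = x <= geom.L0
    return CellPopulation.from_positions(x[keep], y[keep], radius)


def find_front_cells(pop: CellPopulation, geom: DomainGeometry) -> np.ndarray:
    """Indices of front cells.

    Cell i is a front cell iff there is no cell j with x_j > x_i whose y_j
    lies in the periodic band (y_i - R, y_i + R).
    """
    n = pop.n
    if n == 0:
        raise ValueError("empty population has no front")
    order = np.argsort(pop.x)  # scan from posterior; a cell is blocked only by
    xs, ys = pop.x[order], pop.y[order]  # cells strictly to its right
    blocked = np.zeros(n, dtype=bool)
    # O(n^2) double loop in vectorized chunks: for each cell, test all cells
    # with larger x.  n stays modest (<= a few thousand) in this model.
    for k in range(n - 1):
        dy = geom.min_image_dy(ys[k + 1 :] - ys[k])
        right = xs[k + 1 :] > xs[k]
        if np.any(right & (np.abs(dy) < pop.radius)):
            blocked[k] = True
    front_sorted = order[~blocked]
    return np.sort(front_sorted)


def tissue_length(pop: CellPopulation, geom: DomainGeometry) -> float:
    """Tissue length L(t): mean x over front cells (shifted coordinates)."""
    front = find_front_cells(pop, geom)
    return float(pop.x[front].mean())
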