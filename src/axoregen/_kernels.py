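"""Compiled inner loops for the SPH sums.

The strip geometry keeps particle clouds modest (10^3-10^4), but the solver
takes 10^3-10^4 time steps, so the pairwise kernel sums dominate run time.
These routines assume arrays sorted by x and sweep a window of half-width h
along the AP axis, taking the y difference minimal-image.  They require the
periodic width W >= 2h (enforced upstream) so a single image suffices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["self_density_sorted", "cross_density_sorted", "relax_hard_discs"]


@njit(cache=True)
def relax_hard_discs(x, y, radius, width, kappa, eps, max_iter, fallback_angle,
                     jitter_seed=0):
    """Explicit-Euler descent on the hard-disc repulsion potential, in-place.

    Stops when the largest pairwise overlap drops below eps*2R.  The anterior
    wall clamps x >= 0 each iteration; y is periodic with the given width.
    Dense random packings can stall in frustrated force-balance states with
    residual overlap; when no progress is made over 2000 iterations a small
    seeded positional jitter (0.05 R) breaks the symmetry and the descent
    resumes.  Returns (n_iter, final_max_overlap); n_iter == -1 flags
    non-convergence.
    """
    np.random.seed(jitter_seed)
    check_every = 2000
    last_check = 1e30
    n = x.shape[0]
    two_r = 2.0 * radius
    two_r2 = two_r * two_r
    dt0 = 0.1 * radius / (4.0 * kappa * radius)
    half = 0.5 * width
    fx = np.zeros(n)
    fy = np.zeros(n)
    max_ov = 0.0
    for it in range(max_iter + 1):
        order = np.argsort(x)
        for a in range(n):
            fx[a] = 0.0
            fy[a] = 0.0
        max_ov = 0.0
        for aa in range(n):
            a = order[aa]
            xa = x[a]
            ya = y[a]
            for bb in range(aa + 1, n):
                b = order[bb]
                dx = x[b] - xa
                if dx > two_r:
                    break
                dy = y[b] - ya
                if dy > half:
                    dy -= width
                elif dy < -half:
                    dy += width
                r2 = dx * dx + dy * dy
                if r2 < two_r2:
                    dist = np.sqrt(r2)
                    ov = two_r - dist
                    if ov > max_ov:
                        max_ov = ov
                    if dist > 0.0:
                        ux = dx / dist
                        uy = dy / dist
                    else:
                        ux = np.cos(fallback_angle)
                        uy = np.sin(fallback_angle)
                    fmag = 2.0 * kappa * radius * (1.0 - dist / two_r)
                    fx[b] += fmag * ux
                    fy[b] += fmag * uy
                    fx[a] -= fmag * ux
                    fy[a] -= fmag * uy
        if max_ov < eps * two_r:
            return it, max_ov
        if it == max_iter:
            return -1, max_ov
        if it > 0 and it % check_every == 0:
            if max_ov > 0.995 * last_check:  # stalled: frustrated minimum
                for a in range(n):
                    x[a] = max(x[a] + np.random.normal(0.0, 0.05 * radius), 0.0)
                    ynew = y[a] + np.random.normal(0.0, 0.05 * radius)
                    ynew = ynew % width
                    y[a] = ynew
            last_check = max_ov
        fmax = 0.0
        for a in range(n):
            f = np.hypot(fx[a], fy[a])
            if f > fmax:
                fmax = f
        dt = dt0
        if fmax > 0.0 and 0.25 * radius / fmax < dt:
            dt = 0.25 * radius / fmax
        for a in range(n):
            x[a] += dt * fx[a]
            if x[a] < 0.0:
                x[a] = 0.0
            ynew = y[a] + dt * fy[a]
            if ynew >= width:
                ynew -= width
            elif ynew < 0.0:
                ynew += width
            y[a] = ynew
    return -1, max_ov


@njit(cache=True)
def self_density_sorted(x, y, h, width, mass):
    """Density and gradient at every particle (arrays sorted by x).

    Returns (rho, gx, gy) including the self term mass*W(0, h).
    """
    n = x.shape[0]
    h2 = h * h
    w_norm = 4.0 / (np.pi * h**8)
    g_norm = -24.0 / (np.pi * h**8)
    rho = np.full(n, mass * w_norm * h2**3)
    gx = np.zeros(n)
    gy = np.zeros(n)
    half = 0.5 * width
    for i in range(n):
        xi = x[i]
        yi = y[i]
        for j in range(i + 1, n):
            dx = x[j] - xi
            if dx > h:
                break
            dy = y[j] - yi
            if dy > half:
                dy -= width
            elif dy < -half:
                dy += width
            r2 = dx * dx + dy * dy
            if r2 <= h2:
                d = h2 - r2
                wk = mass * w_norm * d * d * d
                rho[i] += wk
                rho[j] += wk
                c = mass * g_norm * d * d
                # gradient at j of kernel centered on i: c * (r_j - r_i)
                gx[j] += c * dx
                gy[j] += c * dy
                gx[i] -= c * dx
                gy[i] -= c * dy
    # antisymmetric mirror images across the absorbing wall x = 0 enforce
    # rho(0) = 0 (method of images): each particle at x < h contributes
    # negative mass at (-x, y)
    for i in range(n):
        if x[i] > h:
            break
        for j in range(n):
            dxm = x[i] + x[j]
            if dxm > h:
                break
            dy = y[j] - y[i]
            if dy > half:
                dy -= width
            elif dy < -half:
                dy += width
            r2 = dxm * dxm + dy * dy
            if r2 <= h2:
                d = h2 - r2
                rho[i] -= mass * w_norm * d * d * d
                # grad at i of -m*W(Zi - mirror(Zj)); q = (dxm, -dy)
                c = -mass * g_norm * d * d
                gx[i] += c * dxm
                gy[i] -= c * dy
    return rho, gx, gy


@njit(cache=True)
def cross_density_sorted(px, py, x, y, h, width, mass):
    """Density, gradient and neighbor count at query points px/py given
    source particles sorted by x.  Returns (rho, gx, gy, count)."""
    m = px.shape[0]
    n = x.shape[0]
    h2 = h * h
    w_norm = 4.0 / (np.pi * h**8)
    g_norm = -24.0 / (np.pi * h**8)
    rho = np.zeros(m)
    gx = np.zeros(m)
    gy = np.zeros(m)
    cnt = np.zeros(m, dtype=np.int64)
    half = 0.5 * width
    for a in range(m):
        lo = np.searchsorted(x, px[a] - h)
        for j in range(lo, n):
            dx = px[a] - x[j]
            if dx < -h:
                break
            dy = py[a] - y[j]
            if dy > half:
                dy -= width
            elif dy < -half:
                dy += width
            r2 = dx * dx + dy * dy
            if r2 <= h2:
                d = h2 - r2
                rho[a] += mass * w_norm * d * d * d
                c = mass * g_norm * d * d
                gx[a] += c * dx
                gy[a] += c * dy
                cnt[a] += 1
        # negative mirror mass across the absorbing wall (rho(0) = 0);
        # virtual images do not count as neighbors
        if px[a] <= h:
            for j in range(n):
                dxm = px[a] + x[j]
                if dxm > h:
                    break
                dy = py[a] - y[j]
                if dy > half:
                    dy -= width
                elif dy < -half:
                    dy += width
                r2 = dxm * dxm + dy * dy
                if r2 <= h2:
                    d = h2 - r2
                    rho[a] -= mass * w_norm * d * d * d
                    c = -mass * g_norm * d * d
                    gx[a] += c * dxm
                    gy[a] += c * dy
    return rho, gx, gy, cnt
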