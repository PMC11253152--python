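"""Poly6 kernel, SPH sums, diffusion/degradation steps, boundary handling."""

import numpy as np
import pytest
from scipy import integrate

from axoregen.geometry import DomainGeometry
from axoregen.signal_sph import (
    SignalField,
    apply_boundaries,
    choose_timestep,
    degradation_step,
    density_profile,
    diffusion_step,
    exposure,
    field_density,
    poly6,
    poly6_grad,
    sph_density,
)


@pytest.fixture
def geom():
    return DomainGeometry(L0=400.0, ymin=0.0, ymax=56.0)


def make_field(geom, n=0, rng=None, h=14.0, D=72.0, k=0.01, rho0=1.0, m=1.0,
               x_hi=None):
    f = SignalField.empty(h=h, D=D, k=k, rho0=rho0, R=7.0, m=m)
    if n:
        x_hi = geom.L0 if x_hi is None else x_hi
        f.x = rng.uniform(0, x_hi, n)
        f.y = rng.uniform(geom.ymin, geom.ymax, n)
    return f


class TestPoly6:
    def test_value_at_origin(self):
        h = 5.0
        assert poly6(np.zeros(2), h) == pytest.approx(4.0 / (np.pi * h**2))

    def test_zero_at_support_boundary(self):
        h = 5.0
        q = np.array([h, 0.0])
        assert poly6(q, h) == 0.0
        assert np.allclose(poly6_grad(q, h), 0.0)
        assert poly6(np.array([h + 1, 0.0]), h) == 0.0

    def test_gradient_zero_at_origin(self):
        assert np.allclose(poly6_grad(np.zeros(2), 3.0), 0.0)

    def test_unit_integral_by_quadrature(self):
        h = 3.0
        val, _ = integrate.quad(
            lambda r: 2 * np.pi * r * poly6(np.array([r, 0.0]), h), 0, h
        )
        assert val == pytest.approx(1.0, rel=1e-10)

    def test_gradient_is_radial_derivative(self):
        h = 4.0
        q = np.array([1.3, -0.7])
        eps = 1e-6
        num = (poly6(q + [eps, 0], h) - poly6(q - [eps, 0], h)) / (2 * eps)
        assert poly6_grad(q, h)[0] == pytest.approx(num, rel=1e-6)


class TestSphDensity:
    def test_single_particle_self_density(self, geom):
        f = make_field(geom)
        f.x = np.array([200.0])
        f.y = np.array([28.0])
        rho = sph_density(np.array([[200.0, 28.0]]), f, geom)
        assert rho[0] == pytest.approx(f.m * 4.0 / (np.pi * f.h**2))

    def test_nonnegative_and_compact_support(self, geom):
        rng = np.random.default_rng(0)
        f = make_field(geom, 100, rng, x_hi=100.0)
        pts = np.column_stack([np.linspace(150, 390, 20), np.full(20, 10.0)])
        rho = sph_density(pts, f, geom)
        assert np.all(rho >= 0)
        assert np.all(rho[pts[:, 0] > 100 + f.h] == 0.0)

    def test_matches_bruteforce_pair_sum(self, geom):
        rng = np.random.default_rng(1)
        f = make_field(geom, 200, rng)
        pts = np.column_stack([rng.uniform(0, 400, 50), rng.uniform(0, 56, 50)])
        rho = sph_density(pts, f, geom)
        for a in range(50):
            dx = pts[a, 0] - f.x
            dy = geom.min_image_dy(pts[a, 1] - f.y)
            r2 = dx * dx + dy * dy
            d = np.maximum(f.h**2 - r2, 0.0)
            brute = f.m * 4 / (np.pi * f.h**8) * np.sum(d**3)
            if pts[a, 0] <= f.h:  # mirror sink correction near the wall
                dxm = pts[a, 0] + f.x
                r2m = dxm * dxm + dy * dy
                dm = np.maximum(f.h**2 - r2m, 0.0)
                brute -= f.m * 4 / (np.pi * f.h**8) * np.sum(dm**3)
            assert rho[a] == pytest.approx(brute, abs=1e-12)

    def test_field_density_consistent_with_cross_eval(self, geom):
        rng = np.random.default_rng(2)
        f = make_field(geom, 300, rng)
        rho_self, _ = field_density(f, geom)
        rho_cross = sph_density(np.column_stack([f.x, f.y]), f, geom)
        assert np.allclose(rho_self, rho_cross, atol=1e-10)

    def test_y_translation_equivariance(self, geom):
        rng = np.random.default_rng(3)
        f = make_field(geom, 150, rng)
        pts = np.column_stack([rng.uniform(0, 400, 30), rng.uniform(0, 56, 30)])
        rho1 = sph_density(pts, f, geom)
        shift = 21.7
        f2 = make_field(geom)
        f2.x, f2.y = f.x, np.asarray(geom.wrap_y(f.y + shift))
        pts2 = pts.copy()
        pts2[:, 1] = geom.wrap_y(pts[:, 1] + shift)
        rho2 = sph_density(pts2, f2, geom)
        assert np.allclose(rho1, rho2, atol=1e-10)

    def test_narrow_strip_rejected(self):
        narrow = DomainGeometry(L0=400.0, ymax=20.0)
        f = SignalField.empty(h=14.0, D=72.0, k=0.01, rho0=1.0, R=7.0)
        f.x, f.y = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        with pytest.raises(ValueError, match="minimal-image"):
            sph_density(np.array([[1.0, 1.0]]), f, geom=narrow)


class TestDiffusionStep:
    def test_flat_lattice_does_not_move(self, geom):
        # uniform lattice filling the periodic strip: gradients cancel
        xg, yg = np.meshgrid(np.arange(2.0, 400.0, 4.0), np.arange(0.0, 56.0, 4.0))
        f = make_field(geom)
        f.x, f.y = xg.ravel().copy(), yg.ravel().copy()
        x0 = f.x.copy()
        interior = (f.x > 40) & (f.x < 360)  # away from the open x ends
        diffusion_step(f, 0.05, geom)
        assert np.max(np.abs(f.x[interior] - x0[interior])) < 1e-9

    def test_particle_count_conserved(self, geom):
        rng = np.random.default_rng(4)
        f = make_field(geom, 400, rng, D=720.0)
        for _ in range(200):
            diffusion_step(f, 0.05, geom)
        assert f.n == 400

    def test_blob_variance_grows_linearly(self):
        # heat-equation behaviour: var(x) grows ~ 2 D_eff t with D_eff below
        # but of the order of D (regularization and particle-sampling bias
        # slow the tails)
        big = DomainGeometry(L0=8000.0, ymax=56.0)
        rng = np.random.default_rng(5)
        f = SignalField.empty(h=28.0, D=3600.0, k=0.01, rho0=60.0, R=7.0, m=60.0)
        f.x = rng.normal(4000.0, 200.0, 8000)
        f.y = rng.uniform(0, 56, 8000)
        dt = choose_timestep(f.D, f.k, f.R)
        ts, vs = [0.0], [f.x.var()]
        for i in range(1, 101):
            diffusion_step(f, dt, big)
            if i % 20 == 0:
                ts.append(i * dt)
                vs.append(f.x.var())
        slope, intercept = np.polyfit(ts, vs, 1)
        r2 = np.corrcoef(ts, vs)[0, 1] ** 2
        assert r2 > 0.99  # linear growth
        assert 0.5 * 2 * f.D < slope < 1.1 * 2 * f.D

    def test_gross_cfl_violation_raises(self, geom):
        rng = np.random.default_rng(6)
        f = make_field(geom, 300, rng, D=72000.0, x_hi=50.0)
        with pytest.raises(RuntimeError, match="CFL"):
            diffusion_step(f, 5.0, geom)


class TestDegradationStep:
    def test_zero_rate_removes_nothing(self, geom):
        rng = np.random.default_rng(7)
        f = make_field(geom, 500, rng, k=0.0)
        assert degradation_step(f, 1.0, rng) == 0
        assert f.n == 500

    def test_single_step_binomial_fraction(self, geom):
        rng = np.random.default_rng(8)
        big = DomainGeometry(L0=100000.0, ymax=56.0)
        f = make_field(big, 100_000, rng, k=0.02)
        removed = degradation_step(f, 4.0, rng)
        p = -np.expm1(-0.02 * 4.0)
        se = np.sqrt(p * (1 - p) * 1e5)
        assert removed == pytest.approx(p * 1e5, abs=3 * se)

    def test_exponential_decay_and_half_life(self, geom):
        rng = np.random.default_rng(9)
        big = DomainGeometry(L0=100000.0, ymax=56.0)
        f = make_field(big, 50_000, rng, k=0.05)
        ts, ns = [0.0], [f.n]
        for i in range(1, 31):
            degradation_step(f, 1.0, rng)
            ts.append(float(i))
            ns.append(f.n)
        lam_fit = -np.polyfit(ts, np.log(ns), 1)[0]
        half_life = np.log(2) / lam_fit
        assert half_life == pytest.approx(np.log(2) / 0.05, rel=0.05)

    def test_protected_strip_exempt(self, geom):
        rng = np.random.default_rng(10)
        f = make_field(geom, 2000, rng, k=0.5)
        n_strip = int((f.x >= 386.0).sum())
        degradation_step(f, 0.2, rng, protect_x_min=386.0)
        assert int((f.x >= 386.0).sum()) == n_strip

    def test_excessive_k_dt_rejected(self, geom):
        rng = np.random.default_rng(11)
        f = make_field(geom, 10, rng, k=1.0)
        with pytest.raises(ValueError, match="0.1"):
            degradation_step(f, 0.5, rng)


class TestApplyBoundaries:
    def test_empty_field_filled_to_ns(self, geom):
        rng = np.random.default_rng(12)
        f = make_field(geom, rho0=2.0, m=1.0)
        apply_boundaries(f, 400.0, geom, rng)
        ns = f.ns_effective(geom, 400.0)
        assert f.n == ns
        assert np.all((f.x >= 400.0 - 14.0) & (f.x <= 400.0))

    def test_saturated_strip_unchanged(self, geom):
        rng = np.random.default_rng(13)
        f = make_field(geom, rho0=2.0)
        apply_boundaries(f, 400.0, geom, rng)
        x0, y0 = f.x.copy(), f.y.copy()
        apply_boundaries(f, 400.0, geom, rng)
        assert np.array_equal(f.x, x0) and np.array_equal(f.y, y0)

    def test_out_of_domain_particles_deleted(self, geom):
        rng = np.random.default_rng(14)
        f = make_field(geom, rho0=2.0)
        f.x = np.array([-1.0, 50.0, 401.0])
        f.y = np.array([5.0, 5.0, 5.0])
        apply_boundaries(f, 400.0, geom, rng)
        assert np.all((f.x >= 0) & (f.x <= 400.0))
        assert 50.0 in f.x

    def test_strip_density_close_to_rho0(self, geom):
        rng = np.random.default_rng(15)
        f = make_field(geom, rho0=4.0, k=0.001)  # lam >> strip width
        apply_boundaries(f, 400.0, geom, rng)
        strip = f.x >= 386.0
        measured = f.m * strip.sum() / (14.0 * geom.width)
        # calibrated count: strip mean density equals the steady-profile
        # average, within 15 % of the nominal front value
        assert measured == pytest.approx(4.0, rel=0.15)

    def test_short_domain_rejected(self, geom):
        rng = np.random.default_rng(16)
        f = make_field(geom)
        with pytest.raises(ValueError):
            apply_boundaries(f, 10.0, geom, rng)


class TestChooseTimestep:
    def test_cfl_branch(self):
        # D huge: CFL bound C(2R)^2/D wins
        assert choose_timestep(7272.0, 0.01, 7.0) == pytest.approx(
            0.5 * 196.0 / 7272.0
        )

    def test_degradation_cap_branch(self):
        # k huge: 0.1/k tightens below 1/k
        assert choose_timestep(1e-3, 10.0, 7.0) == pytest.approx(0.01)

    def test_converted_units_arithmetic(self):
        # D = 0.08 um^2/s = 288 um^2/h, R = 7, C = 0.5: CFL term 0.3402 h
        dt_cfl = 0.5 * (2 * 7.0) ** 2 / (0.08 * 3600.0)
        assert dt_cfl == pytest.approx(0.3402, abs=1e-4)
        assert choose_timestep(288.0, 1e-4, 7.0, cap_hours=1.0) == pytest.approx(
            0.3402, abs=1e-4
        )

    def test_resolution_cap(self):
        assert choose_timestep(1.0, 1e-6, 7.0) == 0.5

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            choose_timestep(0.0, 0.0, 7.0)


class TestExposure:
    def test_no_particles_not_exposed(self, geom):
        f = make_field(geom)
        rho, cnt = exposure(np.array([[100.0, 10.0]]), f, geom)
        assert rho[0] == 0.0 and cnt[0] == 0

    def test_single_particle_insufficient(self, geom):
        # one particle at the cell center: high density but count < 2
        f = make_field(geom)
        f.x, f.y = np.array([200.0]), np.array([28.0])
        rho, cnt = exposure(np.array([[200.0, 28.0]]), f, geom)
        assert cnt[0] == 1
        assert rho[0] > 0

    def test_lattice_density_thresholds(self, geom):
        # regular lattice of spacing a has number density 1/a^2
        for spacing, m in ((2.0, 1.0), (2.0, 0.2)):
            xg, yg = np.meshgrid(
                np.arange(100.0, 300.0, spacing), np.arange(0.0, 56.0, spacing)
            )
            f = make_field(geom, m=m)
            f.x, f.y = xg.ravel().copy(), yg.ravel().copy()
            rho, cnt = exposure(np.array([[200.0, 28.0]]), f, geom)
            expect = m / spacing**2
            assert rho[0] == pytest.approx(expect, rel=0.05)
            assert cnt[0] >= 2


def test_density_profile_histogram(geom):
    f = make_field(geom, m=3.0)
    f.x = np.array([5.0, 15.0, 15.0, 395.0])
    f.y = np.array([1.0, 2.0, 3.0, 4.0])
    centers, rho = density_profile(f, geom, 400.0, bin_width=10.0)
    area = 10.0 * geom.width
    assert rho[0] == pytest.approx(3.0 / area)
    assert rho[1] == pytest.approx(6.0 / area)
    assert rho[-1] == pytest.approx(3.0 / area)
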