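"""Domain geometry and discrete Laplacian contracts."""

import math

import numpy as np
import pytest
from scipy.special import sph_harm_y

from pollenpat.domains import (
    ring_from_front_area,
    sphere_from_front_area,
    apply_laplacian,
    admissible_modes,
    refine_domain,
    interpolate_to_refined,
)
from pollenpat.model import turing_check, dispersion_rate, steady_state


class TestRingGeometry:
    @pytest.mark.parametrize(
        "area,length", [(550.0, 83.14), (350.0, 66.32), (750.0, 97.08)]
    )
    def test_length_from_front_area(self, area, length):
        dom = ring_from_front_area(area)
        assert dom.length == pytest.approx(2 * math.sqrt(math.pi * area), rel=1e-12)
        assert dom.length == pytest.approx(length, abs=0.01)

    def test_radius_round_trip(self):
        dom = ring_from_front_area(613.0)
        assert math.pi * dom.radius**2 == pytest.approx(613.0, rel=1e-12)

    def test_uniform_half_open_nodes(self):
        dom = ring_from_front_area(550.0, n_nodes=64)
        x = dom.node_positions
        assert len(x) == 64 and x[0] == 0.0 and x[-1] < dom.length
        assert np.allclose(np.diff(x), dom.length / 64)

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            ring_from_front_area(-5.0)


class TestSphereGeometry:
    @pytest.mark.parametrize("area,radius", [(550.0, 13.23), (750.0, 15.45)])
    def test_radius(self, area, radius):
        dom = sphere_from_front_area(area, resolution=2)
        assert dom.radius == pytest.approx(math.sqrt(area / math.pi), rel=1e-12)
        assert dom.radius == pytest.approx(radius, abs=0.01)

    def test_surface_area_is_four_front_areas(self, sphere550):
        # discrete (faceted) area converges to 4*pi*R^2 from below
        assert sphere550.surface_area == pytest.approx(4 * 550.0, rel=0.01)

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            sphere_from_front_area(0.0)


class TestLaplacian:
    def test_constant_field_maps_to_zero(self, ring550, sphere550):
        for dom in (ring550, sphere550):
            lap = apply_laplacian(dom, np.full(dom.n_nodes, 3.7))
            assert np.max(np.abs(lap)) < 1e-10

    @pytest.mark.parametrize("m", [1, 3, 7])
    def test_ring_fourier_eigenfunctions(self, ring550, m):
        k = 2 * math.pi * m / ring550.length
        f = np.cos(k * ring550.node_positions)
        lap = apply_laplacian(ring550, f)
        assert np.allclose(lap, -(k**2) * f, atol=1e-8 * k**2)

    @pytest.mark.parametrize("l,m", [(2, 0), (3, 2), (5, 3)])
    def test_sphere_spherical_harmonic_eigenfunctions(self, sphere550_fine, l, m):
        dom = sphere550_fine
        x, y, z = dom.node_positions.T / dom.radius
        theta = np.arccos(np.clip(z, -1, 1))
        phi = np.arctan2(y, x)
        Y = np.real(sph_harm_y(l, m, theta, phi))
        lap = apply_laplacian(dom, Y)
        lam = -l * (l + 1) / dom.radius**2
        # Rayleigh-quotient accuracy of the cotangent operator
        num = np.sum(dom.node_weights * Y * lap)
        den = np.sum(dom.node_weights * Y * Y)
        assert num / den == pytest.approx(lam, rel=0.02)

    def test_refinement_reduces_eigenvalue_error(self):
        errs = []
        for res in (2, 3):
            dom = sphere_from_front_area(550.0, resolution=res)
            x, y, z = dom.node_positions.T / dom.radius
            Y = np.real(sph_harm_y(3, 1, np.arccos(np.clip(z, -1, 1)), np.arctan2(y, x)))
            lap = apply_laplacian(dom, Y)
            lam = -3 * 4 / dom.radius**2
            rq = np.sum(dom.node_weights * Y * lap) / np.sum(dom.node_weights * Y * Y)
            errs.append(abs(rq - lam) / abs(lam))
        assert errs[1] < errs[0] / 2.5  # near second-order convergence

    def test_shape_mismatch_rejected(self, ring550):
        with pytest.raises(ValueError, match="shape"):
            apply_laplacian(ring550, np.zeros(7))


class TestAdmissibleModes:
    def test_matches_dispersion_sign_oracle(self, params, ss, ring550, sphere550):
        rep = turing_check(params)
        ring_modes = admissible_modes(ring550, rep)
        oracle = {
            m
            for m in range(1, 40)
            if dispersion_rate(params, ss, (2 * math.pi * m / ring550.length) ** 2) > 0
        }
        assert ring_modes == oracle
        sph_modes = admissible_modes(sphere550, rep)
        oracle_l = {
            l
            for l in range(1, 40)
            if dispersion_rate(params, ss, l * (l + 1) / sphere550.radius**2) > 0
        }
        assert sph_modes == oracle_l

    def test_fastest_ring_mode_is_three_at_wild_type_size(self, params, ss, ring550):
        rep = turing_check(params)
        modes = sorted(admissible_modes(ring550, rep))
        rates = {
            m: dispersion_rate(params, ss, (2 * math.pi * m / ring550.length) ** 2)
            for m in modes
        }
        assert max(rates, key=rates.get) == 3

    def test_larger_ring_admits_mode_four(self, params):
        rep = turing_check(params)
        assert 4 in admissible_modes(ring_from_front_area(750.0), rep)

    def test_empty_band_gives_empty_set(self, params, ring550):
        from pollenpat.model import TuringReport

        rep = TuringReport(True, False, None, None)
        assert admissible_modes(ring550, rep) == set()


class TestRefinement:
    def test_ring_interpolation_preserves_band_limited_fields(self, ring550):
        fine = refine_domain(ring550)
        x = ring550.node_positions
        f = 1.0 + 0.3 * np.cos(2 * math.pi * 3 * x / ring550.length)
        g = interpolate_to_refined(ring550, fine, f)
        expected = 1.0 + 0.3 * np.cos(2 * math.pi * 3 * fine.node_positions / fine.length)
        assert np.allclose(g, expected, atol=1e-10)

    def test_sphere_interpolation_matches_on_coincident_vertices(self, sphere550):
        fine = refine_domain(sphere550)
        f = sphere550.node_positions[:, 2] / sphere550.radius
        g = interpolate_to_refined(sphere550, fine, f)
        # coarse vertices are a subset of fine vertices
        from scipy.spatial import cKDTree

        _, idx = cKDTree(fine.node_positions).query(sphere550.node_positions)
        assert np.allclose(g[idx], f, atol=1e-12)
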