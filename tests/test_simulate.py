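"""Integration to steady state: determinism, positivity, linear-regime accuracy."""

import math

import numpy as np
import pytest

from pollenpat.model import GMParameters, steady_state, turing_check, dispersion_rate
from pollenpat.domains import ring_from_front_area, refine_domain, interpolate_to_refined
from pollenpat.simulate import Field, SimConfig, initial_condition, integrate, run_one
from pollenpat.classify import classify_pattern


class TestInitialCondition:
    def test_zero_noise_is_exact_steady_state(self, params, ring550, ss):
        f = initial_condition(params, ring550, SimConfig(noise_amp=0.0, seed=1))
        assert np.allclose(f.A, ss.A_star) and np.allclose(f.H, ss.H_star)

    def test_same_seed_same_field(self, params, ring550):
        f1 = initial_condition(params, ring550, SimConfig(seed=17))
        f2 = initial_condition(params, ring550, SimConfig(seed=17))
        assert np.array_equal(f1.A, f2.A) and np.array_equal(f1.H, f2.H)

    def test_noise_bounded(self, params, ring550, ss):
        f = initial_condition(params, ring550, SimConfig(seed=3, noise_amp=5e-4))
        assert np.max(np.abs(f.A - ss.A_star)) <= 5e-4
        assert np.max(np.abs(f.H - ss.H_star)) <= 5e-4

    def test_transient_stimulus_added_to_activator_only(self, params, sphere550, ss):
        stim = np.zeros(sphere550.n_nodes)
        stim[10] = 0.5
        cfg = SimConfig(seed=5, noise_amp=1e-4)
        f = initial_condition(params, sphere550, cfg, transient_stimulus=stim)
        f0 = initial_condition(params, sphere550, cfg)
        assert f.A[10] > ss.A_star + 0.5 - 1e-4
        assert np.array_equal(f.H, f0.H)

    def test_huge_noise_clipped_with_warning(self, params, ring550):
        with pytest.warns(UserWarning, match="clipped"):
            f = initial_condition(params, ring550, SimConfig(seed=2, noise_amp=50.0))
        assert np.all(f.A >= 0) and np.all(f.H > 0)


class TestIntegrate:
    def test_stable_parameters_return_to_homogeneity(self, params, ring550, ss):
        # equal diffusivities cannot produce diffusion-driven instability
        from pollenpat.model import scale_parameter

        p = scale_parameter(params, "D_H", params.D_A / params.D_H)
        assert not turing_check(p).satisfied
        ssp = steady_state(p)
        f = initial_condition(p, ring550, SimConfig(seed=4))
        res = integrate(p, f, SimConfig(seed=4, t_max=5e4))
        assert res.converged
        assert np.allclose(res.final.A, ssp.A_star, rtol=1e-3)
        assert np.allclose(res.final.H, ssp.H_star, rtol=1e-3)

    def test_wild_type_ring_pattern_contrast(self, params, ring550, ss):
        res, label = run_one(params, ring550, SimConfig(seed=11))
        A = res.final.A
        assert res.converged
        assert A.min() < 0.1 * ss.A_star  # activator depleted between spikes
        assert A.max() > 2 * ss.A_star
        assert np.all(res.final.H > 0)  # inhibitor never reaches zero
        assert np.all(A > -1e-9)

    def test_single_mode_growth_matches_dispersion_rate(self, params, ring550, ss):
        m = 3
        k2 = (2 * math.pi * m / ring550.length) ** 2
        sigma = dispersion_rate(params, ss, k2)
        x = ring550.node_positions
        eps = 1e-6
        amps = []
        for t_end in (30.0, 60.0):
            f = Field(
                ring550,
                ss.A_star + eps * np.cos(2 * math.pi * m * x / ring550.length),
                np.full(ring550.n_nodes, ss.H_star),
            )
            cfg = SimConfig(seed=0, noise_amp=0.0, t_max=t_end, steady_tol=1e-14,
                            dt_max=0.25)
            res = integrate(params, f, cfg)
            spec = np.abs(np.fft.rfft(res.final.A - ss.A_star))
            amps.append((spec[m], res.elapsed_model_time))
        measured = math.log(amps[1][0] / amps[0][0]) / (amps[1][1] - amps[0][1])
        assert measured == pytest.approx(sigma, rel=0.05)

    def test_seed_determinism_of_full_run(self, params, ring550):
        r1, l1 = run_one(params, ring550, SimConfig(seed=21))
        r2, l2 = run_one(params, ring550, SimConfig(seed=21))
        assert l1.as_tuple() == l2.as_tuple()
        assert np.array_equal(r1.final.A, r2.final.A)

    def test_shape_mismatch_in_forcing_rejected(self, params, ring550):
        f = initial_condition(params, ring550, SimConfig(seed=0))
        with pytest.raises(ValueError, match="stimulus"):
            integrate(params, f, SimConfig(seed=0), continuous_stimulus=np.zeros(5))


class TestRefinementStability:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_ring_label_stable_under_mesh_doubling(self, params, ring550, ss, seed):
        cfg = SimConfig(seed=seed)
        coarse_ic = initial_condition(params, ring550, cfg)
        fine_dom = refine_domain(ring550)
        fine_ic = Field(
            fine_dom,
            interpolate_to_refined(ring550, fine_dom, coarse_ic.A),
            interpolate_to_refined(ring550, fine_dom, coarse_ic.H),
        )
        res_c = integrate(params, coarse_ic, cfg)
        res_f = integrate(params, fine_ic, cfg)
        lab_c = classify_pattern(res_c.final, A_star=ss.A_star)
        lab_f = classify_pattern(res_f.final, A_star=ss.A_star)
        assert lab_c.as_tuple() == lab_f.as_tuple()
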