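"""Forward-model correctness: GPD cylinder, diameter distributions,
time-dependent zeppelin, composite models, NODDI, and tensor/FA."""

import numpy as np
import pytest
from scipy.integrate import quad

from callosim.schemes import AcquisitionScheme, build_protocol, gradient_amplitude
from callosim.signals import (
    DiameterDistribution,
    MicrostructureParams,
    axcaliber_signal,
    ball_attenuation,
    charmed_signal,
    compartment_signals,
    cylinder_perp_attenuation,
    dispersed_stick_signal,
    distribution_signal,
    dti_fa,
    fa_from_eigenvalues,
    fit_dti,
    kappa_from_od,
    noddi_signal,
    od_from_kappa,
    stick_attenuation,
    watson_sphere_weights,
    zeppelin_attenuation,
    zeppelin_perp_diffusivity,
)

from mc_oracle import mc_cylinder_attenuation


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestCylinderGPD:
    def test_no_gradient_gives_unity(self):
        assert cylinder_perp_attenuation(5.0, 0.0, 7.0, 18.0) == pytest.approx(1.0)

    def test_fully_restricted_limit(self):
        e = cylinder_perp_attenuation(1e-4, 270.0, 7.0, 18.0)
        assert e == pytest.approx(1.0, abs=1e-6)

    def test_monotone_nonincreasing_in_diameter(self):
        d = np.linspace(0.2, 12.0, 60)
        e = cylinder_perp_attenuation(d, np.array([270.0]), 7.0, 30.0)[:, 0]
        assert np.all(np.diff(e) <= 1e-12)
        assert np.all((e > 0) & (e <= 1))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cylinder_perp_attenuation(-1.0, 270.0, 7.0, 18.0)
        with pytest.raises(ValueError):
            cylinder_perp_attenuation(4.0, -5.0, 7.0, 18.0)

    def test_against_random_walk_oracle_single_setting(self):
        # light check here; the full diameter sweep runs in the acceptance
        # suite with 1e5 walkers
        d, Delta = 6.0, 30.0
        G = gradient_amplitude(4000.0, 7.0, Delta)
        e_mc = mc_cylinder_attenuation(d, [G], 7.0, [Delta],
                                       n_walkers=30_000, seed=7)[0, 0]
        e_gpd = cylinder_perp_attenuation(d, G, 7.0, Delta)
        assert e_gpd == pytest.approx(e_mc, rel=0.015)


class TestDiameterDistributions:
    def test_densities_normalized(self):
        xs = np.linspace(1e-4, 25.0, 200_001)
        for dist in (DiameterDistribution("gamma", k=3.0, theta=1.0),
                     DiameterDistribution("gamma_truncated", k=3.0, theta=1.0),
                     DiameterDistribution("poisson", lam=4.0)):
            mass = np.trapezoid(dist.pdf(xs), xs)
            assert mass == pytest.approx(1.0, abs=1e-4)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DiameterDistribution("gamma", k=-1.0, theta=1.0)
        with pytest.raises(ValueError):
            DiameterDistribution("gamma_truncated", k=2.0, theta=1.0,
                                 bounds=(5.0, 1.0))
        with pytest.raises(ValueError):
            DiameterDistribution("weird")

    def test_delta_reduces_to_single_cylinder(self):
        dist = DiameterDistribution("delta", d=4.0)
        e = distribution_signal(dist, 270.0, 7.0, 30.0)
        assert e == pytest.approx(
            cylinder_perp_attenuation(4.0, 270.0, 7.0, 30.0), abs=1e-12)

    def test_truncation_negligible_when_tails_are(self):
        g = DiameterDistribution("gamma", k=3.0, theta=1.0)
        gt = DiameterDistribution("gamma_truncated", k=3.0, theta=1.0,
                                  bounds=(0.1, 20.0))
        Gs = np.array([150.0, 270.0])
        e = distribution_signal(g, Gs, 7.0, 30.0)
        et = distribution_signal(gt, Gs, 7.0, 30.0)
        np.testing.assert_allclose(e, et, atol=1e-4)

    def test_larger_mean_attenuates_more_at_long_delta(self):
        G = np.array([270.0])
        prev = None
        for mean in (2.0, 4.0, 6.0, 8.0):
            dist = DiameterDistribution("gamma", k=3.0, theta=mean / 3.0)
            e = distribution_signal(dist, G, 7.0, 55.0)[0]
            if prev is not None:
                assert e <= prev
            prev = e

    def test_poisson_against_direct_quadrature(self):
        lam = 4.0
        dist = DiameterDistribution("poisson", lam=lam)
        G, Delta = 270.0, 30.0
        e_pkg = distribution_signal(dist, np.array([G]), 7.0, Delta)[0]

        def integrand_num(d):
            return dist.pdf(d) * d**2

        def integrand_sig(d):
            return (dist.pdf(d) * d**2
                    * cylinder_perp_attenuation(float(d), G, 7.0, Delta))

        num, _ = quad(integrand_sig, 1e-3, 25.0, limit=300)
        den, _ = quad(integrand_num, 1e-3, 25.0, limit=300)
        assert e_pkg == pytest.approx(num / den, abs=1e-4)

    def test_volume_weighting_shifts_mean_up(self):
        dist = DiameterDistribution("gamma", k=3.0, theta=1.5)
        assert dist.volume_weighted_mean() > dist.mean()
        # gamma: number mean k*theta, volume-weighted mean (k+2)*theta
        assert dist.volume_weighted_mean() == pytest.approx(
            (3.0 + 2.0) * 1.5, rel=1e-3)


class TestZeppelin:
    def test_zero_disorder_is_time_independent(self):
        for Delta in (18.0, 30.0, 55.0):
            assert zeppelin_perp_diffusivity(Delta, 7.0, 0.5, 0.0) == 0.5

    def test_decreasing_with_diffusion_time(self):
        d18 = zeppelin_perp_diffusivity(18.0, 7.0, 0.5, 1.0)
        d55 = zeppelin_perp_diffusivity(55.0, 7.0, 0.5, 1.0)
        assert d55 < d18

    def test_long_time_asymptote(self):
        assert zeppelin_perp_diffusivity(1e4, 7.0, 0.5, 1.0) == pytest.approx(
            0.5, abs=1e-3)

    def test_invalid_timing(self):
        with pytest.raises(ValueError):
            zeppelin_perp_diffusivity(5.0, 7.0, 0.5, 1.0)


class TestCompartmentSignals:
    def test_ball_arithmetic(self):
        assert ball_attenuation(1000.0, 2.0) == pytest.approx(np.exp(-2.0))

    def test_stick_perpendicular_gradient(self):
        e = stick_attenuation(np.array([3000.0]), np.array([[1.0, 0.0, 0.0]]),
                              [0.0, 0.0, 1.0], 1.7)
        assert e[0] == pytest.approx(1.0)

    def test_zeppelin_isotropic_limit_equals_ball(self, protocol2):
        ez = zeppelin_attenuation(protocol2.bvals, protocol2.bvecs,
                                  [0.0, 0.0, 1.0], 1.1, 1.1)
        eb = ball_attenuation(protocol2.bvals, 1.1)
        np.testing.assert_allclose(ez, eb, atol=1e-13)

    def test_unity_at_b0(self, protocol2):
        params = MicrostructureParams(fr=0.4, A=0.5,
                                      dist=DiameterDistribution("delta", d=3.0))
        sig = compartment_signals(protocol2, params)
        b0 = protocol2.b0_mask()
        for comp in sig.values():
            np.testing.assert_allclose(comp[b0], 1.0, atol=1e-12)


class TestCompositeModels:
    def test_charmed_fraction_limits(self, protocol2):
        params = MicrostructureParams(dist=DiameterDistribution("delta", d=4.0),
                                      A=0.6)
        sig = compartment_signals(protocol2, params)
        np.testing.assert_allclose(
            charmed_signal(protocol2, params.replace(fr=0.0)),
            sig["zeppelin"], atol=1e-12)
        np.testing.assert_allclose(
            charmed_signal(protocol2, params.replace(fr=1.0)),
            sig["restricted"], atol=1e-12)

    def test_charmed_is_convex_combination(self, protocol2):
        params = MicrostructureParams(fr=0.35, A=0.6,
                                      dist=DiameterDistribution("delta", d=4.0))
        sig = compartment_signals(protocol2, params)
        expected = 0.35 * sig["restricted"] + 0.65 * sig["zeppelin"]
        np.testing.assert_allclose(charmed_signal(protocol2, params),
                                   expected, atol=1e-12)

    def test_axcaliber_delta_family_collapses_to_charmed(self, protocol2):
        params = MicrostructureParams(fr=0.4, A=0.5,
                                      dist=DiameterDistribution("delta", d=5.0))
        np.testing.assert_allclose(axcaliber_signal(protocol2, params),
                                   charmed_signal(protocol2, params),
                                   atol=1e-14)

    def test_diffusion_time_dependence_encodes_resolution_limit(self, protocol2):
        """Large-diameter restricted signal varies across diffusion times;
        below the resolution limit the dependence collapses."""
        def per_delta_signal(mean_d):
            params = MicrostructureParams(
                fr=1.0, A=0.0,
                dist=DiameterDistribution("gamma", k=3.0, theta=mean_d / 3.0))
            sig = axcaliber_signal(protocol2, params)
            out = []
            for Dl in (18.0, 30.0, 42.0, 55.0):
                sel = (protocol2.Delta == Dl) & (protocol2.bvals == 4000.0)
                out.append(np.mean(sig[sel]))
            return np.array(out)

        big = per_delta_signal(6.0)
        small = per_delta_signal(0.5)
        assert big.max() - big.min() > 0.02
        assert (small.max() - small.min()) / small.mean() < 0.005


class TestNoddi:
    def test_od_kappa_mapping(self):
        assert od_from_kappa(1.0) == pytest.approx(0.5)
        assert kappa_from_od(0.5) == pytest.approx(1.0)
        assert od_from_kappa(kappa_from_od(0.04)) == pytest.approx(0.04)

    def test_high_concentration_limit_is_parallel_stick(self, protocol1):
        stick = stick_attenuation(protocol1.bvals, protocol1.bvecs,
                                  [0.0, 0.0, 1.0], 1.7)
        D_perp = 1.7 * (1 - 0.68)
        zep = zeppelin_attenuation(protocol1.bvals, protocol1.bvecs,
                                   [0.0, 0.0, 1.0], 1.7, D_perp)
        iso = ball_attenuation(protocol1.bvals, 3.0)
        composite = 0.98 * (0.68 * stick + 0.32 * zep) + 0.02 * iso
        devs = []
        for kappa in (500.0, 1000.0, 2000.0):
            params = MicrostructureParams(v_ic=0.68, v_iso=0.02, kappa=kappa)
            devs.append(np.abs(noddi_signal(protocol1, params)
                               - composite).max())
        assert devs[0] > devs[1] > devs[2]       # monotone approach
        assert devs[-1] < 2.5e-3
        assert od_from_kappa(2000.0) < 1e-3

    def test_watson_spherical_mean_normalization(self, protocol1):
        """Averaging the dispersed-stick kernel over uniformly distributed
        mean orientations must equal the spherical mean of a plain stick."""
        one = AcquisitionScheme([2400.0], [[0.0, 0.0, 1.0]], 7.0, 23.0)
        # exact identity: averaging over uniformly distributed mean
        # orientations depends only on the angle to the gradient, so
        # integrate over cos(beta) by Gauss-Legendre
        x, w = np.polynomial.legendre.leggauss(64)
        u = 0.5 * (x + 1.0)
        disp = sum(
            wi * dispersed_stick_signal(
                one, [np.sqrt(1.0 - ui**2), 0.0, ui], kappa=4.0)[0]
            for ui, wi in zip(u, 0.5 * w))
        b = 2400.0 / 1000.0
        plain, _ = quad(lambda v: np.exp(-b * 1.7 * v**2), 0.0, 1.0)
        assert disp == pytest.approx(plain, abs=1e-3)

    def test_watson_weights_sum_to_one(self):
        _, w = watson_sphere_weights(kappa=16.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestRotationEquivariance:
    def test_composite_models_equivariant(self, protocol2):
        R = _rotation([1.0, 2.0, 0.5], 1.1)
        params = MicrostructureParams(
            fr=0.4, A=0.6, dist=DiameterDistribution("gamma", k=3.0, theta=1.5),
            orientation=[0.0, 0.0, 1.0])
        rotated_scheme = AcquisitionScheme(
            protocol2.bvals, protocol2.bvecs @ R.T, protocol2.delta,
            protocol2.Delta)
        rotated_params = params.replace(orientation=R @ params.orientation)
        np.testing.assert_allclose(
            axcaliber_signal(rotated_scheme, rotated_params),
            axcaliber_signal(protocol2, params), atol=1e-10)

    def test_noddi_equivariant(self, protocol1):
        R = _rotation([0.3, -1.0, 0.7], 2.0)
        params = MicrostructureParams(v_ic=0.65, v_iso=0.05, kappa=12.0,
                                      orientation=[0.0, 0.0, 1.0])
        rotated_scheme = AcquisitionScheme(
            protocol1.bvals, protocol1.bvecs @ R.T, protocol1.delta,
            protocol1.Delta)
        rotated_params = params.replace(orientation=R @ params.orientation)
        np.testing.assert_allclose(
            noddi_signal(rotated_scheme, rotated_params),
            noddi_signal(protocol1, params), atol=1e-10)


class TestDti:
    def test_isotropic_voxel_fa_zero(self, protocol1):
        sig = ball_attenuation(protocol1.bvals, 1.0)
        assert dti_fa(protocol1, sig) == pytest.approx(0.0, abs=1e-6)

    def test_prolate_tensor_closed_form(self, protocol1):
        evals_true = np.array([1.7, 0.2, 0.2])
        fa_closed = fa_from_eigenvalues(evals_true)
        # independent closed form: sqrt(3/2 * sum((l-lbar)^2) / sum(l^2))
        lbar = evals_true.mean()
        manual = np.sqrt(1.5 * np.sum((evals_true - lbar) ** 2)
                         / np.sum(evals_true**2))
        assert fa_closed == pytest.approx(manual, abs=1e-12)
        sig = zeppelin_attenuation(protocol1.bvals, protocol1.bvecs,
                                   [0.0, 0.0, 1.0], 1.7, 0.2)
        assert dti_fa(protocol1, sig) == pytest.approx(manual, abs=1e-6)

    def test_noise_free_zeppelin_roundtrip(self, protocol1):
        sig = zeppelin_attenuation(protocol1.bvals, protocol1.bvecs,
                                   [0.0, 1.0, 0.0], 1.5, 0.4)
        evals, evecs, _ = fit_dti(protocol1, sig)
        np.testing.assert_allclose(evals, [1.5, 0.4, 0.4], atol=1e-6)
        assert abs(evecs[:, 0] @ np.array([0.0, 1.0, 0.0])) == pytest.approx(
            1.0, abs=1e-6)

    def test_nonpositive_signals_masked_with_warning(self, protocol1):
        sig = ball_attenuation(protocol1.bvals, 1.0)
        sig[5] = -0.1
        with pytest.warns(UserWarning, match="masked"):
            fa = dti_fa(protocol1, sig)
        assert fa == pytest.approx(0.0, abs=1e-5)
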