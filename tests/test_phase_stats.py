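import math

import numpy as np
import pytest

from bloodwalk.gradients import GAMMA_RAD_PER_MS_T, amplitude_for_b, switch_times
from bloodwalk.phase_stats import (
    PhaseEnsemble,
    adc_from_phases,
    isotropic_directions,
    kurtosis_expansion_check,
    phases,
)
from bloodwalk.walker import WalkRecord


def synthetic_record(x_cm_by_label, profiles):
    """WalkRecord stub holding hand-constructed interval centers of mass."""
    n = next(iter(x_cm_by_label.values())).shape[0]
    return WalkRecord(
        profiles=tuple(profiles),
        x_cm=x_cm_by_label,
        dt=1e-3,
        n_steps=1,
        start_compartment=np.zeros(n, np.int8),
        end_compartment=np.zeros(n, np.int8),
        start_position=np.zeros((n, 3)),
        end_position=np.zeros((n, 3)),
        first_exit_time=np.full(n, np.nan),
        intracellular_fraction=np.zeros(n),
    )


class TestIsotropicDirections:
    def test_unit_norm_and_reproducible(self):
        d1 = isotropic_directions(100, seed=5)
        d2 = isotropic_directions(100, seed=5)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, rtol=1e-12)

    def test_mean_direction_small_at_large_n(self):
        d = isotropic_directions(10000, seed=1)
        assert np.linalg.norm(d.mean(axis=0)) < 0.02  # 3-sigma CLT bound

    def test_outer_product_isotropy(self):
        d = isotropic_directions(20000, seed=2)
        cov = d.T @ d / len(d)
        np.testing.assert_allclose(cov, np.eye(3) / 3.0, atol=0.01)


class TestPhases:
    def test_static_particle_has_zero_phase_both_profiles(self):
        mp = switch_times("MP", 40.0, 120.0)
        fc = switch_times("FC", 70.0, 120.0)
        pos = np.array([1.3, -0.4, 2.2])
        x_cm = {
            mp.label: np.tile(pos, (5, mp.K, 1)),
            fc.label: np.tile(pos, (5, fc.K, 1)),
        }
        rec = synthetic_record(x_cm, [mp, fc])
        dirs = isotropic_directions(16, seed=0)
        for prof in (mp, fc):
            ens = phases(rec, prof, dirs, 400.0)
            np.testing.assert_allclose(ens.phi_prime, 0.0, atol=1e-12)

    def test_constant_velocity_nulled_by_fc_not_mp(self):
        mp = switch_times("MP", 40.0, 120.0)
        fc = switch_times("FC", 70.0, 120.0)
        v = np.array([0.02, 0.0, -0.01])  # um/ms

        def cm_for(prof):
            mids = 0.5 * (prof.t[:-1] + prof.t[1:])
            return mids[None, :, None] * v[None, None, :]

        rec = synthetic_record({mp.label: cm_for(mp), fc.label: cm_for(fc)}, [mp, fc])
        dirs = np.eye(3)
        ens_fc = phases(rec, fc, dirs, 400.0)
        np.testing.assert_allclose(ens_fc.phi, 0.0, atol=1e-10)
        # monopolar keeps velocity sensitivity: phi = gamma*g*(v.n)*T^2/4
        ens_mp = phases(rec, mp, dirs, 400.0)
        g = amplitude_for_b(mp, 400.0)
        expected = GAMMA_RAD_PER_MS_T * g * v * 40.0**2 / 4.0
        np.testing.assert_allclose(np.abs(ens_mp.phi[0]), np.abs(expected), rtol=1e-10)

    def test_phi_prime_independent_of_b(self):
        mp = switch_times("MP", 40.0, 120.0)
        rng = np.random.default_rng(3)
        rec = synthetic_record({mp.label: rng.normal(size=(20, 2, 3))}, [mp])
        dirs = isotropic_directions(8, seed=1)
        e1 = phases(rec, mp, dirs, 400.0)
        e2 = phases(rec, mp, dirs, 50.0)
        np.testing.assert_allclose(e1.phi_prime, e2.phi_prime, rtol=1e-10)

    def test_unrecorded_profile_rejected(self):
        mp = switch_times("MP", 40.0, 120.0)
        other = switch_times("MP", 60.0, 120.0)
        rec = synthetic_record({mp.label: np.zeros((3, 2, 3))}, [mp])
        with pytest.raises(KeyError):
            phases(rec, other, np.eye(3), 400.0)


def gaussian_ensemble(D=1.5, b_s_mm2=400.0, n=200000, seed=0):
    rng = np.random.default_rng(seed)
    phi_prime = rng.normal(0.0, math.sqrt(2.0 * D), size=(n, 1))
    return PhaseEnsemble(phi_prime=phi_prime, directions=np.eye(3)[:1], b=b_s_mm2 * 1e-3)


def scale_mixture_phases(n, seed, weights=(0.45, 0.45, 0.1), variances=(0.5, 2.0, 8.0)):
    """Three-component Gaussian scale mixture: genuinely non-Gaussian phases
    with non-vanishing fourth AND sixth cumulants (a two-component mixture
    has an identically zero sixth cumulant and cannot probe the O(b^2) term)."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    sd = np.sqrt(np.asarray(variances))[comp]
    return (rng.standard_normal(n) * sd)[:, None]


class TestAdcFromPhases:
    def test_gaussian_phases_recover_diffusivity_with_zero_kurtosis(self):
        D = 1.5
        stats = adc_from_phases(gaussian_ensemble(D=D), seed=4)
        assert abs(stats.adc_0 - D) < 3.0 * stats.se_adc_0
        assert abs(stats.adc_b - D) < 3.0 * stats.se_adc_b
        assert abs(stats.k_app) < 3.0 * stats.se_k_app

    def test_two_point_distribution_closed_form(self):
        # phi = +-phi0 equally: |<e^{i phi}>| = cos(phi0), K_app = -2
        b = 0.4
        phi0 = 0.6
        phi_prime = np.array([[phi0], [-phi0]] * 500) / math.sqrt(b)
        ens = PhaseEnsemble(phi_prime=phi_prime, directions=np.eye(3)[:1], b=b)
        stats = adc_from_phases(ens, seed=0)
        assert stats.adc_b == pytest.approx(-math.log(math.cos(phi0)) / b, rel=1e-9)
        assert stats.k_app == pytest.approx(-2.0, abs=1e-9)

    def test_small_b_limit_approaches_adc0(self):
        # non-Gaussian scale mixture: adc_b -> adc_0 as the weighting vanishes
        phi_prime = scale_mixture_phases(n=1000000, seed=9)

        def gap(b):
            ens = PhaseEnsemble(phi_prime=phi_prime, directions=np.eye(3)[:1], b=b)
            stats = adc_from_phases(ens, n_boot=10, seed=1)
            return abs(stats.adc_b - stats.adc_0) / stats.adc_0

        assert gap(0.004) < 0.01
        assert gap(0.004) < gap(0.4) / 10.0

    def test_signal_null_raises(self):
        b = 0.4
        phi = np.array([[math.pi / 2], [-math.pi / 2]]) / math.sqrt(b)
        ens = PhaseEnsemble(phi_prime=phi, directions=np.eye(3)[:1], b=b)
        with pytest.raises(FloatingPointError):
            adc_from_phases(ens, n_boot=2, seed=0)


class TestKurtosisExpansion:
    @staticmethod
    def mixture_ensemble(b, n=1000000, seed=11):
        return PhaseEnsemble(
            phi_prime=scale_mixture_phases(n, seed), directions=np.eye(3)[:1], b=b
        )

    def test_gaussian_residual_negligible(self):
        stats = adc_from_phases(gaussian_ensemble(n=400000, seed=2), n_boot=20, seed=0)
        resid, scale = kurtosis_expansion_check(stats)
        assert resid < 5e-3  # K_app ~ 0 and ADC_b ~ ADC_0

    def test_residual_scales_as_b_squared(self):
        r_full, s_full = kurtosis_expansion_check(
            adc_from_phases(self.mixture_ensemble(0.2), n_boot=20, seed=0)
        )
        r_half, s_half = kurtosis_expansion_check(
            adc_from_phases(self.mixture_ensemble(0.1), n_boot=20, seed=0)
        )
        ratio = r_full / r_half
        assert 2.5 < ratio < 6.0  # ~4 for a clean b^2 scaling
        assert s_full == pytest.approx(4.0 * s_half, rel=1e-9)

    def test_residual_bounded_by_next_order_scale(self):
        stats = adc_from_phases(self.mixture_ensemble(0.1), n_boot=20, seed=0)
        resid, scale = kurtosis_expansion_check(stats)
        assert resid < 3.0 * scale
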