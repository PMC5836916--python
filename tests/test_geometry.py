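import math

import numpy as np
import pytest
from scipy.optimize import minimize

from bloodwalk.geometry import (
    REF_DIAMETER_UM,
    REF_HEIGHT_UM,
    CompartmentParams,
    build_unit_cell,
    distance_to_membrane,
    free_cell,
    intracellular_water_fraction,
    locate,
    permeability_from_lifetime,
)


class TestBuildUnitCell:
    def test_reference_cell_gap_matches_printed_step_size(self, reference_cell):
        # 1% of the plasma gap at HCT 43% / MCV 87.7 fL is the 8.56 nm step
        assert 0.01 * reference_cell.gap * 1000.0 == pytest.approx(8.56, abs=0.01)

    def test_unscaled_cylinder_surface_to_volume(self):
        # S/V = 2/h + 2/r for the 8.00 x 1.75 um reference cylinder
        sv = 2.0 / REF_HEIGHT_UM + 2.0 / (REF_DIAMETER_UM / 2.0)
        assert sv == pytest.approx(1.643, abs=1e-3)

    def test_mcv_scaling_factor(self):
        v0 = math.pi * 4.0**2 * 1.75
        assert v0 == pytest.approx(87.965, abs=1e-3)
        cell = build_unit_cell(0.43, 87.7)
        assert cell.cyl_diameter / REF_DIAMETER_UM == pytest.approx(
            (87.7 / v0) ** (1 / 3), rel=1e-12
        )
        # aspect ratio preserved exactly under scaling
        assert cell.cyl_diameter / cell.cyl_height == pytest.approx(
            8.00 / 1.75, rel=1e-12
        )

    @pytest.mark.parametrize("hct", [0.1, 0.3, 0.43, 0.5, 0.6, 0.7])
    @pytest.mark.parametrize("mcv", [60.0, 87.7, 120.0])
    def test_volume_fraction_identity_and_equal_gap(self, hct, mcv):
        cell = build_unit_cell(hct, mcv)
        assert cell.cyl_volume / cell.cell_volume == pytest.approx(hct, rel=1e-12)
        assert cell.cell_xy - cell.cyl_diameter == pytest.approx(
            cell.cell_z - cell.cyl_height, rel=1e-9
        )
        assert cell.gap > 0.0

    @pytest.mark.parametrize("hct", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_hct_rejected(self, hct):
        with pytest.raises(ValueError):
            build_unit_cell(hct, 87.7)

    def test_packing_limit_is_infeasible(self):
        # beyond hct = pi/4 the cylinder cannot fit the cuboid with a
        # positive equal gap (zero-gap box already has hct = pi/4)
        with pytest.raises(ValueError):
            build_unit_cell(0.9, 87.7)
        build_unit_cell(0.78, 87.7)  # just inside the limit


class TestLocate:
    def test_center_is_erythrocyte_and_corner_is_plasma(self, reference_cell):
        assert locate(reference_cell, (0.0, 0.0, 0.0)) == "erythrocyte"
        corner = (
            reference_cell.cell_xy / 2,
            reference_cell.cell_xy / 2,
            reference_cell.cell_z / 2,
        )
        assert locate(reference_cell, corner) == "plasma"

    def test_periodic_images_equivalent(self, reference_cell, rng):
        L = np.array(
            [reference_cell.cell_xy, reference_cell.cell_xy, reference_cell.cell_z]
        )
        for _ in range(50):
            p = rng.uniform(-1.5, 1.5, 3) * L
            shift = rng.integers(-2, 3, 3) * L
            assert locate(reference_cell, p) == locate(reference_cell, p + shift)

    def test_free_cell_is_all_plasma(self, rng):
        cell = free_cell(10.0)
        for _ in range(20):
            assert locate(cell, rng.uniform(-5, 5, 3)) == "plasma"


class TestDistanceToMembrane:
    def test_axis_midpoint_distance_is_half_height(self, reference_cell):
        d = distance_to_membrane(reference_cell, (0.0, 0.0, 0.0))
        assert d == pytest.approx(reference_cell.cyl_height / 2.0, rel=1e-12)

    def test_point_on_lateral_surface_is_zero(self, reference_cell):
        p = (reference_cell.radius, 0.0, 0.0)
        assert distance_to_membrane(reference_cell, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_numeric_surface_minimization(self, reference_cell, rng):
        """Oracle: numeric minimization of |p - q| over the parametrized
        membrane patches (lateral wall, two caps) of the 27 nearest images."""
        cell = reference_cell
        R, hh = cell.radius, cell.cyl_height / 2.0
        L = np.array([cell.cell_xy, cell.cell_xy, cell.cell_z])

        def oracle(p):
            best = np.inf
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    for iz in (-1, 0, 1):
                        c = np.array([ix, iy, iz]) * L

                        def lateral(v):
                            th, z = v
                            q = c + [R * np.cos(th), R * np.sin(th), np.clip(z, -hh, hh)]
                            return np.linalg.norm(p - q)

                        def cap(v, sgn):
                            r, th = v
                            r = np.clip(r, 0.0, R)
                            q = c + [r * np.cos(th), r * np.sin(th), sgn * hh]
                            return np.linalg.norm(p - q)

                        th0 = math.atan2(p[1] - c[1], p[0] - c[0])
                        for fun, x0 in [
                            (lateral, [th0, np.clip(p[2] - c[2], -hh, hh)]),
                            (lambda v: cap(v, 1.0), [min(np.hypot(*(p[:2] - c[:2])), R), th0]),
                            (lambda v: cap(v, -1.0), [min(np.hypot(*(p[:2] - c[:2])), R), th0]),
                        ]:
                            res = minimize(fun, x0, method="Nelder-Mead",
                                           options={"xatol": 1e-10, "fatol": 1e-14})
                            best = min(best, res.fun)
            return best

        for _ in range(60):
            p = rng.uniform(-0.5, 0.5, 3) * L
            assert distance_to_membrane(cell, p) == pytest.approx(
                oracle(p), abs=1e-6
            )


class TestWaterFractionAndPermeability:
    def test_printed_default_fraction(self):
        assert intracellular_water_fraction(0.43, 0.95, 0.70) == pytest.approx(
            0.3573, abs=2e-4
        )

    def test_limits(self):
        assert intracellular_water_fraction(0.0, 0.95, 0.70) == 0.0
        assert intracellular_water_fraction(1.0, 0.95, 0.70) == 1.0

    def test_monotone_in_hct(self):
        hcts = np.linspace(0.01, 0.99, 50)
        fs = [intracellular_water_fraction(h, 0.95, 0.70) for h in hcts]
        assert np.all(np.diff(fs) > 0.0)

    def test_permeability_values(self, reference_cell):
        kappa_e, kappa_p = permeability_from_lifetime(reference_cell, 12.0, 0.95, 0.70)
        # (V/S)/tau_e with S/V ~ 1.64 um^-1
        assert kappa_e == pytest.approx((1.0 / 1.6445) / 12.0, rel=1e-3)
        assert kappa_p == pytest.approx(kappa_e * 0.70 / 0.95, rel=1e-12)
        # stationarity relation kappa_e = kappa_p * c_p / c_e
        assert kappa_e == pytest.approx(kappa_p * 0.95 / 0.70, rel=1e-12)

    def test_long_lifetime_limit(self, reference_cell):
        kappa_e, _ = permeability_from_lifetime(reference_cell, 1e9, 0.95, 0.70)
        assert kappa_e == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            permeability_from_lifetime(reference_cell, 0.0, 0.95, 0.70)

    def test_params_for_cell_fills_derived_fields(self, reference_cell):
        p = CompartmentParams().for_cell(reference_cell)
        assert p.f == pytest.approx(0.3573, abs=2e-4)
        assert p.kappa_e == pytest.approx(0.0507, abs=5e-4)
        assert p.D_e < p.D_p
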