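"""Periodic blood unit cell: red-blood-cell geometry, water fractions, permeability.

The substrate for the random walk is a cuboid unit cell with one oblate
cylinder (the red blood cell, RBC) centered at the origin, cylinder axis
along z, repeated periodically in all three directions.  The cylinder keeps
the reference aspect ratio 8.00 µm diameter to 1.75 µm height and is scaled
isotropically to the requested mean corpuscular volume (MCV); the cuboid is
sized so that the cylinder occupies exactly the hematocrit (HCT) volume
fraction, with the same plasma gap ``g`` along x, y and z.

Internal units are µm and ms throughout (diffusivities in µm²/ms,
permeabilities in µm/ms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "REF_DIAMETER_UM",
    "REF_HEIGHT_UM",
    "BloodUnitCell",
    "CompartmentParams",
    "build_unit_cell",
    "free_cell",
    "locate",
    "distance_to_membrane",
    "intracellular_water_fraction",
    "permeability_from_lifetime",
]

#: Reference oblate-cylinder RBC dimensions (µm); preserved under MCV scaling.
REF_DIAMETER_UM = 8.00
REF_HEIGHT_UM = 1.75

# mm²/s -> µm²/ms
MM2_PER_S_TO_UM2_PER_MS = 1.0e3


@dataclass(frozen=True)
class BloodUnitCell:
    """Periodic cuboid unit cell containing one centered oblate-cylinder RBC.

    Lengths in µm.  ``cell_xy`` is the cuboid edge along x and y, ``cell_z``
    along z; ``gap`` is the shortest plasma gap between periodic RBC images
    (equal in all three axes by construction).
    """

    hct: float
    mcv: float
    cyl_diameter: float
    cyl_height: float
    cell_xy: float
    cell_z: float

    @property
    def gap(self) -> float:
        return self.cell_xy - self.cyl_diameter

    @property
    def radius(self) -> float:
        return 0.5 * self.cyl_diameter

    @property
    def cyl_volume(self) -> float:
        return math.pi * self.radius**2 * self.cyl_height

    @property
    def cell_volume(self) -> float:
        return self.cell_xy**2 * self.cell_z

    @property
    def surface_to_volume(self) -> float:
        """RBC surface-to-volume ratio S/V = 2/h + 2/r (µm⁻¹)."""
        if self.cyl_diameter == 0.0:
            return 0.0
        return 2.0 / self.cyl_height + 2.0 / self.radius

    def wrap(self, point: np.ndarray) -> np.ndarray:
        """Wrap coordinates into the primary cell [-L/2, L/2) per axis."""
        p = np.asarray(point, dtype=float)
        L = np.array([self.cell_xy, self.cell_xy, self.cell_z])
        return p - L * np.floor(p / L + 0.5)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap"] = self.gap
        d["surface_to_volume"] = self.surface_to_volume
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_unit_cell(hct: float, mcv: float) -> BloodUnitCell:
    """Size the unit cell so the RBC volume fraction equals the hematocrit.

    The reference cylinder (8.00 µm × 1.75 µm) is scaled isotropically so its
    volume equals ``mcv`` (fL = µm³); the cuboid edge lengths are d+g and h+g
    with a single gap g solving (d+g)²(h+g) = mcv/hct.

    Parameters
    ----------
    hct : float
        Hematocrit as a volume fraction, 0 < hct < 1.
    mcv : float
        Mean corpuscular volume in fL.

    Returns
    -------
    BloodUnitCell
    """
    if not 0.0 < hct < 1.0:
        raise ValueError(f"hct must lie in (0, 1), got {hct}")
    if mcv <= 0.0:
        raise ValueError(f"mcv must be positive, got {mcv}")

    v0 = math.pi * (REF_DIAMETER_UM / 2.0) ** 2 * REF_HEIGHT_UM
    scale = (mcv / v0) ** (1.0 / 3.0)
    d = REF_DIAMETER_UM * scale
    h = REF_HEIGHT_UM * scale

    # (d+g)^2 (h+g) = mcv/hct  ->  g^3 + (2d+h) g^2 + (d^2+2dh) g + d^2 h - V = 0
    v_cell = mcv / hct
    coeffs = [1.0, 2.0 * d + h, d * d + 2.0 * d * h, d * d * h - v_cell]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    positive = real[real > 0.0]
    if positive.size == 0:
        raise ValueError(f"no positive gap solves the cell volume for hct={hct}, mcv={mcv}")
    # Descartes: exactly one sign change, so one positive root.
    g = float(positive.min())

    cell = BloodUnitCell(
        hct=hct, mcv=mcv, cyl_diameter=d, cyl_height=h, cell_xy=d + g, cell_z=h + g
    )
    assert abs(cell.cyl_volume / cell.cell_volume - hct) < 1e-10
    return cell


def free_cell(size: float = 10.0) -> BloodUnitCell:
    """Membrane-free control cell: periodic cube with no RBC (pure plasma)."""
    return BloodUnitCell(
        hct=0.0, mcv=0.0, cyl_diameter=0.0, cyl_height=0.0, cell_xy=size, cell_z=size
    )


def locate(cell: BloodUnitCell, point) -> str:
    """Compartment of a point: ``"erythrocyte"`` or ``"plasma"``.

    Periodic images map to the same compartment.
    """
    x, y, z = cell.wrap(point)
    inside = (x * x + y * y < cell.radius**2) and (abs(z) < 0.5 * cell.cyl_height)
    return "erythrocyte" if inside else "plasma"


def _cylinder_surface_distance(p: np.ndarray, radius: float, half_h: float) -> float:
    """Unsigned distance from p to the boundary of a capped cylinder at origin."""
    rho = math.hypot(p[0], p[1])
    dr = rho - radius
    dz = abs(p[2]) - half_h
    if dr > 0.0 or dz > 0.0:
        # outside: distance to the nearest of lateral band / cap disc / rim
        return math.hypot(max(dr, 0.0), max(dz, 0.0))
    # inside: nearest face
    return min(-dr, -dz)


def distance_to_membrane(cell: BloodUnitCell, point) -> float:
    """Shortest Euclidean distance (µm) from a point to the RBC membrane,
    minimized over the 27 nearest periodic images."""
    p = cell.wrap(point)
    radius, half_h = cell.radius, 0.5 * cell.cyl_height
    Lxy, Lz = cell.cell_xy, cell.cell_z
    best = math.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                q = np.array([p[0] - ix * Lxy, p[1] - iy * Lxy, p[2] - iz * Lz])
                d = _cylinder_surface_distance(q, radius, half_h)
                if d < best:
                    best = d
    return best


def intracellular_water_fraction(hct: float, c_p: float, c_e: float) -> float:
    """Fraction of blood water residing in RBCs.

    f = c_e·HCT / [c_e·HCT + c_p·(1−HCT)], with c_p and c_e the free-water
    concentrations of plasma and erythrocytes.
    """
    if not 0.0 <= hct <= 1.0:
        raise ValueError(f"hct must lie in [0, 1], got {hct}")
    if c_p <= 0.0 or c_e <= 0.0:
        raise ValueError("water concentrations must be positive")
    return c_e * hct / (c_e * hct + c_p * (1.0 - hct))


def permeability_from_lifetime(
    cell: BloodUnitCell, tau_e: float, c_p: float, c_e: float
) -> tuple[float, float]:
    """Membrane permeabilities (κ_e, κ_p) in µm/ms from the intracellular
    pre-exchange lifetime τ_e (ms): κ_e = (V/S)/τ_e, κ_p = κ_e·c_e/c_p.

    The κ_e/κ_p ratio keeps the compartment water concentrations stationary.
    """
    if tau_e <= 0.0:
        raise ValueError(f"tau_e must be positive, got {tau_e}")
    sv = cell.surface_to_volume
    if sv == 0.0:
        return 0.0, 0.0
    kappa_e = (1.0 / sv) / tau_e
    kappa_p = kappa_e * c_e / c_p
    return kappa_e, kappa_p


@dataclass(frozen=True)
class CompartmentParams:
    """Diffusion/exchange parameters of the two blood-water compartments.

    Diffusivities in µm²/ms (defaults: plasma 2.75e-3 mm²/s at 37 °C,
    erythrocyte interior 1.00e-3 mm²/s), dimensionless free-water
    concentrations, intracellular pre-exchange lifetime τ_e in ms.
    Permeabilities and the intracellular water fraction are derived for a
    particular unit cell via :meth:`for_cell`.
    """

    D_p: float = 2.75e-3 * MM2_PER_S_TO_UM2_PER_MS
    D_e: float = 1.00e-3 * MM2_PER_S_TO_UM2_PER_MS
    c_p: float = 0.95
    c_e: float = 0.70
    tau_e: float = 12.0
    kappa_e: float = field(default=math.nan)
    kappa_p: float = field(default=math.nan)
    f: float = field(default=math.nan)

    def __post_init__(self):
        if min(self.D_p, self.D_e, self.c_p, self.c_e) <= 0.0:
            raise ValueError("diffusivities and concentrations must be positive")
        if self.tau_e <= 0.0:
            raise ValueError("tau_e must be positive")

    def for_cell(self, cell: BloodUnitCell) -> "CompartmentParams":
        """Return a copy with κ_e, κ_p and f derived for ``cell``."""
        kappa_e, kappa_p = permeability_from_lifetime(cell, self.tau_e, self.c_p, self.c_e)
        f = intracellular_water_fraction(cell.hct, self.c_p, self.c_e)
        return CompartmentParams(
            D_p=self.D_p, D_e=self.D_e, c_p=self.c_p, c_e=self.c_e,
            tau_e=self.tau_e, kappa_e=kappa_e, kappa_p=kappa_p, f=f,
        )
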