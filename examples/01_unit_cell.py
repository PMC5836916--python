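"""Build the reference blood unit cell and inspect its derived quantities.

The cell holds one oblate-cylinder red blood cell (scaled to the sample MCV)
in a periodic cuboid sized so the RBC occupies exactly the hematocrit volume
fraction, with an equal plasma gap along all three axes.
"""

from bloodwalk import CompartmentParams, build_unit_cell

cell = build_unit_cell(hct=0.43, mcv=87.7)
params = CompartmentParams().for_cell(cell)

print(f"cylinder: d = {cell.cyl_diameter:.3f} um, h = {cell.cyl_height:.3f} um")
print(f"cuboid:   {cell.cell_xy:.3f} x {cell.cell_xy:.3f} x {cell.cell_z:.3f} um")
print(f"plasma gap g = {cell.gap:.4f} um  (1% step = {10.0 * cell.gap:.2f} nm)")
print(f"S/V = {cell.surface_to_volume:.3f} 1/um")
print(f"intracellular water fraction f = {params.f:.4f}")
print(f"kappa_e = {params.kappa_e:.4f} um/ms, kappa_p = {params.kappa_p:.4f} um/ms")

# The gap sets the walker step size; f sets the start-compartment weighting;
# kappa_e = (V/S)/tau_e converts the 12 ms pre-exchange lifetime into the
# membrane permeability used by the transmission rule.
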