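"""Compare monopolar and flow-compensated effective gradient waveforms.

Both spin-echo waveforms null the zeroth gradient moment; the FC profile
additionally nulls the first moment, so constant-velocity spins accrue no
phase.  The price is a ~8x smaller b-value coefficient a = b/(gamma^2 g^2 T^3),
i.e. ~2.9x stronger gradients for the same b at equal T.
"""

from bloodwalk import (
    amplitude_for_b,
    dimensionless_b_coefficient,
    gradient_moments,
    switch_times,
)

for kind, T in (("MP", 40.0), ("FC", 70.0)):
    prof = switch_times(kind, T, TE=120.0)
    a = dimensionless_b_coefficient(prof)
    g = amplitude_for_b(prof, 400.0)
    m0, m1 = gradient_moments(prof, g)
    print(f"{kind}: switch times {[round(float(t), 3) for t in prof.t]} ms")
    print(f"    a = {a:.6f}   g(b=400 s/mm2) = {g:.3e} T/um")
    note = "(nulled)" if kind == "FC" else "(velocity-sensitive)"
    print(f"    M0 = {m0:.2e}   M1 = {m1:.2e} {note}")
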