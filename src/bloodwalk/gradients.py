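"""Effective diffusion-gradient waveforms for monopolar and flow-compensated encoding.

A spin-echo diffusion block of total duration T is placed symmetrically about
the refocusing pulse at TE/2.  The *effective* waveform (physical gradient
with the sign flipped after refocusing) is piecewise constant on K intervals
with alternating polarity (−1)^k:

* monopolar (MP):          K = 2, switch times t_k = TE/2 + (k−1)·T/2
* flow-compensated (FC):   K = 4, switch times
                           t_k = TE/2 + (T/4)·sgn(k−2)·(√2)^{|k−2|}

so the FC interval durations are (T(2−√2)/4, √2T/4, √2T/4, T(2−√2)/4).
Both waveforms have vanishing zeroth moment (spin-echo refocusing); the FC
waveform additionally nulls the first moment, removing phase from constant
velocity.  The b-value scales as b = a·γ²g²T³ with a = 1/12 for MP and
a = √2/8 − 1/6 ≈ 0.010110 for FC.

Units: ms for times, ms/µm² for b internally (the public interface accepts
b in the clinical s/mm²; 1 s/mm² = 1e-3 ms/µm²), gradient amplitude g in
T/µm with γ in rad·ms⁻¹·T⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GAMMA_RAD_PER_MS_T",
    "S_MM2_TO_MS_UM2",
    "SequenceProfile",
    "switch_times",
    "b_value_numeric",
    "dimensionless_b_coefficient",
    "amplitude_for_b",
    "gradient_moments",
]

#: Proton gyromagnetic ratio, rad·ms⁻¹·T⁻¹ (2.6752218744e8 rad·s⁻¹·T⁻¹).
GAMMA_RAD_PER_MS_T = 2.6752218744e5

#: Conversion of clinical b-values: 1 s/mm² = 1e-3 ms/µm².
S_MM2_TO_MS_UM2 = 1.0e-3


@dataclass(frozen=True)
class SequenceProfile:
    """Piecewise-constant effective gradient waveform.

    ``t`` holds the K+1 switch times (gradient on at t[0], off at t[K]);
    interval k = 1..K has duration ``dt[k-1]`` and polarity ``signs[k-1]``
    = (−1)^k.  ``b`` (ms/µm², optional) and the derived amplitude ``g``
    (T/µm) are attached by :func:`amplitude_for_b`.
    """

    kind: str
    TE: float
    T: float
    t: np.ndarray
    b: float | None = None
    g: float | None = None

    @property
    def K(self) -> int:
        return len(self.t) - 1

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.t)

    @property
    def signs(self) -> np.ndarray:
        return np.array([(-1.0) ** k for k in range(1, self.K + 1)])

    @property
    def label(self) -> str:
        return f"{self.kind}_T{self.T:g}_TE{self.TE:g}"

    def with_b(self, b_s_mm2: float) -> "SequenceProfile":
        """Attach a target b-value (s/mm²) and the matching amplitude."""
        g = amplitude_for_b(self, b_s_mm2)
        return replace(self, b=b_s_mm2 * S_MM2_TO_MS_UM2, g=g)


def switch_times(kind: str, T: float, TE: float) -> SequenceProfile:
    """Build the MP or FC profile switch times for diffusion time T and echo
    time TE (both ms).  The waveform is symmetric about TE/2 and must fit
    before the echo, so TE >= T is required."""
    kind = kind.upper()
    if T <= 0.0:
        raise ValueError(f"T must be positive, got {T}")
    if TE < T:
        raise ValueError(f"waveform does not fit: TE={TE} < T={T}")
    if kind == "MP":
        t = np.array([TE / 2.0 + (k - 1) * T / 2.0 for k in range(3)])
    elif kind == "FC":
        t = np.array(
            [
                TE / 2.0 + (T / 4.0) * np.sign(k - 2) * math.sqrt(2.0) ** abs(k - 2)
                for k in range(5)
            ]
        )
    else:
        raise ValueError(f"unknown profile kind {kind!r} (expected 'MP' or 'FC')")
    return SequenceProfile(kind=kind, TE=TE, T=T, t=t)


def b_value_numeric(profile: SequenceProfile, g: float) -> float:
    """b-value (ms/µm²) of the profile at amplitude g (T/µm).

    b = γ²∫q(t)²dt with q the running integral of the effective waveform;
    q is piecewise linear, so each segment integrates in closed form as
    Δt/3·(q₀² + q₀q₁ + q₁²).
    """
    if g < 0.0:
        raise ValueError("amplitude must be non-negative")
    dt = profile.dt
    signs = profile.signs
    q_nodes = GAMMA_RAD_PER_MS_T * g * np.concatenate([[0.0], np.cumsum(signs * dt)])
    q0, q1 = q_nodes[:-1], q_nodes[1:]
    return float(np.sum(dt / 3.0 * (q0 * q0 + q0 * q1 + q1 * q1)))


def dimensionless_b_coefficient(profile: SequenceProfile) -> float:
    """a = b/(γ²g²T³); 1/12 for MP and √2/8 − 1/6 for FC, independent of TE."""
    g = 1.0e-6  # arbitrary; a is amplitude-independent
    return b_value_numeric(profile, g) / (GAMMA_RAD_PER_MS_T**2 * g**2 * profile.T**3)


def amplitude_for_b(profile: SequenceProfile, b_target_s_mm2: float) -> float:
    """Gradient amplitude g (T/µm) realizing the target b-value (s/mm²)."""
    if b_target_s_mm2 < 0.0:
        raise ValueError("b must be non-negative")
    b_unit = b_value_numeric(profile, 1.0)
    return math.sqrt(b_target_s_mm2 * S_MM2_TO_MS_UM2 / b_unit)


def gradient_moments(profile: SequenceProfile, g: float = 1.0) -> tuple[float, float]:
    """Zeroth and first moments (M0, M1) of the effective waveform, the first
    moment taken about the waveform midpoint TE/2.

    M0 = 0 for both kinds (spin-echo refocusing); M1 = 0 only for FC.
    """
    t0, t1 = profile.t[:-1], profile.t[1:]
    signs = profile.signs
    mid = profile.TE / 2.0
    m0 = g * float(np.sum(signs * (t1 - t0)))
    m1 = g * float(np.sum(signs * 0.5 * ((t1 - mid) ** 2 - (t0 - mid) ** 2)))
    return m0, m1
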