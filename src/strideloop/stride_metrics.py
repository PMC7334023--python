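"""Per-stride mechanical outcomes from conditioned trajectories.

Net mass-specific work W_net follows the work-loop convention: fascicle
velocity in m/s (shortening negative) times tendon force gives muscle
power with the sign flipped, P = -F * v, so that shortening under load
produces positive power; the trapezoidal time integral of P over one cycle,
divided by muscle mass, is W_net in J/kg.  A counter-clockwise loop in the
force-length plane therefore corresponds to net positive work.

Force landmarks are the peak force F_pk, the fractional length and velocity
sampled at the instant of peak force (L_pkF, V_pkF), and the fraction of
the cycle with force above a threshold (T_force, threshold default 5% of
that stride's peak force).
"""

from __future__ import annotations

import numpy as np

from .recordings_io import ValidationError
from .signal_conditioning import differentiate


def compute_stride_work(F, L, L_o_mm: float, dt: float, muscle_mass_g: float) -> float:
    """Mass-specific net work over one stride (J/kg, shortening positive).

    ``F`` in N, ``L`` fractional fascicle length, ``L_o_mm`` the reference
    length so that the metric velocity is dL/dt * L_o.
    """
    F = np.asarray(F, float)
    L = np.asarray(L, float)
    if F.shape != L.shape:
        raise ValidationError(f"mismatched array lengths: {F.shape} vs {L.shape}")
    if muscle_mass_g <= 0:
        raise ValidationError("muscle_mass_g must be > 0")
    v_m = differentiate(L, dt) * (L_o_mm / 1000.0)  # m/s, shortening negative
    power = -F * v_m                                # W, shortening positive
    work = np.trapezoid(power, dx=dt)               # J
    return float(work / (muscle_mass_g / 1000.0))


def work_loop_area(F, L, L_o_mm: float) -> float:
    """Signed area of the closed force-length loop (J).

    Equals -(integral of F dx) around the cycle; positive for a
    counter-clockwise loop in the force-length plane.  The loop is closed
    between the last and first sample.
    """
    F = np.asarray(F, float)
    x = np.asarray(L, float) * (L_o_mm / 1000.0)  # m
    Fc = np.concatenate([F, F[:1]])
    xc = np.concatenate([x, x[:1]])
    return float(-np.sum(0.5 * (Fc[1:] + Fc[:-1]) * np.diff(xc)))


def force_landmarks(F, L, V, threshold_frac: float = 0.05,
                    refine: bool = False) -> dict:
    """Peak-force landmarks and force duration for one stride.

    Returns a dict with F_pk, L_pkF, V_pkF and T_force.  An all-zero force
    stride yields F_pk = 0 with the other landmarks missing (NaN) rather
    than fabricated.  Exact ties at the peak resolve to the first index.

    With ``refine=True`` the peak instant is refined with a 3-point
    parabolic fit (a near-quadratic force peak makes the discrete argmax
    wander on a flat top), and L_pkF/V_pkF are interpolated at the refined
    instant.
    """
    F = np.asarray(F, float)
    L = np.asarray(L, float)
    V = np.asarray(V, float)
    if not (F.shape == L.shape == V.shape):
        raise ValidationError("F, L, V must have equal lengths")
    f_pk = float(F.max())
    if f_pk <= 0:
        return {"F_pk": 0.0, "L_pkF": np.nan, "V_pkF": np.nan, "T_force": 0.0}
    i_pk = int(np.argmax(F))
    thr = threshold_frac * f_pk
    t_force = float(np.count_nonzero(F > thr) / F.size)
    l_pk, v_pk = float(L[i_pk]), float(V[i_pk])
    if refine and 0 < i_pk < F.size - 1:
        y0, y1, y2 = F[i_pk - 1], F[i_pk], F[i_pk + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
            x = i_pk + delta
            j = int(np.floor(x))
            frac = x - j
            if 0 <= j < F.size - 1:
                l_pk = float((1 - frac) * L[j] + frac * L[j + 1])
                v_pk = float((1 - frac) * V[j] + frac * V[j + 1])
    return {"F_pk": f_pk, "L_pkF": l_pk, "V_pkF": v_pk, "T_force": t_force}


def mechanical_metrics(cycle, threshold_frac: float = 0.05,
                       refine_landmarks: bool = True) -> dict:
    """All mechanical per-stride metrics for a phase-resampled cycle."""
    n = cycle.phase.size
    dt = cycle.T_stride / n
    L = cycle.channels["L"]
    F = cycle.channels["F"]
    V = differentiate(L, dt)
    out = {"T_stride": cycle.T_stride}
    out["W_net"] = compute_stride_work(F, L, cycle.L_o_mm, dt, cycle.muscle_mass_g)
    out.update(force_landmarks(F, L, V, threshold_frac=threshold_frac,
                               refine=refine_landmarks))
    return out
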