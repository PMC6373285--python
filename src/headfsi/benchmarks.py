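"""Canonical verification problems for the hydrocode.

Small, self-contained benchmark drivers with closed-form references:

* acoustic pulse transit in a water column (speed vs ``sqrt(K/rho)``);
* square-wave advection (donor cell vs van Leer accuracy ordering, total
  variation behaviour);
* steady Couette flow in the shear gap (wall stress vs ``gamma * V / h``).

These are the package's own convergence evidence; tests and the acceptance
script call them rather than re-scripting the setups.
"""

from __future__ import annotations

import numpy as np

from .advection import advect_donor_cell, advect_van_leer
from .column import FluidColumn
from .materials import bulk_sound_speed
from .simulate import ShearGapSim, merge_config

__all__ = [
    "acoustic_speed",
    "advection_square_wave",
    "couette_wall_stress",
    "total_variation",
]


def acoustic_speed(n_cells: int = 200, length: float = 1.0, cfl: float = 0.5,
                   scheme: str = "van_leer",
                   pulse_amplitude: float = 0.01,
                   pulse_duration: float = 1e-4) -> dict:
    """Measure the sound speed of a small pressure pulse in a water column.

    A short haversine velocity pulse is driven at the wall of a fully
    fluid-filled column; the pulse transit time between two interior probe
    cells gives the propagation speed, compared against the bulk sound
    speed ``sqrt(K/rho)``.

    Returns a dict with ``measured``, ``reference`` (m/s) and ``rel_error``.
    """
    h = length / n_cells
    col = FluidColumn([h] * n_cells, [True] * n_cells, mode="fsi", scheme=scheme)
    c0 = col.sound_speed0
    ia, ib = n_cells // 4, (3 * n_cells) // 4
    xa, xb = (ia + 0.5) * h, (ib + 0.5) * h
    dt = col.stable_dt(cfl)
    t_end = xb / c0 + 2.5 * pulse_duration
    n_steps = int(np.ceil(t_end / dt))

    t = 0.0
    wall_pos = 0.0
    times = np.empty(n_steps)
    pa = np.empty(n_steps)
    pb = np.empty(n_steps)
    for step in range(n_steps):
        tau = t / pulse_duration
        v = pulse_amplitude * np.sin(np.pi * tau) ** 2 if tau < 1.0 else 0.0
        wall_pos += dt * v
        col.set_wall(wall_pos, v)
        col.step(dt)
        t += dt
        times[step] = t
        pa[step] = col.last_pressures[ia]
        pb[step] = col.last_pressures[ib]

    ta = times[int(np.argmax(pa))]
    tb = times[int(np.argmax(pb))]
    if tb <= ta:
        raise RuntimeError("pulse did not traverse the probe span")
    measured = (xb - xa) / (tb - ta)
    reference = bulk_sound_speed(col.elastic.K, col.elastic.rho)
    return {
        "measured": float(measured),
        "reference": float(reference),
        "rel_error": float(abs(measured - reference) / reference),
    }


def total_variation(field: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(field))))


def advection_square_wave(n_cells: int = 200, wave_width: int = 20,
                          courant: float = 0.2, n_steps: int = 100) -> dict:
    """Advect a unit square wave and compare the two remap schemes.

    The transport per step is ``courant`` cell widths; with the defaults the
    profile travels exactly 20 cells, so the exact solution is a pure shift
    and the L1 errors of the two schemes are directly comparable. Also
    reports the total variation history of the van Leer solution (TVD
    check) and both schemes' conservation errors.
    """
    h = 1.0
    vol = np.full(n_cells, h)
    start = n_cells // 4
    exact0 = np.zeros(n_cells)
    exact0[start:start + wave_width] = 1.0
    shift = courant * n_steps * h
    if abs(shift - round(shift)) > 1e-12:
        raise ValueError("choose courant * n_steps integer for an exact shift")
    exact = np.roll(exact0, int(round(shift)))

    tv_faces = np.zeros(n_cells + 1)
    tv_faces[1:-1] = courant * h  # uniform rightward transport, closed ends
    # keep the boundary faces closed; profile must stay away from the edges
    out = {}
    tv_history = []
    for name, fn in (("donor_cell", advect_donor_cell), ("van_leer", advect_van_leer)):
        field = exact0.copy() * h  # content = conc * volume
        for _ in range(n_steps):
            field = fn(field, tv_faces, vol)
            if name == "van_leer":
                tv_history.append(total_variation(field / vol))
        conc = field / vol
        out[name] = {
            "l1_error": float(np.sum(np.abs(conc - exact)) * h),
            "conservation_error": float(abs(field.sum() - exact0.sum() * h)),
            "min": float(conc.min()),
            "max": float(conc.max()),
        }
    out["van_leer"]["tv_history"] = tv_history
    return out


def couette_wall_stress(gamma: float = 1.0, gap: float = 2e-3,
                        wall_velocity: float = 1.0, n_layers: int = 4,
                        t_end: float = 0.05) -> dict:
    """Steady Couette flow in the FSI shear gap against ``gamma * V / h``."""
    cfg = {
        "experiment": "shear_gap",
        "mode": "fsi",
        "t_end": t_end,
        "materials": {"fluid": {"gamma": gamma}},
        "geometry": {"gap": gap, "csf_layers": n_layers},
        "shear": {"bottom": "fixed", "wall_velocity": wall_velocity},
    }
    result = ShearGapSim(cfg).run()
    measured = result.peaks["wall_shear"]
    reference = gamma * wall_velocity / gap
    return {
        "measured": float(measured),
        "reference": float(reference),
        "rel_error": float(abs(measured - reference) / reference),
    }
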