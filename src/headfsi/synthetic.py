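"""Synthetic inputs: loading pulses, perturbed rating fixtures, geometries.

No cadaver recordings or 3D head meshes exist at desk scale, so every input
the experiments need is generated here: impact kinematic pulses with the
documented peak magnitudes (450 g translational, 26.2 krad/s^2 rotational
for the ASDH reconstruction case), reference/perturbed curve pairs with
known expected effects on each CORA component, and runnable surrogate
geometry blocks. All generators are pure functions of their spec (and seed)
and reproduce bitwise on repeated calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import SignalCurve

__all__ = [
    "GRAVITY",
    "PulseSpec",
    "PerturbationSpec",
    "LoadingCurves",
    "make_pulse",
    "make_case_asdh",
    "perturb_curve",
    "make_geometry",
]

#: standard gravity used for the g-to-m/s^2 conversion, exactly
GRAVITY = 9.81


@dataclass(frozen=True)
class PulseSpec:
    """A single loading pulse: zero outside [onset, onset + duration]."""

    shape: str = "haversine"
    peak: float = 0.0
    duration: float = 0.01
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("haversine", "triangular"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.peak < 0 or self.duration <= 0:
            raise ValueError("peak must be >= 0 and duration > 0")


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled degradation of a reference curve for rating fixtures."""

    time_shift: float = 0.0
    amplitude_scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class LoadingCurves:
    """Paired skull-kinematics histories for one impact case."""

    translational: SignalCurve  # m/s^2
    rotational: SignalCurve  # rad/s^2


def make_pulse(spec: PulseSpec, sample_interval: float = 1e-5,
               t_end: float | None = None, channel_label: str = "") -> SignalCurve:
    """Sample a pulse; max value equals ``spec.peak`` (to 1e-9 relative).

    The grid always contains the pulse apex exactly: the sample interval is
    nudged so an integer number of steps spans [onset, onset + duration/2].
    """
    if sample_interval >= spec.duration / 10:
        raise ValueError("sample_interval must resolve the pulse (< duration/10)")
    half = spec.duration / 2
    n_half = max(1, int(round(half / sample_interval)))
    dt = half / n_half
    end = t_end if t_end is not None else spec.onset + spec.duration
    n = int(np.ceil((end - 0.0) / dt)) + 1
    t = dt * np.arange(n)
    tau = (t - spec.onset) / spec.duration
    inside = (tau >= 0.0) & (tau <= 1.0)
    if spec.shape == "haversine":
        y = np.where(inside, spec.peak * np.sin(np.pi * np.clip(tau, 0, 1)) ** 2, 0.0)
    else:  # triangular
        y = np.where(inside, spec.peak * (1.0 - np.abs(2.0 * np.clip(tau, 0, 1) - 1.0)), 0.0)
    y[np.abs(y) < 1e-14 * spec.peak] = 0.0  # snap sin(pi) residue at the support edges
    return SignalCurve(t, y, channel_label)


def make_case_asdh(sample_interval: float = 1e-5, duration: float = 0.01,
                   t_end: float | None = None) -> LoadingCurves:
    """The ASDH reconstruction loading: 450 g translational and
    26.2 krad/s^2 rotational acceleration pulses (10 ms default duration)."""
    trans = make_pulse(
        PulseSpec("haversine", 450.0 * GRAVITY, duration), sample_interval,
        t_end, "translational_acceleration",
    )
    rot = make_pulse(
        PulseSpec("haversine", 26.2e3, duration), sample_interval,
        t_end, "rotational_acceleration",
    )
    return LoadingCurves(trans, rot)


def perturb_curve(ref: SignalCurve, spec: PerturbationSpec) -> SignalCurve:
    """``amplitude_scale * ref(t - time_shift) + N(0, noise_sd)``, seeded.

    The output lives on the reference grid; values outside the shifted
    support clamp to the reference's edge values.
    """
    shifted = np.interp(ref.times - spec.time_shift, ref.times, ref.values)
    vals = spec.amplitude_scale * shifted
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.size)
    return SignalCurve(ref.times, vals, ref.channel_label)


#: surrogate geometry presets; CSF gaps default to two element layers
#: across the thickness (the mesh-converged default)
_GEOMETRY_PRESETS = {
    "radial_column": {
        "gap": 3e-3,  # CSF gap thickness each side, m
        "csf_layers": 2,
        "void_thickness": 2e-3,  # initially empty mesh beyond the fluid, m
        "void_layers": 2,
        "brain_length": 0.06,  # brain surrogate rod, m
        "brain_elements": 12,
    },
    "shear_gap": {
        "gap": 3e-3,  # CSF shear gap, m
        "csf_layers": 2,
        "brain_thickness": 0.1,  # lumped brain block, m
    },
}


def make_geometry(preset: str, overrides: dict | None = None) -> dict:
    """A complete runnable geometry block for a surrogate experiment."""
    if preset not in _GEOMETRY_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(_GEOMETRY_PRESETS)}"
        )
    block = dict(_GEOMETRY_PRESETS[preset])
    for key, val in (overrides or {}).items():
        if key not in block:
            raise ValueError(f"unknown geometry key {key!r} for preset {preset!r}")
        block[key] = val
    return block
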