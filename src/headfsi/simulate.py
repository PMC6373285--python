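"""Surrogate brain-skull interface experiments.

Two canonical one-dimensional experiments stand in for the 3D head:

* **radial column** — skull wall | CSF gap | brain rod | CSF gap | skull
  wall along one axis. Exercises the normal-direction physics: equation of
  state, coup/contrecoup pressure pattern, tensile cut-off, penalty
  coupling, and (in FSI mode) multi-material advection into void mesh.

* **shear gap** — skull plate | CSF layer | brain block in the tangential
  direction. Exercises the mechanism behind ASDH prediction: the tangential
  drag the CSF layer transmits, which differs by orders of magnitude
  between the Newtonian FSI fluid and the tensor-viscosity sliding CSF, and
  the resulting brain-skull relative motion driving bridging-vein strain.

``run_simulation`` takes a nested config (YAML-compatible dict), runs the
selected experiment/mode, and returns a :class:`SimulationResult` holding
probe time histories, peak summaries and a conservation ledger.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .column import BrainRod, CouplingConfig, FluidColumn, penalty_force
from .materials import (
    ElasticFluidParams,
    MieGruneisenParams,
    ViscousParams,
    bulk_sound_speed,
)
from .signals import SignalCurve
from .synthetic import PulseSpec, make_geometry, make_pulse

__all__ = ["DEFAULT_CONFIG", "SimulationResult", "run_simulation",
           "RadialColumnSim", "ShearGapSim", "load_config", "merge_config"]


DEFAULT_CONFIG: dict = {
    "experiment": "shear_gap",  # or "radial_column"
    "mode": "fsi",  # or "sliding"
    "t_end": 0.015,
    "seed": 0,
    "geometry": {},  # merged over the experiment preset
    "materials": {
        "fluid": {
            "rho0": 1000.0,
            "K": 2.19e9,
            "VC": 0.3,
            "gamma": 0.001,
            "C": 1482.9,
            "S1": 2.1057,
            "S2": -0.1744,
            "S3": 0.010085,
            "gamma0": 1.2,
            "a_vc": 0.0,
            "p_cut": -22e6,
            "energy_term": True,
        },
        "brain": {"density": 1040.0, "modulus": 2.19e9, "viscosity": 500.0},
    },
    "loading": {
        "translational": {"shape": "haversine", "peak": 450.0 * 9.81,
                          "duration": 0.01, "onset": 0.0},
        "rotational": {"shape": "haversine", "peak": 26.2e3,
                       "duration": 0.01, "onset": 0.0},
        "translational_csv": None,
        "rotational_csv": None,
        "effective_radius": 0.06,  # head radius mapping rad/s^2 -> m/s^2
    },
    "numerics": {
        "cfl": 0.5,
        "advection": "van_leer",  # or "donor_cell"
        "penalty_factor": 0.1,
        "bulk_q": [0.06, 1.5],
        "mesh_relaxation": 1.0,
        "sample_interval": 1e-5,
        "record_stride": 20,
    },
    "shear": {
        # elastic tether standing in for falx/tentorium/neck restraint
        "tether_frequency_hz": 50.0,
        "tether_damping_ratio": 0.05,
        "bottom": "block",  # or "fixed" (Couette benchmarks)
        "wall_velocity": None,  # constant plate speed overriding the pulse
        "bv_spring_stiffness": 0.0,  # N/m^3: veins as kinematic gauges by default
    },
    "output_dir": None,
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict merge (override wins); returns a new dict."""
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path) -> dict:
    """Read a YAML run config and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULT_CONFIG, user)


@dataclass
class SimulationResult:
    """Probe histories, peak summaries and conservation ledger of one run."""

    experiment: str
    mode: str
    signals: dict[str, SignalCurve]
    peaks: dict[str, float]
    ledger: dict
    config: dict = field(repr=False, default_factory=dict)

    def write_outputs(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, sig in self.signals.items():
            sig.to_csv(out / f"{name}.csv")
        with open(out / "ledger.json", "w") as fh:
            json.dump({"experiment": self.experiment, "mode": self.mode,
                       "peaks": self.peaks, **self.ledger}, fh, indent=2)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _fluid_params(mat: dict, delta_l: float):
    eos = MieGruneisenParams(
        C=mat["C"], S1=mat["S1"], S2=mat["S2"], S3=mat["S3"],
        gamma0=mat["gamma0"], a_vc=mat["a_vc"], rho0=mat["rho0"],
        p_cut=mat["p_cut"],
    )
    viscous = ViscousParams(gamma=mat["gamma"])
    elastic = ElasticFluidParams(K=mat["K"], VC=mat["VC"], rho=mat["rho0"],
                                 delta_L=delta_l)
    return eos, viscous, elastic


def _loading_curve(block: dict | None, csv_path, t_end: float,
                   sample_interval: float, label: str) -> SignalCurve:
    if csv_path:
        return SignalCurve.from_csv(csv_path, label)
    spec = PulseSpec(block.get("shape", "haversine"), block["peak"],
                     block["duration"], block.get("onset", 0.0))
    if spec.peak == 0.0:
        n = max(2, int(np.ceil(t_end / sample_interval)) + 1)
        t = sample_interval * np.arange(n)
        return SignalCurve(t, np.zeros(n), label)
    return make_pulse(spec, sample_interval, t_end=max(t_end, spec.onset + spec.duration),
                      channel_label=label)


def _integrate_curve(curve: SignalCurve) -> SignalCurve:
    """Cumulative trapezoidal integral on the curve's own grid."""
    dt = curve.sample_interval
    v = np.concatenate(([0.0], np.cumsum(0.5 * dt * (curve.values[1:] + curve.values[:-1]))))
    return SignalCurve(curve.times, v, curve.channel_label + "_int")


# ----------------------------------------------------------------------
# radial column
# ----------------------------------------------------------------------

class RadialColumnSim:
    """Skull | CSF | brain | CSF | skull column under prescribed skull motion.

    Both skull walls move rigidly with the doubly integrated translational
    acceleration; the ALE fluid meshes ride with the skull. The right-hand
    gap is handled in a mirrored frame so both gaps share the wall-on-the-
    left :class:`FluidColumn` implementation.
    """

    def __init__(self, config: dict) -> None:
        cfg = merge_config(DEFAULT_CONFIG, config)
        cfg["experiment"] = "radial_column"
        self.config = cfg
        self.mode = cfg["mode"]
        geo = make_geometry("radial_column", cfg["geometry"])
        num = cfg["numerics"]
        mat = cfg["materials"]["fluid"]
        brain = cfg["materials"]["brain"]

        gap, nl = geo["gap"], geo["csf_layers"]
        h = gap / nl
        if self.mode == "fsi":
            vh = geo["void_thickness"] / geo["void_layers"]
            widths = [h] * nl + [vh] * geo["void_layers"]
            filled = [True] * nl + [False] * geo["void_layers"]
        else:
            widths = [h] * nl
            filled = [True] * nl
        eos, viscous, elastic = _fluid_params(mat, h)

        def column():
            return FluidColumn(
                widths, filled, self.mode, eos, viscous, elastic,
                scheme=num["advection"], bulk_q=tuple(num["bulk_q"]),
                mesh_relaxation=num["mesh_relaxation"],
                energy_term=mat["energy_term"],
            )

        self.left = column()
        self.right = column()  # mirrored frame: xi = W0 - x
        self.rod = BrainRod(geo["brain_length"], geo["brain_elements"],
                            brain["modulus"], brain["viscosity"],
                            brain["density"], x0=gap)
        self.W0 = 2 * gap + geo["brain_length"]
        self.coupling = CouplingConfig(
            num["penalty_factor"],
            "fsi_tension_compression" if self.mode == "fsi" else "sliding_normal_only",
        )
        self.k_pen = self.left.penalty_stiffness(num["penalty_factor"])
        self.cfl = num["cfl"]
        self.record_stride = num["record_stride"]
        self.t_end = cfg["t_end"]

        load = cfg["loading"]
        acc = _loading_curve(load["translational"], load["translational_csv"],
                             self.t_end, num["sample_interval"],
                             "translational_acceleration")
        vel = _integrate_curve(acc)
        disp = _integrate_curve(vel)
        self.skull_vel, self.skull_disp = vel, disp
        self.rod_x0 = self.rod.x.copy()

    def _dt(self) -> float:
        dts = [self.left.stable_dt(self.cfl), self.right.stable_dt(self.cfl),
               self.rod.stable_dt(self.cfl)]
        m_ref = min(self.left.node_mass_floor, float(self.rod.mass.min()))
        dts.append(self.cfl / np.sqrt(self.k_pen / m_ref))
        return min(dts)

    def _couple(self) -> tuple[float, float, float, float]:
        """Penalty forces: (on brain left node, on left fluid surface,
        on brain right node, on right fluid surface [mirrored frame])."""
        d_left = self.left.surface_position() - self.rod.x[0]
        f_bl = penalty_force(d_left, self.k_pen, self.coupling)
        xi_brain = self.W0 - self.rod.x[-1]
        d_right = self.right.surface_position() - xi_brain
        f_br_mirror = penalty_force(d_right, self.k_pen, self.coupling)
        return f_bl, -f_bl, -f_br_mirror, -f_br_mirror

    def run(self, n_steps: int | None = None) -> SimulationResult:
        dt = self._dt()
        total = n_steps if n_steps is not None else int(np.ceil(self.t_end / dt))
        rec_t, rec = [], {k: [] for k in
                          ("relative_displacement", "pressure_coup",
                           "pressure_contrecoup", "csf_shear")}
        ledger_rows = []
        c0 = self.left.sound_speed0
        mass0 = self.left.total_fluid_mass + self.right.total_fluid_mass

        t = 0.0
        for step in range(total):
            x_s = float(np.interp(t, self.skull_disp.times, self.skull_disp.values))
            v_s = float(np.interp(t, self.skull_vel.times, self.skull_vel.values))
            self.left.set_wall(x_s, v_s)
            self.right.set_wall(-x_s, -v_s)  # mirrored frame

            f_bl, f_fl, f_br, f_fr = self._couple()
            self.left.lagrangian_step(dt, f_fl)
            self.right.lagrangian_step(dt, f_fr)
            self.rod.step(dt, force_left=f_bl, force_right=f_br)
            self.left.remap_to_reference()
            self.right.remap_to_reference()
            t += dt

            if not (np.all(np.isfinite(self.left.u)) and np.all(np.isfinite(self.right.u))
                    and np.all(np.isfinite(self.rod.u))):
                raise RuntimeError("instability: non-finite velocities")
            if max(np.max(np.abs(self.left.u)), np.max(np.abs(self.right.u))) > 3 * c0:
                raise RuntimeError("instability: fluid velocity exceeds 3x sound speed")

            if step % self.record_stride == 0 or step == total - 1:
                rec_t.append(t)
                rec["relative_displacement"].append(
                    (self.rod.x[0] - self.left.x[0]) - self.rod_x0[0])
                # skull accelerating +x drives the left (trailing) wall into
                # the lagging brain: left gap = coup, right gap = contrecoup
                rec["pressure_coup"].append(self.left.last_pressures[0])
                rec["pressure_contrecoup"].append(self.right.last_pressures[0])
                rec["csf_shear"].append(max(np.max(np.abs(self.left.last_shear)),
                                            np.max(np.abs(self.right.last_shear))))
                mass = self.left.total_fluid_mass + self.right.total_fluid_mass
                mom = (self.left.total_momentum - self.right.total_momentum
                       + self.rod.momentum)
                ledger_rows.append({
                    "t": t, "fluid_mass": mass,
                    "mass_error_rel": abs(mass - mass0) / mass0,
                    "momentum": mom,
                    "kinetic_energy": (self.left.kinetic_energy
                                       + self.right.kinetic_energy
                                       + self.rod.kinetic_energy),
                    "internal_energy": (self.left.internal_energy
                                        + self.right.internal_energy),
                })

        times = np.asarray(rec_t)
        if times.size < 2:
            raise RuntimeError("run too short: fewer than two records")
        grid = np.linspace(times[0], times[-1], times.size)
        signals = {
            k: SignalCurve(grid, np.interp(grid, times, np.asarray(v)), k)
            for k, v in rec.items()
        }
        peaks = {
            "relative_displacement": float(np.max(np.abs(rec["relative_displacement"]))),
            "pressure_coup": float(np.max(rec["pressure_coup"])),
            "pressure_contrecoup": float(np.min(rec["pressure_contrecoup"])),
            "csf_shear": float(np.max(rec["csf_shear"])),
        }
        ledger = {
            "dt": dt, "n_steps": total,
            "mass_error_rel": ledger_rows[-1]["mass_error_rel"],
            "rows": ledger_rows,
        }
        return SimulationResult("radial_column", self.mode, signals, peaks,
                                ledger, self.config)


# ----------------------------------------------------------------------
# shear gap
# ----------------------------------------------------------------------

class ShearGapSim:
    """Tangential shear of the CSF layer between skull plate and brain block.

    Cell-centred tangential velocities diffuse momentum across the gap with
    the mode's effective viscosity (Newtonian ``gamma`` in FSI mode, the
    tensor-viscosity coefficient ``VC * dy * a * rho`` in sliding mode);
    no-slip at both walls. The brain block is a rigid lumped mass, restrained
    by an elastic tether to the skull standing in for falx/tentorium/neck.
    """

    def __init__(self, config: dict) -> None:
        cfg = merge_config(DEFAULT_CONFIG, config)
        cfg["experiment"] = "shear_gap"
        self.config = cfg
        self.mode = cfg["mode"]
        geo = make_geometry("shear_gap", cfg["geometry"])
        num = cfg["numerics"]
        mat = cfg["materials"]["fluid"]
        brain = cfg["materials"]["brain"]
        shear = cfg["shear"]

        self.gap = geo["gap"]
        self.n = geo["csf_layers"]
        self.dy = self.gap / self.n
        self.rho = mat["rho0"]
        a = bulk_sound_speed(mat["K"], mat["rho0"])
        if self.mode == "fsi":
            self.mu_eff = mat["gamma"]
        else:
            self.mu_eff = mat["VC"] * self.dy * a * self.rho

        self.u = np.zeros(self.n)
        self.M_b = brain["density"] * geo["brain_thickness"]
        self.U_b = 0.0
        self.D_b = 0.0
        self.bottom = shear["bottom"]
        omega = 2 * np.pi * shear["tether_frequency_hz"]
        self.k_t = self.M_b * omega**2 if self.bottom == "block" else 0.0
        self.c_t = 2 * shear["tether_damping_ratio"] * np.sqrt(self.k_t * self.M_b)
        self.k_bv = shear["bv_spring_stiffness"]

        self.t_end = cfg["t_end"]
        self.cfl = num["cfl"]
        self.record_stride = num["record_stride"]
        self.sample_interval = num["sample_interval"]

        if shear["wall_velocity"] is not None:
            v = float(shear["wall_velocity"])
            n = max(2, int(np.ceil(self.t_end / self.sample_interval)) + 1)
            tgrid = self.sample_interval * np.arange(n)
            self.plate_vel = SignalCurve(tgrid, np.full(n, v), "plate_velocity")
        else:
            load = cfg["loading"]
            alpha = _loading_curve(load["rotational"], load["rotational_csv"],
                                   self.t_end, self.sample_interval,
                                   "rotational_acceleration")
            acc = SignalCurve(alpha.times,
                              alpha.values * load["effective_radius"],
                              "tangential_acceleration")
            self.plate_vel = _integrate_curve(acc)
        self.plate_disp = _integrate_curve(self.plate_vel)

    def _dt(self) -> float:
        dts = [0.5 * self.rho * self.dy**2 / self.mu_eff if self.mu_eff > 0 else np.inf,
               self.sample_interval]
        if self.k_t > 0:
            dts.append(1.0 / np.sqrt(self.k_t / self.M_b))
        return self.cfl * min(dts)

    def run(self) -> SimulationResult:
        dt = self._dt()
        total = int(np.ceil(self.t_end / dt))
        rec_t, rec = [], {k: [] for k in
                          ("relative_displacement", "wall_shear", "csf_shear",
                           "skull_displacement", "brain_displacement")}
        mom_ledger = []
        impulse = 0.0
        t = 0.0
        for step in range(total):
            v_s = float(np.interp(t, self.plate_vel.times, self.plate_vel.values))
            d_s = float(np.interp(t, self.plate_disp.times, self.plate_disp.values))
            u_bot = 0.0 if self.bottom == "fixed" else self.U_b

            tau = np.empty(self.n + 1)
            tau[0] = self.mu_eff * (self.u[0] - u_bot) / (0.5 * self.dy)
            tau[1:-1] = self.mu_eff * np.diff(self.u) / self.dy
            tau[-1] = self.mu_eff * (v_s - self.u[-1]) / (0.5 * self.dy)

            self.u += dt * (tau[1:] - tau[:-1]) / (self.rho * self.dy)
            f_tether = -self.k_t * (self.D_b - d_s) - self.c_t * (self.U_b - v_s)
            f_bv = -self.k_bv * (self.D_b - d_s)
            if self.bottom == "block":
                self.U_b += dt * (tau[0] + f_tether + f_bv) / self.M_b
                self.D_b += dt * self.U_b
                impulse += dt * (tau[-1] + f_tether + f_bv)
            else:
                impulse += dt * (tau[-1] - tau[0])
            t += dt

            if not np.all(np.isfinite(self.u)):
                raise RuntimeError("instability: non-finite shear velocities")

            if step % self.record_stride == 0 or step == total - 1:
                rec_t.append(t)
                rec["relative_displacement"].append(d_s - self.D_b)
                rec["wall_shear"].append(tau[-1])
                rec["csf_shear"].append(float(np.max(np.abs(tau))))
                rec["skull_displacement"].append(d_s)
                rec["brain_displacement"].append(self.D_b)
                mom = self.rho * self.dy * float(self.u.sum()) + (
                    self.M_b * self.U_b if self.bottom == "block" else 0.0)
                mom_ledger.append({"t": t, "momentum": mom, "impulse": impulse})

        times = np.asarray(rec_t)
        grid = np.linspace(times[0], times[-1], times.size)
        signals = {
            k: SignalCurve(grid, np.interp(grid, times, np.asarray(v)), k)
            for k, v in rec.items()
        }
        peaks = {
            "relative_displacement": float(np.max(np.abs(rec["relative_displacement"]))),
            "csf_shear": float(np.max(rec["csf_shear"])),
            "wall_shear": float(rec["wall_shear"][-1]),
        }
        ledger = {"dt": dt, "n_steps": total, "effective_viscosity": self.mu_eff,
                  "rows": mom_ledger}
        return SimulationResult("shear_gap", self.mode, signals, peaks, ledger,
                                self.config)


# ----------------------------------------------------------------------

def run_simulation(config: dict) -> SimulationResult:
    """Run the experiment selected by ``config`` and return its result.

    Deterministic for a fixed config: the solvers contain no randomness
    (the seed only affects synthetic perturbation fixtures elsewhere).
    """
    cfg = merge_config(DEFAULT_CONFIG, config)
    exp = cfg["experiment"]
    if exp == "radial_column":
        result = RadialColumnSim(cfg).run()
    elif exp == "shear_gap":
        result = ShearGapSim(cfg).run()
    else:
        raise ValueError(f"unknown experiment {exp!r}")
    if cfg.get("output_dir"):
        result.write_outputs(cfg["output_dir"])
    return result
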