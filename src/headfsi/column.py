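"""One-dimensional multi-material ALE hydrocode for the brain-skull column.

The radial physics of the head (coup/contrecoup pressures, brain-skull
normal coupling) is exercised on a canonical surrogate: a rigid skull wall,
a CSF gap, a deformable brain rod, a second CSF gap and the opposite skull
wall, all along one axis. Each CSF gap is a :class:`FluidColumn` — a
staggered-grid explicit solver advanced by the classic two-phase operator
split:

1. **Lagrangian phase** — the mesh follows the material exactly; cell
   pressures come from the equation of state (Mie-Gruneisen in FSI mode,
   elastic-fluid rate law in sliding mode), deviatoric stresses from the
   mode's viscosity law, plus standard linear+quadratic artificial bulk
   viscosity; nodal velocities and positions advance by central differences.
2. **Advection phase** — node positions are pulled back to the reference
   mesh (which rides rigidly with the prescribed skull motion, optionally
   relaxed by mass-weighted neighbour smoothing) and cell contents (fluid
   volume, mass, internal energy, nodal momentum on the dual grid) are
   remapped conservatively with the donor-cell or van Leer scheme.

Cells carry two materials, CSF and void: void cells have no mass, no
pressure, and exist so the fluid surface can migrate into initially empty
regions. The brain rod is a Lagrangian linear viscoelastic (Kelvin-Voigt)
solid. Fluid and structure exchange equal-and-opposite penalty forces
proportional to the detected penetration of the brain end node into the
fluid-occupied region; FSI mode transmits both tension and compression
across the interface, sliding mode compression only (free separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .advection import advect_donor_cell, advect_van_leer
from .materials import (
    ElasticFluidParams,
    MieGruneisenParams,
    ViscousParams,
    bulk_sound_speed,
    gruneisen_pressure,
)

__all__ = [
    "AleMesh",
    "CellState",
    "StructureState",
    "CouplingConfig",
    "FluidColumn",
    "BrainRod",
    "stable_timestep",
    "penalty_force",
]

_MASS_TOL = 1e-12


def _repair_negative(arr: np.ndarray) -> np.ndarray:
    """Zero tiny negative remap undershoots, conservatively.

    The deficit is removed proportionally from the positive cells so the
    column total is exactly preserved (mass conservation is a hard
    invariant of the remap).
    """
    if not np.any(arr < 0):
        return arr
    arr = arr.copy()
    deficit = -arr[arr < 0].sum()
    arr[arr < 0] = 0.0
    pos = arr.sum()
    if pos > 0:
        arr *= (pos - deficit) / pos
    return arr


@dataclass
class AleMesh:
    """Node positions, reference offsets and mesh velocity of one column."""

    node_positions: np.ndarray
    reference_offsets: np.ndarray
    mesh_velocity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.node_positions) <= 0):
            raise ValueError("mesh tangled: node positions must be increasing")


@dataclass
class CellState:
    """Per-cell multi-material state ({csf, void}; void is massless)."""

    fluid_mass: np.ndarray
    fluid_volume: np.ndarray
    internal_energy: np.ndarray
    cell_volume: np.ndarray

    @property
    def volume_fraction(self) -> np.ndarray:
        return self.fluid_volume / self.cell_volume


@dataclass
class StructureState:
    """Brain-surrogate rod state (Kelvin-Voigt linear viscoelastic)."""

    node_positions: np.ndarray
    node_velocities: np.ndarray
    modulus: float
    viscosity: float
    density: float


@dataclass(frozen=True)
class CouplingConfig:
    """Penalty fluid-structure coupling.

    ``contact_mode`` is ``fsi_tension_compression`` (coupled interface:
    restoring force for both penetration and gap opening) or
    ``sliding_normal_only`` (compression-only, free separation).
    """

    penalty_factor: float = 0.1
    contact_mode: str = "fsi_tension_compression"

    def __post_init__(self) -> None:
        if self.penalty_factor <= 0:
            raise ValueError("penalty_factor must be positive")
        if self.contact_mode not in ("fsi_tension_compression", "sliding_normal_only"):
            raise ValueError(f"unknown contact_mode {self.contact_mode!r}")


def penalty_force(depth: float, stiffness: float, config: CouplingConfig) -> float:
    """Coupling force magnitude for a penetration ``depth`` (m, signed).

    Positive depth = structure overlaps fluid; the returned force is the one
    applied to the structure (pushing it out of the fluid); the fluid
    receives the opposite. In sliding mode a negative depth (gap) produces
    no force.
    """
    if config.contact_mode == "sliding_normal_only" and depth <= 0.0:
        return 0.0
    return stiffness * depth


def stable_timestep(cell_widths, fluid_mask, material, cfl: float,
                    density: float | None = None) -> float:
    """Explicit timestep: ``cfl * min(width / c)`` over fluid-bearing cells.

    For the elastic-fluid (sliding) material the tensor-viscosity diffusion
    limit ``width / (2 * VC * a)`` is also applied, which is the binding
    constraint at small ``VC``-damped cells. Void cells are excluded.
    """
    if not 0 < cfl <= 1:
        raise ValueError("cfl must lie in (0, 1]")
    w = np.asarray(cell_widths, float)[np.asarray(fluid_mask, bool)]
    if w.size == 0:
        raise ValueError("empty fluid domain: no cells to set the timestep")
    if isinstance(material, MieGruneisenParams):
        c = material.C
        dt = np.min(w) / c
    elif isinstance(material, ElasticFluidParams):
        rho = density if density is not None else material.rho
        c = bulk_sound_speed(material.K, rho)
        dt = min(np.min(w) / c, np.min(w) / (2.0 * material.VC * c))
    else:
        raise TypeError(f"unsupported material {type(material).__name__}")
    return cfl * float(dt)


class FluidColumn:
    """One CSF gap: wall (prescribed skull) at the left, brain side at the right.

    The orchestrator mirrors coordinates for the right-hand gap so that this
    class never needs to know its orientation.

    Parameters
    ----------
    widths :
        Initial cell widths (m), wall side first.
    fluid_filled :
        Boolean per cell; unfilled cells are void.
    mode :
        ``"fsi"`` (Mie-Gruneisen EOS + Newtonian viscosity, ALE remap) or
        ``"sliding"`` (elastic-fluid law + tensor viscosity, Lagrangian).
    """

    def __init__(
        self,
        widths,
        fluid_filled,
        mode: str = "fsi",
        eos: MieGruneisenParams | None = None,
        viscous: ViscousParams | None = None,
        elastic: ElasticFluidParams | None = None,
        scheme: str = "van_leer",
        bulk_q: tuple[float, float] = (0.06, 1.5),
        mesh_relaxation: float = 1.0,
        energy_term: bool = True,
    ) -> None:
        widths = np.asarray(widths, float)
        filled = np.asarray(fluid_filled, bool)
        if widths.size != filled.size:
            raise ValueError("widths and fluid_filled must have equal length")
        if mode not in ("fsi", "sliding"):
            raise ValueError(f"unknown mode {mode!r}")
        if scheme not in ("van_leer", "donor_cell"):
            raise ValueError(f"unknown advection scheme {scheme!r}")
        self.mode = mode
        self.eos = eos or MieGruneisenParams()
        self.viscous = viscous or ViscousParams()
        self.elastic = elastic or ElasticFluidParams()
        self.scheme = scheme
        self.c_lin, self.c_quad = bulk_q
        self.mesh_relaxation = mesh_relaxation
        self.energy_term = energy_term

        n = widths.size
        self.n_cells = n
        x = np.concatenate(([0.0], np.cumsum(widths)))
        self.ref_offsets = x.copy()
        self.x = x.copy()
        self.u = np.zeros(n + 1)
        rho0 = self.rho0
        self.vf = np.where(filled, widths, 0.0)
        self.m_f = rho0 * self.vf
        self.E_f = np.zeros(n)
        self.P_state = np.zeros(n)  # integrated pressure, sliding mode only
        self.wall_disp = 0.0
        self.wall_vel = 0.0
        self.boundary_impulse = 0.0
        self.h_ref = float(np.min(widths[filled])) if filled.any() else float(np.min(widths))
        # small-cell stabilization: inertia floor for surface nodes
        self.node_mass_floor = 0.1 * rho0 * self.h_ref
        self.last_pressures = np.zeros(n)
        self.last_shear = np.zeros(n)

    # ------------------------------------------------------------------
    @property
    def rho0(self) -> float:
        return self.eos.rho0 if self.mode == "fsi" else self.elastic.rho

    @property
    def sound_speed0(self) -> float:
        if self.mode == "fsi":
            return self.eos.C
        return bulk_sound_speed(self.elastic.K, self.elastic.rho)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.x)

    @property
    def frac(self) -> np.ndarray:
        return self.vf / self.widths

    @property
    def total_fluid_mass(self) -> float:
        return float(self.m_f.sum())

    @property
    def total_momentum(self) -> float:
        return float(np.sum(self._node_masses() * self.u))

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self._node_masses() * self.u**2))

    @property
    def internal_energy(self) -> float:
        return float(self.E_f.sum())

    def surface_position(self) -> float:
        """Void/fluid interface: wall position plus total fluid thickness."""
        return float(self.x[0] + self.vf.sum())

    def surface_node(self) -> int:
        """Index of the last node with meaningful adjacent fluid mass."""
        idx = np.nonzero(self.m_f > 1e-6 * self.rho0 * self.h_ref)[0]
        return int(idx[-1] + 1) if idx.size else 0

    def penalty_stiffness(self, factor: float) -> float:
        """k = factor * K_bulk * A / dL with unit face area."""
        k_bulk = self.elastic.K if self.mode == "sliding" else self.eos.rho0 * self.eos.C**2
        return factor * k_bulk / self.h_ref

    def stable_dt(self, cfl: float) -> float:
        mask = self.m_f > _MASS_TOL
        mat = self.eos if self.mode == "fsi" else self.elastic
        return stable_timestep(self.widths, mask, mat, cfl)

    def _stress_mask(self) -> np.ndarray:
        """Cells that carry fluid stress.

        Thin partial slabs at the fluid surface (tiny mass, volume or
        fraction) are treated as a pressure-free free surface: their density
        estimate ``m_f / vf`` is dominated by remap round-off and the
        physical load path runs through the full cells and the penalty
        coupling. Their mass and energy still advect and conserve.
        """
        m_small = 1e-6 * self.rho0 * self.h_ref
        v_small = 1e-6 * self.h_ref
        return (self.m_f > m_small) & (self.vf > v_small) & (self.frac > 0.05)

    def _node_masses(self) -> np.ndarray:
        mn = np.zeros(self.x.size)
        mn[:-1] += 0.5 * self.m_f
        mn[1:] += 0.5 * self.m_f
        return mn

    # ------------------------------------------------------------------
    def _fluid_stress(self, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell fluid pressure (incl. q), shear stress, strain rate."""
        h = self.widths
        eps_rate = (self.u[1:] - self.u[:-1]) / h
        mask = self._stress_mask()
        rho_f = np.where(mask, self.m_f / np.maximum(self.vf, 1e-300), self.rho0)
        p = np.zeros(self.n_cells)
        if self.mode == "fsi":
            mu = rho_f / self.eos.rho0 - 1.0
            e_ref = np.where(mask, self.E_f * self.eos.rho0 / np.maximum(self.m_f, _MASS_TOL), 0.0)
            p = np.where(mask,
                         gruneisen_pressure(self.eos, mu, e_ref,
                                            energy_term=self.energy_term),
                         0.0)
        else:
            self.P_state = self.P_state - dt * self.elastic.K * eps_rate
            p = np.where(mask, self.P_state, 0.0)
        # artificial bulk viscosity on compression
        du = self.u[1:] - self.u[:-1]
        q = np.where(
            mask & (du < 0),
            self.c_quad * rho_f * du**2 + self.c_lin * rho_f * self.sound_speed0 * np.abs(du),
            0.0,
        )
        # deviatoric stress at uniaxial strain: eps_dot'_xx = (2/3) eps_dot
        dev_rate = (2.0 / 3.0) * eps_rate
        if self.mode == "fsi":
            shear = self.viscous.gamma * dev_rate
        else:
            a = bulk_sound_speed(self.elastic.K, self.elastic.rho)
            shear = self.elastic.VC * h * a * rho_f * dev_rate
        shear = np.where(mask, shear, 0.0)
        self.last_pressures = np.where(mask, p, 0.0)
        self.last_shear = shear
        return p + q, shear, eps_rate

    def lagrangian_step(self, dt: float, surface_force: float = 0.0) -> None:
        """Advance one Lagrangian phase (mesh follows material).

        ``surface_force`` is the fluid-side penalty coupling force, applied
        at the surface node.
        """
        pq, shear, eps_rate = self._fluid_stress(dt)
        mask = self._stress_mask()
        sigma_f = -pq + shear
        sigma = np.where(mask, self.frac * sigma_f, 0.0)

        f = np.zeros(self.x.size)
        f[1:-1] = sigma[1:] - sigma[:-1]
        f[-1] = -sigma[-1]
        f[self.surface_node()] += surface_force

        mn = self._node_masses()
        dynamic = mn > self.node_mass_floor * 0.01
        dynamic[0] = False  # wall node prescribed
        inertia = np.maximum(mn, self.node_mass_floor)
        u_old = self.u.copy()
        self.u = np.where(dynamic, self.u + dt * f / inertia, self.u)
        self.u[~dynamic] = self.wall_vel
        self.u[0] = self.wall_vel
        # external-impulse ledger: wall traction, coupling force, and the
        # impulse absorbed by prescribed (slaved) nodes
        slaved = ~dynamic
        self.boundary_impulse += (
            dt * (-sigma[0]) + dt * surface_force
            + float(np.sum(mn[slaved] * (self.u[slaved] - u_old[slaved]) - dt * f[slaved]))
        )

        new_x = self.x + dt * self.u
        if np.any(np.diff(new_x) <= 0):
            raise RuntimeError("mesh tangled during Lagrangian phase")
        # energy: stress power on the fluid portion of each cell
        self.E_f = np.where(mask, self.E_f + dt * sigma_f * eps_rate * self.vf, self.E_f)
        self.vf = self.frac * np.diff(new_x)
        self.x = new_x

    # ------------------------------------------------------------------
    def _advect(self, content, tv, vol):
        fn = advect_van_leer if self.scheme == "van_leer" else advect_donor_cell
        return fn(content, tv, vol)

    def remap_to_reference(self) -> np.ndarray:
        """Advection phase: pull the mesh back to the reference and remap.

        The target mesh is the reference grid riding with the prescribed
        wall motion, optionally blended (``mesh_relaxation`` < 1) with a
        mass-weighted neighbour smoothing of the Lagrangian positions.
        Returns the per-face transport volumes.
        """
        if self.mode == "sliding":
            return np.zeros(self.x.size)  # Lagrangian: no remap
        # reference grid anchored at the current wall node, so the boundary
        # faces are exactly closed (zero transport volume)
        x_ref = self.ref_offsets + self.x[0]
        if self._node_masses()[-1] > self.node_mass_floor * 0.01:
            # far end is a free fluid surface: the end node tracks the
            # material so no content fluxes through the boundary face
            x_ref = x_ref.copy()
            x_ref[-1] = self.x[-1]
        target = x_ref
        if self.mesh_relaxation < 1.0:
            sm = self.x.copy()
            w = self._node_masses() + self.node_mass_floor
            sm[1:-1] = (
                w[:-2] * self.x[:-2] + w[1:-1] * self.x[1:-1] + w[2:] * self.x[2:]
            ) / (w[:-2] + w[1:-1] + w[2:])
            target = self.mesh_relaxation * x_ref + (1 - self.mesh_relaxation) * sm
            target[0], target[-1] = x_ref[0], x_ref[-1]
        if np.any(np.diff(target) <= 0):
            raise RuntimeError("target mesh tangled during remap")

        tv = self.x - target
        vol_old = self.widths
        mn_old = self._node_masses()
        p_node = mn_old * self.u

        self.vf = _repair_negative(self._advect(self.vf, tv, vol_old))
        self.m_f = _repair_negative(self._advect(self.m_f, tv, vol_old))
        self.E_f = self._advect(self.E_f, tv, vol_old)
        self.E_f[self.m_f <= _MASS_TOL] = 0.0

        # staggered momentum remap on the dual grid
        centers = 0.5 * (self.x[:-1] + self.x[1:])
        dual_edges = np.concatenate(([self.x[0]], centers, [self.x[-1]]))
        dual_vol = np.diff(dual_edges)
        dual_tv = np.empty(self.x.size + 1)
        dual_tv[0] = tv[0]
        dual_tv[-1] = tv[-1]
        dual_tv[1:-1] = 0.5 * (tv[:-1] + tv[1:])
        cap = np.minimum(np.abs(dual_tv[1:-1]), 0.999 * np.minimum(dual_vol[:-1], dual_vol[1:]))
        dual_tv[1:-1] = np.sign(dual_tv[1:-1]) * cap
        p_new = self._advect(p_node, dual_tv, dual_vol)

        self.x = target
        self.vf = np.minimum(self.vf, self.widths)
        mn_new = self._node_masses()
        dynamic = mn_new > self.node_mass_floor * 0.01
        dynamic[0] = False
        self.u = np.where(dynamic, p_new / np.maximum(mn_new, self.node_mass_floor),
                          self.wall_vel)
        # momentum absorbed by prescribed nodes / the surface inertia floor
        self.boundary_impulse += float(np.sum(mn_new * self.u - p_new))
        return tv

    # ------------------------------------------------------------------
    def set_wall(self, disp: float, vel: float) -> None:
        self.wall_disp = disp
        self.wall_vel = vel

    def step(self, dt: float, surface_force: float = 0.0) -> None:
        """One full operator-split cycle."""
        self.lagrangian_step(dt, surface_force)
        self.remap_to_reference()

    def mesh(self) -> AleMesh:
        return AleMesh(self.x.copy(), self.ref_offsets.copy(), self.u.copy())

    def cell_state(self) -> CellState:
        return CellState(self.m_f.copy(), self.vf.copy(), self.E_f.copy(),
                         self.widths.copy())


class BrainRod:
    """Lagrangian brain surrogate: a lumped-mass Kelvin-Voigt rod."""

    def __init__(self, length: float, n_elements: int, modulus: float,
                 viscosity: float, density: float, x0: float = 0.0) -> None:
        if length <= 0 or n_elements < 1:
            raise ValueError("rod needs positive length and at least one element")
        self.h0 = length / n_elements
        self.x = x0 + self.h0 * np.arange(n_elements + 1)
        self.u = np.zeros(n_elements + 1)
        self.modulus = modulus
        self.viscosity = viscosity
        self.density = density
        m = density * self.h0
        self.mass = np.full(n_elements + 1, m)
        self.mass[0] = self.mass[-1] = 0.5 * m

    @property
    def momentum(self) -> float:
        return float(np.sum(self.mass * self.u))

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.mass * self.u**2))

    def stable_dt(self, cfl: float) -> float:
        c = np.sqrt(self.modulus / self.density)
        dt_a = self.h0 / c if c > 0 else np.inf
        dt_v = (self.density * self.h0**2 / (2 * self.viscosity)
                if self.viscosity > 0 else np.inf)
        return cfl * min(dt_a, dt_v)

    def step(self, dt: float, force_left: float = 0.0, force_right: float = 0.0) -> None:
        h = np.diff(self.x)
        if np.any(h <= 0):
            raise RuntimeError("brain rod element inverted")
        strain = h / self.h0 - 1.0
        rate = (self.u[1:] - self.u[:-1]) / self.h0
        sigma = self.modulus * strain + self.viscosity * rate
        f = np.zeros(self.x.size)
        f[1:-1] = sigma[1:] - sigma[:-1]
        f[0] = sigma[0] + force_left
        f[-1] = -sigma[-1] + force_right
        self.u += dt * f / self.mass
        self.x += dt * self.u

    def state(self) -> StructureState:
        return StructureState(self.x.copy(), self.u.copy(), self.modulus,
                              self.viscosity, self.density)
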