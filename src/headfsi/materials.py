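"""CSF material models for the two brain-skull interface treatments.

Two parameterizations of the cerebrospinal fluid are provided:

* **Elastic fluid** (the Lagrangian "sliding" treatment): pressure rate
  proportional to the dilatational strain rate, ``dP/dt = -K * tr(eps_dot)``,
  with a *tensor viscosity* deviatoric stress
  ``sigma_v = VC * dL * a * rho * eps_dot'`` whose coefficient ``VC`` is a
  numerical damping device, not a physical viscosity.

* **Mie-Gruneisen fluid** (the ALE/FSI treatment): shock-physics equation of
  state with the standard water constants, a Newtonian deviatoric stress
  ``sigma_v = gamma * eps_dot'`` at the true dynamic viscosity of water, and
  a tensile cut-off pressure standing in for cavitation limiting.

The contrast between the two deviatoric laws (several orders of magnitude in
effective viscosity at head-impact element sizes) is the mechanistic root of
the different brain-skull relative motion the two treatments predict.
All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "ElasticFluidParams",
    "MieGruneisenParams",
    "ViscousParams",
    "elastic_fluid_pressure_rate",
    "bulk_sound_speed",
    "elastic_fluid_deviatoric",
    "compression_mu",
    "gruneisen_pressure",
    "newtonian_deviatoric",
    "effective_viscosity_ratio",
]


@dataclass(frozen=True)
class ElasticFluidParams:
    """Elastic-fluid CSF (sliding treatment).

    ``K`` bulk modulus [Pa], ``VC`` tensor viscosity coefficient
    (recommended band 0.1-0.5), ``rho`` density [kg/m^3], ``delta_L``
    characteristic element length [m] (cube root of element volume for
    non-cubic elements).
    """

    K: float = 2.19e9
    VC: float = 0.3
    rho: float = 1000.0
    delta_L: float = 1.5e-3

    def __post_init__(self) -> None:
        if self.K <= 0 or self.rho <= 0 or self.delta_L <= 0:
            raise ValueError("K, rho and delta_L must be positive")
        if not 0.1 <= self.VC <= 0.5:
            warnings.warn(
                f"VC={self.VC} outside the recommended 0.1-0.5 band",
                stacklevel=2,
            )

    @property
    def sound_speed(self) -> float:
        return bulk_sound_speed(self.K, self.rho)


@dataclass(frozen=True)
class MieGruneisenParams:
    """Mie-Gruneisen EOS constants (defaults: water).

    ``C`` is the intercept of the shock-velocity/particle-velocity (vs-vp)
    curve [m/s]; ``S1..S3`` its slope coefficients; ``gamma0`` the Gruneisen
    gamma; ``a_vc`` the first-order volume correction to gamma0 (the EOS's
    own "a", distinct from the elastic fluid's sound speed); ``rho0`` the
    reference density [kg/m^3]; ``p_cut`` the tensile cut-off pressure [Pa],
    a hard floor standing in for cavitation.
    """

    C: float = 1482.9
    S1: float = 2.1057
    S2: float = -0.1744
    S3: float = 0.010085
    gamma0: float = 1.2
    a_vc: float = 0.0
    rho0: float = 1000.0
    p_cut: float = -22e6

    def __post_init__(self) -> None:
        if self.C <= 0 or self.rho0 <= 0:
            raise ValueError("C and rho0 must be positive")
        if self.p_cut > 0:
            raise ValueError("p_cut is a tensile limit and must be <= 0")


@dataclass(frozen=True)
class ViscousParams:
    """Newtonian deviatoric response: dynamic viscosity ``gamma`` [Pa s]."""

    gamma: float = 0.001

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("dynamic viscosity must be non-negative")


# ----------------------------------------------------------------------

def elastic_fluid_pressure_rate(params: ElasticFluidParams, vol_strain_rate) -> float:
    """Pressure rate ``-K * tr(eps_dot)`` [Pa/s]; compression raises pressure."""
    return -params.K * np.asarray(vol_strain_rate, float)


def bulk_sound_speed(K: float, rho: float) -> float:
    """Fluid bulk sound speed ``sqrt(K/rho)`` [m/s]."""
    if K <= 0 or rho <= 0:
        raise ValueError("bulk sound speed requires K > 0 and rho > 0")
    return float(np.sqrt(K / rho))


def _require_tracefree(tensor: np.ndarray) -> np.ndarray:
    t = np.asarray(tensor, float)
    if t.ndim == 2:
        tr = abs(np.trace(t))
        scale = np.max(np.abs(t)) if t.size else 0.0
        if scale > 0 and tr > 1e-9 * scale:
            raise ValueError("deviatoric strain rate must be trace-free")
    return t


def elastic_fluid_deviatoric(params: ElasticFluidParams, dev_strain_rate) -> np.ndarray:
    """Tensor-viscosity stress ``VC * dL * a * rho * eps_dot'`` [Pa]."""
    e = _require_tracefree(dev_strain_rate)
    coeff = params.VC * params.delta_L * params.sound_speed * params.rho
    return coeff * e


def compression_mu(rho: float, rho0: float) -> float:
    """Compression measure ``mu = rho/rho0 - 1`` (negative in expansion)."""
    if rho <= 0 or rho0 <= 0:
        raise ValueError("densities must be positive")
    return rho / rho0 - 1.0


def gruneisen_pressure(
    params: MieGruneisenParams,
    mu: float,
    internal_energy_density: float = 0.0,
    energy_term: bool = True,
    apply_cutoff: bool = True,
) -> float:
    """Mie-Gruneisen pressure [Pa] at compression ``mu``.

    The Hugoniot-referenced polynomial-in-``mu`` pressure, plus (by default)
    the standard internal-energy term ``(gamma0 + a_vc*mu) * E`` with ``E``
    the internal energy per unit *reference* volume [Pa]; with ``E = 0`` or
    ``energy_term=False`` the bare cold-curve expression is recovered. The
    result is floored at the tensile cut-off ``p_cut``.

    Accepts scalars or arrays (element-wise).

    Raises
    ------
    ValueError
        If the denominator of the Hugoniot term is non-positive (compression
        beyond the EOS's admissible range).
    """
    c, s1, s2, s3 = params.C, params.S1, params.S2, params.S3
    g0, a = params.gamma0, params.a_vc
    mu = np.asarray(mu, float)
    e = np.asarray(internal_energy_density, float)
    num = params.rho0 * c * c * mu * (1.0 + (1.0 - g0 / 2.0) * mu - (a / 2.0) * mu * mu)
    den = 1.0 - (s1 - 1.0) * mu - s2 * mu * mu / (mu + 1.0) - s3 * mu**3 / (mu + 1.0) ** 2
    if np.any(den <= 0.0):
        raise ValueError("EOS compression out of range (denominator <= 0)")
    p = num / den
    if energy_term:
        p = p + (g0 + a * mu) * e
    if apply_cutoff:
        p = np.maximum(p, params.p_cut)
    return float(p) if p.ndim == 0 else p


def newtonian_deviatoric(params: ViscousParams, dev_strain_rate) -> np.ndarray:
    """Newtonian stress ``gamma * eps_dot'`` [Pa]."""
    e = _require_tracefree(dev_strain_rate)
    return params.gamma * e


def effective_viscosity_ratio(ef: ElasticFluidParams, vp: ViscousParams) -> float:
    """Ratio of the two deviatoric laws' effective viscosities.

    ``(VC * dL * a * rho) / gamma`` — how much stiffer in shear the
    sliding-treatment CSF is than the Newtonian FSI fluid at equal deviatoric
    strain rate. At head-model element sizes (millimetres) this exceeds 1e5,
    which is the mechanism behind the orders-of-magnitude CSF shear stress
    contrast between the two treatments.
    """
    if vp.gamma <= 0:
        raise ValueError("ratio undefined for zero dynamic viscosity")
    return ef.VC * ef.delta_L * ef.sound_speed * ef.rho / vp.gamma
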