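"""Reduced units and physical constants.

The simulation works in reduced units: energy in kT, length in nm, time in
units of 0.1 ns.  Temperature is fixed at 310 K and the cellular viscosity
at 5 cP; these are the unique choices under which the tabulated diffusion
coefficients (50 um^2/s for a 0.9 nm FG bead, 10.0/6.1/4.5 um^2/s for
9/15/20 nm cargos) follow from the Stokes-Einstein relation.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Default absolute temperature, K.
T_DEFAULT = 310.0

#: Thermal energy at the default temperature, J.
KT_J = KB * T_DEFAULT

#: Default cellular viscosity, cP (1 cP = 1e-3 Pa s).
VISCOSITY_CP = 5.0

#: Average protein density, g/cm^3.
PROTEIN_DENSITY = 1.35

#: Reduced time unit, seconds (0.1 ns).
TIME_UNIT_S = 1.0e-10

#: Reduced time unit, ns.
TIME_UNIT_NS = 0.1


def kT_joules(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kT in joules."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB * temperature


def stokes_drag(radius_nm: float, viscosity_cp: float = VISCOSITY_CP) -> float:
    """Stokes drag coefficient zeta = 6*pi*eta*R for a sphere, in kg/s.

    Parameters are the hydrodynamic radius in nm and the solvent viscosity
    in cP.
    """
    if radius_nm <= 0 or viscosity_cp <= 0:
        raise ValueError("radius and viscosity must be positive")
    return 6.0 * math.pi * viscosity_cp * 1e-3 * radius_nm * 1e-9


def diffusion_from_drag(drag_kg_s: float, temperature: float = T_DEFAULT) -> float:
    """Einstein relation D = kT/zeta, returned in um^2/s."""
    if drag_kg_s <= 0:
        raise ValueError("drag must be positive")
    return kT_joules(temperature) / drag_kg_s * 1e12  # m^2/s -> um^2/s


def diffusion_coefficient(
    radius_nm: float,
    viscosity_cp: float = VISCOSITY_CP,
    temperature: float = T_DEFAULT,
) -> float:
    """Stokes-Einstein diffusion coefficient in um^2/s."""
    return diffusion_from_drag(stokes_drag(radius_nm, viscosity_cp), temperature)


def diffusion_to_reduced(D_um2_s: float) -> float:
    """Convert a diffusion coefficient from um^2/s to nm^2 per reduced time.

    1 um^2/s = 1e6 nm^2/s = 1e-4 nm^2 / (0.1 ns).
    """
    return D_um2_s * 1e-4


def reduced_time_to_ms(t_reduced: float) -> float:
    """Convert reduced time (units of 0.1 ns) to milliseconds."""
    return t_reduced * TIME_UNIT_S * 1e3


def ms_to_reduced_time(t_ms: float) -> float:
    """Convert milliseconds to reduced time units (0.1 ns)."""
    return t_ms * 1e-3 / TIME_UNIT_S
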