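"""Equivalent-circuit model of the microfluidic tumor-treating-field device.

The device is a stack of five parallel compartments between two electrodes:

    electrode | PDMS wall | media channel | gel region | media channel | PDMS wall | electrode

Electrically this is a single series loop driven by the frequency
generator.  Electrodes, media and the collagen gel are ohmic slabs; each
PDMS wall is a resistor in parallel with a capacitor (the wall is a near
perfect insulator at DC and couples the signal capacitively at the
100-200 kHz operating frequencies).  Solving the complex voltage divider
gives the transfer ratio V_gel / V_in, from which the field in the gel
(in V/cm) and the generator voltage required for a target field follow
by linearity.

All lengths are SI metres internally; :mod:`ttfield.config` converts the
micrometre/kilohertz units used in configuration files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.constants import epsilon_0

__all__ = [
    "MaterialSet",
    "DeviceGeometry",
    "CircuitElement",
    "CircuitNetwork",
    "FieldSolution",
    "resistance_of_slab",
    "capacitance_of_slab",
    "rc_parallel_impedance",
    "build_network",
    "transfer_ratio",
    "resistive_divider_limit",
    "gel_field",
    "required_input_voltage",
    "frequency_sweep",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSet:
    """Bulk electrical properties of the device compartments.

    Resistivities are in Ω·m.  Defaults are the published values for a
    silver-PDMS composite electrode, cell-culture media, collagen gel
    and bulk PDMS.  ``epsr_pdms`` is the relative permittivity of the
    PDMS wall used for its parallel-plate capacitance; 2.75 is a typical
    literature value for cured PDMS.
    """

    rho_electrode: float = 1.67e-5
    rho_media: float = 0.67
    rho_gel: float = 800.0
    rho_pdms: float = 1.2e12
    epsr_pdms: float = 2.75

    def __post_init__(self) -> None:
        for name in ("rho_electrode", "rho_media", "rho_gel", "rho_pdms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsr_pdms < 1:
            raise ValueError("epsr_pdms must be >= 1")


@dataclass(frozen=True)
class DeviceGeometry:
    """Compartment dimensions, in metres.

    Widths are the conduction lengths across each compartment (the
    direction of current flow, perpendicular to the channels);
    ``channel_height`` is the SU-8 layer thickness and ``region_length``
    the extent of the parallel-channel region along the device.  The
    conduction cross-section of every compartment is
    ``channel_height * region_length``, so the transfer ratio is
    invariant to ``region_length`` (every impedance scales identically).
    """

    channel_height: float = 120e-6
    gel_width: float = 1300e-6
    media_width: float = 500e-6
    wall_width: float = 150e-6
    electrode_width: float = 500e-6
    region_length: float = 10e-3

    def __post_init__(self) -> None:
        for name in (
            "channel_height",
            "gel_width",
            "media_width",
            "wall_width",
            "electrode_width",
            "region_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cross_section(self) -> float:
        """Conduction cross-section (m²), shared by all compartments."""
        return self.channel_height * self.region_length


@dataclass(frozen=True)
class CircuitElement:
    """One series element: a resistor or an RC-parallel pair."""

    label: str
    kind: str  # "resistor" | "rc_parallel"
    R: float
    C: float = 0.0
    is_gel: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("resistor", "rc_parallel"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.C < 0:
            raise ValueError("C must be non-negative")

    def impedance(self, f: float) -> complex:
        """Complex impedance at frequency ``f`` (Hz)."""
        if self.kind == "resistor":
            return complex(self.R)
        return rc_parallel_impedance(self.R, self.C, f)


@dataclass(frozen=True)
class CircuitNetwork:
    """Ordered series chain of circuit elements with one gel element."""

    elements: tuple[CircuitElement, ...]

    def __post_init__(self) -> None:
        n_gel = sum(e.is_gel for e in self.elements)
        if n_gel != 1:
            raise ValueError(f"network must have exactly one gel element, got {n_gel}")

    @property
    def gel(self) -> CircuitElement:
        return next(e for e in self.elements if e.is_gel)

    def total_impedance(self, f: float) -> complex:
        return sum((e.impedance(f) for e in self.elements), complex(0.0))


@dataclass(frozen=True)
class FieldSolution:
    """Solved operating point of the divider at one frequency."""

    frequency: float  # Hz
    v_in: float  # volts, amplitude
    v_gel: complex  # volts
    transfer_ratio: complex  # dimensionless
    field: float  # V/cm


# --------------------------------------------------------------------------
# element-level physics
# --------------------------------------------------------------------------

def resistance_of_slab(rho: float, length: float, area: float) -> float:
    """Ohmic resistance R = ρ·L/A of a uniform slab.

    Parameters are the resistivity (Ω·m), conduction length (m) and
    cross-sectional area (m²); all must be positive.
    """
    if rho <= 0 or length <= 0 or area <= 0:
        raise ValueError("rho, length and area must all be positive")
    return rho * length / area


def capacitance_of_slab(epsr: float, area: float, thickness: float) -> float:
    """Parallel-plate capacitance C = ε₀·εr·A/d of a dielectric slab."""
    if epsr <= 0 or area <= 0 or thickness <= 0:
        raise ValueError("epsr, area and thickness must all be positive")
    return epsilon_0 * epsr * area / thickness


def rc_parallel_impedance(R: float, C: float, f: float) -> complex:
    """Impedance of a resistor R in parallel with a capacitor C at f Hz.

    Z = R / (1 + i·2πf·R·C).  With C = 0 (or f = 0) this reduces to R;
    as f → ∞ the capacitor shorts the pair and |Z| → 0.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if C < 0:
        raise ValueError("C must be non-negative")
    if f < 0:
        raise ValueError("f must be non-negative")
    return R / (1 + 1j * 2 * math.pi * f * R * C)


# --------------------------------------------------------------------------
# network construction and solution
# --------------------------------------------------------------------------

def build_network(geometry: DeviceGeometry, materials: MaterialSet) -> CircuitNetwork:
    """Compile geometry and materials into the 7-element series chain.

    Layout: R_e, Z_pdms, R_media, R_gel (tagged), R_media, Z_pdms, R_e.
    Every resistance uses the compartment width as conduction length and
    the shared ``height × region_length`` cross-section; each PDMS wall
    capacitance uses the wall width as plate separation.
    """
    area = geometry.cross_section
    r_e = resistance_of_slab(materials.rho_electrode, geometry.electrode_width, area)
    r_pdms = resistance_of_slab(materials.rho_pdms, geometry.wall_width, area)
    c_pdms = capacitance_of_slab(materials.epsr_pdms, area, geometry.wall_width)
    r_media = resistance_of_slab(materials.rho_media, geometry.media_width, area)
    r_gel = resistance_of_slab(materials.rho_gel, geometry.gel_width, area)

    return CircuitNetwork(
        elements=(
            CircuitElement("electrode", "resistor", r_e),
            CircuitElement("pdms_wall", "rc_parallel", r_pdms, c_pdms),
            CircuitElement("media", "resistor", r_media),
            CircuitElement("gel", "resistor", r_gel, is_gel=True),
            CircuitElement("media", "resistor", r_media),
            CircuitElement("pdms_wall", "rc_parallel", r_pdms, c_pdms),
            CircuitElement("electrode", "resistor", r_e),
        )
    )


def transfer_ratio(network: CircuitNetwork, f: float) -> complex:
    """Complex divider ratio V_gel / V_in = Z_gel / Σ Z_k at frequency f."""
    if f < 0:
        raise ValueError("f must be non-negative")
    return network.gel.impedance(f) / network.total_impedance(f)


def resistive_divider_limit(network: CircuitNetwork) -> float:
    """High-frequency limit of |transfer ratio|.

    As f → ∞ every capacitor shorts its RC pair, leaving the purely
    resistive divider over the resistor-only elements:
    R_gel / Σ R_k over elements with kind == "resistor".
    """
    r_total = sum(e.R for e in network.elements if e.kind == "resistor")
    return network.gel.R / r_total


def gel_field(v_in: float, network: CircuitNetwork, f: float, gel_width: float) -> float:
    """Field magnitude in the gel (V/cm) for input amplitude ``v_in`` volts."""
    if v_in <= 0:
        raise ValueError("v_in must be positive")
    v_gel = abs(v_in * transfer_ratio(network, f))
    return v_gel / (gel_width * 100.0)  # m → cm


def required_input_voltage(
    target_field: float, network: CircuitNetwork, f: float, gel_width: float
) -> float:
    """Generator amplitude (V) delivering ``target_field`` V/cm in the gel.

    The divider is linear, so the inverse is analytic:
    v_in = E_target · (100·gel_width) / |transfer ratio|.
    """
    if target_field <= 0:
        raise ValueError("target_field must be positive")
    ratio = abs(transfer_ratio(network, f))
    return target_field * gel_width * 100.0 / ratio


def frequency_sweep(
    network: CircuitNetwork,
    f_grid: Sequence[float],
    v_in: float,
    gel_width: float,
) -> list[FieldSolution]:
    """Solve the divider over a frequency grid at fixed input amplitude."""
    f_grid = list(f_grid)
    if not f_grid:
        raise ValueError("frequency grid must be non-empty")
    if any(f < 0 for f in f_grid):
        raise ValueError("frequencies must be non-negative")
    out = []
    for f in f_grid:
        ratio = transfer_ratio(network, f)
        v_gel = v_in * ratio
        out.append(
            FieldSolution(
                frequency=f,
                v_in=v_in,
                v_gel=v_gel,
                transfer_ratio=ratio,
                field=abs(v_gel) / (gel_width * 100.0),
            )
        )
    return out
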