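"""Configuration loading with unit conversion.

Config files are YAML (or JSON, a YAML subset) with blocks

    geometry:      # μm except region_length_mm
      channel_height_um: 120
      gel_width_um: 1300
      media_width_um: 500
      wall_width_um: 150
      electrode_width_um: 500
      region_length_mm: 10
    materials:     # Ω·m
      rho_electrode: 1.67e-5
      rho_media: 0.67
      rho_gel: 800
      rho_pdms: 1.2e12
      epsr_pdms: 2.75
    stimulation:
      frequency_khz: 200
      target_field_v_per_cm: 1.1   # or v_in_volts: ...
      rms: false                   # voltages are amplitudes unless true

Values are converted to SI on load.  Omitted keys fall back to the
defaults of :class:`~ttfield.device_model.DeviceGeometry` and
:class:`~ttfield.device_model.MaterialSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .device_model import DeviceGeometry, MaterialSet

__all__ = ["StimulationSettings", "load_device_config", "parse_device_config"]


@dataclass(frozen=True)
class StimulationSettings:
    frequency_hz: float
    target_field_v_per_cm: float | None = None
    v_in_volts: float | None = None
    rms: bool = False

    def __post_init__(self) -> None:
        if self.frequency_hz < 0:
            raise ValueError("frequency must be non-negative")
        if self.target_field_v_per_cm is None and self.v_in_volts is None:
            raise ValueError("stimulation needs target_field_v_per_cm or v_in_volts")

    @property
    def amplitude_scale(self) -> float:
        """Multiply RMS-specified voltages by √2 to get amplitudes."""
        return math.sqrt(2.0) if self.rms else 1.0


def parse_device_config(raw: dict) -> tuple[DeviceGeometry, MaterialSet, StimulationSettings]:
    geo_raw = raw.get("geometry", {})
    geometry = DeviceGeometry(
        channel_height=geo_raw.get("channel_height_um", 120.0) * 1e-6,
        gel_width=geo_raw.get("gel_width_um", 1300.0) * 1e-6,
        media_width=geo_raw.get("media_width_um", 500.0) * 1e-6,
        wall_width=geo_raw.get("wall_width_um", 150.0) * 1e-6,
        electrode_width=geo_raw.get("electrode_width_um", 500.0) * 1e-6,
        region_length=geo_raw.get("region_length_mm", 10.0) * 1e-3,
    )
    mat_raw = raw.get("materials", {})
    materials = MaterialSet(
        rho_electrode=mat_raw.get("rho_electrode", 1.67e-5),
        rho_media=mat_raw.get("rho_media", 0.67),
        rho_gel=mat_raw.get("rho_gel", 800.0),
        rho_pdms=mat_raw.get("rho_pdms", 1.2e12),
        epsr_pdms=mat_raw.get("epsr_pdms", 2.75),
    )
    stim_raw = raw.get("stimulation", {})
    target = stim_raw.get("target_field_v_per_cm")
    v_in = stim_raw.get("v_in_volts")
    if target is None and v_in is None:
        target = 1.1  # study operating point, V/cm
    stimulation = StimulationSettings(
        frequency_hz=stim_raw.get("frequency_khz", 200.0) * 1e3,
        target_field_v_per_cm=target,
        v_in_volts=v_in,
        rms=bool(stim_raw.get("rms", False)),
    )
    return geometry, materials, stimulation


def load_device_config(path: str | Path) -> tuple[DeviceGeometry, MaterialSet, StimulationSettings]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_device_config(raw)
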