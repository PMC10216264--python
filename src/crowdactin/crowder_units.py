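"""Concentration arithmetic for crowding agents.

Two conversion pairs:

* stock solutions: %w/w ↔ molarity, assuming a solution density
  (default 1.00 g/mL — under that assumption 15% w/w PEG 8000 is
  ~18.8 mM, 30% w/w BSA ~4.5 mM, and 40% w/w sucrose ~1.2 M);
* simulation boxes: molecule count ↔ millimolar concentration via
  ``c = n / (N_A · V)``.

A small table of molar masses for the crowders handled here is
included; the sucrose entry is the standard 342.30 g/mol, with the
389.52 g/mol parameterized-model variant available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import AVOGADRO

__all__ = [
    "CrowderSpec",
    "BoxConcentration",
    "CROWDER_MOLAR_MASSES",
    "percent_ww_to_molar",
    "molar_to_percent_ww",
    "count_to_concentration",
    "concentration_to_count",
    "box_volume_for",
    "format_concentration",
]

#: Molar masses in g/mol for the crowding agents used throughout.
CROWDER_MOLAR_MASSES: dict[str, float] = {
    "PEG8000": 8000.0,
    "BSA": 66540.3,
    "sucrose": 342.30,
    # Variants used in atomistic simulation models of the same crowders.
    "sucrose_md_model": 389.52,
    "PEG_md_model": 385.25,
}

#: nm³ → L
_NM3_TO_L = 1e-24


@dataclass
class CrowderSpec:
    """A crowding agent stock: %w/w at an assumed solution density."""

    name: str
    molar_mass: float
    percent_ww: float
    assumed_density: float = 1.0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not 0 <= self.percent_ww < 100:
            raise ValueError("percent_ww must lie in [0, 100)")
        if self.assumed_density <= 0:
            raise ValueError("assumed_density must be positive")

    @property
    def concentration_mM(self) -> float:
        return percent_ww_to_molar(self.percent_ww, self.molar_mass, self.assumed_density)


@dataclass
class BoxConcentration:
    """Molecule count in a simulation box and the implied molarity."""

    n_molecules: int
    box_volume: float  # nm³

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.box_volume <= 0:
            raise ValueError("box_volume must be positive")

    @property
    def concentration_mM(self) -> float:
        return count_to_concentration(self.n_molecules, self.box_volume)


def percent_ww_to_molar(
    percent_ww: float,
    molar_mass: float,
    density: float = 1.0,
) -> float:
    """%w/w → mM: ``(percent/100) · density · 10⁶ / molar_mass``.

    ``density`` is the solution density in g/mL; the mass fraction
    times density gives g solute per mL solution, hence per L, hence
    mol/L through the molar mass.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    if not 0 <= percent_ww < 100:
        raise ValueError("percent_ww must lie in [0, 100)")
    grams_per_liter = percent_ww / 100.0 * density * 1000.0
    return grams_per_liter / molar_mass * 1000.0


def molar_to_percent_ww(
    concentration_mM: float,
    molar_mass: float,
    density: float = 1.0,
) -> float:
    """Exact inverse of :func:`percent_ww_to_molar`."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_mM / 1000.0 * molar_mass / (density * 1000.0) * 100.0


def count_to_concentration(n_molecules: float, box_volume_nm3: float) -> float:
    """Molecule count in a box of given nm³ volume → mM."""
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    if n_molecules < 0:
        raise ValueError("molecule count must be non-negative")
    mol = n_molecules / AVOGADRO
    liters = box_volume_nm3 * _NM3_TO_L
    return mol / liters * 1000.0


def concentration_to_count(concentration_mM: float, box_volume_nm3: float) -> int:
    """mM in a box of given nm³ volume → nearest integer molecule count."""
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    if concentration_mM < 0:
        raise ValueError("concentration must be non-negative")
    exact = concentration_mM / 1000.0 * AVOGADRO * box_volume_nm3 * _NM3_TO_L
    return int(round(exact))


def box_volume_for(n_molecules: float, concentration_mM: float) -> float:
    """Box volume (nm³) holding ``n_molecules`` at ``concentration_mM``."""
    if n_molecules <= 0 or concentration_mM <= 0:
        raise ValueError("count and concentration must be positive")
    return n_molecules / (concentration_mM / 1000.0 * AVOGADRO * _NM3_TO_L)


def format_concentration(concentration_mM: float) -> str:
    """Report to 1 decimal place, switching to M at or above 1000 mM."""
    if concentration_mM >= 1000.0:
        return f"{concentration_mM / 1000.0:.1f} M"
    return f"{concentration_mM:.1f} mM"
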