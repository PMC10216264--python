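"""Physical constants and unit algebra shared across the package.

Internal conventions: molecular trajectories use Å and ns; imaging and
fluorescence use µm and s.  All conversions between those systems go
through this module so the factors live in exactly one place
(1 Å²/ns = 10 µm²/s = 10 nm²/µs).
"""

from __future__ import annotations

#: Coulomb constant in kcal·mol⁻¹·Å·e⁻² (biomolecular convention).
COULOMB_KCAL_MOL_ANG_E2 = 332.0636

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214e23

#: Multiply a diffusion coefficient in Å²/ns by this to get µm²/s.
ANG2_PER_NS_TO_UM2_PER_S = 10.0

# Diffusion-coefficient units, expressed as the factor to µm²/s.
_DIFFUSION_UNIT_TO_UM2_S = {
    "A2/ns": 10.0,
    "um2/s": 1.0,
    "nm2/us": 1.0,
}

# Accepted spellings (unicode and ASCII) for each canonical label.
_DIFFUSION_ALIASES = {
    "A2/ns": "A2/ns",
    "Å²/ns": "A2/ns",
    "A^2/ns": "A2/ns",
    "um2/s": "um2/s",
    "µm²/s": "um2/s",
    "um^2/s": "um2/s",
    "nm2/us": "nm2/us",
    "nm²/µs": "nm2/us",
    "nm^2/us": "nm2/us",
}


def convert_diffusion_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a diffusion coefficient between Å²/ns, µm²/s and nm²/µs.

    Exact unit algebra; round-tripping through any chain of units is the
    identity up to floating point.

    Raises
    ------
    ValueError
        If either unit label is not recognised.
    """
    try:
        src = _DIFFUSION_ALIASES[from_unit]
    except KeyError:
        raise ValueError(f"unknown diffusion unit {from_unit!r}") from None
    try:
        dst = _DIFFUSION_ALIASES[to_unit]
    except KeyError:
        raise ValueError(f"unknown diffusion unit {to_unit!r}") from None
    return value * _DIFFUSION_UNIT_TO_UM2_S[src] / _DIFFUSION_UNIT_TO_UM2_S[dst]
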