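"""Bundled physical parameter tables.

Van der Waals radii follow Bondi's compilation; Lennard-Jones parameters
are a minimal per-element table with Lorentz-Berthelot combination,
adequate for *relative* inter-chain energies (the classification layer only
consumes differences between systems, never absolute force-field energies).
"""

from __future__ import annotations

import warnings

#: Bondi-style van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
}

#: Fallback radius for elements missing from the table, Å.
DEFAULT_VDW_RADIUS: float = 1.70

#: Per-element 12-6 parameters: (sigma Å, epsilon kJ/mol). Amber-like scale.
LJ_TABLE: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.066),
    "C": (3.40, 0.360),
    "N": (3.25, 0.711),
    "O": (2.96, 0.880),
    "P": (3.74, 0.837),
    "S": (3.56, 1.046),
}

DEFAULT_LJ: tuple[float, float] = (3.40, 0.360)

#: Residues whose carbon/sulfur atoms count toward the hydrophobic surface.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY"}
)

#: Residue codes recognised as phospho-serine.
PHOSPHOSERINE_CODES: frozenset[str] = frozenset({"SEP"})


def vdw_radius(element: str) -> float:
    """Look up the van der Waals radius of ``element`` (case-insensitive).

    Unknown elements fall back to 1.7 Å with a warning.
    """
    key = element.strip().upper()
    try:
        return VDW_RADII[key]
    except KeyError:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"using {DEFAULT_VDW_RADIUS} Å",
            stacklevel=2,
        )
        return DEFAULT_VDW_RADIUS


def lj_parameters(element: str) -> tuple[float, float]:
    """Return ``(sigma, epsilon)`` for ``element``; default type if unknown."""
    key = element.strip().upper()
    try:
        return LJ_TABLE[key]
    except KeyError:
        warnings.warn(
            f"no Lennard-Jones parameters for element {element!r}; "
            "using the default carbon-like type",
            stacklevel=2,
        )
        return DEFAULT_LJ
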