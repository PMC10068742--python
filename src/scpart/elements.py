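"""Element lookup tables: standard atomic weights and Bondi van der Waals radii.

Radii are in nm and can be overridden per element via a plain-text config file
(one ``ELEMENT radius_nm`` pair per line, ``#`` comments allowed).
"""

from __future__ import annotations

import os

#: Standard atomic weights, u (IUPAC 2021, abridged).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "He": 4.0026,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.904,
}

#: Bondi van der Waals radii, nm.
BONDI_RADII: dict[str, float] = {
    "H": 0.120,
    "D": 0.120,
    "He": 0.140,
    "Li": 0.182,
    "B": 0.192,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "Na": 0.227,
    "Mg": 0.173,
    "Si": 0.210,
    "P": 0.180,
    "S": 0.180,
    "Cl": 0.175,
    "K": 0.275,
    "Ca": 0.231,
    "Fe": 0.194,
    "Zn": 0.139,
    "Br": 0.185,
    "I": 0.198,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol has no tabulated mass or radius."""


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise UnknownElementError(f"no tabulated atomic mass for element {element!r}") from None


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    if overrides and element in overrides:
        return overrides[element]
    try:
        return BONDI_RADII[element]
    except KeyError:
        raise UnknownElementError(f"no tabulated vdW radius for element {element!r}") from None


def load_radius_overrides(path: str | os.PathLike) -> dict[str, float]:
    """Parse an ``ELEMENT radius_nm`` override file."""
    overrides: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'ELEMENT radius_nm', got {raw!r}")
            element, radius = parts[0], float(parts[1])
            if radius <= 0:
                raise ValueError(f"{path}:{lineno}: radius must be positive")
            overrides[element.capitalize()] = radius
    return overrides


def guess_element(atom_name: str) -> str:
    """Infer an element symbol from a coordinate-file atom name.

    Leading digits are stripped (``1HB`` style), then the longest leading
    alphabetic run is matched against the tables, preferring a two-letter
    symbol only when the one-letter prefix is not itself tabulated
    (GRO/PDB names are upper case, so ``CL1`` on a carbon must stay carbon).
    """
    stripped = atom_name.strip().lstrip("0123456789")
    alpha = ""
    for ch in stripped:
        if ch.isalpha():
            alpha += ch
        else:
            break
    if not alpha:
        raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")
    one = alpha[0].upper()
    if one in ATOMIC_MASSES:
        return one
    if len(alpha) >= 2:
        two = alpha[0].upper() + alpha[1].lower()
        if two in ATOMIC_MASSES:
            return two
    raise UnknownElementError(f"cannot infer element from atom name {atom_name!r}")
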