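"""Core domain model: atoms, frames, configuration ensembles, molecule types.

An ensemble stores coordinates as a ``(n_frames, n_atoms, 3)`` array in nm with
static per-atom topology (element, mass, radius, molecule assignment) shared by
all frames. :class:`Atom` and :class:`Frame` are lightweight record views onto
those arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .elements import atomic_mass

#: Residue names recognised as water across GRO/PDB dialects.
WATER_RESIDUE_NAMES = frozenset({"SOL", "TIP3", "HOH", "WAT", "H2O", "TIP3P", "SPC"})

#: Full molecular weight of water, u. Single-site water beads carry this mass
#: so that mass-density profiles of coarse fixtures stay physical.
WATER_MOLECULAR_WEIGHT = 18.015

ROLES = ("lipid", "water", "solute")


class EnsembleError(ValueError):
    """Inconsistent ensemble structure (atom counts, ordering, boxes)."""


@dataclass(frozen=True)
class Atom:
    """One typed atom of one molecule, coordinates in nm."""

    element: str
    coordinates: tuple[float, float, float]
    mass: float
    vdw_radius: float
    molecule_id: int
    molecule_type: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if not self.vdw_radius > 0:
            raise ValueError(f"vdW radius must be positive, got {self.vdw_radius}")
        if not all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates: {self.coordinates}")


@dataclass(frozen=True)
class MoleculeTypeSpec:
    """Description of one molecule species (e.g. CER2, CHOL, H2O)."""

    name: str
    molecular_weight: float
    atom_elements: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.role != "water":
            expected = sum(atomic_mass(e) for e in self.atom_elements)
            if abs(expected - self.molecular_weight) > 0.5:
                raise ValueError(
                    f"molecular weight of {self.name!r} ({self.molecular_weight}) "
                    f"does not match its elements ({expected:.3f} u)"
                )


class Frame:
    """A single snapshot: an ordered atom collection plus box edges (nm)."""

    def __init__(self, ensemble: "ConfigurationEnsemble", index: int):
        self._ens = ensemble
        self.index = index

    @property
    def coordinates(self) -> np.ndarray:
        return self._ens.coords[self.index]

    @property
    def box(self) -> np.ndarray:
        return self._ens.boxes[self.index]

    @property
    def atoms(self) -> list[Atom]:
        ens = self._ens
        xyz = self.coordinates
        return [
            Atom(
                element=ens.elements[i],
                coordinates=tuple(xyz[i]),
                mass=float(ens.masses[i]),
                vdw_radius=float(ens.radii[i]),
                molecule_id=int(ens.molecule_ids[i]),
                molecule_type=ens.molecule_types[i],
                name=ens.atom_names[i],
            )
            for i in range(ens.n_atoms)
        ]

    def __len__(self) -> int:
        return self._ens.n_atoms


@dataclass
class ConfigurationEnsemble:
    """Frames of typed, molecule-assigned atoms with per-frame box dimensions.

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) array, nm
    boxes : (n_frames, 3) array, nm; NaN marks an unknown box (PDB without
        CRYST1), rejected at the point of use, not at read time.
    elements, atom_names, molecule_types : per-atom metadata, length n_atoms
    masses, radii : per-atom arrays, u and nm
    molecule_ids : per-atom integer molecule assignment, contiguous runs
    molecule_catalog : molecule_type name -> :class:`MoleculeTypeSpec`
    """

    coords: np.ndarray
    boxes: np.ndarray
    elements: list[str]
    atom_names: list[str]
    masses: np.ndarray
    radii: np.ndarray
    molecule_ids: np.ndarray
    molecule_types: list[str]
    molecule_catalog: dict[str, MoleculeTypeSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise EnsembleError("ensemble needs at least one frame")
        if self.boxes.shape != (self.coords.shape[0], 3):
            raise EnsembleError("boxes must be (n_frames, 3)")
        n = self.n_atoms
        for attr in ("elements", "atom_names", "molecule_types"):
            if len(getattr(self, attr)) != n:
                raise EnsembleError(f"{attr} length {len(getattr(self, attr))} != n_atoms {n}")
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        for attr in ("masses", "radii", "molecule_ids"):
            if getattr(self, attr).shape != (n,):
                raise EnsembleError(f"{attr} must have shape ({n},)")
        if np.any(self.masses <= 0) or np.any(self.radii <= 0):
            raise EnsembleError("masses and radii must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError("non-finite coordinates in ensemble")
        # heuristic tripwire for an Angstrom leak through the nm contract
        if np.nanmax(np.abs(self.coords)) > 1e3:
            raise EnsembleError("coordinate magnitude exceeds 1000 nm; units are probably not nm")
        if not self.molecule_catalog:
            self.molecule_catalog = build_molecule_catalog(
                self.elements, self.masses, self.molecule_ids, self.molecule_types
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frames(self) -> list[Frame]:
        return [Frame(self, i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def atom_indices_of_type(self, molecule_type: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.molecule_types) == np.array(molecule_type))

    def molecule_instances(self, molecule_type: str) -> list[np.ndarray]:
        """Atom-index arrays of each molecule of the given type, in file order."""
        mask = [t == molecule_type for t in self.molecule_types]
        ids = self.molecule_ids[mask]
        idx = np.flatnonzero(mask)
        out: list[np.ndarray] = []
        if idx.size == 0:
            return out
        start = 0
        for k in range(1, idx.size + 1):
            if k == idx.size or ids[k] != ids[start]:
                out.append(idx[start:k])
                start = k
        return out

    def count_molecules(self, role: str | None = None) -> int:
        n = 0
        for spec in self.molecule_catalog.values():
            if role is None or spec.role == role:
                n += len(self.molecule_instances(spec.name))
        return n

    def atom_mask_for_role(self, role: str) -> np.ndarray:
        roles = {name: spec.role for name, spec in self.molecule_catalog.items()}
        return np.array([roles.get(t) == role for t in self.molecule_types], dtype=bool)


def infer_role(molecule_type: str, solute_names: Sequence[str] = ()) -> str:
    if molecule_type.upper() in WATER_RESIDUE_NAMES:
        return "water"
    if molecule_type in solute_names:
        return "solute"
    return "lipid"


def build_molecule_catalog(
    elements: Sequence[str],
    masses: np.ndarray,
    molecule_ids: np.ndarray,
    molecule_types: Sequence[str],
    solute_names: Sequence[str] = (),
) -> dict[str, MoleculeTypeSpec]:
    """Derive the per-type catalog from the first molecule of each type."""
    catalog: dict[str, MoleculeTypeSpec] = {}
    n = len(elements)
    i = 0
    while i < n:
        j = i
        while j < n and molecule_ids[j] == molecule_ids[i]:
            j += 1
        mtype = molecule_types[i]
        if mtype not in catalog:
            catalog[mtype] = MoleculeTypeSpec(
                name=mtype,
                molecular_weight=float(np.sum(masses[i:j])),
                atom_elements=tuple(elements[i:j]),
                role=infer_role(mtype, solute_names),
            )
        i = j
    return catalog
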