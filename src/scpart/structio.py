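"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
GRO
    Fixed-column GROMACS coordinate files, nm, one or more concatenated
    frames. Molecule assignment comes from residue number + residue name.
PDB
    ATOM/HETATM records in Angstrom (converted to nm at this boundary),
    MODEL/ENDMDL frames, CRYST1 box. A missing CRYST1 yields an unknown
    (NaN) box rejected only when densities are requested.
Layer table
    An open, self-describing plain-text dialect for slice-wise normalized
    number densities (the role the proprietary .mic format plays upstream;
    byte compatibility with that format is explicitly not claimed). Header
    lines start with ``#`` and carry system name, temperature, grid geometry
    and the molecule catalog; the body has one row per slice: z center then
    one column per (molecule type, atom index).
Free-energy profile
    Two-column TSV: slice-center z and dG in kJ/mol. z is nm unless a
    ``# z_unit: angstrom`` header says otherwise. Spacing must be uniform
    (the L/kg conversion requires equal slice volumes).
Solute table
    CSV with columns ``name``, ``log_klip_exp``, ``log_kow``, optional
    ``log_kow_pred`` and any number of ``log_klip_pred_<SYSTEM>`` columns.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import SoluteRecord
from .constants import DEFAULT_TEMPERATURE
from .core import (
    ConfigurationEnsemble,
    EnsembleError,
    MoleculeTypeSpec,
    WATER_MOLECULAR_WEIGHT,
    WATER_RESIDUE_NAMES,
    build_molecule_catalog,
)
from .elements import atomic_mass, guess_element, vdw_radius
from .partition import FreeEnergyProfile
from .profiles import SliceGrid, WaterProfile

__all__ = [
    "LayerTable",
    "FormatError",
    "read_gro_ensemble",
    "write_gro_ensemble",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_layer_table",
    "write_layer_table",
    "read_dg_profile",
    "write_dg_profile",
    "read_solute_table",
    "write_solute_table",
]

LAYER_TABLE_MAGIC = "# scpart-layer-table v1"


class FormatError(ValueError):
    """Malformed on-disk data; the message names the offending line."""


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_atom_line(line: str, lineno: int) -> tuple[int, str, str, float, float, float]:
    if len(line.rstrip("\n")) < 44:
        raise FormatError(f"line {lineno}: GRO atom record shorter than 44 columns")
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: malformed GRO atom record ({exc})") from None
    if not resname or not atomname:
        raise FormatError(f"line {lineno}: empty residue or atom name")
    return resid, resname, atomname, x, y, z


def read_gro_ensemble(
    path: str | os.PathLike,
    solute_names: Sequence[str] = (),
    radius_overrides: dict[str, float] | None = None,
) -> ConfigurationEnsemble:
    """Read one or more concatenated GRO frames into an ensemble (nm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames_xyz: list[np.ndarray] = []
    boxes: list[list[float]] = []
    topology: list[tuple[int, str, str]] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        frame_no += 1
        if i + 1 >= len(lines):
            raise FormatError(f"line {i + 1}: truncated GRO frame header")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from None
        if i + 2 + natoms > len(lines) - 1:
            raise FormatError(f"frame {frame_no}: file ends before {natoms} atoms + box line")
        xyz = np.empty((natoms, 3))
        topo: list[tuple[int, str, str]] = []
        for k in range(natoms):
            resid, resname, atomname, x, y, z = _parse_gro_atom_line(lines[i + 2 + k], i + 3 + k)
            xyz[k] = (x, y, z)
            topo.append((resid, resname, atomname))
        box_fields = lines[i + 2 + natoms].split()
        if len(box_fields) < 3:
            raise FormatError(f"line {i + 3 + natoms}: GRO box line needs >= 3 floats")
        boxes.append([float(v) for v in box_fields[:3]])
        if topology is None:
            topology = topo
        elif topo != topology:
            raise EnsembleError(
                f"frame {frame_no} atom count/ordering differs from frame 1 "
                f"({len(topo)} vs {len(topology)} atoms)"
            )
        frames_xyz.append(xyz)
        i += 3 + natoms
    if topology is None:
        raise FormatError(f"{path}: no frames found")
    return _assemble(frames_xyz, boxes, topology, solute_names, radius_overrides)


def _assemble(
    frames_xyz: list[np.ndarray],
    boxes: list[list[float]],
    topology: list[tuple[int, str, str]],
    solute_names: Sequence[str],
    radius_overrides: dict[str, float] | None,
) -> ConfigurationEnsemble:
    elements, names, mtypes = [], [], []
    mol_ids = np.empty(len(topology), dtype=int)
    mol_id = -1
    prev: tuple[int, str] | None = None
    for k, (resid, resname, atomname) in enumerate(topology):
        if prev != (resid, resname):
            mol_id += 1
            prev = (resid, resname)
        mol_ids[k] = mol_id
        elements.append(guess_element(atomname))
        names.append(atomname)
        mtypes.append(resname)
    masses = np.array([atomic_mass(e) for e in elements])
    radii = np.array([vdw_radius(e, radius_overrides) for e in elements])
    # single-site waters carry the full molecular mass so densities stay physical
    for start in np.flatnonzero(np.r_[True, np.diff(mol_ids) != 0]):
        if mtypes[start].upper() in WATER_RESIDUE_NAMES:
            members = np.flatnonzero(mol_ids == mol_ids[start])
            if members.size == 1:
                masses[members[0]] = WATER_MOLECULAR_WEIGHT
    catalog = build_molecule_catalog(elements, masses, mol_ids, mtypes, solute_names)
    return ConfigurationEnsemble(
        coords=np.stack(frames_xyz),
        boxes=np.asarray(boxes, dtype=float),
        elements=elements,
        atom_names=names,
        masses=masses,
        radii=radii,
        molecule_ids=mol_ids,
        molecule_types=mtypes,
        molecule_catalog=catalog,
    )


def write_gro_ensemble(ensemble: ConfigurationEnsemble, path: str | os.PathLike, title: str = "scpart") -> None:
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{title} frame {f}\n")
            fh.write(f"{ensemble.n_atoms:5d}\n")
            for k in range(ensemble.n_atoms):
                resid = (int(ensemble.molecule_ids[k]) + 1) % 100000
                x, y, z = ensemble.coords[f, k]
                fh.write(
                    f"{resid:5d}{ensemble.molecule_types[k]:<5.5s}"
                    f"{ensemble.atom_names[k]:>5.5s}{(k + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = ensemble.boxes[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB

def read_pdb_ensemble(
    path: str | os.PathLike,
    solute_names: Sequence[str] = (),
    radius_overrides: dict[str, float] | None = None,
) -> ConfigurationEnsemble:
    """Read ATOM/HETATM records (Angstrom -> nm); MODEL blocks become frames."""
    frames_xyz: list[np.ndarray] = []
    topology: list[tuple[int, str, str]] | None = None
    box: list[float] | None = None
    current_xyz: list[tuple[float, float, float]] = []
    current_topo: list[tuple[int, str, str]] = []
    elements_hint: list[str] = []
    saw_model = False

    def flush(lineno: int) -> None:
        nonlocal topology
        if not current_topo:
            return
        if topology is None:
            topology = list(current_topo)
        elif current_topo != topology:
            raise EnsembleError(f"line {lineno}: MODEL atom count/ordering differs from first model")
        frames_xyz.append(np.asarray(current_xyz, dtype=float))
        current_xyz.clear()
        current_topo.clear()

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = [float(line[6:15]) / 10, float(line[15:24]) / 10, float(line[24:33]) / 10]
                except ValueError:
                    raise FormatError(f"line {lineno}: malformed CRYST1 record") from None
            elif rec == "MODEL":
                saw_model = True
            elif rec == "ENDMDL":
                flush(lineno)
            elif rec in ("ATOM", "HETATM"):
                try:
                    atomname = line[12:16].strip()
                    # columns 18-21: standard 3-char residue names plus the
                    # common 4-char extension (CER2, CERO, ...)
                    resname = line[17:21].strip()
                    resid = int(line[22:26])
                    x = float(line[30:38]) / 10.0
                    y = float(line[38:46]) / 10.0
                    z = float(line[46:54]) / 10.0
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: malformed {rec} record ({exc})") from None
                element_field = line[76:78].strip()
                elements_hint.append(element_field)
                current_xyz.append((x, y, z))
                current_topo.append((resid, resname, atomname))
    flush(lineno=-1)
    if topology is None or not frames_xyz:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    if saw_model and len(frames_xyz) == 0:  # pragma: no cover - defensive
        raise FormatError(f"{path}: MODEL without ENDMDL")
    n_frames = len(frames_xyz)
    if box is None:
        boxes = [[math.nan] * 3] * n_frames
    else:
        boxes = [box] * n_frames
    ens = _assemble(frames_xyz, boxes, topology, solute_names, radius_overrides)
    # trust explicit element columns from the first model where present
    n_atoms = ens.n_atoms
    for k in range(n_atoms):
        hint = elements_hint[k]
        if hint and hint.capitalize() != ens.elements[k]:
            ens.elements[k] = hint.capitalize()
            ens.masses[k] = atomic_mass(ens.elements[k])
            ens.radii[k] = vdw_radius(ens.elements[k], radius_overrides)
    return ens


def write_pdb_ensemble(ensemble: ConfigurationEnsemble, path: str | os.PathLike) -> None:
    """Write frames as MODEL blocks, nm -> Angstrom, with a CRYST1 box."""
    with open(path, "w") as fh:
        box = ensemble.boxes[0]
        if np.all(np.isfinite(box)):
            fh.write(
                f"CRYST1{box[0] * 10:9.3f}{box[1] * 10:9.3f}{box[2] * 10:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for k in range(ensemble.n_atoms):
                x, y, z = ensemble.coords[f, k] * 10.0
                name = ensemble.atom_names[k][:4]
                # 4-char residue names occupy columns 18-21 (CHARMM style)
                fh.write(
                    f"ATOM  {(k + 1) % 100000:5d} {name:<4.4s} "
                    f"{ensemble.molecule_types[k]:<4.4s} "
                    f"{(int(ensemble.molecule_ids[k]) + 1) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{ensemble.elements[k]:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Layer table

@dataclass
class LayerTable:
    """Slice-wise normalized number densities per (molecule type, atom index)."""

    grid: SliceGrid
    densities: dict[str, np.ndarray]  # molecule type -> (n_atoms_per_mol, n_slices)
    catalog: dict[str, MoleculeTypeSpec]
    molecule_counts: dict[str, int]
    system: str = ""
    temperature: float = DEFAULT_TEMPERATURE
    n_frames: int = 1

    def validate(self) -> None:
        if not self.densities:
            raise FormatError("no molecule types in layer table")
        for mtype, dens in self.densities.items():
            if mtype not in self.catalog:
                raise FormatError(f"molecule type {mtype!r} missing from catalog")
            if np.any(dens < 0):
                raise FormatError(f"negative densities for {mtype!r}")
            if np.any(np.abs(dens.sum(axis=1) - 1.0) > 1e-9):
                raise FormatError(f"densities of {mtype!r} do not sum to 1 over slices")
            if dens.shape[1] != self.grid.n:
                raise FormatError(f"density columns of {mtype!r} do not match grid")

    def water_profile(self) -> WaterProfile:
        """Reconstruct x_w from the water type's first-oxygen density row."""
        for mtype, spec in self.catalog.items():
            if spec.role != "water":
                continue
            dens = self.densities[mtype]
            try:
                row = spec.atom_elements.index("O")
            except ValueError:
                row = 0
            n_w_tot = float(self.molecule_counts.get(mtype, 1))
            return WaterProfile(n_w=dens[row] * n_w_tot, n_w_tot=n_w_tot)
        raise FormatError("layer table has no water molecule type")


def write_layer_table(table: LayerTable, path: str | os.PathLike) -> None:
    table.validate()
    grid = table.grid
    with open(path, "w") as fh:
        fh.write(LAYER_TABLE_MAGIC + "\n")
        fh.write(f"# system: {table.system}\n")
        fh.write(f"# temperature_K: {float(table.temperature)!r}\n")
        fh.write(f"# n_frames: {table.n_frames}\n")
        fh.write(f"# n_slices: {grid.n}\n")
        fh.write(f"# slice_thickness_nm: {float(grid.thickness)!r}\n")
        fh.write(f"# box_area_nm2: {float(grid.box_area)!r}\n")
        columns = ["z_nm"]
        for mtype, dens in table.densities.items():
            spec = table.catalog[mtype]
            fh.write(
                f"# molecule: {mtype} role={spec.role} count={table.molecule_counts.get(mtype, 0)}"
                f" mw={float(spec.molecular_weight)!r} elements={','.join(spec.atom_elements)}\n"
            )
            columns += [f"{mtype}:{k}" for k in range(dens.shape[0])]
        fh.write("# columns: " + "\t".join(columns) + "\n")
        blocks = [table.densities[mtype] for mtype in table.densities]
        body = np.vstack([grid.z_centers] + [b for blk in blocks for b in blk]).T
        for row in body:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_layer_table(path: str | os.PathLike) -> LayerTable:
    meta: dict[str, str] = {}
    molecules: list[dict[str, str]] = []
    body_rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != LAYER_TABLE_MAGIC:
            raise FormatError(f"{path}: not a scpart layer table (missing magic header)")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                content = line[1:].strip()
                if content.startswith("molecule:"):
                    fields = content[len("molecule:"):].split()
                    entry = {"name": fields[0]}
                    for item in fields[1:]:
                        key, _, value = item.partition("=")
                        entry[key] = value
                    molecules.append(entry)
                else:
                    key, _, value = content.partition(":")
                    meta[key.strip()] = value.strip()
            else:
                try:
                    body_rows.append([float(v) for v in line.split("\t")])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: unparseable density row") from None
    if not molecules:
        raise FormatError(f"{path}: no molecule types declared")
    try:
        n = int(meta["n_slices"])
        thickness = float(meta["slice_thickness_nm"])
        area = float(meta["box_area_nm2"])
        temperature = float(meta.get("temperature_K", DEFAULT_TEMPERATURE))
        n_frames = int(meta.get("n_frames", 1))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad or missing header field ({exc})") from None
    if len(body_rows) != n:
        raise FormatError(f"{path}: header declares {n} slices but body has {len(body_rows)} rows")
    body = np.asarray(body_rows, dtype=float)
    grid = SliceGrid(n=n, thickness=thickness, box_area=area, z_centers=body[:, 0])
    densities: dict[str, np.ndarray] = {}
    catalog: dict[str, MoleculeTypeSpec] = {}
    counts: dict[str, int] = {}
    col = 1
    for entry in molecules:
        elements = tuple(entry["elements"].split(","))
        n_atoms_mol = len(elements)
        if col + n_atoms_mol > body.shape[1]:
            raise FormatError(f"{path}: body has fewer density columns than the header declares")
        densities[entry["name"]] = body[:, col:col + n_atoms_mol].T.copy()
        catalog[entry["name"]] = MoleculeTypeSpec(
            name=entry["name"],
            molecular_weight=float(entry["mw"]),
            atom_elements=elements,
            role=entry.get("role", "lipid"),
        )
        counts[entry["name"]] = int(entry.get("count", 0))
        col += n_atoms_mol
    if col != body.shape[1]:
        raise FormatError(f"{path}: body has more density columns than the header declares")
    table = LayerTable(
        grid=grid,
        densities=densities,
        catalog=catalog,
        molecule_counts=counts,
        system=meta.get("system", ""),
        temperature=temperature,
        n_frames=n_frames,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Free-energy profiles

SPACING_TOL = 0.01  # max |dz - mean dz| as a fraction of mean dz


def read_dg_profile(path: str | os.PathLike, temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergyProfile:
    z_unit = "nm"
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                content = line[1:].strip().lower()
                if content.startswith("z_unit:"):
                    z_unit = content.split(":", 1)[1].strip()
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'z dG' columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparseable numeric fields") from None
    if not rows:
        raise FormatError(f"{path}: empty free-energy profile")
    z = np.array([r[0] for r in rows])
    dg = np.array([r[1] for r in rows])
    if z_unit in ("angstrom", "a", "å", "ang"):
        z = z / 10.0
    elif z_unit != "nm":
        raise FormatError(f"{path}: unknown z unit {z_unit!r}")
    if np.any(np.diff(z) <= 0):
        raise FormatError(f"{path}: z column must be strictly increasing")
    if z.size > 1:
        dz = np.diff(z)
        if np.max(np.abs(dz - dz.mean())) > SPACING_TOL * dz.mean():
            raise FormatError(
                f"{path}: non-uniform slice spacing (max deviation exceeds 1% of mean); "
                "equal slice volumes are required"
            )
    return FreeEnergyProfile(z_centers=z, dg=dg, temperature=temperature)


def write_dg_profile(profile: FreeEnergyProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# z_unit: nm\n")
        fh.write("# z_nm\tdG_kJ_per_mol\n")
        for z, g in zip(profile.z_centers, profile.dg):
            fh.write(f"{float(z)!r}\t{float(g)!r}\n")


# ---------------------------------------------------------------------------
# Solute tables

PRED_PREFIX = "log_klip_pred_"


def read_solute_table(path: str | os.PathLike) -> list[SoluteRecord]:
    df = pd.read_csv(path)
    required = {"name", "log_klip_exp", "log_kow"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate solute names: {sorted(set(dupes))}")
    pred_cols = [c for c in df.columns if c.startswith(PRED_PREFIX)]
    records = []
    for _, row in df.iterrows():
        preds = {
            c[len(PRED_PREFIX):]: float(row[c])
            for c in pred_cols
            if pd.notna(row[c])
        }
        records.append(
            SoluteRecord(
                name=str(row["name"]),
                log_klip_exp=float(row["log_klip_exp"]) if pd.notna(row["log_klip_exp"]) else None,
                log_kow=float(row["log_kow"]) if pd.notna(row["log_kow"]) else None,
                log_kow_pred=float(row["log_kow_pred"])
                if "log_kow_pred" in df.columns and pd.notna(row["log_kow_pred"])
                else None,
                log_klip_pred=preds,
            )
        )
    return records


def compile_layer_table(
    ensemble: ConfigurationEnsemble,
    grid: SliceGrid,
    system: str = "",
    symmetrized: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> LayerTable:
    """Compile per-atom number densities of an ensemble into a layer table,
    optionally symmetrized about the lipid bilayer center."""
    from .profiles import (
        locate_bilayer_center,
        mass_density_profile,
        number_density_profiles,
        symmetrize,
    )

    profile_set = number_density_profiles(ensemble, grid)
    densities = profile_set.number_densities
    if symmetrized:
        rho_lipid = mass_density_profile(ensemble, grid, "lipid")
        center = locate_bilayer_center(rho_lipid, grid)
        densities = {
            mtype: np.vstack([symmetrize(row, grid, center) for row in dens])
            for mtype, dens in densities.items()
        }
    counts = {t: len(ensemble.molecule_instances(t)) for t in densities}
    table = LayerTable(
        grid=grid,
        densities=densities,
        catalog={t: ensemble.molecule_catalog[t] for t in densities},
        molecule_counts=counts,
        system=system,
        temperature=temperature,
        n_frames=ensemble.n_frames,
    )
    table.validate()
    return table


def write_solute_table(records: Sequence[SoluteRecord], path: str | os.PathLike) -> None:
    systems = sorted({s for r in records for s in r.log_klip_pred})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "name": r.name,
            "log_klip_exp": r.log_klip_exp,
            "log_kow": r.log_kow,
        }
        if any(rec.log_kow_pred is not None for rec in records):
            row["log_kow_pred"] = r.log_kow_pred
        for s in systems:
            row[PRED_PREFIX + s] = r.log_klip_pred.get(s)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
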