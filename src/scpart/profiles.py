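"""z-axis slicing and time-averaged density profiles of bilayer ensembles.

The membrane normal is z. Binning is half-open ``[z_lo, z_hi)`` on coordinates
wrapped into ``[0, box_z)``; for fluctuating (NPT) boxes each frame is binned
in fractional coordinates ``z / box_z(frame)`` on a fixed n-slice grid, while
the slice volume uses the time-averaged box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .constants import AMU_KG, NM3_TO_M3

if TYPE_CHECKING:  # pragma: no cover
    from .core import ConfigurationEnsemble

NORMALIZATION_TOL = 1e-9


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SliceGrid:
    """Uniform slicing of the z axis: n slices of equal thickness and volume."""

    n: int
    thickness: float  # nm
    box_area: float  # nm^2, x*y
    z_centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ProfileError("slice count must be >= 1")
        if self.thickness <= 0 or self.box_area <= 0:
            raise ProfileError("thickness and box area must be positive")
        if self.z_centers is None:
            centers = (np.arange(self.n) + 0.5) * self.thickness
            object.__setattr__(self, "z_centers", centers)
        else:
            object.__setattr__(self, "z_centers", np.asarray(self.z_centers, dtype=float))
            if self.z_centers.shape != (self.n,):
                raise ProfileError("z_centers length must equal n")

    @property
    def box_z(self) -> float:
        return self.n * self.thickness

    @property
    def slice_volume(self) -> float:
        """delta V in nm^3."""
        return self.thickness * self.box_area


@dataclass
class WaterProfile:
    """Per-slice water occupancy: counts n_w(z_i) and fractions x_w(z_i)."""

    n_w: np.ndarray  # time-averaged waters per slice, may be fractional
    n_w_tot: float

    def __post_init__(self) -> None:
        self.n_w = np.asarray(self.n_w, dtype=float)
        if self.n_w_tot <= 0:
            raise ProfileError("total water count must be positive")
        if np.any(self.n_w < 0):
            raise ProfileError("negative water counts")

    @property
    def x_w(self) -> np.ndarray:
        return self.n_w / self.n_w_tot


@dataclass
class DensityProfileSet:
    """Normalized per-atom number densities plus derived mass/water profiles.

    ``number_densities[molecule_type]`` has shape ``(n_atoms_per_molecule, n)``;
    each per-atom row is averaged over frames and molecule instances and sums
    to 1 over slices.
    """

    grid: SliceGrid
    number_densities: dict[str, np.ndarray]
    mass_density: np.ndarray | None = None  # kg/m^3, selection-dependent
    water_profile: WaterProfile | None = None

    def validate(self) -> None:
        for mtype, dens in self.number_densities.items():
            if np.any(dens < 0):
                raise ProfileError(f"negative density for {mtype}")
            sums = dens.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > NORMALIZATION_TOL):
                raise ProfileError(f"per-atom densities of {mtype} do not sum to 1")


def build_slice_grid(box: np.ndarray, target_thickness: float = 0.1) -> SliceGrid:
    """Slice a box along z into ``max(1, round(box_z / target_thickness))`` slices."""
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(~np.isfinite(box)) or np.any(box <= 0):
        raise ProfileError(f"box must be 3 positive finite edge lengths, got {box}")
    if target_thickness <= 0:
        raise ProfileError("target thickness must be positive")
    n = max(1, int(np.floor(box[2] / target_thickness + 0.5)))
    return SliceGrid(n=n, thickness=box[2] / n, box_area=float(box[0] * box[1]))


def _mean_box(ensemble: "ConfigurationEnsemble") -> np.ndarray:
    boxes = ensemble.boxes
    if np.any(~np.isfinite(boxes)):
        raise ProfileError("ensemble has frames with no box (e.g. PDB without CRYST1)")
    return boxes.mean(axis=0)


def grid_for_ensemble(ensemble: "ConfigurationEnsemble", target_thickness: float = 0.1) -> SliceGrid:
    return build_slice_grid(_mean_box(ensemble), target_thickness)


def _check_grid_compatible(ensemble: "ConfigurationEnsemble", grid: SliceGrid) -> None:
    mean_z = _mean_box(ensemble)[2]
    if abs(mean_z - grid.box_z) > 0.01 * grid.box_z:
        raise ProfileError(
            f"grid box_z {grid.box_z:.4f} nm differs from ensemble mean box_z "
            f"{mean_z:.4f} nm by more than 1%"
        )


def _slice_indices(z: np.ndarray, box_z: float, n: int) -> np.ndarray:
    """Half-open periodic binning of z coordinates into n slices."""
    frac = np.mod(z / box_z, 1.0)
    idx = np.floor(frac * n).astype(int)
    return np.clip(idx, 0, n - 1)  # guards frac*n == n from float round-up


def number_density_profiles(ensemble: "ConfigurationEnsemble", grid: SliceGrid) -> DensityProfileSet:
    """Time-averaged normalized number density of each atom of each molecule type.

    For atom k of a molecule type with m instances observed over F frames, the
    density at slice i is the fraction of the m*F (frame, instance) pairs whose
    atom k falls in slice i; each per-atom density therefore sums to exactly 1.
    """
    if ensemble.n_frames < 1 or ensemble.n_atoms < 1:
        raise ProfileError("empty ensemble")
    _check_grid_compatible(ensemble, grid)
    n = grid.n
    densities: dict[str, np.ndarray] = {}
    for mtype in ensemble.molecule_catalog:
        instances = ensemble.molecule_instances(mtype)
        if not instances:
            continue
        n_atoms_mol = len(instances[0])
        counts = np.zeros((n_atoms_mol, n))
        for f in range(ensemble.n_frames):
            box_z = ensemble.boxes[f, 2]
            for inst in instances:
                idx = _slice_indices(ensemble.coords[f, inst, 2], box_z, n)
                counts[np.arange(n_atoms_mol), idx] += 1.0
        densities[mtype] = counts / (ensemble.n_frames * len(instances))
    profile_set = DensityProfileSet(grid=grid, number_densities=densities)
    profile_set.validate()
    return profile_set


def water_fraction_profile(ensemble: "ConfigurationEnsemble", grid: SliceGrid) -> WaterProfile:
    """Water slice occupancy, each water located by its oxygen (first O) atom."""
    _check_grid_compatible(ensemble, grid)
    water_types = [name for name, s in ensemble.molecule_catalog.items() if s.role == "water"]
    oxygen_indices: list[int] = []
    for mtype in water_types:
        for inst in ensemble.molecule_instances(mtype):
            o_atoms = [i for i in inst if ensemble.elements[i] == "O"]
            oxygen_indices.append(int(o_atoms[0]) if o_atoms else int(inst[0]))
    if not oxygen_indices:
        raise ProfileError("water phase required: ensemble contains no water molecules")
    ox = np.array(oxygen_indices)
    counts = np.zeros(grid.n)
    for f in range(ensemble.n_frames):
        idx = _slice_indices(ensemble.coords[f, ox, 2], ensemble.boxes[f, 2], grid.n)
        counts += np.bincount(idx, minlength=grid.n)
    n_w = counts / ensemble.n_frames
    return WaterProfile(n_w=n_w, n_w_tot=float(len(oxygen_indices)))


def mass_density_profile(
    ensemble: "ConfigurationEnsemble", grid: SliceGrid, selection: str = "all"
) -> np.ndarray:
    """Per-slice mass density rho_i in kg/m^3 for a molecule-role selection."""
    import warnings

    if selection not in ("lipid", "water", "solute", "all"):
        raise ProfileError(f"selection must be a molecule role or 'all', got {selection!r}")
    _check_grid_compatible(ensemble, grid)
    if selection == "all":
        mask = np.ones(ensemble.n_atoms, dtype=bool)
    else:
        mask = ensemble.atom_mask_for_role(selection)
    if not mask.any():
        warnings.warn(f"selection {selection!r} matches no atoms; returning a zero profile")
        return np.zeros(grid.n)
    sel = np.flatnonzero(mask)
    masses = ensemble.masses[sel]
    accum = np.zeros(grid.n)
    for f in range(ensemble.n_frames):
        idx = _slice_indices(ensemble.coords[f, sel, 2], ensemble.boxes[f, 2], grid.n)
        accum += np.bincount(idx, weights=masses, minlength=grid.n)
    mean_mass_u = accum / ensemble.n_frames
    return mean_mass_u * AMU_KG / (grid.slice_volume * NM3_TO_M3)


def locate_bilayer_center(profile: np.ndarray, grid: SliceGrid) -> float:
    """Density-weighted circular mean z of a profile under periodic z."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (grid.n,):
        raise ProfileError("profile length must equal grid.n")
    total = profile.sum()
    if total <= 0:
        raise ProfileError("cannot locate center of an all-zero profile")
    theta = 2.0 * np.pi * grid.z_centers / grid.box_z
    s = np.sum(profile * np.sin(theta))
    c = np.sum(profile * np.cos(theta))
    center = grid.box_z * (np.arctan2(s, c) / (2.0 * np.pi))
    return float(np.mod(center, grid.box_z))


def _mirror(n: int) -> np.ndarray:
    # even n: i <-> n-1-i; odd n: middle slice is its own mirror
    return np.arange(n)[::-1]


def symmetrize(profile: np.ndarray, grid: SliceGrid, center: float) -> np.ndarray:
    """Symmetrize a per-slice profile about the bilayer center.

    The profile is cyclically shifted by a whole number of slices so the slice
    containing ``center`` lands on the grid midpoint, then averaged with its
    mirror image. Whole-slice shifts preserve the total sum exactly.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (grid.n,):
        raise ProfileError("profile length must equal grid.n")
    if not (0.0 <= center <= grid.box_z):
        raise ProfileError(f"center {center} outside box [0, {grid.box_z}]")
    n = grid.n
    center_idx = int(np.floor(np.mod(center / grid.box_z, 1.0) * n)) % n
    target = (n - 1) // 2
    shifted = np.roll(profile, target - center_idx)
    return 0.5 * (shifted + shifted[_mirror(n)])
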