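"""Shrake-Rupley solvent-accessible surface area and representative-conformer
selection.

Each atom's vdW sphere is inflated by the probe radius and covered with a
deterministic Fibonacci spiral lattice; the accessible area is the sphere area
times the fraction of lattice points not buried inside any neighbouring
inflated sphere. The lattice is seed-free, so results are exactly reproducible
for a fixed ``n_points``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_PROBE_RADIUS
from .core import ConfigurationEnsemble


class SASAError(ValueError):
    pass


@dataclass
class SASARecord:
    """SASA values of every (frame, molecule instance) of one molecule type."""

    molecule_type: str
    values: np.ndarray  # (n_frames, n_instances), nm^2
    mean_sasa: float
    selected: tuple[int, int]  # (frame index, molecule index)

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n_points)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * k / golden
    cos_theta = 1.0 - 2.0 * (k + 0.5) / n_points
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    return np.column_stack((sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta))


def shrake_rupley(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area in nm^2.

    Parameters
    ----------
    coordinates : (n_atoms, 3) array, nm
    radii : (n_atoms,) vdW radii, nm
    probe_radius : probe sphere radius, nm (0.14 = water)
    n_points : lattice points per atom sphere (>= 32)
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coordinates.size == 0:
        return 0.0, np.zeros(0)
    if coordinates.ndim != 2 or coordinates.shape[1] != 3:
        raise SASAError("coordinates must be (n_atoms, 3)")
    if radii.shape != (coordinates.shape[0],) or np.any(radii <= 0):
        raise SASAError("one positive radius per atom required")
    if n_points < 32:
        raise SASAError("n_points must be >= 32")
    if probe_radius < 0:
        raise SASAError("probe radius must be non-negative")
    inflated = radii + probe_radius
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coordinates)
    max_r = float(inflated.max())
    per_atom = np.empty(coordinates.shape[0])
    for i in range(coordinates.shape[0]):
        r_i = inflated[i]
        neighbors = tree.query_ball_point(coordinates[i], r_i + max_r)
        neighbors = [j for j in neighbors if j != i]
        points = coordinates[i] + r_i * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((points - coordinates[j]) ** 2, axis=1)
            accessible &= d2 >= inflated[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * r_i**2 * accessible.sum() / n_points
    return float(per_atom.sum()), per_atom


def nearest_to_mean_index(values: np.ndarray, mean: float | None = None) -> tuple[int, int]:
    """(frame, molecule) whose SASA is nearest the mean; earliest pair in
    frame-major iteration order wins ties (C-order argmin)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SASAError("empty SASA distribution")
    if mean is None:
        mean = float(values.mean())
    flat_idx = int(np.argmin(np.abs(values - mean)))
    return (flat_idx // values.shape[1], flat_idx % values.shape[1])


def sasa_distribution(
    ensemble: ConfigurationEnsemble,
    molecule_type: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> SASARecord:
    """Per-instance SASA over all frames, computed in the occluding context of
    all non-water atoms of each frame (water is the solvent, not an occluder).
    """
    if molecule_type not in ensemble.molecule_catalog:
        raise SASAError(f"unknown molecule type {molecule_type!r}")
    instances = ensemble.molecule_instances(molecule_type)
    if not instances:
        raise SASAError(f"no molecules of type {molecule_type!r} in ensemble")
    water_mask = ensemble.atom_mask_for_role("water")
    context = np.flatnonzero(~water_mask)
    pos_in_context = {int(a): k for k, a in enumerate(context)}
    values = np.empty((ensemble.n_frames, len(instances)))
    for f in range(ensemble.n_frames):
        _, per_atom = shrake_rupley(
            ensemble.coords[f, context],
            ensemble.radii[context],
            probe_radius=probe_radius,
            n_points=n_points,
        )
        for m, inst in enumerate(instances):
            rows = [pos_in_context[int(a)] for a in inst]
            values[f, m] = per_atom[rows].sum()
    mean = float(values.mean())
    selected = nearest_to_mean_index(values, mean)
    return SASARecord(
        molecule_type=molecule_type, values=values, mean_sasa=mean, selected=selected
    )


def select_representative_conformer(
    record: SASARecord, ensemble: ConfigurationEnsemble
) -> tuple[int, int, np.ndarray]:
    """The conformer whose SASA is nearest the type mean, centred on its centroid."""
    if record.values.size == 0:
        raise SASAError("empty SASA record")
    frame, mol = record.selected
    inst = ensemble.molecule_instances(record.molecule_type)[mol]
    xyz = ensemble.coords[frame, inst].copy()
    xyz -= xyz.mean(axis=0)
    return frame, mol, xyz
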