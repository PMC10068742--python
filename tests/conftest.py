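import numpy as np
import pytest

from scpart.core import ConfigurationEnsemble, build_molecule_catalog
from scpart.profiles import SliceGrid, build_slice_grid
from scpart.synthetic import FixtureSpec, generate_bilayer_fixture


def make_ensemble(coords, box, elements, molecule_ids, molecule_types, masses=None, names=None):
    """Hand-rolled ensemble builder for tiny test systems."""
    from scpart.elements import atomic_mass, vdw_radius

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms = coords.shape[:2]
    boxes = np.tile(np.asarray(box, dtype=float), (n_frames, 1))
    if masses is None:
        masses = np.array([atomic_mass(e) for e in elements])
    radii = np.array([vdw_radius(e) for e in elements])
    mol_ids = np.asarray(molecule_ids)
    catalog = build_molecule_catalog(elements, np.asarray(masses, float), mol_ids, molecule_types)
    return ConfigurationEnsemble(
        coords=coords,
        boxes=boxes,
        elements=list(elements),
        atom_names=names or [f"{e}{i}" for i, e in enumerate(elements)],
        masses=np.asarray(masses, float),
        radii=radii,
        molecule_ids=mol_ids,
        molecule_types=list(molecule_types),
        molecule_catalog=catalog,
    )


def single_water_ensemble(z, box=(1.0, 1.0, 1.0), n_frames=1):
    """One single-site water at fixed z, optionally repeated over frames."""
    coords = np.array([[[0.5, 0.5, z]]] * n_frames)
    return make_ensemble(coords, box, ["O"], [0], ["H2O"], masses=[18.015], names=["OW"])


@pytest.fixture
def small_bilayer():
    """A small but leaflet-structured fixture shared by several suites."""
    spec = FixtureSpec(
        lipid_counts={"CER2": 6, "LIGN": 6, "CHOL": 6},
        waters_per_lipid=10,
        box=(4.0, 4.0, 10.0),
        n_frames=3,
        leaflet_half_thickness=2.0,
        noise_sigma=0.05,
        seed=42,
    )
    return generate_bilayer_fixture(spec)


@pytest.fixture
def small_grid():
    return build_slice_grid(np.array([4.0, 4.0, 10.0]), 0.1)


@pytest.fixture
def grid10():
    return SliceGrid(n=10, thickness=0.1, box_area=1.0)
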