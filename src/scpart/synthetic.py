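"""Synthetic inputs for the whole pipeline: bilayer-like ensembles, parametric
free-energy profiles, and solute benchmark tables with known structure.

Lipids are coarse bead-chains (one head-group bead run plus a tail run) whose
element compositions are chosen so per-type molecular weights land near the
real lipids (CER2 ~650, CER3 ~652, LIGN ~369, CHOL ~386 g/mol), which keeps
the L/kg conversion realistic. Water is a single O-site bead carrying the full
18.015 u. Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmark import SoluteRecord
from .constants import DEFAULT_TEMPERATURE
from .core import (
    ConfigurationEnsemble,
    MoleculeTypeSpec,
    WATER_MOLECULAR_WEIGHT,
    build_molecule_catalog,
)
from .elements import atomic_mass, vdw_radius
from .partition import FreeEnergyProfile
from .profiles import SliceGrid

GEOMETRIES = ("single_bilayer", "stacked_trilayer", "amorphous")

#: Ordered bead elements per lipid type: heteroatom head run, carbon tail run,
#: trailing light beads to trim the molecular weight onto the real value.
BEAD_ELEMENTS: dict[str, tuple[str, ...]] = {
    "CER2": ("N", "O", "O") + ("C",) * 50 + ("H",) * 4,   # 650.59 u (~650)
    "CER3": ("N", "O", "O", "O") + ("C",) * 49 + ("H",) * 2,  # 652.55 u (~652)
    "LIGN": ("O", "O") + ("C",) * 28,                      # 368.31 u (~368.6)
    "CHOL": ("O",) + ("C",) * 30 + ("H",) * 10,            # 386.41 u (~386.7)
    "CERO": ("O", "O", "O", "O") + ("C",) * 79 + ("H",) * 1,  # 1013.89 u
}

#: Lipid compositions of the five studied systems (counts per type, waters).
SYSTEM_COMPOSITIONS: dict[str, dict[str, int]] = {
    "HPm2": {"CER2": 50, "LIGN": 50, "CHOL": 50, "H2O": 4500},
    "HPm3": {"CER3": 50, "LIGN": 50, "CHOL": 50, "H2O": 4500},
    "HPm2t": {"CER2": 150, "LIGN": 150, "CHOL": 150, "H2O": 4500},
    "Amor": {"CER2": 50, "CER3": 50, "LIGN": 100, "CHOL": 100, "H2O": 9346},
    "LPP": {"CER2": 150, "CER3": 50, "CERO": 40, "LIGN": 240, "CHOL": 240, "H2O": 11235},
}

MIN_LATERAL_SPACING = 0.25  # nm between lipid grid sites


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a bilayer-like configuration ensemble."""

    geometry: str = "single_bilayer"
    lipid_counts: dict[str, int] = field(default_factory=lambda: {"CER2": 50, "LIGN": 50, "CHOL": 50})
    waters_per_lipid: float = 30.0
    n_waters: int | None = None  # overrides waters_per_lipid when set
    box: tuple[float, float, float] = (6.0, 6.0, 10.0)
    n_frames: int = 3
    noise_sigma: float = 0.05  # nm, per-frame positional jitter
    leaflet_half_thickness: float = 2.0  # nm from bilayer center to head plane
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise SyntheticError(f"geometry must be one of {GEOMETRIES}")
        if any(c < 0 for c in self.lipid_counts.values()):
            raise SyntheticError("lipid counts must be >= 0")
        if self.n_frames < 1:
            raise SyntheticError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise SyntheticError("noise sigma must be >= 0")

    @property
    def total_waters(self) -> int:
        if self.n_waters is not None:
            return int(self.n_waters)
        return int(round(self.waters_per_lipid * sum(self.lipid_counts.values())))


@dataclass(frozen=True)
class DGProfileSpec:
    """Parametric double-well free-energy profile along the membrane normal."""

    well_depth: float = 10.0  # kJ/mol, depth of the leaflet wells
    well_center_offset: float = 1.0  # nm from bilayer center to each well
    well_width: float = 0.5  # nm, Gaussian sigma of the wells
    head_barrier_height: float = 0.0  # kJ/mol at the head planes
    head_offset: float = 2.0  # nm from center to the head planes
    head_width: float = 0.3  # nm
    noise_sigma: float = 0.0  # kJ/mol
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_width <= 0 or self.head_width <= 0:
            raise SyntheticError("widths must be positive")


@dataclass(frozen=True)
class SoluteSetSpec:
    """Recipe for a benchmark table obeying log K_lip = beta * log K_ow + noise."""

    n_solutes: int = 64
    beta_true: float = 0.7
    noise_sigma: float = 0.3  # log units on the experimental values
    log_kow_range: tuple[float, float] = (-2.0, 8.0)
    n_extreme: int = 2  # planted with log_kow > 5
    n_hydrophilic: int = 16  # planted with log_kow < 1
    systems: tuple[str, ...] = ()
    pred_noise_sigma: float = 0.2
    hydrophilic_bias: float = 1.0  # underprediction strength for log_kow < 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_solutes < self.n_extreme + self.n_hydrophilic:
            raise SyntheticError("n_solutes must cover the planted strata")
        if self.noise_sigma < 0 or self.pred_noise_sigma < 0:
            raise SyntheticError("noise sigmas must be >= 0")


# ---------------------------------------------------------------------------
# bilayer fixtures

def _lattice_sites(n: int, lx: float, ly: float) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    if lx / side < MIN_LATERAL_SPACING or ly / side < MIN_LATERAL_SPACING:
        raise SyntheticError(
            f"box {lx}x{ly} nm too small for {n} lipids per leaflet at "
            f"{MIN_LATERAL_SPACING} nm minimum spacing"
        )
    xs = (np.arange(side) + 0.5) * lx / side
    ys = (np.arange(side) + 0.5) * ly / side
    grid = np.array([(x, y) for y in ys for x in xs])
    return grid[:n]


def _chain_coords(head_xy: np.ndarray, z_head: float, z_core: float, n_beads: int) -> np.ndarray:
    zs = np.linspace(z_head, z_core, n_beads)
    out = np.empty((n_beads, 3))
    out[:, 0] = head_xy[0]
    out[:, 1] = head_xy[1]
    out[:, 2] = zs
    return out


def _leaflet_planes(spec: FixtureSpec) -> list[tuple[float, float]]:
    """(head plane z, core z) per leaflet, for the chosen geometry."""
    zc = spec.box[2] / 2.0
    h = spec.leaflet_half_thickness
    if spec.geometry == "single_bilayer":
        return [(zc + h, zc + 0.1), (zc - h, zc - 0.1)]
    # stacked_trilayer: three contiguous bilayers centered on zc
    planes = []
    for k in (-1, 0, 1):
        c = zc + 2.0 * h * k
        planes += [(c + h, c + 0.1), (c - h, c - 0.1)]
    return planes


def generate_bilayer_fixture(spec: FixtureSpec) -> ConfigurationEnsemble:
    """Build a bilayer-like ensemble per the spec; identical specs (and seeds)
    give bitwise-identical coordinates."""
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    zc = lz / 2.0
    unknown = [t for t in spec.lipid_counts if t not in BEAD_ELEMENTS]
    if unknown:
        raise SyntheticError(f"no bead composition for lipid types {unknown}")

    base_xyz: list[np.ndarray] = []
    elements: list[str] = []
    names: list[str] = []
    mtypes: list[str] = []
    mol_ids: list[int] = []
    mol_id = 0

    def add_molecule(xyz: np.ndarray, mtype: str, elems: tuple[str, ...]) -> None:
        nonlocal mol_id
        base_xyz.append(xyz)
        elements.extend(elems)
        names.extend(f"{e}{k + 1}" for k, e in enumerate(elems))
        mtypes.extend([mtype] * len(elems))
        mol_ids.extend([mol_id] * len(elems))
        mol_id += 1

    n_lip_total = sum(spec.lipid_counts.values())
    if spec.geometry in ("single_bilayer", "stacked_trilayer"):
        planes = _leaflet_planes(spec)
        n_leaflets = len(planes)
        per_leaflet = int(np.ceil(n_lip_total / n_leaflets))
        sites = {k: _lattice_sites(per_leaflet, lx, ly) for k in range(n_leaflets)}
        used = dict.fromkeys(range(n_leaflets), 0)
        leaflet_cycle = 0
        for mtype, count in spec.lipid_counts.items():
            elems = BEAD_ELEMENTS[mtype]
            for _ in range(count):
                k = leaflet_cycle % n_leaflets
                leaflet_cycle += 1
                z_head, z_core = planes[k]
                xy = sites[k][used[k]]
                used[k] += 1
                z_head_jit = z_head + rng.normal(0.0, 0.1)
                add_molecule(_chain_coords(xy, z_head_jit, z_core, len(elems)), mtype, elems)
        water_slabs = _water_slabs(spec)
    else:  # amorphous: lipid slab at the bottom, water slab on top
        lipid_top = 0.55 * lz
        for mtype, count in spec.lipid_counts.items():
            elems = BEAD_ELEMENTS[mtype]
            for _ in range(count):
                head = np.array([rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(0.3, lipid_top - 0.3)])
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                steps = np.arange(len(elems))[:, None] * 0.04 * direction[None, :]
                xyz = head[None, :] + steps
                xyz[:, 2] = np.clip(xyz[:, 2], 0.05, lipid_top - 0.05)
                add_molecule(xyz, mtype, elems)
        water_slabs = [(lipid_top + 0.2, lz)]

    n_waters = spec.total_waters
    if n_waters > 0:
        zw = _sample_in_slabs(rng, water_slabs, n_waters)
        xw = rng.uniform(0, lx, n_waters)
        yw = rng.uniform(0, ly, n_waters)
        for k in range(n_waters):
            add_molecule(np.array([[xw[k], yw[k], zw[k]]]), "H2O", ("O",))

    base = np.vstack(base_xyz)
    coords = np.empty((spec.n_frames, base.shape[0], 3))
    for f in range(spec.n_frames):
        jitter = rng.normal(0.0, spec.noise_sigma, base.shape) if spec.noise_sigma > 0 else 0.0
        frame = base + jitter
        coords[f] = np.mod(frame, np.array(spec.box))

    masses = np.array([atomic_mass(e) for e in elements])
    radii = np.array([vdw_radius(e) for e in elements])
    mol_ids_arr = np.asarray(mol_ids)
    water_names = [k for k, t in enumerate(mtypes) if t == "H2O"]
    masses[water_names] = WATER_MOLECULAR_WEIGHT
    catalog = build_molecule_catalog(elements, masses, mol_ids_arr, mtypes)
    boxes = np.tile(np.array(spec.box, dtype=float), (spec.n_frames, 1))
    return ConfigurationEnsemble(
        coords=coords,
        boxes=boxes,
        elements=elements,
        atom_names=names,
        masses=masses,
        radii=radii,
        molecule_ids=mol_ids_arr,
        molecule_types=mtypes,
        molecule_catalog=catalog,
    )


def _water_slabs(spec: FixtureSpec) -> list[tuple[float, float]]:
    zc = spec.box[2] / 2.0
    h = spec.leaflet_half_thickness
    gap = 0.3
    if spec.geometry == "single_bilayer":
        outer = h + gap
    else:
        outer = 3.0 * h + gap
    lo_slab = (0.0, max(zc - outer, 0.0))
    hi_slab = (min(zc + outer, spec.box[2]), spec.box[2])
    slabs = [s for s in (lo_slab, hi_slab) if s[1] - s[0] > 0.1]
    if not slabs:
        raise SyntheticError("box too small along z to hold water slabs outside the lipid stack")
    return slabs


def _sample_in_slabs(rng: np.random.Generator, slabs: list[tuple[float, float]], n: int) -> np.ndarray:
    widths = np.array([hi - lo for lo, hi in slabs])
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    u = rng.uniform(0.0, edges[-1], n)
    z = np.empty(n)
    for k, (lo, _) in enumerate(slabs):
        mask = (u >= edges[k]) & (u < edges[k + 1])
        z[mask] = lo + (u[mask] - edges[k])
    return z


def fixture_spec_for_system(system: str, n_frames: int = 3, seed: int = 0) -> FixtureSpec:
    """FixtureSpec matching one of the five studied compositions."""
    if system not in SYSTEM_COMPOSITIONS:
        raise SyntheticError(f"unknown system {system!r}; known: {sorted(SYSTEM_COMPOSITIONS)}")
    comp = dict(SYSTEM_COMPOSITIONS[system])
    n_waters = comp.pop("H2O")
    geometry = {"HPm2t": "stacked_trilayer", "Amor": "amorphous"}.get(system, "single_bilayer")
    n_lip = sum(comp.values())
    side = max(6.0, MIN_LATERAL_SPACING * np.ceil(np.sqrt(n_lip / 2)) * 1.6)
    lz = 24.0 if geometry == "stacked_trilayer" else 10.4
    if system == "LPP":
        side, lz = 10.0, 14.0
    return FixtureSpec(
        geometry=geometry,
        lipid_counts=comp,
        n_waters=n_waters,
        box=(float(side), float(side), float(lz)),
        n_frames=n_frames,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# free-energy profiles

def generate_dg_profile(spec: DGProfileSpec, grid: SliceGrid) -> FreeEnergyProfile:
    """Double Gaussian wells (one per leaflet) plus optional head barriers and
    seeded noise; approximately zero in the water slabs (bulk-water reference)."""
    rng = np.random.default_rng(spec.seed)
    z = grid.z_centers
    zc = grid.box_z / 2.0

    def gauss(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((z - center) / width) ** 2)

    dg = -spec.well_depth * (
        gauss(zc - spec.well_center_offset, spec.well_width)
        + gauss(zc + spec.well_center_offset, spec.well_width)
    )
    if spec.head_barrier_height:
        dg = dg + spec.head_barrier_height * (
            gauss(zc - spec.head_offset, spec.head_width)
            + gauss(zc + spec.head_offset, spec.head_width)
        )
    if spec.noise_sigma > 0:
        dg = dg + rng.normal(0.0, spec.noise_sigma, z.size)
    return FreeEnergyProfile(z_centers=z, dg=dg, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# solute tables

def generate_solute_table(spec: SoluteSetSpec) -> list[SoluteRecord]:
    """Benchmark records with planted log_kow strata and known slope/noise.

    Optional per-system predictions emulate the hydrophilic underprediction:
    a negative bias proportional to max(0, 1 - log_kow) plus seeded noise.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.log_kow_range
    n_mid = spec.n_solutes - spec.n_extreme - spec.n_hydrophilic
    kow = np.concatenate([
        rng.uniform(lo, min(0.99, 1.0), spec.n_hydrophilic),
        rng.uniform(1.0, 5.0, n_mid),
        rng.uniform(max(5.5, 5.0), hi, spec.n_extreme),
    ])
    rng.shuffle(kow)
    klip = spec.beta_true * kow + (
        rng.normal(0.0, spec.noise_sigma, spec.n_solutes) if spec.noise_sigma > 0 else 0.0
    )
    records = []
    for i in range(spec.n_solutes):
        preds = {}
        for system in spec.systems:
            bias = -spec.hydrophilic_bias * max(0.0, 1.0 - kow[i])
            noise = rng.normal(0.0, spec.pred_noise_sigma) if spec.pred_noise_sigma > 0 else 0.0
            preds[system] = float(klip[i] + bias + noise)
        records.append(
            SoluteRecord(
                name=f"solute_{i + 1:03d}",
                log_klip_exp=float(klip[i]),
                log_kow=float(kow[i]),
                log_klip_pred=preds,
            )
        )
    return records
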