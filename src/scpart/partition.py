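"""Boltzmann integration of a slice-wise free-energy profile into lipid/water
partition coefficients.

Two forms are produced: the extensive mol/mol coefficient

    K = sum_i V(z_i) exp(-dG(z_i)/RT) / sum_i V(z_i) x_w(z_i) exp(-dG(z_i)/RT)

(with uniform slice volume V(z_i) = dV, which cancels), and the intensive
L/kg conversion

    K_Lkg = K * dV[L] * N_A / (n_lip * M_lip / 1000)

i.e. moles of solute per kg of lipid over moles of solute per liter of water.
The exponentials are evaluated with the maximum Boltzmann weight factored out,
so profiles with |dG| up to hundreds of kJ/mol neither overflow nor collapse
to 0/inf, and K stays strictly positive even for strongly hydrophilic solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, N_A, NM3_TO_L, R_KJ
from .profiles import SliceGrid, WaterProfile

__all__ = [
    "FreeEnergyProfile",
    "BilayerComposition",
    "PartitionCoefficient",
    "k_mol_per_mol",
    "k_L_per_kg",
    "partition_coefficient",
    "predict_from_files",
    "R_KJ",
    "N_A",
]


class PartitionError(ValueError):
    pass


@dataclass
class FreeEnergyProfile:
    """Per-slice free energy dG(z_i) in kJ/mol, referenced to bulk water."""

    z_centers: np.ndarray  # nm
    dg: np.ndarray  # kJ/mol
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.z_centers.shape != self.dg.shape or self.z_centers.ndim != 1:
            raise PartitionError("z_centers and dg must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.dg)):
            raise PartitionError("free energies must be finite")
        if self.temperature <= 0:
            raise PartitionError("temperature must be positive")

    @property
    def n(self) -> int:
        return self.z_centers.size


@dataclass
class BilayerComposition:
    """Lipid counts and mean molecular weight of one simulated system."""

    lipid_counts: dict[str, int]
    molecular_weights: dict[str, float]  # g/mol per lipid type
    n_w_tot: int = 0

    def __post_init__(self) -> None:
        for name, count in self.lipid_counts.items():
            if count < 0:
                raise PartitionError(f"negative count for {name}")
            if count > 0 and name not in self.molecular_weights:
                raise PartitionError(f"no molecular weight for lipid type {name!r}")

    @property
    def n_lip(self) -> int:
        return sum(self.lipid_counts.values())

    @property
    def mean_molecular_weight(self) -> float:
        """Count-weighted mean lipid molecular weight, g/mol."""
        n = self.n_lip
        if n == 0:
            raise PartitionError("composition has no lipids")
        total = sum(c * self.molecular_weights[t] for t, c in self.lipid_counts.items() if c > 0)
        return total / n

    @property
    def lipid_mass_kg(self) -> float:
        return self.n_lip * self.mean_molecular_weight / N_A / 1000.0


@dataclass
class PartitionCoefficient:
    """K in mol/mol and L/kg with base-10 logarithms."""

    k_molmol: float
    k_Lkg: float
    log10_k_molmol: float = field(init=False)
    log10_k_Lkg: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.k_molmol > 0 and self.k_Lkg > 0):
            raise PartitionError("partition coefficients must be strictly positive")
        self.log10_k_molmol = math.log10(self.k_molmol)
        self.log10_k_Lkg = math.log10(self.k_Lkg)


def _check_same_grid(profile: FreeEnergyProfile, water: WaterProfile) -> None:
    if profile.n != water.n_w.size:
        raise PartitionError(
            f"grid mismatch: free-energy profile has {profile.n} slices, "
            f"water profile has {water.n_w.size}"
        )


def k_mol_per_mol(profile: FreeEnergyProfile, water: WaterProfile) -> float:
    """Extensive mol/mol partition coefficient from a free-energy profile.

    Uniform slice volumes cancel between numerator and denominator; the
    computation runs in log space relative to the largest Boltzmann weight.
    """
    _check_same_grid(profile, water)
    x_w = water.x_w
    if np.sum(x_w) <= 0:
        raise PartitionError("water profile is all zero")
    beta_dg = profile.dg / (R_KJ * profile.temperature)
    shift = np.min(beta_dg)  # factor out the max weight exp(-shift)
    w = np.exp(-(beta_dg - shift))
    numerator = float(np.sum(w))
    denominator = float(np.sum(x_w * w))
    if denominator == 0.0:
        # all water mass sits in slices whose shifted weight underflowed:
        # recompute the denominator with its own shift and combine in logs
        masked = np.where(x_w > 0, beta_dg, np.inf)
        shift_d = np.min(masked)
        denom_shifted = float(np.sum(x_w * np.exp(-(beta_dg - shift_d))))
        return float(np.exp(np.log(numerator) - np.log(denom_shifted) + (shift_d - shift)))
    return numerator / denominator


def k_L_per_kg(k_molmol: float, grid: SliceGrid, composition: BilayerComposition) -> float:
    """Convert the extensive mol/mol coefficient to the intensive L/kg form."""
    if composition.n_lip == 0:
        raise PartitionError("composition has no lipids")
    if k_molmol <= 0:
        raise PartitionError("k_molmol must be positive")
    dv_liters = grid.slice_volume * NM3_TO_L
    return k_molmol * dv_liters / composition.lipid_mass_kg


def partition_coefficient(
    profile: FreeEnergyProfile,
    water: WaterProfile,
    grid: SliceGrid,
    composition: BilayerComposition,
) -> PartitionCoefficient:
    if grid.n != profile.n:
        raise PartitionError(f"grid has {grid.n} slices, profile has {profile.n}")
    k = k_mol_per_mol(profile, water)
    return PartitionCoefficient(k_molmol=k, k_Lkg=k_L_per_kg(k, grid, composition))


def composition_from_counts(
    catalog: dict, counts: dict[str, int]
) -> BilayerComposition:
    """Composition from a molecule catalog + per-type molecule counts
    (works with both ensemble catalogs and layer-table catalogs)."""
    lipid_counts = {t: c for t, c in counts.items() if catalog[t].role == "lipid" and c > 0}
    weights = {t: catalog[t].molecular_weight for t in lipid_counts}
    n_w = sum(c for t, c in counts.items() if catalog[t].role == "water")
    return BilayerComposition(lipid_counts=lipid_counts, molecular_weights=weights, n_w_tot=int(n_w))


def predict_from_files(
    dg_path,
    layer_table_path,
    composition: BilayerComposition | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PartitionCoefficient:
    """Full file-level pipeline: dG TSV + layer table -> PartitionCoefficient.

    When no composition is given, lipid counts and molecular weights are taken
    from the layer table's molecule catalog.
    """
    from .structio import read_dg_profile, read_layer_table

    profile = read_dg_profile(dg_path, temperature=temperature)
    table = read_layer_table(layer_table_path)
    if composition is None:
        composition = composition_from_counts(table.catalog, table.molecule_counts)
    if table.grid.n != profile.n:
        raise PartitionError(
            f"grid mismatch: layer table has {table.grid.n} slices, "
            f"free-energy profile has {profile.n}"
        )
    return partition_coefficient(profile, table.water_profile(), table.grid, composition)
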