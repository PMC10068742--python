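# scpart

Post-processing toolkit for predicting stratum-corneum (SC) lipid/water
partition coefficients from bilayer simulation output:

- **structio** — readers/writers for multi-frame GRO and PDB coordinate
  ensembles, slice-wise layer tables, free-energy profile TSVs, and solute
  benchmark CSVs.
- **profiles** — z-axis slice grids (~1 Å slices), time-averaged normalized
  per-atom number densities, water-fraction and mass-density profiles, and
  symmetrization about the bilayer center.
- **sasa** — deterministic Shrake–Rupley solvent-accessible surface area
  (Fibonacci point lattice), per-type SASA distributions over an ensemble, and
  nearest-to-mean representative conformer selection.
- **partition** — Boltzmann integration of a per-slice free-energy profile
  ΔG(z) into the extensive mol/mol partition coefficient
  `K = Σ δV e^(−ΔG/RT) / Σ δV x_w e^(−ΔG/RT)` and its intensive L/kg form
  `K·δV·N_A/(n_lip·M_lip/1000)`, overflow-safe for |ΔG| of hundreds of kJ/mol.
- **benchmark** — residuals (predicted − experimental), RMSE, dataset filters
  (drop log K_ow > 5; reduced set keeps log K_ow ≥ 1), through-origin QSPR
  fits `log K_lip = β · log K_ow`, and residual quadrant analysis.
- **synthetic** — generators for bilayer-like bead ensembles (single bilayer,
  stacked tri-layer with anhydrous core, amorphous biphasic), parametric
  ΔG(z) profiles, and solute tables with planted strata — every pipeline
  input without running MD or quantum chemistry.

ΔG(z) profiles are always *inputs*: this package integrates them, it never
computes them.

## CLI

```sh
# generate a synthetic fully-hydrated bilayer (150 lipids, 4500 waters)
scpart simulate bilayer --system HPm2 --seed 1 --frames 3 --out hpm2.gro

# compile slice densities (~1 Å slices), symmetrized, plus mass profiles
scpart densities --in hpm2.gro --slices auto --symmetrize \
    --out layers.tsv --massprofile mass.tsv

# SASA distribution + representative conformer of one lipid type
scpart sasa --in hpm2.gro --type CER2 --probe 0.14 --ndots 960 \
    --dist-out sasa.tsv --select-out conformer.pdb

# integrate a free-energy profile into K (mol/mol and L/kg)
scpart simulate dgprofile --seed 1 --slices 104 --box-z 10.4 --out dg.tsv
scpart partition --dg dg.tsv --layers layers.tsv --out k.json

# benchmark predictions against experimental values
scpart simulate solutes --seed 1 --out solutes.csv
scpart benchmark --solutes solutes.csv --systems HPm2 --out report.json

# format conversion / validation
scpart convert --in hpm2.gro --out hpm2.pdb
scpart validate --in hpm2.gro
```

`simulate` subcommands also accept `--spec spec.yaml` whose keys mirror the
`FixtureSpec` / `DGProfileSpec` / `SoluteSetSpec` dataclass fields, e.g.

```yaml
# bilayer spec
geometry: single_bilayer        # single_bilayer | stacked_trilayer | amorphous
lipid_counts: {CER2: 50, LIGN: 50, CHOL: 50}
waters_per_lipid: 30
box: [6.0, 6.0, 10.4]
n_frames: 3
noise_sigma: 0.05
```

## Layer-table format

`scpart densities` writes an open, self-describing TSV dialect (see
`docs/layer_table_format.md`): `#`-prefixed header lines carry the system
name, temperature, slice geometry, and the molecule catalog; each body row is
a slice center z followed by one normalized number-density column per
(molecule type, atom index). Byte compatibility with proprietary micelle/
membrane input formats of commercial thermodynamics packages is not claimed.

## Units

All in-memory coordinates are nm (Å→nm conversion happens only at the PDB
boundary); masses in u; ΔG in kJ/mol; temperatures in K; K_lip in mol/mol and
L/kg; logs are base 10.
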