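# scpart layer-table dialect (v1)

A plain-text, tab-separated, self-describing container for slice-wise
normalized number densities of a membrane-normal (z) slicing.

## Header

Every header line starts with `#`. The first line is the magic string:

```
# scpart-layer-table v1
```

followed by key/value lines:

| key                  | meaning                                      |
|----------------------|----------------------------------------------|
| `system`             | free-form system name                        |
| `temperature_K`      | temperature of the source ensemble, K        |
| `n_frames`           | number of frames averaged over               |
| `n_slices`           | slice count n (must equal the body row count)|
| `slice_thickness_nm` | uniform slice thickness, nm                  |
| `box_area_nm2`       | lateral box area x·y, nm²                    |

then one `# molecule:` line per molecule type, in body column order:

```
# molecule: CER2 role=lipid count=50 mw=650.587 elements=N,O,O,C,...
```

- `role` is one of `lipid`, `water`, `solute`
- `count` is the number of molecules of that type in the source system
  (needed to reconstruct water counts n_w from fractions)
- `elements` is the ordered per-atom element list; its length sets the number
  of density columns the type occupies

A final `# columns:` line names each body column (`z_nm`, then
`TYPE:atom_index`).

## Body

One row per slice, `n_slices` rows total. Column 1 is the slice center z in
nm; the remaining columns are the normalized number densities of each
(molecule type, atom index), in catalog order. Each atom's density column
sums to 1 over all slices (tolerance 1e-9) and is non-negative. Numbers are
written with full `repr` precision, so read∘write round-trips are exact to
float64.

## Semantics

The density of atom k of type T at slice i is the fraction of all
(frame, molecule-instance) observations of that atom whose wrapped z
coordinate falls in slice i (half-open slices `[z_lo, z_hi)`, periodic wrap
at the box edge). The water fraction profile x_w(z_i) is the density row of
the water type's oxygen atom; multiplying by `count` recovers n_w(z_i).

This dialect is an open stand-in for the role proprietary micelle input files
play in commercial membrane-thermodynamics workflows; no byte compatibility
with any proprietary format is claimed.
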