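# spinemorph

Automated morphometry of dendritic spines from light-microscopy-derived 3D
triangle meshes. Given per-spine OBJ/PLY meshes (micrometers) and a manifest
with each spine's dendritic-shaft insertion point, the pipeline:

1. **Classifies completeness** (groups A–E: complete & separable, complete &
   not separable, detached head, two components, three-plus components).
2. **Repairs** incomplete spines (groups C/D) by bridging with a thin
   cylinder — from the insertion point to the nearest vertex, and/or between
   the two closest components — so neck length becomes measurable.
3. **Separates head and neck** with unsupervised per-face features (shape
   diameter function + distance to a curve skeleton), a two-component
   Gaussian mixture, and an exact graph-cut refinement with dihedral-angle
   smoothness (default smoothing λ = 0.5).
4. **Measures** head volume/area/sphericity, neck length (skeleton arc
   length) and neck diameter (median SDF; never reported for repaired
   spines), spine length and volume.
5. **Analyzes populations**: density histograms on log-scale bins,
   Mann–Whitney U (exact or tie-corrected asymptotic), Spearman ρ with a
   Wald slope test, and dip tests of unimodality in 1D plus 2D/3D
   projection variants.
6. **Models passive neck resistance** R ∝ l/(πr²) with cross-population
   ratios and reference-scaled absolute values.

A synthetic-spine generator (`spinemorph.synthetic_spines`) builds
watertight parametric spines with exact per-face ground truth — including
degraded variants for every completeness group — so the whole pipeline is
testable without microscopy data.

## CLI

```sh
# make a synthetic dataset (OBJ fixtures + manifest + ground truth)
spinemorph synth --out ds/ --n 20 --group A --group C --seed 1

# full pipeline: classify -> repair -> segment -> measure -> stats
spinemorph run --manifest ds/manifest.json --out results/ --seed 1

# individual stages
spinemorph repair    --manifest ds/manifest.json --out repaired/
spinemorph segment   --manifest ds/manifest.json --out labels/
spinemorph measure   --manifest ds/manifest.json --out morphometry.csv
spinemorph stats     --csv morphometry.csv --grouping species --out stats.json
spinemorph resistance --csv morphometry.csv --reference-megohm 226
```

`run` writes `morphometry.csv` (one row per measured spine, units in the
header), `census.json` (A–E counts/fractions, exclusions, per-scope
statistics for group A and A∪C∪D), and `provenance.json`. Reruns with the
same manifest and seed are byte-identical.

Manifest format (JSON or YAML):

```json
{"unit_scale": 1.0, "z_correction": 0.84,
 "spines": [{"id": "s1", "path": "s1.obj",
             "insertion_point": [1.2, 3.4, 0.5],
             "species": "human", "compartment": "basal",
             "subject": "case40", "dendrite": "d3"}]}
```

`z_correction` rescales the axial dimension once at load time (0.84 for the
confocal acquisition this pipeline was built around; 1.0 otherwise).

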