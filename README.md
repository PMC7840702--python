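# mitomorph

Quantification of single-cell mitochondrial morphology from multichannel
fluorescence microscopy, for cell biologists and immunologists studying
mitochondrial dynamics (e.g. DRP1-dependent fission in macrophages
responding to inflammatory stimuli such as LPS).

The mitochondrial network shifts between a *networked* state — elongated,
tubular, fused organelles — and a *fragmented* state — many small,
near-spherical pieces produced by fission. `mitomorph` measures that shift
per cell:

1. **Nuclei** are detected on the nuclear-stain (DAPI-type) channel by
   two-class Otsu thresholding: the threshold *t* maximizes the
   between-class variance σ²_B(t) = w₀w₁(μ₀ − μ₁)² of the pixel-intensity
   split {I ≤ t} / {I > t}.
2. **Cells** are delineated on the whole-cell stain (CellTracker-type
   channel) by expanding each nucleus through the stain's foreground —
   seeded geodesic propagation, so every cell contains exactly one
   nucleus. Border-touching cells are excluded from measurement.
3. **Mitochondrial objects** are segmented on the mitochondrial marker
   channel (Complex I-type), measured (area *A* in µm², Crofton perimeter
   *P*, form factor FF = 4πA/P²) and classified: an object is
   **fragmented** iff *A* < 1 µm² **and** FF > 0.6 (both strict).
4. **Length** of each object is measured on its Zhang–Suen skeleton as the
   edge sum over adjacent skeleton pixels (1 per orthogonal step, √2 per
   diagonal step) × pixel size.
5. **Aggregation**: objects are related to cells by majority pixel
   overlap; per-cell records (counts, fragmented fraction, mean length)
   are averaged within each independent experiment, then experiments are
   averaged per condition (experiments, not cells, are the replicate
   unit).

A synthetic-field generator renders macrophage-like fields — one nucleus
per cell, cytoplasm, and a mitochondrial compartment mixing sub-µm²
puncta with curvilinear filaments, degraded by Gaussian blur and
Poisson-Gaussian noise — together with ground-truth label maps, so the
whole pipeline is testable end-to-end without microscope data.

## Worked example

```python
from mitomorph import GeneratorConfig, PipelineConfig, generate_field, analyze_field

mock = GeneratorConfig(frag_fraction=0.3, filament_length_um=3.0, seed=7)
field, truth = generate_field(mock, field_id="demo")
result = analyze_field(field, PipelineConfig())

print(f"cells: {result.cells.n_objects}, mito objects: {result.mito.n_objects}")
frag = sum(o.is_fragmented for o in result.objects)
print(f"fragmented: {frag}/{len(result.objects)} "
      f"(truth {truth.fragmented_fraction:.3f})")
for row in result.per_cell[:3]:
    print(f"cell {row.cell_id}: n_mito={row.n_mito}, "
          f"fragmented={row.n_fragmented}, "
          f"mean_length={row.mean_mito_length_um:.2f} um")
```

prints

```
cells: 10, mito objects: 132
fragmented: 43/132 (truth 0.326)
cell 1: n_mito=14, fragmented=4, mean_length=2.01 um
cell 2: n_mito=13, fragmented=2, mean_length=2.50 um
cell 3: n_mito=14, fragmented=6, mean_length=1.78 um
```

i.e. the ten simulated cells carry 132 detected mitochondrial objects, of
which 33% are classified fragmented — matching the generator's truth
fraction of 0.326 — and per-cell mean mitochondrial lengths of ~2 µm,
as expected for the mock-like condition (30% puncta, 3 µm filaments).

## Command line

```sh
mitomorph generate --config conditions.yaml --out data/ --seed 1
mitomorph run --dataset data/ --out results/ --save-masks
mitomorph summarize --per-cell results/per_cell.csv --out results/
```

`run` writes `per_object.csv`, `per_object_skeleton.csv`, `per_cell.csv`,
`condition_summary.csv` (per experiment), `condition_grand_means.csv`
(across experiments) and a `manifest.json` recording every threshold,
estimator and convention used, so a run is fully reproducible from its
outputs. `segment` and `measure` run single fields.

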