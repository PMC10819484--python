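# rhizoquant

Desk-scale toolkit for evaluating organic amendments — in particular black
soldier fly larval frass and its water extracts — on germinating seeds, for
agronomy and soil-ecology researchers who run paper-based germination
assays. It covers the two quantitative legs of such an assay:

1. **Root-hair phenotyping from micrographs.** A GIS-style image pipeline
   measures the projected root-hair surface area *Ha* (mm²) and the
   specific root-hair area

   *sHa = Ha / L*  (mm² mm⁻¹),

   where *L* is the root length visible in the image. The micrograph is
   converted to a floating-point band, reclassified into *k* = 10 intensity
   classes by exact **natural-breaks (Fisher–Jenks)** clustering — the
   partition of the sorted values into contiguous classes minimising the
   within-class sum of squared deviations — the hair classes are extracted
   with a conditioned query, the binary raster is vectorised into
   pixel-edge-exact polygons, and components not attached to the root body
   are deleted as false positives. Physical units come from a 2 mm scale
   segment photographed in each image; root length is measured on the
   pruned skeleton of the root-body mask.

2. **Germination phytotoxicity indices.** From germinated-seed counts and
   mean organ lengths of sample vs. distilled-water control:

   GERIR% = 100 · (G₁/G₂) · (R₁/R₂),  GERIS% = 100 · (G₁/G₂) · (S₁/S₂),

   with verdicts at the conventional 50 / 70 / 80% thresholds, plus
   frass-composition metrics (organic C / total N ratio, organic matter =
   organic C × 1.724, field ranges such as the electrical-conductivity span
   of extracts). Reference composition tables for four frass types (two
   larval diets × thermal treatment) ship as packaged CSV fixtures.

A synthetic micrograph generator with exact ground truth (region masks,
attached hair area, analytic centerline length) supports end-to-end
validation without real imagery.

## Worked example

```sh
python examples/02_root_hair_pipeline.py
```

```
pixel size          : 0.0200 mm/px
root length         : 11.82 mm (true centerline 11.49 mm)
Ha  (hair area)     : 0.8036 mm^2 (true 0.8036 mm^2)
sHa (Ha / length)   : 0.06799 mm^2/mm
components kept     : 31
false positives cut : 5 (specks planted: 5)
```

The pipeline recovers the planted hair area exactly (residual error on this
fixture is below the printed precision), removes all five detached specks —
the automated replacement for manual cleaning in a GIS — and measures the
root within 3% of the analytic centerline, giving sHa, the hair area per mm
of root. `examples/01_natural_breaks.py` and
`examples/03_phytotoxicity_indices.py` demonstrate the classifier and the
index/composition calculations; the `rhizoquant` console script
(`roothair`, `indices`, `fixtures` subcommands) batches the same operations
over YAML-configured image sets and CSV tables.

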