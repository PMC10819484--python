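# Methods

## Natural-breaks classification

`jenks_breaks` solves the 1-D k-class minimum within-class-SSD partition
exactly with Fisher's dynamic programme over the sorted *distinct* values
and their multiplicities, O(k·d²) in the number of distinct values d. A
suffix formulation lets the optimal partition be rebuilt front-to-back
taking the smallest feasible boundary at each step, so among equal-SSD
optima the lexicographically smallest break vector is returned and the
result is fully deterministic. Breaks are the lower bounds of classes
1..k−1; intervals are left-closed/right-open, a value equal to a break goes
to the higher class, and out-of-range values clamp to the end classes.

Megapixel rasters are classified through a 1024-bin histogram of the
intensity range (`reclassify(..., bins=1024)`), which is *exact* whenever
the image has ≤ 1024 distinct intensities — always true for 8-bit data and
its luminance transform at our canvas sizes — and an optimal-partition-of-
binned-values approximation otherwise; `exact=True` forces the per-value
computation.

## Image pipeline

* **Float conversion.** RGB → BT.709 luminance (0.2126 R + 0.7152 G +
  0.0722 B) normalised to [0, 1]; a single-channel option exists. One fixed
  rule keeps runs byte-reproducible.
* **Scale.** mm/px = known scale-segment length (default 2 mm) / Euclidean
  pixel distance between its annotated endpoints. Automatic scale-bar
  detection is out of scope; endpoints are operator annotations.
* **Conditioned query.** Which of the k = 10 classes are "root hairs" is an
  operator decision. The API takes explicit class ids; alternatively
  `select_classes` picks classes whose *mean* pixel intensity falls in an
  operator-supplied window (means rather than break intervals, so a class
  that merely abuts the window from another intensity mode is not dragged
  in). The synthetic tests use the window implied by the generator's
  intensity layout — the in-silico analogue of the operator recognising
  hair colour.
* **Vectorisation.** Connected components under 8-connectivity (hairs are
  thin and often diagonal); each component's polygon is the union of its
  unit pixel squares — boundaries trace pixel edges with no smoothing — so
  vector area equals pixel_count × pixel_size² exactly and area
  conservation is a hard test, not a tolerance.
* **Cleaning.** A component is kept iff ≥ 1 of its pixels is 8-adjacent to
  the root-body mask. This automates the manual deletion of false positives
  "not attached to root structures"; removals are retained in an audit list
  and logged. Cleaning is monotone (Ha can only decrease) and idempotent.
  An empty root mask removes everything and warns.

## Root length and sHa

The root-body mask (darkest classes, or a supplied annotation) is
skeletonised; endpoint spurs shorter than `prune_mm` (default 0.3 mm) are
removed so hair-induced branches do not inflate length; the geodesic
endpoint-to-endpoint path is found with diagonal steps weighted √2. Two
corrections matter numerically:

* summing per-step weights over-counts oblique digitized curves by up to
  ~8%, so the geodesic is re-measured as a chord polyline sampled every
  5 skeleton pixels;
* the medial axis stops about half a root width short of each tip, so the
  Euclidean distance-transform value at both terminal pixels is added — a
  straight band of length L then measures L, not L − width.

On a 10 mm straight band the method reads 10.01 mm; on curved synthetic
roots it is within ~3% of the analytic centerline arc. If the mask splits,
the largest component is measured with a warning. A manually annotated
polyline (mm coordinates) takes precedence when provided, mirroring how a
GIS operator would digitise length. sHa = Ha / L with L > 0 enforced.

## Germination indices and composition metrics

GERIR and GERIS follow the standard definitions (100 × germination ratio ×
organ-length ratio). S₁/S₂ are mean *shoot* lengths — the shoot index is
shoot-based by construction even though assay write-ups sometimes mislabel
the symbols. Indices are not capped at 100%: values above 100% are
informative (stimulation). Verdicts are strict (`index < threshold`), with
50% the classical convention and 70/80% stricter alternatives.

`percent_lower(a, b)` uses the reference-denominator convention
100 × (b − a)/b; relative-difference conventions vary across the
literature, so the function is explicit about its reference and the choice
is configurable by swapping arguments. Organic matter is estimated from
organic carbon with the conventional 1.724 factor (the inverse "58% carbon
in organic matter" assumption). The packaged tables cover four frass types
(Gainesville vs. whey diet × untreated vs. 70 °C/1 h) under three
preparations (solid, 1:5 "as-such" extract, 1:2 extract after equilibration
to 85% water content); censored entries (below detection) are stored as
missing, and `field_range` refuses subsets containing missing values rather
than silently dropping them.

## Synthetic micrographs

The generator emulates the content the pipeline must handle: a light noisy
background (intensity 0.85), a dark root band (0.15) of width 0.5 mm along
a sine centerline whose arc length is computed analytically, intermediate-
intensity hairs (0.50) rooted just inside the root boundary and pointing
outward with ±20° jitter, detached hair-intensity specks placed ≥ 2 px from
any root structure (so cleaning must remove exactly them), a 2 mm scale bar,
and additive Gaussian noise (σ = 0.03) clipped to [0, 1] and quantised to
8 bits. Defaults — 480×640 px at 0.02 mm/px, root segments of ~11–12 mm —
match the field of view of an 8× germinating-seed micrograph, where root
segments of roughly 10–13 mm are typical. All randomness flows from one
explicit seed; images are byte-reproducible.

What the generator does **not** model: optical blur and partial-volume
pixels at region edges, uneven illumination, colour (channels are equal, so
luminance is the identity), germination paper texture, seed bodies, and
overlapping or in-soil roots. Passing the end-to-end suite therefore shows
the measurement chain is correct and unbiased on cleanly separable imagery;
on real micrographs the class query and the hair/background contrast become
operator-dependent, and accuracy will be limited by edge blur rather than
by the machinery tested here.

## Problem sizes and numerical choices

The validation grid is 20 fixtures at 480×640 px (hair counts 10–60, sine
amplitudes 0.2–1.0 mm, 3–8 specks), chosen to span sparse to dense hair
cover; the whole grid runs in a few seconds. The enumeration oracle for the
classifier covers all instances up to n = 12, k = 4, where brute force
(≤ C(11,3) partitions) is trivially exhaustive. Acceptance-style checks on
the classifier use integer-valued samples so SSD comparisons are exact in
floating point; scale-equivariance and histogram-equivalence tests allow
1e-9 relative slack for reordered summation. Degenerate inputs are defined,
not accidental: uniform images yield one class; k larger than the number of
distinct values is an error in `jenks_breaks` but is clamped in
`reclassify` (an image cannot be made more classes than it has values); an
image whose heuristic hair query matches nothing reports Ha = 0.

## Known limitations

* Hair morphology beyond projected area (counts, lengths, density) is out
  of scope, as is any in-soil imaging.
* The attachment rule implements only "not attached to root structures";
  attached artefacts (e.g. seed fragments touching the root) would survive
  cleaning, as they would have under the criterion it automates.
* The histogram path's binned optimum is not guaranteed identical to the
  unbinned optimum for >1024 distinct intensities (float imagery); tests
  show label agreement >97% on smooth unimodal data, and `exact=True` is
  available when fidelity matters more than runtime.
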