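# Methods

## The measurement model

`mitomorph` treats a field of view as three co-registered 2D intensity
images — nuclear stain, whole-cell stain, mitochondrial marker — with a
single lateral calibration in µm/pixel. All geometry is computed on the
pixel grid with 8-connectivity for every foreground component; area is
pixel count × pixel_size², and the coordinate convention is row-major,
0-based.

### Thresholding

Every channel is binarized by two-class Otsu thresholding computed per
field: the threshold maximizes the between-class variance
w₀w₁(μ₀ − μ₁)² of the split {I ≤ t}/{I > t}, with ties broken toward the
smallest t. For integer images in [0, 255] the search is exact over the
values present; other data are histogrammed into 256 uniform bins between
the image minimum and maximum and the maximizing bin's upper edge is
returned. A constant image raises an error rather than returning an
arbitrary cut. No smoothing is applied before thresholding.

### Nuclei and cells

Nuclei are the hole-filled, 8-connected Otsu foreground components of the
nuclear channel, with components below `nuclei_min_area_um2`
(default 20 µm²) removed as debris. Nuclei touching the field border are
kept: the border policy applies to cells.

Cells are obtained by seeded geodesic propagation: the cell foreground is
the Otsu foreground of the cell channel united with all nucleus pixels,
and every foreground pixel joins the nucleus reachable by the shortest
8-connected path inside the foreground, with step weights 1 (orthogonal)
and √2 (diagonal). Distances are carried as integer step-count pairs
(n_orth, n_diag) and compared through the canonical key
n_orth + √2·n_diag, which makes comparisons exact — two distinct pairs can
never be truly equal because √2 is irrational — so the assignment is
bit-reproducible and identical to per-seed shortest-path computation.
Ties between nuclei at exactly equal distance go to the lower label.
Foreground components containing a single nucleus are assigned wholesale;
the heap search runs only where components are shared. Cells touching the
field border are removed before measurement, because partial cells bias
per-cell counts; this exclusion is recorded in the run manifest. There is
no declumping of touching nuclei and no intensity-guided propagation.

### Mitochondrial objects

Objects are 8-connected Otsu foreground components of the mitochondrial
channel with at least `mito_min_area_px` pixels (default 4, suppressing
speckle). For each object:

* area A = pixel count × pixel_size²;
* perimeter P by the 4-direction Crofton boundary-configuration
  estimator (naive boundary-pixel counting overestimates P and therefore
  depresses the form factor);
* form factor FF = 4πA/P², dimensionless (1 for a perfect circle).

An object is **fragmented** iff A < 1 µm² and FF > 0.6; both
inequalities are strict, so an object at exactly 1 µm² or exactly 0.6 is
non-fragmented. The thresholds are configurable
(`fragment_max_area_um2`, `fragment_min_form_factor`) but default to
these reference values.

### Skeleton length

Each object is thinned by topology-preserving Zhang–Suen skeletonization
(idempotent; the skeleton is a subset of the object). Length is the sum
over unique 8-adjacent skeleton-pixel pairs of the step length — 1 for
orthogonal, √2 for diagonal — times the pixel size; an isolated pixel has
length 0. This edge-sum rule is less biased for oblique filaments than a
raw pixel count; the pixel count is nevertheless exported alongside. A
cell's "average mitochondrial length" is the unweighted mean of
whole-skeleton total lengths over its objects (per-object, not
per-branch, averaging; branchpoint counts are exported as extras). Puncta
collapse to near-points, so a fragmenting network shortens the per-cell
mean.

### Relating and aggregating

Each mitochondrial object is assigned to the cell covering the majority
of its pixels; if background covers strictly more pixels than any cell
(e.g. the parent cell was removed at the border) the object is
unassigned, excluded from per-cell statistics and counted in a field
QC column. Exact ties between cells go to the lower label; a
background/cell tie goes to the cell (assignment is favoured over
discarding). Majority overlap, rather than centroid containment, is used
because blur can push filament ends across cell boundaries.

Per-cell records include cells with zero mitochondria, whose
fragmented fraction and mean length are *missing* (NaN), never zero;
aggregation ignores missing values. Summaries are two-stage: cells are
averaged within each (condition, experiment) group, then the condition
value is the unweighted mean over experiments with its across-experiment
sample SD (missing for a single experiment). Experiments are the
averaging unit, so doubling one experiment's cell count does not change
the grand mean's weighting. Within-group means are computed over sorted
values so that summaries are bit-identical under any permutation of the
input rows.

## The synthetic-field generator

The generator emulates adherent macrophage fields at high magnification:
disjoint circular cells, each with one concentric nucleus, and a
mitochondrial compartment of puncta (fragmented phenotype) and
constant-curvature filaments (networked phenotype) confined to the
cytoplasmic annulus, mutually separated by ≥3 px so truth objects never
merge. Channels are rendered as background/foreground intensity levels,
blurred with a Gaussian PSF proxy, and corrupted by Poisson shot noise
(gain-scaled) plus additive Gaussian read noise. Ground truth — label
maps, per-object class, per-cell counts, per-object lengths — is recorded
before blur and noise.

Defaults (all configurable) and their rationale:

| parameter | default | rationale |
| --- | --- | --- |
| pixel_size_um | 0.1 µm/px | plausible for a 100×/1.4 NA oil objective with a standard camera |
| field_shape | 640 × 640 px | 64 µm field holding ~10 cells |
| cell radius | 60 ± 4 px | ≈12 µm diameter adherent macrophage |
| nucleus radius | 32 ± 2 px | ≈6.4 µm diameter; area ≈32 µm², safely above the 20 µm² debris floor |
| n_mito_per_cell | 15 | moderate per-cell organelle count at this scale |
| frag_fraction | 0.5 | probability an object is rendered as a punctum |
| punctum_radius_um | 0.4 µm | truth area πr² ≈ 0.5 µm², below the 1 µm² cut |
| filament_length_um | 2.5 µm (σ = 15%) | µm-scale tubule; sampled lengths are floored at 5× width so filaments stay geometrically separable from puncta |
| filament_width_px | 3 px | ≈0.3 µm tubule diameter |
| curvature | uniform ± 0.04 rad/px | gentle bending without self-overlap |
| blur_sigma_px | 1.0 px | PSF proxy comparable to the diffraction limit at this sampling |
| noise_gain / read SD | 2.0 / 8.0 | shot + read noise that stresses Otsu without defeating it |

Radii are sampled normally and clipped to ±2 SD; cell placement uses
rejection sampling with a bounded retry budget and fails loudly, naming
the density, when the requested cells cannot fit. Each cell receives
round(n_mito_per_cell) objects; an object that cannot be placed after its
retry budget in a crowded cell is dropped (the truth tables reflect what
was actually rendered). Puncta are anti-aliased disks binarized at 0.5,
so truth areas stay analytic (πr²) to within a one-pixel boundary band.
All randomness flows from a single integer seed; identical
(config, seed) pairs are bit-identical.

What the generator does **not** emulate: 3D structure and defocus,
time-lapse dynamics and photobleaching, chromatic aberration and channel
misregistration, illumination gradients, touching/overlapping cells,
intensity heterogeneity within organelles, and bulb-like swollen
mitochondria. Passing recovery tests therefore shows the measurement
chain is correct under the stated degradations, not that segmentation is
robust to every real-microscope artifact — per-cell counts on real data
still warrant visual QC of the masks (`--save-masks`).

## Numerical choices and degenerate inputs

* Otsu ties → smallest threshold; constant images are errors.
* Geodesic ties → lower nucleus label, exactly (integer step-count keys).
* Relate ties → lower cell label; background plurality → unassigned.
* Empty masks, empty nuclei maps, dangling object ids, duplicate cell
  rows and zero-cell experiments raise errors naming the offender rather
  than degrading silently.
* Ratios over zero denominators are NaN and are skipped by averages.
* The pipeline's outputs are byte-deterministic for fixed inputs and
  config; the manifest carries no timestamps.

## Problem sizes used in validation

The bundled checks run on synthetic fields of 640×640 px with 10 cells
and ~15 objects per cell: 4 fields per fragmentation level across five
levels for recovery, and 2 fields per condition per replicate across five
replicates for the mock-vs-stimulated contrast. These sizes give several
hundred objects per readout (binomial SE of a recovered fraction
≈ 0.02), well inside the ±0.10 recovery tolerance, while keeping a full
validation run around a minute on one CPU.

## Known limitations

* The "average length" convention (per-object within cell) is one of
  several defensible readings; per-branch averaging would differ for
  highly branched networks.
* Strict inequalities at exactly 1 µm² / 0.6 are a convention; objects
  landing exactly on a boundary are vanishingly rare on real data but
  the choice is documented and fixed.
* Touching nuclei are not declumped; heavily confluent fields will
  under-segment.
* The mitochondrial channel threshold is per-field Otsu; fields with
  almost no mitochondrial signal can threshold on noise (mitigated by
  the minimum object size, but not eliminated).
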