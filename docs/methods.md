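# Methods

This note documents the models, parameter choices and numerical conventions
behind `spatialtme`, and what the synthetic-data experiments do and do not
demonstrate about real tissue.

## Cell tables and units

All coordinates are in μm with the origin at the top-left of the image
frame and 1 px = 1 μm, the native resolution of rasterized IMC
acquisitions. A cell table carries `cell_id`, `image_id`, `patient_id`,
`x_um`, `y_um`, plus marker intensity columns (`marker__*`) and/or type
annotations. Densities are cells/mm²; areas in mm²; graph distances in
hops; percentages on 0–100.

## Synthetic tissue generator

The generator emulates the geometry of a TMA-based IMC study: one circular
1.5 mm core per tumor region, several regions per patient (1–8,
configurable). Each core contains irregular tumor-nest blobs — jittered-
radius star polygons built from low-order harmonic perturbations (default
3 nests, radii 120–280 μm, irregularity 0.25), clipped to the disc — with
everything else stroma. Cells are placed by dart throwing: per
(class, compartment) a Poisson count around `area × target density` is
drawn and positions are sampled uniformly within the compartment subject
to a **4 μm minimum spacing** (an approximate nuclear exclusion radius
that also removes zero-distance ties from k-NN constructions). Densities
whose expectation exceeds 55% of the hexagonal packing bound are rejected
as infeasible.

Marker intensities follow a two-component log-normal model: log-intensity
N(0, 0.35²) for negative cells and N(log 10, 0.35²) for positive cells
(10× separation), with the generating component recorded as the true
positivity flag. This gives the mixture-based positivity caller a
nontrivial but recoverable signal.

Two sources of count variability are modeled: Poisson sampling noise and a
per-core lognormal multiplier on each (class, compartment) density with
**CV = 0.15**. The multiplier represents residual between-region
biological variability *within* a TME archetype; the archetypes themselves
carry the between-class variability. With this CV the robust z-scores of
the planted cohorts span roughly ±8, comparable to z-score heatmaps of
real IMC cohorts.

The four planted TME archetypes differ in TIL (CD8 + CD4 + B),
macrophage and neutrophil densities per compartment, with contrasts of
roughly 3–10× between classes (e.g. TIL tumor-nest density 300 / 60 / 30 /
100 cells/mm² for the high / excluded / low / neutrophil archetypes, TIL
stroma 350 / 700 / 60 / 140). B cells are stromal-only, as they are in
real NSCLC tissue. Recovery cohorts plant the classes with *unbalanced*
proportions (excluded and immune-low most frequent), as real cohorts are
unbalanced; this is also what gives the consensus ΔAUC diagnostic its
characteristic peak at k = 4 — with four equally frequent, well-separated
classes the cluster hierarchy splits off one class per k and the CDF-area
gain necessarily shrinks with k.

Barrier planting covers a contiguous random arc of each nest boundary
(fraction = coverage) with αSMA⁺ fibroblasts at ~5 μm spacing in layers
filling the band thickness (default 10 μm). Community planting divides the
core into equal angular sectors with sector-specific composition profiles,
realized by thinning a homogeneous Poisson process, so realized counts
remain exactly Poisson.

**What the generator does not model:** nuclear/membrane texture, raw
multichannel images, segmentation errors, spillover, spatially correlated
marker noise, gradual (non-sector) community boundaries, vascular trees,
or necrosis. Passing recovery tests therefore demonstrates correctness of
the estimators under idealized geometry, not robustness to segmentation or
staining artifacts.

## Phenotyping

Positivity: per marker, a 2-component Gaussian mixture on log intensities;
the threshold is the intensity at which the posterior of the high
component crosses 0.5 (scanned on a 513-point grid between the component
means). Degenerate fits — component separation below 1 SD or a component
weight below 1% — fall back to the 0.9 quantile. Constant columns yield no
positives and a warning. Because calls are `intensity > threshold`,
positivity is monotone in intensity.

Lineage scoring: for lineage L with marker set M_L, score = (#required
positive) − (#required negative) − (#positive lineage-defining markers
outside M_L). Ties break toward the larger marker set (most specific),
then panel order; non-positive best scores give `unassigned`. The
missing-marker penalty is what lets a CD45-only cell land in the
leukocyte catch-all rather than a specific T-cell lineage.

Subtype rules are (parents, required-positive, required-negative) triples;
the largest required-positive set wins, ties in table order; unmatched
cells keep their lineage label, so final labels always partition the
cells. Pathology masks act on cell centers only.

On default generator cores the full pipeline recovers ~99.5% of
generating classes (the residual errors are marker-noise flips).

## Densities and robust z

Compartment areas come from the mask (or, for synthetic data, the nest
geometry); background contributes neither cells nor area. The `total`
compartment uses summed counts over summed areas, so count conservation
holds exactly. Robust z-scores use MAD **without** the 1.4826 Gaussian
consistency factor by default — the plain median/MAD convention — with the
factor available as an option; zero-MAD columns are flagged and returned
as zeros.

## TME consensus classification

Consensus clustering: `reps` = 1,000 (250 in the test suite, which is
indistinguishable at these separations) subsamples of 75% of cores,
hierarchical clustering of the Chebyshev (maximum-coordinate) distance
matrix with Ward linkage — Ward applied to a non-Euclidean dissimilarity,
i.e. the `ward.D` convention. Consensus(i,j) = co-clustered/co-sampled;
pairs never co-sampled (possible only at very small n) are set to 0.5 with
a warning. Final labels per k come from Ward clustering of 1 − consensus.
The model-selection diagnostic is the CDF area A(k) of the consensus
values and its **relative** increment ΔAUC(k) = (A(k) − A(k−1)) / A(k−1)
(the consensus-clustering delta-area-plot convention), with A(k_min)
reported at the smallest k. k is fixed at 4 by default; the diagnostic is
reported, not used to pick k. Each k requires at least 2k cores.

Cluster → class naming uses the cluster means of the criterion scores:
highest neutrophil-proportion z → *TS:Neutrophil high*; of the rest,
highest nest TIL/MΦ z → *TS:TIL+MΦ high*; lowest nest immune z →
*TS:Immune low*; remainder → *T:TIL+MΦ excluded*.

Criterion scores take the **max** over the z-scored features of a group
("TIL *or* macrophage"): `til_mac_nest`, `til_mac_stroma`, `immune_nest`,
and the neutrophil proportion of all cells per compartment (robust-z, max
over compartments). Cutoffs are the equal-sensitivity/specificity ROC
point: candidates are midpoints between consecutive distinct scores,
|sens − spec| is minimized, and ties resolve to the midpoint of the
optimal candidate interval. With one predictor a logistic model is
monotone in the raw score, so the raw score is thresholded directly; the
direction flag records whether in-class scores are high or low. The
high / low / neutrophil criteria contrast each cluster against all others;
the excluded criteria are pairwise by construction — nest score below the
*high* cluster's boundary and stroma score above the *immune-low*
cluster's — because that is what defines the excluded phenotype. Cores
failing their cluster's criteria are `undefined`; on planted cohorts at
the default effect sizes the undefined rate is a few percent and label
recovery exceeds 95%.

## Communities

Windows contain **W = 10 cells total including the center** (the
window-size sweep 2/5/10/15/20 is supported); neighbor ties at equal
distance break by cell id. Eligible types default to those averaging ≥ 10
cells per core, excluding unassigned/ambiguous cells; cores with fewer
than W eligible cells are skipped with a warning. Mini-batch k-means
(batch 1024, 3 restarts, fixed seed) clusters the pooled windows; the
elbow k* maximizes the second difference of the distortion (inertia)
curve, the discrete-curvature reading of an "elbow locator". Subsampling
concordance refits on one third of the windows (3 repetitions), matches
labels by solving the assignment problem on the confusion matrix, and
reports per-repetition agreement plus the median.

Enrichment compares, per core, a type's share within a community against
its share in the rest of the core, with a patient random intercept
(linear mixed model, Wald test). Cores lacking the community contribute 0,
not a missing value. When the variance component collapses the fit
degenerates to the ordinary fixed-effect comparison, which is the same
test at zero random-effect variance; under shuffled labels the p-values
are uniform (KS-checked in the test suite).

## Barrier score

Tumor-cell spatial clusters: DBSCAN, eps = 25 μm, min 3 cells; boundaries
from shapely's concave hull (ratio 0.3) with a convex-hull fallback for
degenerate geometries; areas in μm². Only tumor cells in clusters
≥ 2,000 μm² are path targets, and the same eligibility applies to the
adjacency test for counted fibroblasts — a barrier around a handful of
scattered tumor cells is not a macroscopic barrier.

The cell graph connects each cell to its 5 nearest neighbors
(mutualized/undirected). For each non-perivascular CD8 T cell, BFS gives
hop distances; all eligible tumor cells at the minimal distance are
scored. Among equal-length shortest paths to the *same* tumor cell one
canonical path is scored: each node's predecessor is its
smallest-id neighbor on the previous BFS level, making the choice
deterministic and independent of row order. A counted fibroblast is a
non-perivascular αSMA⁺ fibroblast adjacent to ≥ 1 eligible tumor cell.
Indicator mode (default) scores a path 1 if any counted fibroblast lies
on it; count mode reports the number. Per-cell score = mean over the tied
nearest-target paths; per-core = mean over CD8 T cells. Indicator scores
live in [0, 1] and are invariant to rigid transforms of the coordinates.
Both modes are exposed because "presence on the path" and "number along
the path" are both defensible readings of fibroblast interposition;
indicator is the default as the directly interpretable fraction-screened.

## Interaction testing

Without segmentation masks, contact is a centroid rule: neighbors iff
centroid distance ≤ 5 μm + r_i + r_j, with per-cell radii from an
`area_um2` column when present, else a fixed 5 μm equivalent radius — a
table-level surrogate for mask dilation. The per-image statistic for an
ordered pair (A, B) is the mean count of B neighbors over A cells; labels
are permuted over fixed positions (n_perm = 1,000 default, one shared
permutation per repetition), and p = (1 + #{perm ≥ obs}) / (n_perm + 1)
(add-one, so never exactly 0). Interaction / avoidance at p ≤ α = 0.05 in
the respective tail. The statistic is discrete; at sparse densities tie
mass makes the p-values conservative, while at realistic tissue densities
(thousands of cells per mm²) they are uniform under complete spatial
randomness to KS precision.

Cross-core aggregation models the binary presence of a relation per core
with a logistic GEE clustered on patient (exchangeable working
correlation) — the marginal counterpart of a patient random intercept,
chosen for stable small-sample behavior — against the group indicator,
with BH adjustment across pairs. Pairs are reported only when testable in
≥ 90% of cores; all-0/all-1 outcomes are flagged without an estimate.
These p-values are discrete (binary outcomes over tens of cores carry an
atom at p = 1 when group frequencies tie exactly), so their null behavior
is validated by false-positive rate rather than KS uniformity.

## Heterogeneity statistics

ITH score: z-score each feature across the cohort → SD across each
multi-core patient's cores → mean over patients → z-score across features
(mean 0, SD 1 by construction; invariant to feature order).

Class-homogeneity bootstrap: per iteration and per n ∈ {2, 3, 4}, each
tumor having the class in any core contributes n cores drawn **with
replacement** (also when it has fewer than n cores); the ratio of
all-same-class tumors to tumors-having-the-class is averaged over
iterations, then over n. Averaging ratios first over iterations and then
over n is the documented order; at these sizes the alternative order
differs only in Monte-Carlo noise. The ITH probability is the complement.

TAN: high iff tTAN or sTAN exceeds its histology-specific cutoff
(diagnostic-slide defaults LUAD 2%/1%, LUSC 3%/2%); cutoffs can be
re-derived from a TME reference with the same equal-error ROC machinery as
the TME criteria. TMB: muts/Mb with high at ≥ 10, boundary inclusive.
Subclonal expansion: max per-region CCF over leaf clones; a single-node
tree's root is terminal.

## Problem sizes and determinism

The test suite and acceptance script run on cohorts of 64 cores
(16 patients × 4), single default cores of ~2,500 cells, 500-simulation
null calibrations, and 1,000-iteration bootstraps — sizes at which every
planted effect is recovered with comfortable margins and the whole suite
completes in a few minutes. All randomness flows from explicit seeds;
identical seed + config reproduce outputs byte-for-byte.

## Known limitations

- Positivity calling is per-marker and ignores cluster-level context; it
  will not reproduce probabilistic phenotyping on borderline populations.
- The compartment classifier is out of scope: masks (or the generator's
  geometry) are inputs.
- Consensus clustering at very small cohorts (< 2k cores per candidate k)
  is refused rather than approximated.
- The GEE aggregation estimates marginal, not subject-specific, odds
  ratios; with very few patients its sandwich errors are anti-conservative.
- Survival modeling, sequencing-derived analyses (beyond the TMB/CCF
  utilities) and raw-image processing are deliberately not implemented.
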