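# Methods

## Shape representations

**Landmarks.** A leaf is an ordered configuration of 15 homologous points:
the petiolar junction (landmark 1), vein bases and the distal branch point
(2–6), the apex (7), lobe tips (8–11) and sinuses (12–15). Only landmarks
1–6 have a fixed anatomical reading in the package; the identities of the
remaining points are metadata carried by the polygon spec, not code, because
different landmarking schemes place them differently.

**Generalized Procrustes analysis.** Configurations are centred, scaled to
unit centroid size (root summed squared distances to the centroid), and
iteratively rotated onto the evolving mean until the mean moves less than
`tol = 1e-8` (root-summed-squares), with `max_iter = 100`. Reflection is
allowed by default and exposed as a flag; the optimal orthogonal map comes
from the SVD of the cross-covariance, with a determinant correction when
reflections are forbidden. A GPA solution is defined only up to one global
rotation; for reproducibility the converged mean is rotated onto the first
input configuration. The reported Procrustes distance is the partial
(unit-size, no residual rescaling) superimposition residual.

**Elliptical Fourier descriptors.** Binary masks are traced with
Moore-neighbour boundary following (deterministic start: left-most pixel of
the top-most foreground row; output forced counter-clockwise). The chain
code — unit steps for even codes, sqrt(2) for odd — is the piecewise-linear
arc-length parameterization of the contour, and the per-harmonic
coefficients are its exact segment-wise integrals (the Kuhl–Giardina closed
form); the same closed form serves arbitrary closed polylines, which is how
the pipeline computes EFDs from spline outlines without rasterising.
Normalization uses the first-harmonic ellipse: the starting point moves to a
semi-major-axis tip, the contour rotates so that axis lies on +x, and all
coefficients divide by the semi-major axis length, leaving a_1 = 1,
b_1 = c_1 = 0. The semi-major axis has two tips; the half-period ambiguity
is broken by choosing the orientation whose reconstructed point at parameter
zero has the larger x-coordinate. This tie-break is deterministic but not
guaranteed to match SHAPE's undocumented choice, so bit-compatibility with
legacy `.nef` files is not promised — only the invariance properties
(rotation, scale, starting point, to 1e-6).

A consequence of arc-length parameterization worth knowing: the normalized
d_1 of a geometric 2:1 ellipse is ≈ 0.587, not 0.5 — the 0.5 would arise
only under a uniform-angle parameterization, which chain codes do not
realise. The tests pin this value against an independent continuous oracle.

## Subareas and allometry

The shipped polygon spec (`leafmorph/data/polygon_spec.yaml`) tiles the
whole-leaf polygon into four subregions whose every internal edge is shared
by exactly two polygons, so the shoelace subareas sum to the total area
identically — provided each polygon is simple and positively oriented on the
given configuration. Leaves violating that condition (possible under heavy
landmark noise, since the vein polygons are thin) are flagged and excluded
from closure assertions and fits. The exact vertex lists are an assumption:
published figures define the subregions graphically, so the spec is
configuration a user can replace.

Allometry is OLS of sqrt(subarea) on sqrt(total area) per subregion, overall
or per species, requiring ≥ 3 leaves and non-constant total area per group;
confidence bands are pointwise 95% intervals from the OLS covariance.
Zero-area subregions enter as sqrt(0) = 0 rather than being dropped.

## Effect decomposition

Each trait column — 30 aligned coordinates plus 4H EFD coefficients — is fit
independently by OLS with the design `1 + species + node + species:node`,
treatment-coded against a reference species (alphabetically first by
default, overridable). Node is a numeric covariate, not a factor: the
heteroblasty effect is one slope and each non-reference species has one
interaction slope, which is what a single-row-per-term heatmap requires.
The decomposition is estimation-only; no sums-of-squares table is produced
because the downstream product is the signed effect magnitudes. Constant
trait columns (the normalization-fixed a_1, b_1, c_1) are flagged and fitted
as structural zeros; species observed at a single node value have their
coefficients marked non-estimable (NaN). All columns share one design
matrix, so the fit is a single multi-RHS least-squares solve; a unit test
checks coefficient and standard-error agreement with statsmodels OLS.
Trait ordering for heatmaps is complete-linkage agglomerative clustering on
Euclidean distances between effect profiles (scipy linkage; ties broken by
input index).

## Discrimination and variability

Per node, every leaf is assigned by an LDA trained on the node's remaining
leaves: Gaussian classes, pooled within-class covariance, priors
proportional to training counts (configurable to uniform in principle — the
count-prior default matches the reference R behaviour). With more features
than leaves the pooled covariance is singular and receives a ridge
`eps = 1e-8 * trace / p`, warned once. Species with fewer than two leaves at
a node are excluded from that node (a declared rule — the source analyses do
not state one), and near-constant features (variance < 1e-12) are dropped
before fitting. Variability is the sample SD (n−1) of each trait over all
leaves of a node, pooled across species.

## Trajectories

The embedding contract is method-agnostic: any deterministic-under-seed 2-D
embedding that co-locates duplicate rows qualifies. The default is t-SNE at
perplexity 40 (auto-reduced with a warning when n < 3·perplexity + 1); a PCA
projection is available where exact determinism and speed matter. Vine
vectors run from the first to the last *sampled* node (vines may have gaps).
The convergence statistic is mean pairwise Euclidean distance among vector
bases over the same among tips — mean pairwise distance rather than variance
because it is robust to the arbitrary scale of t-SNE embeddings.

## The synthetic generator

The generator emulates the study design: `n_species = 8` x
`vines_per_species = 5` x `nodes_per_vine = 10` as a desk-scale stand-in for
~40 species x 1–13 vines x 10 nodes. A leaf at node k of species s is

    P = (size_base + size_gain * k) * (J + w_s(k) * D_s + noise)

with `juvenile_weight w0 = 0.1` at node 1, a logistic transition
(`rate = 1.5` ± 30% per species, inflection at node 3 — the change
concentrates early in the series, which is what saturating heteroblastic
change looks like), per-landmark isotropic Gaussian noise
(`shape_noise_sd = 0.02` in mean-shape units, comfortably above the
node-1 between-species separation w0·|D| and below the adult separation
|D|), and linear size growth (`size_base = 1`, `size_gain = 0.25` per node).
A `trajectory="linear"` mode makes w exactly affine in k so that the
trait-model coefficients have closed-form generating values.

Species directions D_s are built from a lobing field (sinuses cut inward,
lobe tips push outward) scaled by a per-species depth spread over
`±lobing_spread = ±0.55`, plus per-species boundary jitter (sd 0.02), then
centred so the mean direction across species is zero. Species labels are
assigned flattest-first, so the default reference species has an almost flat
trajectory — mirroring the convenient choice of a round-leaved reference —
and the fitted magnitude ordering |species| > |interaction| > |heteroblasty|
is a structural property of the design, not of one seed.

**Built-in exact allometry.** The blade/vein slope parameters
(`blade_slope = 0.68 > vein_slope = 0.20`) are normalised into subarea
fractions f_i (two blades, two veins, summing to 1). The juvenile template's
interior landmarks are solved so each subregion carries exactly f_i of the
total area (three 1-D affine roots, since the shoelace form is linear in any
single coordinate). Each species direction then receives a minimum-norm
correction, spread over all 30 coordinates by a Gauss–Newton iteration,
enforcing proportionality of the mixed shoelace form B_i(J, D) = f_i·B_T and
of the pure form A_i(D) = f_i·A_T(D). Because the shoelace area is
quadratic, these two conditions make A_i(J + wD) = f_i·A_total(J + wD) for
*every* w, so noise-free sqrt-subarea regressions are lines through the
origin with slope exactly sqrt(f_i), per species, at machine precision.

What the generator does **not** emulate: per-species differences in
allometric slope (the shared juvenile forces shared fractions, so all
species lie on the same generating lines — real species vary, some
bimodally); scanning artefacts, petioles, damaged or missing leaves;
asymmetry beyond the per-species jitter; and any venation structure beyond
the landmark skeleton. Passing tests therefore demonstrate that the
analysis chain recovers the structure it targets when that structure is
present — not that real scans are this clean.

Outlines are periodic cubic splines through the ten boundary landmarks
(interpolating at smoothing 0); masks are rasterised at a chosen resolution
with half-pixel centring so pixel counts are area-consistent to ~2% at
resolution ≥ 100. One root seed drives species construction and noise
through separate substreams, and the pipeline derives per-stage seeds by
hashing stage names, so adding a stage never perturbs earlier streams.

## Numerical choices and degenerate inputs

- Harmonic count defaults to H = 20 (configurable); traits use 4H
  coefficients with the three normalization-fixed ones dropped.
- GPA objective is non-increasing across iterations; alignment agreement
  with an independent alternating-minimization oracle is tested to 1e-6 on
  10 configurations.
- Degenerate inputs fail loudly: coincident landmarks (no centroid size),
  chains shorter than 8 moves, masks with zero or several components,
  degenerate first harmonics, self-intersecting outlines at rasterisation.
- Node renumbering (tip-first ↔ base-first) maps node k to
  max(node in vine) − k + 1 per vine; it is an involution whenever numbering
  starts at 1, which both conventions guarantee.

## Problem sizes in the test suite

Unit tests run on handfuls of configurations; the end-to-end checks use the
default 400-leaf design (and one 1,000-leaf run for closure), 10 generator
seeds for the discrimination and trajectory orderings, and t-SNE on 400x107
trait matrices — sizes chosen so the full suite completes in a couple of
minutes on one CPU while leaving every ordering test with a clear margin.
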