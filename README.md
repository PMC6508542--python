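# leafmorph

Geometric morphometrics of **heteroblastic leaf series** — the node-to-node
change in leaf shape along a shoot produced by the temporal development of the
shoot apical meristem. The package quantifies how divergent leaf shapes
between species (the motivating system is *Passiflora*, whose vines run from
round juvenile leaves to deeply lobed adult ones) arise from a shared
juvenile form, using two complementary shape representations:

- **Landmarks** — 15 homologous (x, y) points per leaf (petiolar junction,
  vein bases, lobe tips, sinuses), placed in a common shape space by
  generalized Procrustes analysis (GPA): translation, unit centroid-size
  scaling, rotation, and optionally reflection are removed by iterative
  superimposition onto the evolving mean shape.
- **Elliptical Fourier Descriptors (EFDs)** — a binary leaf mask is traced to
  an 8-connected Freeman chain code, the contour's x(t), y(t) arc-length
  parameterization is decomposed into per-harmonic quadruples
  (a_n, b_n, c_n, d_n) following Kuhl & Giardina, and the first-harmonic
  ellipse normalizes size, rotation and starting point (a_1 = 1,
  b_1 = c_1 = 0). SHAPE-dialect `.nef` files are read and written.

On top of these representations the package implements the study's analysis
chain:

1. **Subarea allometry** — each aligned leaf is tiled into distal blade,
   proximal blade, midvein and proximal-vein polygons (shoelace areas; the
   shipped polygon spec tiles the leaf exactly, so subareas sum to the total);
   OLS of `sqrt(subarea) ~ sqrt(total area)` with 95% confidence bands,
   overall or per species.
2. **Effect decomposition** — per trait (aligned coordinates and EFD
   coefficients), the linear model `trait ~ species * node` with treatment
   coding: species main effects, a single heteroblasty (node) slope, and
   species x node interaction slopes, relative to a reference species whose
   effects are structural zeros.
3. **Per-node discrimination** — leave-one-out linear discriminant analysis
   (pooled within-class covariance, count priors) assigning each leaf to a
   species using only leaves of the same node, plus per-node trait standard
   deviations.
4. **Trajectories** — t-SNE (perplexity 40) embedding of all leaves; each
   vine becomes a vector from its first to its last sampled node; the
   base/tip mean-pairwise-distance ratio quantifies juvenile convergence.

A **synthetic generator** (`leafmorph.synthetic`) produces heteroblastic leaf
series with known ground truth — a shared juvenile configuration J,
species-specific adult shapes M_s = J + D_s reached along logistic
trajectories w_s(k), allometric size growth, and exact built-in subarea
allometry — so every stage of the chain can be tested against generating
values.

## Worked example

```python
from leafmorph import SimParams, generate_dataset, build_trait_matrix, TraitEffectsModel
from leafmorph.allometry import collection_subareas, fit_allometry
from leafmorph.procrustes import align_collection
from leafmorph.discrimination import node_discrimination_table
from leafmorph.trajectories import embed_2d, vine_vectors, convergence_stat

coll, truth = generate_dataset(SimParams(seed=17))   # 8 species x 5 vines x 10 nodes
aligned, gpa_result = align_collection(coll)

fits = fit_allometry(collection_subareas(aligned), group_by="overall")
print(fits.summary())

traits = build_trait_matrix(coll, n_harmonics=20).informative()
print(TraitEffectsModel(traits).fit().summary())

table = node_discrimination_table(traits)
print({r.node: round(r.average, 2) for r in table})

emb = embed_2d(traits, perplexity=40, seed=17)
base, tip, ratio = convergence_stat(vine_vectors(emb, coll))
print(f"base dispersion {base:.2f}, tip dispersion {tip:.2f}, ratio {ratio:.2f}")
```

prints

```
Allometric fits (grouped by overall)
==============================================
     overall distal_blade    slope=0.6245 (se 0.0297)  R2=0.546  n=369
     overall proximal_blade  slope=0.6934 (se 0.0317)  R2=0.565  n=369
     overall midvein         slope=0.1321 (se 0.0406)  R2=0.028  n=369
     overall proximal_vein   slope=0.3992 (se 0.0866)  R2=0.055  n=369
Trait effect decomposition: trait ~ species * node
reference species: sp01
traits fitted: 107
species labels: 8

mean |effect| across traits:
  species      0.00451
  interaction  0.00127
  heteroblasty 0.00063
{1: 0.03, 2: 0.15, 3: 0.65, 4: 0.72, 5: 0.82, 6: 0.83, 7: 0.93, 8: 0.78, 9: 0.75, 10: 0.75}
base dispersion 8.44, tip dispersion 18.10, ratio 0.47
```

Reading the numbers: blade subareas expand faster than vein subareas with
overall leaf size (slopes 0.62–0.69 vs 0.13–0.40); species effects dominate
the interaction effects, which in turn dominate the plain heteroblasty
effect; leaves from node 1 are almost impossible to assign to a species
(3% correct, chance is 12.5%) while later nodes reach 75–93%; and vine
vectors start from a region of shape space half as dispersed as where they
end (ratio 0.47) — divergent trajectories out of a shared juvenile shape.

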