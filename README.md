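# svrlsm — multivariate lesion-symptom mapping with permutation inference

`svrlsm` implements support-vector-regression lesion-symptom mapping for
stroke cohorts at two spatial levels, plus the graph analyses built on top
of them:

* **SVR-VLSM** (voxel level): relates per-voxel lesion status across
  subjects to a behavioral residual score using a multivariate SVR over all
  included voxels at once;
* **SVR-CLSM** (edge level): applies the same machinery to node-pair
  *disconnection* values — the proportional loss of structural
  connectivity inferred by intersecting each lesion with a reference
  shortest-path tractography atlas;
* **maximally disconnected subgraph** extraction over the significant
  edges, node-level disconnection counts, and a post-hoc seed-node
  screening with three sequential criteria.

It is aimed at researchers in stroke neuropsychology (the motivating case
is limb apraxia: impaired tool-use gesturing after left-hemisphere stroke,
controlled for meaningless-gesture imitation) and at method developers who
need a fully seeded, synthetic test bed for lesion-symptom mapping
pipelines.

## The method

For each analysis a behavioral residual is formed by OLS: the primary
score is regressed on a control score (tool-use on imitation; right-hand
grip on left-hand grip), isolating variance unique to the primary ability.
Features are either the binary lesion matrix over voxels lesioned in at
least 10% of subjects — scaled per subject by 1/√(lesion volume), the
*direct total lesion volume control* (dTLVC), so every lesion vector has
unit norm — or the edge-disconnection matrix over edges disconnected in at
least 10% of subjects, residualized on three nuisance factors (cumulative
disconnection of the regions flagged by the voxel analysis, total lesion
volume, months post-stroke).

An epsilon-insensitive SVR (Gaussian kernel, kernel scale σ = 1, so
K(x,y) = exp(−‖x−y‖²/σ²)) is fitted under 5-fold cross-validation; the
five fold maps of back-projected feature weights **w** = Xᵀα are averaged.
Significance is assessed by a Monte-Carlo permutation scheme: the
behavioral vector is shuffled across subjects (10,000 iterations at full
scale), the whole cross-validated map is recomputed each time, and each
feature is z-scored against its null mean and SD:

    z_j = (w_true,j − mean_null,j) / sd_null,j

Maps are thresholded one-tailed at z < −1.65 (P < 0.05); voxel clusters
below a contiguity extent criterion (500 voxels at 1 mm³ resolution,
rescaled for toy grids) are discarded. Disconnection of a node pair (i, j)
is, per reference subject r,

    loss_r(i, j) = Σ_{v ∈ lesion} p_r(v) / Σ_v p_r(v)

averaged over reference subjects, where p_r is the pair's path-visitation
probability map. The maximally disconnected subgraph is the connected
subgraph of surviving edges with the greatest total |z| (with positive
weights this is the best connected component; an exact and a greedy solver
are provided and cross-checked).

Because real cohort lesions are not publicly archivable, the package
ships a first-class synthetic module: seeded parcellations, reference path
atlases, contiguous lesion blobs with log-normal volumes, and behavioral
scores with planted voxel/edge effects — everything needed to validate
calibration and recovery end to end. A 57-row behavioral table from the
motivating cohort is packaged for the behavior-level statistics.

## Worked example

```python
from svrlsm import RunConfig, SvrConfig, run_full_pipeline, simulate_inputs

parcellation, atlas, model, lesions, behavior = simulate_inputs(seed=5)
config = RunConfig(analysis="tool_use",
                   svr=SvrConfig(n_permutations=500, seed=5), seed=5)
result = run_full_pipeline(config, parcellation, atlas, lesions, behavior)
```

This generates a 57-subject synthetic study on a 32³ grid with 12 nodes
(planted effects on one "parietal" target node and on the edge (2, 4)),
then runs behavior preparation → SVR-VLSM → localizer extraction →
disconnectomes → nuisance regression → SVR-CLSM → subgraph. Printing the
headline fields gives:

```
subjects: 57, r(tool-use, imitation) = 0.44
cluster 1: 1821 voxels, peak z = -3.70
cluster 2: 15 voxels, peak z = -2.19
localizer nodes: [2, 3, 4, 7, 10, 11, 12]
significant edges: 6
subgraph nodes: [1, 2, 3, 4, 7, 10, 12], total |z| = 13.1
most-disconnected node: node_03 (3 surviving edges)
```

The primary/control correlation (0.44) reflects the generator's
lesion-severity channel; the dominant 1,821-voxel cluster sits on the
planted target region; and the planted edge (2, 4) survives into the
maximally disconnected subgraph. With `config.outdir` set, every stage
writes TSV/NIfTI artifacts plus a JSON manifest (seeds, config hash) that
makes reruns byte-identical.

The same stages are available from the shell:

```sh
svrlsm simulate --seed 5 --out study/
svrlsm run-all --analysis tool_use --permutations 500 --seed 5 --out out/
```

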