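# morphdrift

A tested, reusable pipeline from raw 3D skull landmarks to an
evolutionary-mode verdict: Procrustes superimposition with object-symmetry
correction, permutation-based shape ANCOVA and PCA, phenotypic covariance
(P-matrix) construction from interlandmark distances, random-skewers matrix
comparison, and a simulation-based multivariate drift test
(divergence ~ MVN(0, P·t/Ne)) that discriminates genetic drift from
directional selection between two temporal samples.

## Layout

| module | role |
| --- | --- |
| `morphdrift.morphio` | TPS / long-CSV landmark I/O, metadata join, template validation |
| `morphdrift.superimpose` | OPA/GPA, reflect-relabel symmetry decomposition, TPS imputation of missing landmarks, dorsal/ventral view merging, centroid size |
| `morphdrift.shapestats` | sequential-SS (type I) RRPP linear models with Goodall F, nested-model comparison, homogeneity of slopes, digitizing-error %, shape PCA |
| `morphdrift.traitcov` | interlandmark-distance traits (bilateral averaging), P-matrices, random skewers |
| `morphdrift.driftmode` | generation arithmetic and the multivariate drift test |
| `morphdrift.synthgen` | synthetic landmark datasets and drift/selection trait populations with known ground truth |
| `morphdrift.templates` | stand-in cranium (43 landmarks, dorsal 18 / ventral 30 / 5 common) and mandible (15) templates |
| `morphdrift.cli` | pipeline orchestration (`morphdrift` console script) |

The shipped templates reproduce the structural counts of the study system
(landmark numbers, bilateral pairing, view membership) but their geometry
and distance-trait list are documented stand-ins; real anatomical
definitions live in supplementary material not distributed here.

## CLI

```bash
# full pipeline on a simulated demo dataset
morphdrift all --config run.yaml
# or stage by stage
morphdrift align --config run.yaml
morphdrift drift --config run.yaml --t 370 --ne 24905 --seed 1
```

A minimal `run.yaml`:

```yaml
outdir: out
seed: 1
n_perm: 1000      # RRPP permutations
n_vectors: 1000   # random skewers
t: 370            # generations between periods
ne: 24905         # effective population size
n_sim: 1000       # drift simulations
n_boot: 1000      # bootstrap resamples of the observed divergence
```

Point `landmarks:` / `metadata:` / `template:` at your own TPS or long-CSV
data to skip the simulated demo. Every run writes the intermediates
(aligned shapes, ANOVA tables, PCA scores, trait matrix, P-matrices,
skewers and drift JSON) plus a `manifest.json` with the seed, config echo,
per-stage wall times and artifact hashes.

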