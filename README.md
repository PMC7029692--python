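# conngrad

Voxel-wise connectivity-gradient mapping by spectral reordering.

`conngrad` takes voxel connectivity profiles — tractography streamline-count
fingerprints or resting-state fMRI time series — for an ordered set of seed
voxels, builds a voxel-by-voxel cosine similarity matrix, and spectrally
reorders it with the Fiedler vector of the generalized graph-Laplacian
eigenproblem `L v = λ D v` (L = D − A). The second-smallest eigenvalue λ₂
(the algebraic connectivity) quantifies how graded the change in
connectivity is: near 0 for hard-clustered structure, larger for graded
transitions. Hard clusters are then extracted from the two ends of the
reordered matrix and characterized by their average connectivity, with
permutation (sign-flip, max-cluster-size) inference for seed-based
functional connectivity contrasts.

## What's in the box

| module | purpose |
|---|---|
| `conngrad.roi_geometry` | gray/white-interface seed ROI extraction, streamline-map thresholding/downsampling, group fingerprint assembly |
| `conngrad.similarity` | structural cosine and shifted (+1) time-series cosine similarity matrices; z-standardized group averaging |
| `conngrad.spectral` | generalized Laplacian eigenproblem, Fiedler reordering, λ₂ gradation metric, rank back-projection |
| `conngrad.clusters` | end-of-matrix hard-cluster extraction, advisory end-cluster suggestion, cluster connectivity maps |
| `conngrad.fmri_qc` | Friston-24 motion expansion, artifact scrubbing (>1 mm framewise / z>2.5), run exclusion (<300 s retained / >3 mm), nuisance regression, Fisher-z seed maps, permutation cluster statistics |
| `conngrad.synthetic_data` | deterministic phantoms: segmentations, two-endmember fingerprints/time series with graded↔clustered truth, motion traces with planted spikes |

## CLI

All commands live under one entry point:

```sh
# synthetic fixture bundle
conngrad make-phantom --mode graded --participants 6 --seed 7 -o fixtures/

# seed ROI from segmentations
conngrad build-roi --white wm.nii.gz --csf csf.nii.gz --roi region.nii.gz \
    --connectivity 6 --csf-dilate 1 -o seeds.nii.gz

# structural branch
conngrad group-fingerprints --mode proportion --template seeds.nii.gz \
    --participants manifest.tsv -o fp.npz
conngrad similarity --kind structural --fingerprints fp.npz -o sim.npz
conngrad reorder --similarity sim.npz -o res.npz --rank-map ranks.nii.gz
conngrad gradation --per-participant matrices.tsv -o lambda2.tsv
conngrad extract-clusters --similarity sim.npz --reordering res.npz \
    --ranges "red:1:120,purple:480:600" -o clusters/

# functional branch
conngrad qc --motion rp.txt --global-signal gs.txt -o qc.tsv
conngrad seedmap --bold bold.nii.gz --cluster-mask clusters/cluster_red.nii.gz -o z.nii.gz
conngrad group-stats --maps-a mapsA.tsv --maps-b mapsB.tsv --paired -o stats/
```

## Conventions

- Seed voxel order is lexicographic in (i, j, k) and fixes matrix row order
  everywhere; ranks in reordered matrices are 1-based.
- Voxel indices are 0-based internally; distances use the NIfTI affine (mm).
- Native streamline thresholding is strict (`> 5`); binarization and
  cluster-map floors are inclusive (`>= 5`). Both are arguments.
- Matrices and fingerprints are stored as `.npz` with the seed voxel list,
  grid affine and mode tag embedded; volumes are NIfTI-1.
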