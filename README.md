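# voxtex

Voxel-wise 3D texture mapping with explainable classification for
co-registered brain volumes. The pipeline:

1. **Synthetic cohorts** (`voxtex.synthetic`) — brain-shaped three-compartment
   phantoms (CSF/GM/WM-like bands plus correlated subject noise) with a
   *texture-only* group effect planted inside known ROIs: voxel values are
   permuted or rank-matched so that co-occurrence structure changes while ROI
   histograms (hence mean intensity and volume) are exactly preserved.
   Groups follow the FEP / CHR_NT / CHR_T / HC convention (defaults
   77/58/15/44).
2. **Intensity prep** (`voxtex.prep`) — histogram equalization over foreground
   voxels (exact empirical CDF; a 256-entry LUT is emitted for audit) and
   equal-width quantization to G gray levels (default 16, even, 2–256), plus
   a bin-count sweep utility (2–256 step 2).
3. **GLCM texture maps** (`voxtex.glcm`) — a 7x7x7 cube slides over each
   quantized volume; co-occurrences over the 13 unique distance-1 3D
   directions are pooled, symmetrized and normalized per cube, and six
   features (entropy, sum entropy, difference entropy, energy, contrast,
   homogeneity; log base 2) are written to cube centers. Background-touching
   pairs are excluded; boundary cubes are cropped. Maps are smoothed with a
   truncated 7x7x7 Gaussian. The fast blocked implementation is validated
   against a naive per-voxel, per-pair enumeration.
4. **Classification** (`voxtex.classify`) — repeated stratified nested CV
   (default 10 reps x 10 outer folds x 10 reps x 10 inner folds = 10,000
   inner fits). Welch-t top-k feature selection (default k=200) runs inside
   the inner cycle only; the outer model — a 5-hidden-layer x 2-unit tanh MLP
   with linear output, batch-trained by Levenberg–Marquardt with an L2
   penalty — is refit on the outer-training set with the inner consensus
   feature set. Metrics (balanced accuracy, sensitivity, specificity) come
   from outer hold-outs only; a third group can be scored as external
   validation by majority vote across all stored outer models.
5. **LRP heatmaps** (`voxtex.lrp`) — epsilon-rule layer-wise relevance
   propagation of the output score down to input voxels, for correctly
   classified hold-out subjects; positive relevance extraction and Gaussian
   smoothing (10 mm FWHM or voxel-support kernels).
6. **Clustering** (`voxtex.cluster`) — affinity propagation (negative squared
   Euclidean similarities, median preference, damping 0.9) over subjects'
   positive-relevance maps; clusters are reported as size-ranked labels with
   per-cluster mean heatmaps.
7. **Pipeline/CLI** (`voxtex.pipeline`, `voxtex.cli`) — end-to-end runs for
   schema **a** (FEP vs HC) and **b** (FEP vs CHR_NT), with CHR_T external
   validation, on synthetic or user-provided NIfTI cohorts.

## CLI

```bash
# generate a phantom cohort
voxtex simulate --config cohort.yaml --out cohort/

# sanity-check any cohort directory (NIfTI volumes + subjects.tsv)
voxtex validate cohort/

# per-volume stages
voxtex prep cohort/FEP_000.nii.gz --n-bins 16 --out q.nii.gz --lut-csv lut.csv
voxtex texture cohort/FEP_000.nii.gz --n-bins 16 --out-dir maps/

# end-to-end (texture -> nested CV -> LRP -> clustering -> external validation)
voxtex run-all --config run.yaml
```

Example `run.yaml`:

```yaml
cohort:
  group_sizes: {FEP: 20, HC: 20, CHR_T: 5}
  grid_shape: [24, 24, 24]
  seed: 7
  effect: {kind: pair-shuffle, magnitude: 0.8, affected_groups: [FEP, CHR_T]}
n_bins: 16
schema: a
features: [difference_entropy, contrast]
cv: {outer_folds: 3, inner_folds: 3, outer_reps: 2, inner_reps: 1, k_features: 50, epochs_max: 60}
out_dir: results/run1
```

`cohort` may instead be a path to a directory containing one NIfTI per
subject and a `subjects.tsv` with columns `subject_id` and `group`.

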