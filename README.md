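# sparsedecode

Semisupervised sparse-representation decoding of brain states from
block-design fMRI, with a built-in simulator so every method is testable
without any real scan.

The package implements:

- **sparse_core** — an ℓ1-penalized sparse-coding solver (gradient
  projection on the positive/negative split with Barzilai–Borwein steps,
  proximal rescue and an exact active-set polish) plus per-class
  coefficient masking.
- **classifiers** — residual SRC, average-coefficient SRC-AVE, and a
  linear discriminant classifier with Ledoit–Wolf-style covariance
  shrinkage, all sharing one labeled-dictionary interface.
- **semisupervised** — confidence-gated self-training (each test volume
  whose prediction margin exceeds an adaptive threshold `alpha * mean of
  previous margins` joins the dictionary under its predicted label), a
  naïve always-update variant, and random-subspace online ensembles
  (LDC or SRC-AVE members, majority vote, 75% vote-confidence gate).
- **simdata** — a block-design BOLD simulator: 27 spatial sources on a
  square grid, double-gamma HRF, 12 task blocks (4 per task) alternating
  with rest at TR 2 s, baseline 800, task amplitude 1.5, shared-region
  amplitude 2, unique-event nuisance sources, Gaussian noise scaled to a
  requested contrast-to-noise ratio, per-subject affine perturbations,
  optional head-motion drift. Two dataset groups: same task layout in
  both runs, or cross-decoding with partially overlapping novel-task
  layouts.
- **pipeline** — correlation-based voxel selection against the
  task-union reference regressor, two-stage z-scoring, linear
  detrending, experiment orchestration (classifier comparison and
  alpha sweeps), Wilcoxon signed-rank statistics, and the CLI.

## CLI

```bash
# generate a simulated collection (HDF5)
sparsedecode simulate --group 1 --subjects 4 --cnr-levels 3 \
    --grid-size 24 --seed 1 --out runs/coll.h5

# decode one dataset with one classifier
sparsedecode decode --collection runs/coll.h5 --index 0 \
    --classifier semisrc_ave --out-dir results/

# full roster comparison with paired statistics
sparsedecode compare --collection runs/coll.h5 --out-dir results/

# threshold-coefficient grid search
sparsedecode sweep-alpha --collection runs/coll.h5 --out-dir results/
```

All defaults (penalty scale, solver tolerances, feature count, alpha
per experiment type, ensemble geometry) live in a YAML config
(`sparsedecode.pipeline.DecodeConfig`; pass `--config file.yaml`).

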