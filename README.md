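# specspat

Weakly supervised spectral–spatial classification of hyperspectral scenes.

A pixel-wise RBF-SVM trained on a small stratified sample produces a seed
class-probability map, which is then refined by an iterative
energy-minimization scheme (iterated conditional modes) whose neighborhood
energy trades a Gaussian spectral-similarity kernel against a Gaussian
spatial-nearness kernel plus a label-agreement vote. Optional layers add
band-subset ensembling with majority voting and weak-label feedback
(re-running refinement with the refined map substituted for the seed).
Evaluation reports overall accuracy, average accuracy, Cohen's kappa and
per-class accuracies. A synthetic scene generator makes every stage testable
offline.

## Layout

| module                 | role |
|------------------------|------|
| `specspat.core`        | `HyperCube`, `LabelMap`, `PixelTable`, `ProbabilityMap`; band exclusion (with named sensor presets), per-band min–max normalization, background masking, mirror padding |
| `specspat.io`          | ENVI (BSQ/BIL/BIP + `.hdr`), MAT containers, portable `.npz` archives |
| `specspat.reduction`   | PCA projection chosen by cumulative explained-variance threshold (default 0.92, capped at 18 components) |
| `specspat.seed`        | stratified train split, 5-fold grid search for (C, γ), calibrated SVM probabilities |
| `specspat.refine`      | spatial/spectral kernels, class energies (two potential forms), ICM sweeps, probability updates, convergence loop, weak-label feedback |
| `specspat.ensemble`    | random band partition + majority vote with probability tie-breaking |
| `specspat.evaluation`  | confusion matrix, OA/AA/kappa |
| `specspat.synthetic`   | seeded synthetic scenes (contiguous regions, smooth signatures, boundary mixing, background, open-set classes), seed corruption, transfer pairs |
| `specspat.cli`         | YAML-config pipeline runner and subcommands |

## CLI

```sh
# generate a synthetic labeled scene
specspat simulate --rows 40 --cols 40 --bands 30 --classes 3 --seed 1 --out scene/

# full pipeline from a config file
specspat run --config config.yaml

# stage by stage
specspat fit --cube scene/cube.npz --labels scene/labels.npz --c 35 --gamma 8 --out fit/
specspat refine --seed-probs fit/seed_probs.npz --features fit/features_raster.npz --r 1 --out refined/
specspat evaluate --truth scene/labels.npz --pred refined/refined_map.img

# cross-scene transfer: refinement parameters are locked to the fixed set
# (γ=7, r=4, σw=1.3, σs=1.3, β=0.4); only the SVM cost C is re-tuned
specspat transfer --cube new/cube.npz --labels new/labels.npz --c-grid 8,16,35 --out transfer/
```

A minimal `config.yaml`:

```yaml
scene: {m: 40, n: 40, d: 30, k: 3, layout: voronoi, noise_sd: 0.5,
        class_separation: 3.0, background_fraction: 0.1}
fraction: 0.1
min_per_class: 10
svm: {C: 35, gamma: 8}
refine: {r: 1}
out_dir: out
seed: 5
```

Real scenes are configured with `cube_path`/`labels_path` instead of
`scene`, plus optionally a `band_exclusion` preset
(`indian_pines`, `salinas`, `pavia_university`, `prisma_swir`) or explicit
`{ranges: [[lo, hi], ...], singletons: [...]}` lists (1-based band indices).

Every run writes the classification maps (ENVI rasters), the refined
probability map, metrics JSON, the per-iteration convergence log, and a
`params.json` audit record; identical config + seed reproduces byte-identical
reports.

## Notes

- Benchmark scenes (Indian Pines, Salinas, Pavia University) are external
  downloads; `read_cube`/`read_labels` accept their MAT containers directly
  and the presets reproduce the conventional band filtering, but no network
  access is required for any test.
- `RefineParams.prob_update` selects whether the energy's neighbor
  probabilities stay anchored to the seed map (default, converges to an
  exact fixed point) or are replaced by each iteration's conditionals.
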