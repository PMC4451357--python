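# eigenbrain

An eigenimage-based computer-aided-diagnosis pipeline for two-class analysis
of co-registered, brain-masked 3D structural volumes (e.g. disease vs.
control cohorts). Given per-subject NIfTI volumes and a binary label table,
the pipeline:

1. **Key-slice selection** — scores every coronal slice by the inter-class
   variance (squared Euclidean norm of the difference between class-mean
   images) and keeps slices at ≥ 50% of the maximum, thinned to every 10th
   slice.
2. **Eigenimage decomposition** — standardizes each key-slice stack per
   voxel, then computes an orthonormal eigenimage ("eigenbrain") basis by
   PCA using the small N×N covariance trick (N subjects ≪ A pixels), plus
   per-subject projection scores.
3. **MIE selection** — screens the leading eigenbrains with two-sided
   Welch's t-tests on the scores and selects the most important eigenbrain:
   the smallest index significant (p < 0.05) on *every* key slice.
4. **Classification** — soft-margin SVM (linear / RBF / polynomial kernels)
   trained by sequential minimal optimization, with optional particle-swarm
   hyperparameter tuning, evaluated by repeated stratified K-fold
   cross-validation (accuracy, sensitivity, specificity, precision; the
   disease class is positive).
5. **Region detection** — rectifies the MIE loading image, thresholds at
   the 0.98 quantile per slice, and reports the highlighted voxels,
   optionally aggregated against a user-supplied integer label volume.

A synthetic phantom generator (`eigenbrain.phantom`) produces registered
brain-like cohorts with known class-dependent effect regions and a
ground-truth mask, so the entire pipeline is testable without external data.

## Command-line usage

```sh
# generate a synthetic cohort (98 controls, 28 disease; one effect region)
eigenbrain simulate --out data/ --shape 64 64 64 --n-nc 98 --n-ad 28 \
    --effect 32 32 32 7 50 --noise-sd 1 --seed 1

# individual stages
eigenbrain icv     --volumes data/ --labels data/labels.csv --out out/
eigenbrain eigen   --volumes data/ --labels data/labels.csv --out out/
eigenbrain mie     --volumes data/ --labels data/labels.csv --out out/
eigenbrain cv      --volumes data/ --labels data/labels.csv --kernel pol \
                   --folds 10 --reps 50 --seed 1 --out out/
eigenbrain regions --volumes data/ --labels data/labels.csv --out out/

# or the whole pipeline from a YAML config
eigenbrain run --config config.yaml --out out/ --seed 1
```

Slice indices and coordinates are 0-based internally and 1-based in all
human-readable output. Every output embeds the config hash and seed; a run
is fully reproducible from `config.yaml`.

## Library usage

```python
import eigenbrain as eb

cfg = eb.PhantomConfig(n_nc=98, n_ad=28,
                       effect_regions=(eb.EffectRegion((32, 32, 32), 7.0, 50.0),),
                       noise_sd=1.0, seed=1)
dataset, truth = eb.generate_phantom(cfg)
selection = eb.select_key_slices(eb.compute_icv(dataset))
sets = eb.decompose_stacks(eb.extract_slices(dataset, selection))
mie, wtt = eb.select_mie(sets, dataset.labels)
features = eb.build_features(sets, mie)
report = eb.cross_validate(features.X, dataset.labels, "pol",
                           n_folds=10, reps=50, seed=1)
print(report.summary(percent=True))
```

## Notes and deliberate simplifications

- The phantom is a smooth ellipsoidal shell with an interior cavity plus
  additive spherical mean shifts and i.i.d. Gaussian noise — no anatomical
  realism, bias fields, or registration error.
- Folds are stratified (with 28 positives among 126 subjects, plain random
  folds can lack the minority class entirely).
- The RBF kernel uses denominator σ² (not 2σ²); the inter-class variance
  uses the squared norm. Both have `plain`/alternative switches in config.
- PCA is fit on all subjects pooled before the CV split by default;
  PSO tuning can run nested (per training fold) or once on all data.
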