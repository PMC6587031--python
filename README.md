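# seqradiomics

Multiparametric breast-MRI radiomics for immunohistochemistry (IHC)
subtyping — Luminal A, Luminal B, HER2-positive and triple-negative (TN) —
from dynamic contrast-enhanced (DCE) and diffusion-weighted (DWI) series,
built around three ideas:

1. **Sequential (trajectory) features.** Beyond per-acquisition texture,
   each of the 92 base texture features traces a trajectory across the six
   DCE time points and the three DWI b-values. Ten statistics summarize
   each DCE trajectory (mean, variance, kurtosis, skewness, energy,
   entropy, and four cohort-interactive statistics: mean pairwise Kendall
   tau-b, step-sign conservation, inverse-RMSD stability, z-score
   dispersion); eight summarize each DWI trajectory. With 14 shape
   features this yields a 2,498-column catalog:
   14 + 92·6 + 92·10 + 92·3 + 92·8 = 2,498.

2. **Two-stage feature selection.** A coarse gate keeps feature *f* with
   p-value *p* and single-feature CV error *e* iff

       (p/a)² + (e/b)² < 1

   (an elliptical acceptance domain; (a, b) = (0.6, 0.85) four-class,
   (0.54, 0.76) binary, or tuned by an exhaustive 0.01-step grid search to
   retain about half the catalog). A fine stage ranks survivors with
   lasso, ridge and elastic-net logistic models, sums the three ranks,
   keeps the top 40, and greedily prunes features correlated above
   |r| = 0.4 down to 20 (four-class) or 8 (binary). A Rad-score (the
   coefficient-weighted linear combination of the final standardized
   features) summarizes each subject.

3. **A 20-classifier harness.** Trees (3), discriminant models (2), SVMs
   (6), KNNs (4) and ensembles (5, including an in-package RUSBoost),
   compared by stratified 5-fold cross-validation repeated 10 rounds.

Patient images for the modeled study are not publicly available, so the
package ships a phantom generator: ellipsoidal lesions whose DCE
enhancement curves, mono-exponential DWI decay (subtype-specific ADC mean
and heterogeneity) and Gaussian-random-field texture carry subtype signal
at the study's 26:68:18:22 prevalence. Everything downstream is exercised
end to end on phantoms. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

```python
from seqradiomics.config import PipelineConfig
from seqradiomics.simulate import CohortSpec, PhantomSpec
from seqradiomics.pipeline import run_all
from seqradiomics.models import best_model

spec = CohortSpec(
    n_per_class={"LuminalA": 8, "LuminalB": 20, "HER2pos": 5, "TN": 7},
    phantom=PhantomSpec(grid_shape=(32, 32, 32),
                        spacing=(1.25, 1.25, 1.25),
                        lesion_semi_axes_mm=(7.0, 6.0, 5.0)),
    seed=11)
cfg = PipelineConfig(task="four_class", seed=11)
res = run_all(spec, cfg)
print(res.table.n_features)          # 2498
print(len(res.selection.coarse_accepted), len(res.selection.final))
print(best_model(res.report))
```

prints

```
2498
1829 2
(['svm_fine_gaussian'], 0.9724999999999999)
```

— a 40-subject phantom cohort produced the full 2,498-column catalog; the
elliptical gate kept 1,829 features; correlation pruning left 2 (phantom
subtype signal is strong and shared, so most top-ranked features are
mutually correlated above 0.4 — see the methods note); and the best of the
20 classifiers separated the four subtypes at 97.2% mean accuracy over
10 × 5-fold CV. On label-permuted phantoms the same harness drops to
chance (~52%, near the majority-class rate).

The same pipeline is scriptable from the shell:

```bash
seqradiomics simulate --grid 32 --n-per-class 8,20,5,7 --seed 11 --out-dir cohort/
seqradiomics extract --cohort-dir cohort/ --out static.csv
seqradiomics sequential --table static.csv --out full.csv
seqradiomics select --table full.csv --task four_class --out-dir out/
seqradiomics classify --table full.csv --features out/selection.json --task four_class --out-dir out/
seqradiomics radscore --table out/selected.csv --task tn_binary --out-dir out/
# or everything at once:
seqradiomics run-all --grid 32 --n-per-class 8,20,5,7 --seed 11 --out-dir out/
```

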