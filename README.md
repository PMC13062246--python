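# lactopath

Infer a tumor's lactate metabolic state from routine data: gene expression
when it is available, and H&E histology when it is not.

Lactate accumulation (the Warburg effect) shapes the tumor microenvironment —
high-lactate tumors tend to be proliferative, immune-excluded and
therapy-resistant — but direct lactate measurement needs fresh tissue.
`lactopath` implements a desk-scale version of a two-arm strategy for head
and neck squamous cell carcinoma and other solid tumors:

1. **Expression arm.** Score each sample against a lactate gene signature
   with single-sample GSEA (ssGSEA), call the top/bottom 33% of the cohort
   LAC_H / LAC_L, quantify microenvironment differences as signature-score
   deltas, and test prognostic value with Kaplan–Meier curves and maximally
   selected log-rank cutpoints (proportion band [0.2, 0.8]).
2. **Histology arm.** Cut whole-slide images into non-overlapping 512×512
   tiles, drop near-white background (mean brightness > 216), normalize
   stains with a Vahadane-style sparse-NMF optical-density model, embed
   patches (768-d), aggregate each slide with a small transformer encoder
   (768→512 projection, CLS token, 2 layers, 4 heads × 128-d; permutation-
   invariant over patches), reduce to 128 principal components, select
   features by cross-validated LASSO, and train four probabilistic
   classifiers — XGBoost, gradient boosting, LightGBM, SVM. The
   **integrated lactate score** is the unweighted sum of their class-1
   probabilities, a continuous value in [0, 4].
3. **Validation arm.** Compare immunohistochemistry H-scores
   (`H = 1·%weak + 2·%moderate + 3·%strong`, range 0–300) between
   predicted-high and predicted-low tumors with rank-sum tests.

Real cohorts are controlled-access, so the package ships a first-class
synthetic-data module (`lactopath.synthio`) that reproduces the assumed
statistical structure — a latent lactate axis coupled positively to
proliferation and negatively to immune/stromal programs, class-conditional
slide morphology, proportional-hazards survival, and shifted IHC intensity
tables — making every stage testable end to end.

## Worked example

`examples/04_slide_classification.py` simulates 40 slides (~60 patches
each) with a planted morphology contrast, trains the aggregator and the
ensemble, and evaluates held-out slides:

```
training loss per epoch: [1.229, 1.285, 0.971, 0.875]
LASSO kept 3 of 29 components
held-out AUROC xgboost           : 0.500
held-out AUROC gradient_boosting : 0.700
held-out AUROC lightgbm          : 0.960
held-out AUROC svm               : 1.000
integrated lactate score range on test slides: [1.11, 3.49] (bounds 0..4)
integrated-score AUROC: 1.000 (1.0 = perfect class separation)
```

The training loss falls as the encoder learns the bag-level contrast; with
only 10 held-out slides individual classifiers are noisy (the tree models
see 30 training slides), but the integrated score — the sum of the four
probabilities — separates the classes perfectly here. At the null
(`morphology_effect=0`) the same chain stays at chance.

`examples/05_ihc_hscore.py` validates predicted groups against simulated
staining tables:

```
median H-score: high 137.0 vs low 71.6 (scale 0-300), rank-sum p = 0.0312
```

## Package layout

| module | contents |
| --- | --- |
| `lactopath.synthio` | seeded generators: expression, patch bags (embeddings or drawn tiles), survival, IHC tables |
| `lactopath.genesets` | GMT I/O, ssGSEA, preranked GSEA with permutation p-values, tertile stratification, signature deltas |
| `lactopath.survival` | Kaplan–Meier, log-rank, maximally selected cutpoints with permutation adjustment |
| `lactopath.histology` | tiling, background rules, sparse-NMF stain estimation and normalization |
| `lactopath.mil` | patch featurizer interface, numpy transformer aggregator with backprop, PCA reduction |
| `lactopath.ensemble` | LASSO selection, four-model ensemble, AUROC/DCA/Youden metrics, integrated score |
| `lactopath.ihc` | H-score computation and group comparison |
| `lactopath.pipeline` | one-config orchestration with hashed, reproducible manifests |
| `lactopath.cli` | thin `lactopath` command over all of the above |

See `docs/methods.md` for the statistical details and design decisions.
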