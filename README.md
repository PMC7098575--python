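# gexmap

Gene-expression images from functional hierarchies, with
transfer-learning classifiers for fixed-time survival prediction.

## The problem

Bulk RNA-seq gives each tumour sample a vector of tens of thousands of
gene abundances, while cohorts hold only hundreds of samples.  Predicting
clinically meaningful outcomes — here, whether a patient has a new tumour
event within a fixed horizon of the progression-free interval (PFI) — from
such data invites overfitting, and convolutional networks, which excel
when neighbouring inputs share information, are useless on a raw
expression vector whose neighbouring entries are unrelated genes.

`gexmap` addresses both obstacles:

1. **Gene-expression images.**  A functional-hierarchy catalogue
   (BRITE-style: root → categories → hierarchies → genes) is laid onto an
   `r × c` pixel canvas with an ordered treemap (pivot-by-size).  Every
   node's rectangle has area `A(rec) = D(rec) · a`, where `D(rec)` is its
   descendant-leaf count and `a = r·c / D(root)`, so all genes occupy
   equal area; genes inside each hierarchy rectangle are ordered by mean
   expression.  The resulting template `T` maps each gene to fixed pixels
   (several loci for multiply annotated genes), and a sample's vector
   `g_i` becomes an image `G_i` by writing each value to its gene's
   pixels.  Functionally related genes become spatial neighbours, giving
   convolutions real local structure to exploit.
2. **Transfer learning.**  Because the fixed-time PFI label exists for
   every cohort, a CNN (or a dense MLNN on raw vectors) is pre-trained on
   a large multi-cohort base set and fine-tuned on the small target
   cohort, optimizing the same objective in both phases, with random
   oversampling against the ~1:9 class imbalance.

Labels come from right-censored PFI records binarized at horizon `t`
(default 230 days ≈ 7.67 months): events before `t` are positive, samples
censored before `t` are excluded as unknowable, everything else is
negative.  Models are compared by 10-repeated 5-fold stratified CV (50
fold AUCs), one-sided paired Wilcoxon signed-rank tests and Hochberg
correction; classical baselines (ANOVA/PCA/KPCA × LR/SVM/NN/RF with
SMOTE) and ablation layouts (`M_i` mean-sorted, `R_i` random) are
included.  See `docs/methods.md` for the full model description.

The package is aimed at computational-biology practitioners who want to
reproduce or extend this image-based survival-classification workflow on
their own cohorts or on synthetic benchmarks.

## Worked example

Everything below runs offline on the package's synthetic generator, which
plants the outcome signal in hierarchy blocks (the structure the G layout
exposes to a CNN):

```python
import numpy as np
from gexmap import (SyntheticConfig, simulate_dataset, mean_expression,
                    build_template, validate_template)
from gexmap.survival_labels import label_dataset
from gexmap.image_render import render_sample
from gexmap.tl_models import ModelSpec, make_nn_pipeline, repeated_cv

cfg = SyntheticConfig(seed=42)
tree, sim, pheno = simulate_dataset(cfg)

labels, report = label_dataset(pheno, t=230.0)
T = build_template(tree, mean_expression(sim.matrix), r=64, c=64)

keep = labels[labels.status.isin(['positive', 'negative'])].index
y = (labels.loc[keep, 'status'] == 'positive').astype(int).to_numpy()
X = sim.matrix.subset_samples(keep)
bg = float(X.values.min())
G = np.stack([render_sample(X.sample_vector(s), T, background=bg).grid
              for s in keep])

spec = ModelSpec(kind='cnn', pretrain_epochs=0, finetune_epochs=10)
result = repeated_cv(G, y, make_nn_pipeline(spec, image_shape=(64, 64)),
                     repeats=2, folds=3, seed=0)

rep = validate_template(T)
print(f"simulated {sim.matrix.n_genes} genes x {sim.matrix.n_samples} samples, "
      f"{tree.n_leaves()} tree leaves")
print(f"retained {report['overall']['retained']} samples, "
      f"{report['overall']['positive_fraction']:.1%} positive at t=230 d")
print(f"template: {rep['n_leaves']} leaves, {rep['min_pixels']}-{rep['max_pixels']} px each, "
      f"disjoint={rep['disjoint']}")
print(f"CNN on G images: mean CV AUC = {result.mean_auc():.3f} over "
      f"{len(result.records)} folds")
```

Output:

```
simulated 480 genes x 480 samples, 526 tree leaves
retained 469 samples, 13.4% positive at t=230 d
template: 526 leaves, 4-12 px each, disjoint=True
CNN on G images: mean CV AUC = 0.691 over 6 folds
```

Reading the numbers: 480 genes yield 526 tree leaves because ~10% of
genes are annotated under a second hierarchy; at the 230-day horizon 11
of 480 samples are censored too early and dropped, leaving a 13.4%
positive class; the 64 × 64 template gives every leaf 4–12 disjoint
pixels; and a small CNN reaches AUC ≈ 0.69 against a label whose
theoretical ceiling under these noise settings is ≈ 0.75.

The same pipeline is scriptable from the shell:

```bash
gexmap simulate --out data/ --seed 3
gexmap label --pheno data/phenotype.tsv --t 230 --out labels.tsv
gexmap run --config config.yaml        # preprocess → tree → template → images → CV
gexmap compare cnn_R.tsv mlnn.tsv --reference cnn_G.tsv
```

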