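# Methods

`gexmap` implements a workflow for predicting fixed-time progression-free
interval (PFI) from bulk RNA-seq expression, built around two ideas: a
biologically driven transformation of expression vectors into 2-D
"gene-expression images", and a supervised transfer-learning (TL) recipe
that pre-trains on a large multi-cohort base set before fine-tuning on a
small target cohort.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Expression pre-processing

Input is a genes x samples matrix of `log2(TPM + 0.001)` abundances.
Feature selection is fully unsupervised: genes constant across all samples
(population SD exactly zero; "constant" is read literally) are removed,
then the top-k genes by median absolute deviation are retained
(`select_top_mad`, default k = 20000).  MAD is the unscaled
`median(|x - median(x)|)`; ties at the k-th rank break by input order so
the selection is deterministic.  Rows are treated as atomic features — no
transcript-to-gene collapsing is attempted, since the mapping from
transcript rows to gene-level features is not part of this workflow's
contract.

## Functional-hierarchy tree

Genes are organized by a functional-hierarchy catalogue (BRITE-style):
root ("Genes and Proteins") -> functional categories -> individual
hierarchies -> gene leaves.  Building the tree for an expression matrix
requires composing identifier maps: hierarchy id -> KEGG human gene id
(link table), KEGG gene id -> HUGO symbol (gene-list table; the symbol is
taken as the description's leading token up to the first comma or
semicolon, the only consistent convention in that file's free text), and
HUGO symbol <-> ENSEMBL id (HGNC complete set).  All hops may be
many-to-many; a gene annotated under several hierarchies appears as one
leaf per hierarchy (so leaves >= distinct genes), but collapses to a
single leaf per (gene, hierarchy) pair because a leaf is a display slot
and duplicates would double-count area.  Hierarchies with no mapped gene
and categories with no hierarchy are pruned.  Sibling order above the
gene level follows first appearance in the reference file, making layouts
reproducible.

## Treemap template

The tree is converted into a sample-independent template image `T` on an
`r x c` canvas by an ordered treemap.  Every node's rectangle has area
`A(rec) = D(rec) * a`, where `D(rec)` is its descendant-leaf count and
`a = r*c / D(root)` the nominal per-leaf area, so all genes occupy equal
area.  The subdivision is the pivot-by-size ordered treemap: the pivot is
the largest-area sibling (first on ties); siblings split into
(L1, pivot, L2, L3); L1 fills a leading strip, the pivot sits above L2 in
a middle strip whose width is chosen (by scanning all split points) to
make the pivot as square as possible, and L3 fills the trailing strip;
strips run along the longer side of the current rectangle.  The same
procedure is applied at every level, including gene leaves inside their
hierarchy rectangle, where leaves are first sorted ascending by mean
expression across all training samples (ties by gene id).  The template
therefore depends only on the tree and the per-gene means — never on any
individual sample.

Continuous coordinates use a top-left origin and half-open rectangles;
split boundaries are computed from cumulative leaf counts, which keeps
area conservation exact to floating-point accumulation (observed worst
error ~1e-12 on a 175 x 175 canvas, well within the 1e-9 tolerance the
tests assert).

**Rasterization.** The subdivision is replayed on the integer pixel grid:
each split boundary is rounded half-away-from-zero, then clamped so every
sub-region keeps at least one pixel row/column per descendant leaf.
Snapping shared boundaries (rather than rounding each leaf rectangle
independently) makes the pixel blocks tile without overlap by
construction; the occupancy clamp guarantees that no leaf vanishes even
when its continuous rectangle is a sub-pixel sliver.  Where the rounded
boundary would leave a region unable to hold its leaves, the boundary is
searched outward from the rounded position, and split choices that admit
no integer realization fall back to the next-most-square choice.  This
matters at published scale: 17723 leaves on 175 x 175 pixels leave ~1.73
px per leaf, and independent rounding of the continuous rectangles was
measured to drop 3 leaves.  A grid that cannot hold all leaves raises a
`ResolutionError` instructing a larger canvas; empirically canvases with
at least ~30% more pixels than leaves always rasterize, while tighter
grids can hit genuinely infeasible integer partitions (splitting nine
cells 4/5 in a 3 x 3 box has no guillotine solution) and then error
explicitly rather than drop a leaf.  No border pixels are reserved
between rectangles.

## Gene-expression images

Three per-sample layouts are produced, always as continuous-valued grids
(models never consume the quantized PNG exports, avoiding the information
loss of discrete colour maps):

* **G** (hierarchy-driven): each gene's value is written to every pixel
  block `T` assigns it — a multiply annotated gene occupies multiple loci.
* **M** (mean-sorted ablation): one pixel per distinct gene, row-major in
  ascending order of mean expression.
* **R** (random ablation): one pixel per gene in a single seeded random
  permutation shared by all samples, destroying local structure.

M and R use one pixel per distinct gene rather than the multi-locus leaf
expansion, matching their role as plain orderings of the gene list.
Background pixels (uncovered canvas, spare capacity in M/R) carry the
global minimum of the training matrix — the least informative value under
the lighter-is-higher display convention.  PNG export min-max scales with
training-set constants so the maximum expression maps to 255.

## Fixed-time labels and rebalancing

A PFI record (event indicator, time in days) is binarized at horizon `t`
(default 230 days, ~7.67 months under a 30-day-month convention):
positive if the event occurred strictly before `t`; excluded if censored
strictly before `t` (event status at `t` unknowable); negative otherwise.
"Before" is strict (`< t`), with an `strict=False` switch for the
inclusive reading; records with missing outcome fields are excluded with
a distinct "missing" status.  Labels are monotone in `t` by construction:
positives stay positive and exclusions stay excluded as `t` grows.

Class imbalance (roughly 1:9 at the default conditions) is handled by
random oversampling (duplication of minority rows) in the deep-learning
arms and SMOTE (synthetic points `x + u (x_nn - x)`, `u ~ U[0,1]`, drawn
between minority nearest neighbours) in the classical ML arms, in both
cases applied inside training folds only.

## Models and transfer learning

The CNN consumes single-channel images (convolution -> ReLU -> max
pooling blocks, then dense layers with dropout and a sigmoid head); the
MLNN consumes raw expression vectors (dense layers with batch
normalization, ReLU and dropout).  Both are trained with Adam on binary
cross-entropy by a small numpy engine written for this package; at the
scales used here (64 x 64 images, a few hundred samples) the models have
tens of thousands of parameters and train in seconds on one CPU, and the
engine keeps training bit-reproducible for fixed seeds.  Default desk
scale architecture: one conv block (6 filters, 5 x 5 kernels, 4 x 4 max
pooling), one dense layer of 16 units, dropout 0.2.  Inputs are
standardized per feature with training-fold statistics.

Transfer learning trains the same objective in two phases: full
supervised pre-training on the (randomly oversampled) base set, then
continued training on the (randomly oversampled) target training folds
with phase-specific learning rate, batch size and epoch count (defaults:
1e-3/64/8 pre-train, 5e-4/32/10 fine-tune).  Fine-tuning with zero epochs
returns the pre-trained model unchanged.

## Evaluation protocol

Repeated stratified k-fold cross-validation (10 x 5 at full scale, i.e.
50 fold records).  Stratification is used because the positive class sits
near 10%.  All trained steps — reducers, resampling, the model, and the
decision threshold — are fitted inside the training folds.  The threshold
maximizes Youden's J (sensitivity + specificity - 1) on the training-fold
ROC, taking the lowest qualifying cut on ties; fitting it on training
rather than validation scores avoids an optimistic bias, with the
alternative reading available by computing the threshold on validation
scores explicitly.  Reported metrics: AUC (rank-based, threshold-free),
sensitivity, specificity, F-measure, accuracy and MCC (defined 0 when a
confusion-matrix factor is empty).

Model comparison uses one-sided paired Wilcoxon signed-rank tests on the
fold-wise AUC vectors (exact null for small n, normal approximation
otherwise; all-zero difference vectors give p = 1), with Hochberg step-up
correction across comparisons.

Classical baselines combine a reducer (ANOVA k-best, PCA, RBF kernel
PCA; 32 components by default) with a classifier (logistic regression,
RBF SVM, one-hidden-layer NN, random forest), SMOTE applied after the
reducer inside each training fold — 12 combinations.

Hyper-parameters can be tuned jointly (both phases' learning rates and
batch sizes included) by a sequential Bayesian search: a Matern-kernel
Gaussian-process surrogate with expected improvement over a bounded box
space, one third of the budget (minimum 3 points) spent on seeded random
exploration.  The default budget is 10 iterations — enough for the
low-dimensional spaces exercised here — with the budget exposed as a
parameter for larger searches.

## Synthetic benchmark

The generator emulates the structure the workflow assumes, at desk scale:

* a functional hierarchy of 4 categories x 3 hierarchies x 40 genes
  (480 genes), with 10% of genes annotated under a second hierarchy;
* expression values `baseline + N(0, noise_sd)` with per-gene baselines
  drawn once from N(4, 1.5) (so the mean-expression ordering is
  non-trivial); a latent high-risk flag (prevalence 0.3) adds an
  `effect_size` of 0.5 (in log-expression units, against noise SD 1.0) to
  every gene of 2 randomly chosen signal hierarchies — the outcome signal
  is deliberately concentrated in hierarchy blocks, which is exactly the
  structure the hierarchy-driven layout can exploit and a random layout
  cannot;
* 4 cohorts x 120 samples sharing the signal mechanism, so pre-training
  on some cohorts genuinely transfers to the others;
* exponential event times with mean 4500 days for low-risk samples and an
  8-fold hazard for high-risk samples, plus independent uniform censoring
  calibrated to a 30% censoring rate.  At the 230-day horizon this yields
  ~13% positives among retained samples, close to the 9-12% of the
  full-scale cohorts, while keeping the label informative about the
  latent risk (the label's Bayes-optimal AUC given perfect risk recovery
  is ~0.75 at these settings).

The default canvas for synthetic runs is 64 x 64 (the full 175 x 175 is
exercised by the geometry tests); experiment sizes were chosen so the
whole suite runs on one CPU in minutes.

Two miniature experiments reproduce the full-scale mechanisms
(`gexmap.experiments`):

* **Layout ablation** — the same CNN, the same samples, labels, folds and
  seeds, trained once on G images and once on R images; 10 repeats of
  stratified 3-fold CV give 30 paired fold AUCs compared by one-sided
  Wilcoxon.
* **Transfer benefit** — an MLNN on expression vectors with the last
  quarter of cohorts as target and the rest as base (pre-training helps
  only when the base set is much larger than the target, as in the
  full-scale 31-vs-2-cohort design); 10 seeded stratified train/test
  splits of the target, with pretrain+finetune and finetune-only sharing
  each split.

What passing these tests shows: the pipeline end to end can detect
hierarchy-block signal through the image representation, the G layout
carries usable local structure that the R layout destroys, and supervised
pre-training on shared-mechanism cohorts improves a small-cohort
classifier.  What it does not show: performance on real tumour data.  The
generator draws genes independently around their baselines — it has no
inter-gene correlation beyond the block effect, no cohort-specific batch
structure, no heavy-tailed expression distributions, and its censoring is
uniform rather than administrative.  Absolute AUC values on the synthetic
benchmark are therefore not comparable to published full-scale figures.

## Known limitations

* Continuous-time survival modelling (Cox-type losses) is out of scope;
  only fixed-horizon binarization is provided.
* The ordered-treemap implementation follows the published pivot-by-size
  definition but is not guaranteed to be bit-identical to other
  implementations of the same family; layouts are deterministic and
  reproducible within this package.
* No live retrieval of catalogue or identifier tables is implemented; the
  parsers consume local flat files, and tests and experiments run entirely
  on synthetic fixtures generated at run time.
* Single-channel images only; no data augmentation (none is used in the
  underlying design).
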