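"""Miniature study designs: layout ablation and transfer benefit.

These functions reproduce, at desk scale on synthetic data, the two
mechanisms the full-scale study tests:

* ``layout_ablation_experiment`` — does the hierarchy-driven image layout
  (G) let a CNN outperform the same CNN on randomly arranged images (R)?
  The synthetic outcome signal is concentrated in hierarchy blocks, so the
  G layout is informative by construction and the comparison is evaluated
  fold-wise paired.
* ``transfer_benefit_experiment`` — does supervised pre-training on base
  cohorts followed by fine-tuning on the target cohort beat training on
  the target cohort alone?  All cohorts share the outcome mechanism, so
  transfer is beneficial by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .expression_data import mean_expression
from .image_render import render_random, render_sample
from .survival_labels import NEGATIVE, POSITIVE, label_dataset
from .synthetic_data import SyntheticConfig, simulate_dataset
from .tl_models import (
    CVResult,
    ModelSpec,
    Standardizer,
    build_mlnn,
    make_nn_pipeline,
    pretrain_finetune,
    repeated_cv,
)
from .treemap_layout import build_template

__all__ = [
    "AblationOutcome",
    "layout_ablation_experiment",
    "transfer_benefit_experiment",
]


def _labelled_dataset(cfg: SyntheticConfig):
    """Simulate, binarize at the configured horizon and drop excluded samples."""
    tree, sim, pheno = simulate_dataset(cfg)
    labels, _ = label_dataset(pheno, cfg.horizon_days)
    keep = labels[labels["status"].isin([POSITIVE, NEGATIVE])].index
    y = (labels.loc[keep, "status"] == POSITIVE).astype(int).to_numpy()
    X = sim.matrix.subset_samples(keep)
    cohorts = pd.Series(sim.cohorts, index=sim.matrix.sample_ids).loc[keep]
    return tree, sim, X, y, cohorts


@dataclass(frozen=True)
class AblationOutcome:
    """Paired CV results of the CNN on hierarchy (G) vs random (R) images."""

    hierarchy: CVResult
    random: CVResult

    @property
    def paired_differences(self) -> np.ndarray:
        return self.hierarchy.auc_values - self.random.auc_values


def layout_ablation_experiment(
    cfg: SyntheticConfig | None = None,
    spec: ModelSpec | None = None,
    repeats: int = 10,
    folds: int = 3,
    seed: int = 0,
) -> AblationOutcome:
    """Train the same CNN on G-layout and R-layout images of one dataset.

    Both arms share samples, labels, CV folds and model seeds, so the
    fold-wise AUC vectors are paired.  The random arrangement uses one
    fixed seeded permutation for all samples.
    """
    cfg = cfg if cfg is not None else SyntheticConfig(seed=seed)
    spec = spec if spec is not None else ModelSpec(
        kind="cnn", pretrain_epochs=0, finetune_epochs=10
    )
    tree, sim, X, y, _ = _labelled_dataset(cfg)
    means = mean_expression(sim.matrix)
    T = build_template(tree, means, r=cfg.canvas, c=cfg.canvas)
    background = float(X.values.min())
    G = np.stack([
        render_sample(X.sample_vector(s), T, background=background).grid
        for s in X.sample_ids
    ])
    R = np.stack([
        render_random(X.sample_vector(s), cfg.seed + 10_007, cfg.canvas, cfg.canvas,
                      background=background).grid
        for s in X.sample_ids
    ])
    shape = (cfg.canvas, cfg.canvas)
    res_g = repeated_cv(G, y, make_nn_pipeline(spec, image_shape=shape),
                        repeats=repeats, folds=folds, seed=seed,
                        provenance={"name": "cnn-G"})
    res_r = repeated_cv(R, y, make_nn_pipeline(spec, image_shape=shape),
                        repeats=repeats, folds=folds, seed=seed,
                        provenance={"name": "cnn-R"})
    return AblationOutcome(hierarchy=res_g, random=res_r)


def transfer_benefit_experiment(
    cfg: SyntheticConfig | None = None,
    spec: ModelSpec | None = None,
    n_seeds: int = 10,
    test_fraction: float = 1 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare pretrain+finetune against finetune-only on shared-signal cohorts.

    The last quarter of the cohorts (at least one) forms the target set,
    the rest the base set — pre-training only pays off when the base set
    is much larger than the target, as in the full-scale design.  For each
    seed the target is split stratified into train/test;
    both arms share the split and the test AUC is recorded.  Returns one
    row per seed with columns ``pretrain_finetune`` and ``finetune_only``.
    """
    cfg = cfg if cfg is not None else SyntheticConfig(seed=seed)
    spec = spec if spec is not None else ModelSpec(
        kind="mlnn", dense_units=(32,), pretrain_epochs=20, finetune_epochs=20
    )
    _, _, X, y, cohorts = _labelled_dataset(cfg)
    names = sorted(cohorts.unique())
    n_target = max(1, len(names) // 4)
    target_names = set(names[len(names) - n_target:])
    is_target = cohorts.isin(target_names).to_numpy()
    feats = X.values.T  # samples x genes
    Xb, yb = feats[~is_target], y[~is_target]
    Xt, yt = feats[is_target], y[is_target]

    from sklearn.metrics import roc_auc_score

    rows = []
    for s in range(n_seeds):
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                          random_state=(seed + s) % 2**31)
        (tr, te), = splitter.split(Xt, yt)
        scaler = Standardizer().fit(Xt[tr])
        Xt_tr, Xt_te = scaler.transform(Xt[tr]), scaler.transform(Xt[te])
        Xb_s = scaler.transform(Xb)
        factory = lambda sp: build_mlnn(sp, Xt_tr.shape[1])
        run_spec = replace(spec, seed=(seed + 977 * s) % 2**31)
        with_tl = pretrain_finetune(factory, (Xb_s, yb), (Xt_tr, yt[tr]), run_spec)
        without = pretrain_finetune(factory, (Xb_s[:0], yb[:0]), (Xt_tr, yt[tr]),
                                    replace(run_spec, pretrain_epochs=0))
        rows.append({
            "seed": s,
            "pretrain_finetune": roc_auc_score(yt[te], with_tl.predict_proba(Xt_te)),
            "finetune_only": roc_auc_score(yt[te], without.predict_proba(Xt_te)),
        })
    return pd.DataFrame(rows)
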