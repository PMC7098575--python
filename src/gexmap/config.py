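"""Run configuration and the end-to-end pipeline.

A run reads an expression matrix, a phenotype table and the BRITE-style
mapping files, then executes preprocess -> tree -> layout -> render ->
label -> train/evaluate, leaving every artifact in the output directory
with a JSON provenance sidecar (config hash, seeds, package version).
Stages are pure functions of (inputs, config, seeds); with ``resume=True``
a stage whose artifact already exists is skipped, so deleting an
intermediate regenerates only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .expression_data import (
    filter_constant_genes,
    mean_expression,
    read_expression_matrix,
    read_phenotype_table,
    select_top_mad,
)
from .brite_hierarchy import (
    build_hierarchy_tree,
    build_id_chain,
    parse_brite_reference,
    parse_link_table,
)
from .image_render import export_images, render_mean_sorted, render_random, render_sample
from .survival_labels import NEGATIVE, POSITIVE, label_dataset
from .tl_models import ModelSpec, make_nn_pipeline, repeated_cv
from .treemap_layout import build_template

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    expression_path: str = ""
    phenotype_path: str = ""
    brite_reference_path: str = ""
    brite_link_path: str = ""
    kegg_list_path: str = ""
    hgnc_path: str = ""
    out_dir: str = "gexmap_run"
    horizon_days: float = 230.0
    top_k_genes: int = 20_000
    canvas_rows: int = 64
    canvas_cols: int = 64
    layout_kind: str = "G"           # G | M | R
    target_cohorts: tuple = ()
    cv_repeats: int = 10
    cv_folds: int = 5
    seed: int = 0
    random_layout_seed: int = 0
    model: ModelSpec = field(default_factory=ModelSpec)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        model = obj.pop("model", None)
        cfg = cls(**{k: v for k, v in obj.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if model:
            cfg.model = ModelSpec(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in model.items()
            })
        cfg.target_cohorts = tuple(cfg.target_cohorts)
        return cfg

    def to_yaml(self, path) -> None:
        # json round-trip converts tuples to lists for safe_dump
        obj = json.loads(json.dumps(dataclasses.asdict(self)))
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))

    def digest(self) -> str:
        obj = dataclasses.asdict(self)
        obj["target_cohorts"] = sorted(self.target_cohorts)
        return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sidecar(path: Path, cfg: RunConfig, stage: str, extra: dict | None = None) -> None:
    payload = {
        "stage": stage,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "gexmap_version": __version__,
    }
    payload.update(extra or {})
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(payload, indent=2)
    )


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute the full workflow; returns a dict of artifact paths and results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def stage(name: str, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc

    # --- preprocess ------------------------------------------------------
    def _preprocess():
        X = read_expression_matrix(cfg.expression_path)
        X = filter_constant_genes(X)
        X = select_top_mad(X, cfg.top_k_genes)
        return X

    X = stage("preprocess", _preprocess)

    # --- tree ------------------------------------------------------------
    def _tree():
        catalogue = parse_brite_reference(cfg.brite_reference_path)
        links = parse_link_table(cfg.brite_link_path)
        chain = build_id_chain(cfg.kegg_list_path, cfg.hgnc_path)
        return build_hierarchy_tree(catalogue, links, chain, X.gene_ids)

    tree = stage("tree", _tree)
    X_annot = X.subset_genes(sorted({leaf.gene_id for leaf in tree.leaves()}))

    # --- layout ----------------------------------------------------------
    template_path = out / "template.json"

    def _layout():
        means = mean_expression(X_annot)
        T = build_template(tree, means, r=cfg.canvas_rows, c=cfg.canvas_cols)
        template_path.write_text(T.to_json())
        _sidecar(template_path, cfg, "layout", {"fingerprint": T.fingerprint})
        return T

    if resume and template_path.exists():
        from .treemap_layout import TemplateLayout

        T = TemplateLayout.from_json(template_path.read_text())
    else:
        T = stage("layout", _layout)
    artifacts["template"] = template_path

    # --- label -----------------------------------------------------------
    labels_path = out / "labels.tsv"

    def _label():
        pheno = read_phenotype_table(cfg.phenotype_path)
        labels, report = label_dataset(pheno, cfg.horizon_days)
        labels.to_csv(labels_path, sep="\t")
        _sidecar(labels_path, cfg, "label", {"report": report})
        return labels

    labels = stage("label", _label)
    artifacts["labels"] = labels_path

    retained = labels[labels["status"].isin([POSITIVE, NEGATIVE])]
    retained = retained.loc[[s for s in retained.index if s in set(X.sample_ids)]]
    y = (retained["status"] == POSITIVE).astype(int).to_numpy()

    # --- render ----------------------------------------------------------
    images_path = out / f"images_{cfg.layout_kind}.npz"

    def _render():
        background = float(X_annot.values.min())
        means = mean_expression(X_annot)
        imgs = []
        for sid in retained.index:
            g = X_annot.sample_vector(sid)
            if cfg.layout_kind == "G":
                im = render_sample(g, T, background=background, sample_id=sid)
            elif cfg.layout_kind == "M":
                im = render_mean_sorted(g, means, cfg.canvas_rows, cfg.canvas_cols,
                                        background=background, sample_id=sid)
            else:
                im = render_random(g, cfg.random_layout_seed, cfg.canvas_rows,
                                   cfg.canvas_cols, background=background, sample_id=sid)
            imgs.append(im)
        export_images(imgs, images_path)
        _sidecar(images_path, cfg, "render", {"n_images": len(imgs)})
        return np.stack([im.grid for im in imgs])

    grids = stage("render", _render)
    artifacts["images"] = images_path

    # --- train / evaluate -------------------------------------------------
    cv_path = out / "cv_results.tsv"

    def _train():
        if cfg.model.kind == "cnn":
            features = grids
            pipeline = make_nn_pipeline(cfg.model, image_shape=grids.shape[1:])
        else:
            features = X_annot.data[list(retained.index)].to_numpy().T
            pipeline = make_nn_pipeline(cfg.model)
        result = repeated_cv(features, y, pipeline, repeats=cfg.cv_repeats,
                             folds=cfg.cv_folds, seed=cfg.seed,
                             provenance={"name": f"{cfg.model.kind}-{cfg.layout_kind}"})
        result.records.to_csv(cv_path, sep="\t", index=False)
        _sidecar(cv_path, cfg, "train", {"mean_auc": result.mean_auc()})
        return result

    cv_result = stage("train", _train)
    artifacts["cv_results"] = cv_path
    artifacts["cv_result"] = cv_result
    return artifacts
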