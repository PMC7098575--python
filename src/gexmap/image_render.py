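"""Per-sample gene-expression images.

Three layouts are supported:

* ``G`` — hierarchy-driven: each gene's value is written to every pixel
  block the template T assigns to it (one block per annotated hierarchy).
* ``M`` — mean-sorted ablation: one pixel per distinct gene, filled
  row-major in ascending order of mean expression.
* ``R`` — random ablation: one pixel per gene in a seeded random order
  shared by all samples, destroying any local structure.

Pixels not owned by any gene carry a background value, by convention the
global minimum expression of the training matrix (the darkest gray under
the lighter-is-higher display rule).  Models always consume the continuous
grids; the 8-bit PNG export exists for visual inspection only, to avoid
the information loss of quantized colour maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .treemap_layout import TemplateLayout

__all__ = [
    "GeneExpressionImage",
    "render_sample",
    "mean_sorted_order",
    "random_gene_order",
    "render_mean_sorted",
    "render_random",
    "export_images",
    "load_images",
]


@dataclass(frozen=True)
class GeneExpressionImage:
    """An r x c grid of continuous expression values for one sample."""

    sample_id: str
    grid: np.ndarray
    layout_kind: str  # "G", "M" or "R"
    fingerprint: str

    def __post_init__(self) -> None:
        if self.grid.ndim != 2:
            raise ValueError("image grid must be 2-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("image grid contains non-finite values")
        if self.layout_kind not in ("G", "M", "R"):
            raise ValueError(f"unknown layout kind {self.layout_kind!r}")


def _as_series(g) -> pd.Series:
    return g if isinstance(g, pd.Series) else pd.Series(dict(g))


def render_sample(g, T: TemplateLayout, background: float | None = None,
                  sample_id: str = "") -> GeneExpressionImage:
    """Render one sample's vector through the hierarchy template T (a G image).

    ``background`` fills pixels not covered by any leaf; it defaults to the
    minimum of ``g`` but should be the global training-set minimum so the
    background is constant across samples.
    """
    g = _as_series(g)
    if background is None:
        background = float(g.min())
    grid = np.full((T.r, T.c), float(background), dtype=float)
    values = g.to_dict()
    for leaf_key, gene in T.leaf_gene.items():
        if gene not in values:
            raise KeyError(f"gene {gene!r} required by the template is absent from the sample")
        r0, r1, c0, c1 = T.leaf_blocks[leaf_key]
        grid[r0:r1, c0:c1] = values[gene]
    return GeneExpressionImage(
        sample_id=sample_id, grid=grid, layout_kind="G", fingerprint=T.fingerprint
    )


def mean_sorted_order(means) -> list:
    """Gene ids sorted ascending by mean expression, ties by gene id."""
    means = _as_series(means)
    return sorted(means.index, key=lambda gid: (float(means[gid]), str(gid)))


def random_gene_order(gene_ids, seed: int) -> list:
    """A seeded random permutation of the genes, identical for every sample.

    The permutation is applied to the sorted gene list so the result does
    not depend on the caller's input ordering.
    """
    base = sorted(map(str, gene_ids))
    rng = np.random.default_rng(seed)
    return [base[i] for i in rng.permutation(len(base))]


def _order_fingerprint(order, kind: str) -> str:
    payload = json.dumps({"kind": kind, "order": list(map(str, order))})
    return hashlib.sha256(payload.encode()).hexdigest()


def _render_row_major(g: pd.Series, order, r: int, c: int, background, kind: str,
                      sample_id: str) -> GeneExpressionImage:
    if len(order) > r * c:
        raise ValueError(f"{len(order)} genes exceed the {r}x{c} pixel capacity")
    if background is None:
        background = float(g.min())
    grid = np.full(r * c, float(background), dtype=float)
    values = g.to_dict()
    for pos, gene in enumerate(order):
        if gene not in values:
            raise KeyError(f"gene {gene!r} in the layout is absent from the sample")
        grid[pos] = values[gene]
    return GeneExpressionImage(
        sample_id=sample_id,
        grid=grid.reshape(r, c),
        layout_kind=kind,
        fingerprint=_order_fingerprint(order, kind),
    )


def render_mean_sorted(g, means, r: int, c: int, background: float | None = None,
                       sample_id: str = "") -> GeneExpressionImage:
    """Render the M ablation image: genes row-major in ascending-mean order."""
    g = _as_series(g)
    return _render_row_major(g, mean_sorted_order(means), r, c, background, "M", sample_id)


def render_random(g, seed: int, r: int, c: int, background: float | None = None,
                  sample_id: str = "") -> GeneExpressionImage:
    """Render the R ablation image: genes row-major in a seeded random order."""
    g = _as_series(g)
    order = random_gene_order(g.index, seed)
    return _render_row_major(g, order, r, c, background, "R", sample_id)


def export_images(images, path, format: str = "array-container",
                  vmin: float | None = None, vmax: float | None = None) -> list:
    """Serialize a batch of images.

    ``array-container`` writes a lossless .npz (stacked float grids) with a
    JSON sidecar recording sample ids, layout kind and fingerprint.  ``png``
    writes one 8-bit grayscale PNG per sample, min-max scaled with
    ``vmin``/``vmax`` (default: global min/max over the batch) so the
    maximum expression maps to 255 (lighter = higher).
    """
    images = list(images)
    if not images:
        raise ValueError("no images to export")
    shapes = {im.grid.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    kinds = {im.layout_kind for im in images}
    prints = {im.fingerprint for im in images}
    if len(kinds) != 1 or len(prints) != 1:
        raise ValueError("images in a batch must share layout kind and fingerprint")
    path = Path(path)
    if format == "array-container":
        stack = np.stack([im.grid for im in images])
        np.savez_compressed(path, images=stack)
        sidecar = {
            "sample_ids": [im.sample_id for im in images],
            "layout_kind": images[0].layout_kind,
            "fingerprint": images[0].fingerprint,
        }
        side_path = path.with_suffix(path.suffix + ".json")
        side_path.write_text(json.dumps(sidecar, indent=2))
        return [path, side_path]
    if format == "png":
        from PIL import Image

        stack = np.stack([im.grid for im in images])
        lo = float(stack.min()) if vmin is None else float(vmin)
        hi = float(stack.max()) if vmax is None else float(vmax)
        span = hi - lo
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for im in images:
            if span > 0:
                scaled = np.clip((im.grid - lo) / span, 0.0, 1.0)
            else:
                scaled = np.full_like(im.grid, 0.5)
            arr = np.round(scaled * 255).astype(np.uint8)
            out = path / f"{im.sample_id or 'sample'}_{im.layout_kind}.png"
            Image.fromarray(arr, mode="L").save(out)
            written.append(out)
        return written
    raise ValueError(f"unknown export format {format!r}")


def load_images(path) -> list:
    """Load a batch written by :func:`export_images` (array-container)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stack = np.load(path)["images"]
    return [
        GeneExpressionImage(
            sample_id=sid,
            grid=stack[i],
            layout_kind=sidecar["layout_kind"],
            fingerprint=sidecar["fingerprint"],
        )
        for i, sid in enumerate(sidecar["sample_ids"])
    ]
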