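"""Ordered treemap (pivot-by-size) layout of a functional-hierarchy tree.

The tree is turned into a sample-independent image template T on an r x c
pixel canvas: the canvas is recursively tiled into nested rectangles, one
per node, with every rectangle's area proportional to its descendant leaf
count, A(rec) = D(rec) * a where a = r*c / D(root) is the nominal per-leaf
area.  Gene leaves inside each hierarchy rectangle are laid out in
ascending order of mean expression, so reading order within a hierarchy
follows average abundance.

Layout conventions: origin top-left, continuous coordinates, half-open
rectangles [x0, x1) x [y0, y1).  Pivot-by-size specifics: the pivot is the
largest-area sibling (first on ties); the sibling list splits into
(L1, pivot, L2, L3); the strip for pivot+L2 is sized so the pivot's
rectangle is as square as possible; strips run along the longer side of
the current rectangle.

Rasterization replays the same subdivision on the integer pixel grid: each
split boundary is rounded half-away-from-zero and then clamped so that
every sub-region keeps at least one pixel row/column per descendant leaf.
Snapping boundaries (rather than each leaf rectangle independently) keeps
the pixel blocks disjoint and tiling by construction, and the clamp
guarantees that no leaf vanishes even when a sliver rectangle is thinner
than a pixel, as long as the canvas has enough pixels overall.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np

from .brite_hierarchy import HierarchyTree, TreeNode

__all__ = [
    "Rect",
    "TemplateLayout",
    "ResolutionError",
    "layout_tree",
    "order_genes_within_hierarchy",
    "rasterize_layout",
    "validate_template",
    "build_template",
]


@dataclass(frozen=True)
class Rect:
    """An axis-aligned rectangle, origin top-left, half-open high edges."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle: {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height


class ResolutionError(ValueError):
    """Raised when the pixel grid is too coarse for every leaf to own a pixel."""


def _snap(v: float) -> int:
    # round half away from zero (coordinates are non-negative here)
    return int(math.floor(v + 0.5))


def _split_children(rect_c, block, counts, a: float) -> list:
    """Tile a region with one sub-region per entry of ``counts``, in order.

    ``rect_c`` is the continuous rectangle as a (x0, y0, x1, y1) tuple;
    ``block`` the matching integer pixel block (c0, r0, c1, r1) or None for
    a continuous-only layout.  Child areas are ``counts * a``.  Returns a
    list of (rect_c, block) pairs.  Iterative (explicit work stack) so deep
    sibling chains cannot exhaust the recursion limit.
    """
    n = len(counts)
    out: list = [None] * n
    if n == 0:
        return out
    counts = np.asarray(counts, dtype=np.int64)
    stack = [(rect_c, block, 0, n)]
    while stack:
        (x0, y0, x1, y1), blk, lo, hi = stack.pop()
        m = hi - lo
        if m == 1:
            out[lo] = ((x0, y0, x1, y1), blk)
            continue
        horizontal = (x1 - x0) >= (y1 - y0)
        # Work in (u, v) with u along the strip direction (the longer side).
        if horizontal:
            u0, v0, u1, v1 = x0, y0, x1, y1
            U0, V0, U1, V1 = blk if blk else (0, 0, 0, 0)
        else:
            u0, v0, u1, v1 = y0, x0, y1, x1
            U0, V0, U1, V1 = (blk[1], blk[0], blk[3], blk[2]) if blk else (0, 0, 0, 0)

        def tup(ua, va, ub, vb):
            return (ua, va, ub, vb) if horizontal else (va, ua, vb, ub)

        def blk_tup(Ua, Va, Ub, Vb):
            return (Ua, Va, Ub, Vb) if horizontal else (Va, Ua, Vb, Ub)

        H_px = V1 - V0
        W_px = U1 - U0

        def ceil_div(k: int, d: int) -> int:
            return -(-k // max(d, 1))

        def min_u(k: int) -> int:
            # minimum u-extent for k leaves in a region of v-extent H_px
            return 0 if k == 0 else max(1, ceil_div(k, H_px))

        seg = counts[lo:hi]
        areas = seg * a
        total = float(areas.sum())
        width = u1 - u0
        height = v1 - v0

        if m == 2:
            k1, k2 = int(seg[0]), int(seg[1])
            frac = float(areas[0]) / total
            um = u0 + width * frac
            if blk:
                lo_u, hi_u = U0 + min_u(k1), U1 - min_u(k2)
                if lo_u <= hi_u:
                    Um = min(max(_snap(um), lo_u), hi_u)
                    b_left, b_right = blk_tup(U0, V0, Um, V1), blk_tup(Um, V0, U1, V1)
                else:
                    # infeasible along the long side: split along the other axis
                    lo_v = V0 + max(1, ceil_div(k1, W_px))
                    hi_v = V1 - max(1, ceil_div(k2, W_px))
                    if lo_v > hi_v:
                        raise ResolutionError(
                            "pixel grid too coarse for the leaf counts; "
                            "increase the canvas resolution"
                        )
                    vm = v0 + height * frac
                    Vm = min(max(_snap(vm), lo_v), hi_v)
                    out[lo] = (tup(u0, v0, u1, vm), blk_tup(U0, V0, U1, Vm))
                    out[lo + 1] = (tup(u0, vm, u1, v1), blk_tup(U0, Vm, U1, V1))
                    continue
            else:
                b_left = b_right = None
            out[lo] = (tup(u0, v0, um, v1), b_left)
            out[lo + 1] = (tup(um, v0, u1, v1), b_right)
            continue

        p = int(np.argmax(seg))  # pivot: largest area, first on ties
        a_l1 = float(areas[:p].sum())
        a_p = float(areas[p])
        k_l1 = int(seg[:p].sum())
        k_p = int(seg[p])
        # Rank L2 = seg[p+1:split] choices by pivot squareness.
        tail_a = np.concatenate(([0.0], np.cumsum(areas[p + 1:])))
        tail_k = np.concatenate(([0], np.cumsum(seg[p + 1:])))
        candidates = []
        for split in range(p + 1, m + 1):
            a_l2 = float(tail_a[split - (p + 1)])
            w2 = width * (a_p + a_l2) / total
            h_p = height * a_p / (a_p + a_l2)
            candidates.append((max(w2 / h_p, h_p / w2), split))
        candidates.sort()

        def integer_bounds(split: int):
            """(Ua, Ub) realizing this split on the grid, or None if infeasible.

            Ub is searched outward from the rounded boundary until the
            pivot/L2 strip can hold its leaves; needed only in rare
            near-capacity regions where plain rounding fails.
            """
            k_l2 = int(tail_k[split - (p + 1)])
            k_l3 = int(seg[split:].sum())
            a_l2 = float(tail_a[split - (p + 1)])
            lo_a = U0 + min_u(k_l1)
            hi_a = U1 - min_u(k_p + k_l2) - min_u(k_l3)
            if lo_a > hi_a:
                return None
            u_a = u0 + width * (a_l1 / total)
            Ua = U0 if k_l1 == 0 else min(max(_snap(u_a), lo_a), hi_a)
            lo_b = Ua + min_u(k_p + k_l2)
            hi_b = U1 - min_u(k_l3)
            if lo_b > hi_b:
                return None
            u_b = u0 + width * ((a_l1 + a_p + a_l2) / total)
            Ub0 = U1 if k_l3 == 0 else min(max(_snap(u_b), lo_b), hi_b)

            def strip_ok(w: int) -> bool:
                need = ceil_div(k_p, w) + (ceil_div(k_l2, w) if k_l2 else 0)
                return need <= H_px

            if k_l3 == 0:
                return (Ua, Ub0) if strip_ok(Ub0 - Ua) else None
            for delta in range(hi_b - lo_b + 1):
                for Ub in (Ub0 + delta, Ub0 - delta):
                    if lo_b <= Ub <= hi_b and strip_ok(Ub - Ua):
                        return (Ua, Ub)
            return None

        if blk:
            chosen = None
            for _, split in candidates:
                bounds = integer_bounds(split)
                if bounds is not None:
                    chosen = (split, *bounds)
                    break
            if chosen is None:
                raise ResolutionError(
                    "pixel grid too coarse for the leaf counts; "
                    "increase the canvas resolution"
                )
            split, Ua, Ub = chosen
        else:
            split = candidates[0][1]
            Ua = Ub = 0

        a_l2 = float(tail_a[split - (p + 1)])
        k_l2 = int(tail_k[split - (p + 1)])
        k_l3 = int(seg[split:].sum())
        u_a = u0 + width * (a_l1 / total)                    # L1 | pivot strip
        u_b = u0 + width * ((a_l1 + a_p + a_l2) / total)     # pivot strip | L3
        v_p = v0 + height * (a_p / (a_p + a_l2))             # pivot | L2

        if blk:
            strip_w = Ub - Ua
            lo_v = V0 + max(1, ceil_div(k_p, strip_w))
            hi_v = V1 - (max(1, ceil_div(k_l2, strip_w)) if k_l2 else 0)
            Vp = V1 if k_l2 == 0 else min(max(_snap(v_p), lo_v), hi_v)
        else:
            Vp = 0

        if p > 0:
            stack.append((tup(u0, v0, u_a, v1),
                          blk_tup(U0, V0, Ua, V1) if blk else None, lo, lo + p))
        out[lo + p] = (tup(u_a, v0, u_b, v_p),
                       blk_tup(Ua, V0, Ub, Vp) if blk else None)
        n_l2 = split - (p + 1)
        if n_l2 == 1:
            out[lo + p + 1] = (tup(u_a, v_p, u_b, v1),
                               blk_tup(Ua, Vp, Ub, V1) if blk else None)
        elif n_l2 > 1:
            stack.append((tup(u_a, v_p, u_b, v1),
                          blk_tup(Ua, Vp, Ub, V1) if blk else None,
                          lo + p + 1, lo + split))
        if split < m:
            stack.append((tup(u_b, v0, u1, v1),
                          blk_tup(Ub, V0, U1, V1) if blk else None,
                          lo + split, hi))
    return out


def _descend(tree: HierarchyTree, width: float, height: float, with_blocks: bool):
    """Walk the tree level by level; returns (rects, leaf_blocks)."""
    counts = tree.descendant_leaf_counts()
    a = width * height / counts["root"]
    rects = {"root": Rect(0.0, 0.0, float(width), float(height))}
    node_rect_c = {"root": (0.0, 0.0, float(width), float(height))}
    node_block = {"root": (0, 0, int(round(width)), int(round(height))) if with_blocks else None}
    leaf_blocks: dict = {}

    def walk(node: TreeNode) -> None:
        if not node.children:
            if with_blocks and node.kind == "leaf":
                c0, r0, c1, r1 = node_block[node.key]
                if c1 <= c0 or r1 <= r0:
                    raise ResolutionError(
                        f"leaf {node.key!r} received an empty pixel block; "
                        "increase the canvas resolution"
                    )
                leaf_blocks[node.key] = (r0, r1, c0, c1)
            return
        child_counts = [counts[c.key] for c in node.children]
        pieces = _split_children(
            node_rect_c[node.key], node_block[node.key], child_counts, a
        )
        for child, (rc, blk) in zip(node.children, pieces):
            node_rect_c[child.key] = rc
            node_block[child.key] = blk
            rects[child.key] = Rect(*rc)
            walk(child)

    walk(tree.root)
    return rects, leaf_blocks


def layout_tree(tree: HierarchyTree, width: float, height: float) -> dict:
    """Compute the nested rectangle of every tree node on a width x height canvas.

    Returns a mapping node key -> Rect.  The root rectangle is the full
    canvas; at every internal node the children's rectangles tile the
    parent exactly, with area D(child) * a.
    """
    if not (width > 0 and height > 0):
        raise ValueError("canvas extents must be positive")
    rects, _ = _descend(tree, width, height, with_blocks=False)
    return rects


def order_genes_within_hierarchy(tree: HierarchyTree, means) -> HierarchyTree:
    """Return a copy of the tree with leaves sorted ascending by mean expression.

    ``means`` maps gene id -> mean expression (a pandas Series or dict).
    Ties break by gene id; category and hierarchy order are untouched.
    """
    getter = means.get if hasattr(means, "get") else means.__getitem__

    def mean_of(leaf: TreeNode) -> float:
        value = getter(leaf.gene_id)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise KeyError(f"no mean expression for gene {leaf.gene_id!r}")
        return float(value)

    root = TreeNode(name=tree.root.name, kind="root", key=tree.root.key)
    for cat in tree.root.children:
        cat_copy = TreeNode(name=cat.name, kind="category", key=cat.key)
        for hier in cat.children:
            leaves = sorted(hier.children, key=lambda lf: (mean_of(lf), lf.gene_id))
            hier_copy = TreeNode(
                name=hier.name, kind="hierarchy", key=hier.key,
                children=[
                    TreeNode(name=lf.name, kind="leaf", key=lf.key, gene_id=lf.gene_id)
                    for lf in leaves
                ],
            )
            cat_copy.children.append(hier_copy)
        root.children.append(cat_copy)
    return HierarchyTree(root)


@dataclass(frozen=True)
class TemplateLayout:
    """The image template T: per-node rectangles plus per-leaf pixel blocks.

    ``leaf_blocks`` maps leaf key -> (row0, row1, col0, col1) half-open pixel
    block; ``gene_leaves`` maps gene id -> tuple of its leaf keys (one per
    annotated hierarchy).  ``a_px`` is the nominal per-leaf pixel area.
    """

    r: int
    c: int
    rects: dict
    leaf_blocks: dict
    leaf_gene: dict
    gene_leaves: dict
    a_px: float

    def pixels(self, leaf_key: str) -> list:
        r0, r1, c0, c1 = self.leaf_blocks[leaf_key]
        return [(row, col) for row in range(r0, r1) for col in range(c0, c1)]

    def pixel_count(self, leaf_key: str) -> int:
        r0, r1, c0, c1 = self.leaf_blocks[leaf_key]
        return (r1 - r0) * (c1 - c0)

    def owner_grid(self) -> np.ndarray:
        """Pixel ownership: leaf index (insertion order) per pixel, -1 uncovered."""
        grid = np.full((self.r, self.c), -1, dtype=np.int32)
        for idx, (r0, r1, c0, c1) in enumerate(self.leaf_blocks.values()):
            grid[r0:r1, c0:c1] = idx
        return grid

    @property
    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "r": self.r,
                "c": self.c,
                "blocks": {k: list(v) for k, v in sorted(self.leaf_blocks.items())},
                "genes": {k: self.leaf_gene[k] for k in sorted(self.leaf_gene)},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "r": self.r,
                "c": self.c,
                "a_px": self.a_px,
                "rects": {k: [rc.x0, rc.y0, rc.x1, rc.y1] for k, rc in self.rects.items()},
                "leaf_blocks": {k: list(v) for k, v in self.leaf_blocks.items()},
                "leaf_gene": self.leaf_gene,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TemplateLayout":
        obj = json.loads(text)
        gene_leaves: dict = {}
        for key, gene in obj["leaf_gene"].items():
            gene_leaves.setdefault(gene, []).append(key)
        return cls(
            r=obj["r"],
            c=obj["c"],
            rects={k: Rect(*v) for k, v in obj["rects"].items()},
            leaf_blocks={k: tuple(v) for k, v in obj["leaf_blocks"].items()},
            leaf_gene=obj["leaf_gene"],
            gene_leaves={g: tuple(v) for g, v in gene_leaves.items()},
            a_px=obj["a_px"],
        )


def rasterize_layout(tree: HierarchyTree, rects: dict, r: int, c: int) -> TemplateLayout:
    """Snap the layout of ``tree`` onto an r x c pixel grid.

    The subdivision that produced ``rects`` is replayed with split
    boundaries rounded to the grid and clamped to keep one pixel per leaf;
    :class:`ResolutionError` is raised when the grid cannot hold all
    leaves.  Pixel blocks tile without overlap by construction.
    """
    if tree.n_leaves() > r * c:
        raise ResolutionError(
            f"{tree.n_leaves()} leaves cannot fit an {r}x{c} grid"
        )
    _, leaf_blocks = _descend(tree, float(c), float(r), with_blocks=True)
    leaf_gene = {leaf.key: leaf.gene_id for leaf in tree.leaves()}
    gene_leaves: dict = {}
    for key, gene in leaf_gene.items():
        gene_leaves.setdefault(gene, []).append(key)
    layout = TemplateLayout(
        r=int(r),
        c=int(c),
        rects=rects,
        leaf_blocks=leaf_blocks,
        leaf_gene=leaf_gene,
        gene_leaves={g: tuple(v) for g, v in gene_leaves.items()},
        a_px=r * c / tree.n_leaves(),
    )
    report = validate_template(layout)
    if not report["disjoint"]:
        raise ValueError("rasterized leaf pixel blocks overlap")
    return layout


def validate_template(T: TemplateLayout) -> dict:
    """Report-only sanity summary of a template layout."""
    sizes = np.array([T.pixel_count(k) for k in T.leaf_blocks], dtype=float)
    covered = int(sizes.sum())
    grid = np.zeros((T.r, T.c), dtype=np.int32)
    for r0, r1, c0, c1 in T.leaf_blocks.values():
        grid[r0:r1, c0:c1] += 1
    disjoint = bool((grid <= 1).all())
    return {
        "n_leaves": len(T.leaf_blocks),
        "min_pixels": int(sizes.min()) if sizes.size else 0,
        "max_pixels": int(sizes.max()) if sizes.size else 0,
        "mean_pixels": float(sizes.mean()) if sizes.size else 0.0,
        "max_rel_deviation": float(np.abs(sizes - T.a_px).max() / T.a_px) if sizes.size else 0.0,
        "covered_pixels": covered,
        "uncovered_pixels": T.r * T.c - int((grid > 0).sum()),
        "disjoint": disjoint,
    }


def build_template(tree: HierarchyTree, means, r: int = 175, c: int = 175) -> TemplateLayout:
    """Order leaves by mean expression, lay out the tree and rasterize.

    Convenience wrapper producing the template T used for all samples: the
    result depends only on the tree and the per-gene means, never on any
    individual sample's values.
    """
    ordered = order_genes_within_hierarchy(tree, means)
    rects = layout_tree(ordered, float(c), float(r))
    return rasterize_layout(ordered, rects, r, c)
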