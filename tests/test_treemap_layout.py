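"""Ordered treemap layout, rasterization and template validation."""

import numpy as np
import pandas as pd
import pytest

from gexmap.synthetic_data import SyntheticConfig, simulate_hierarchy
from gexmap.treemap_layout import (
    Rect,
    ResolutionError,
    TemplateLayout,
    build_template,
    layout_tree,
    order_genes_within_hierarchy,
    rasterize_layout,
    validate_template,
)

TOL = 1e-9


class TestLayoutTree:
    def test_four_categories_tile_level_one(self, make_tree):
        tree = make_tree({
            f"cat{i}": {f"h{i}": [f"g{i}a", f"g{i}b"]} for i in range(4)
        })
        rects = layout_tree(tree, 8.0, 8.0)
        level1 = [rects[c.key] for c in tree.categories()]
        assert len(level1) == 4
        assert sum(rc.area for rc in level1) == pytest.approx(64.0, abs=TOL)

    def test_single_leaf_gets_full_canvas(self, make_tree):
        tree = make_tree({"c": {"h": ["g"]}})
        rects = layout_tree(tree, 5.0, 3.0)
        leaf = rects["h:g"]
        assert (leaf.x0, leaf.y0, leaf.x1, leaf.y1) == (0.0, 0.0, 5.0, 3.0)

    def test_area_formula_on_211_split(self, make_tree):
        # leaf counts (2,1,1) on a 4x1 canvas: areas must equal D(rec)*a = (2,1,1)
        tree = make_tree({"c": {"h1": ["a", "b"], "h2": ["c"], "h3": ["d"]}})
        rects = layout_tree(tree, 4.0, 1.0)
        counts = tree.descendant_leaf_counts()
        a = 4.0 * 1.0 / counts["root"]
        for key in ("h1", "h2", "h3"):
            assert rects[key].area == pytest.approx(counts[key] * a, abs=TOL)

    def test_area_conservation_everywhere_on_random_tree(self):
        cfg = SyntheticConfig(n_categories=3, hierarchies_per_category=4,
                              genes_per_hierarchy=7, multi_annotation_rate=0.2, seed=2)
        tree = simulate_hierarchy(cfg)
        rects = layout_tree(tree, 37.0, 23.0)
        counts = tree.descendant_leaf_counts()
        a = 37.0 * 23.0 / counts["root"]
        for key, rc in rects.items():
            assert rc.area == pytest.approx(counts[key] * a, abs=TOL)

    def test_children_tile_parent_without_gap_or_overlap(self):
        cfg = SyntheticConfig(n_categories=2, hierarchies_per_category=3,
                              genes_per_hierarchy=9, seed=4)
        tree = simulate_hierarchy(cfg)
        rects = layout_tree(tree, 20.0, 20.0)

        def check(node):
            if not node.children:
                return
            parent = rects[node.key]
            kids = [rects[c.key] for c in node.children]
            assert sum(k.area for k in kids) == pytest.approx(parent.area, abs=TOL)
            for k in kids:
                assert k.x0 >= parent.x0 - TOL and k.x1 <= parent.x1 + TOL
                assert k.y0 >= parent.y0 - TOL and k.y1 <= parent.y1 + TOL
            for child in node.children:
                check(child)

        check(tree.root)

    def test_degenerate_extent_rejected(self, make_tree):
        tree = make_tree({"c": {"h": ["g"]}})
        with pytest.raises(ValueError):
            layout_tree(tree, 0.0, 5.0)


class TestOrderGenesWithinHierarchy:
    def test_ascending_mean_order(self, make_tree):
        tree = make_tree({"c": {"h": ["gA", "gB", "gC"]}})
        means = {"gA": 5.0, "gB": 1.0, "gC": 3.0}
        ordered = order_genes_within_hierarchy(tree, means)
        assert [leaf.gene_id for leaf in ordered.leaves()] == ["gB", "gC", "gA"]

    def test_equal_means_fall_back_to_gene_id(self, make_tree):
        tree = make_tree({"c": {"h": ["g3", "g1", "g2"]}})
        ordered = order_genes_within_hierarchy(tree, dict.fromkeys(["g1", "g2", "g3"], 2.0))
        assert [leaf.gene_id for leaf in ordered.leaves()] == ["g1", "g2", "g3"]

    def test_matches_independent_sort_on_random_means(self, make_tree):
        rng = np.random.default_rng(11)
        genes = [f"g{i:02d}" for i in range(20)]
        tree = make_tree({"c": {"h": genes}})
        means = pd.Series(rng.normal(size=20), index=genes)
        ordered = order_genes_within_hierarchy(tree, means)
        expected = sorted(genes, key=lambda g: (means[g], g))
        assert [leaf.gene_id for leaf in ordered.leaves()] == expected

    def test_missing_mean_raises(self, make_tree):
        tree = make_tree({"c": {"h": ["g1", "g2"]}})
        with pytest.raises(KeyError, match="g2"):
            order_genes_within_hierarchy(tree, {"g1": 1.0})

    def test_hierarchy_order_untouched(self, make_tree):
        tree = make_tree({"c1": {"hB": ["g1"], "hA": ["g2"]}, "c2": {"hC": ["g3"]}})
        ordered = order_genes_within_hierarchy(tree, dict.fromkeys(["g1", "g2", "g3"], 0.0))
        assert [h.key for h in ordered.hierarchies()] == ["hB", "hA", "hC"]


def _pixel_center_oracle(rects, tree, r, c):
    """Assign every pixel center to the leaf rectangle containing it."""
    owner = {}
    leaves = {leaf.key: rects[leaf.key] for leaf in tree.leaves()}
    for row in range(r):
        for col in range(c):
            x, y = col + 0.5, row + 0.5
            for key, rc in leaves.items():
                if rc.x0 <= x < rc.x1 and rc.y0 <= y < rc.y1:
                    owner[(row, col)] = key
                    break
    return owner


class TestRasterizeLayout:
    def test_single_leaf_on_ten_by_ten(self, make_tree):
        tree = make_tree({"c": {"h": ["g"]}})
        T = build_template(tree, {"g": 0.0}, r=10, c=10)
        assert T.pixel_count("h:g") == 100

    def test_four_leaves_on_two_by_two_matches_pixel_oracle(self, make_tree):
        tree = make_tree({"c": {"h1": ["a", "b"], "h2": ["c", "d"]}})
        means = dict.fromkeys("abcd", 1.0)
        ordered = order_genes_within_hierarchy(tree, means)
        rects = layout_tree(ordered, 2.0, 2.0)
        T = rasterize_layout(ordered, rects, 2, 2)
        assert all(T.pixel_count(k) == 1 for k in T.leaf_blocks)
        oracle = _pixel_center_oracle(rects, ordered, 2, 2)
        for key in T.leaf_blocks:
            assert T.pixels(key) == [px for px, owner in oracle.items() if owner == key]

    def test_leaf_blocks_inside_hierarchy_rectangle(self, small_dataset):
        tree, sim, _ = small_dataset
        T = build_template(tree, sim.baseline_means, r=32, c=32)
        for hier_key in {k.split(":")[0] for k in T.leaf_blocks}:
            hrect = T.rects[hier_key]
            for key, (r0, r1, c0, c1) in T.leaf_blocks.items():
                if not key.startswith(hier_key + ":"):
                    continue
                assert c0 >= np.floor(hrect.x0) and c1 <= np.ceil(hrect.x1)
                assert r0 >= np.floor(hrect.y0) and r1 <= np.ceil(hrect.y1)

    def test_too_small_canvas_raises_resolution_error(self, make_tree):
        tree = make_tree({"c": {"h": [f"g{i}" for i in range(10)]}})
        with pytest.raises(ResolutionError):
            build_template(tree, dict.fromkeys((f"g{i}" for i in range(10)), 0.0), r=3, c=3)

    def test_deterministic_fingerprint(self, small_dataset):
        tree, sim, _ = small_dataset
        t1 = build_template(tree, sim.baseline_means, r=24, c=24)
        t2 = build_template(tree, sim.baseline_means, r=24, c=24)
        assert t1.fingerprint == t2.fingerprint
        assert t1.leaf_blocks == t2.leaf_blocks

    def test_template_depends_only_on_tree_and_means(self, small_dataset):
        # same tree and means but a different random sample set -> same template
        tree, sim, _ = small_dataset
        t1 = build_template(tree, sim.baseline_means, r=24, c=24)
        perturbed = sim.baseline_means.copy()  # identical values, fresh object
        t2 = build_template(tree, perturbed, r=24, c=24)
        assert t1.fingerprint == t2.fingerprint

    def test_json_round_trip(self, small_dataset):
        tree, sim, _ = small_dataset
        t1 = build_template(tree, sim.baseline_means, r=24, c=24)
        t2 = TemplateLayout.from_json(t1.to_json())
        assert t1.fingerprint == t2.fingerprint
        assert t1.a_px == t2.a_px


class TestValidateTemplate:
    def test_valid_template_passes_all_checks(self, small_dataset):
        tree, sim, _ = small_dataset
        report = validate_template(build_template(tree, sim.baseline_means, r=32, c=32))
        assert report["disjoint"]
        assert report["min_pixels"] >= 1
        assert report["n_leaves"] == tree.n_leaves()

    def test_corrupted_overlap_is_reported(self, make_tree):
        tree = make_tree({"c": {"h": ["a", "b"]}})
        T = build_template(tree, {"a": 0.0, "b": 1.0}, r=4, c=4)
        blocks = dict(T.leaf_blocks)
        first, second = list(blocks)
        blocks[second] = blocks[first]  # force identical (overlapping) blocks
        corrupted = TemplateLayout(
            r=T.r, c=T.c, rects=T.rects, leaf_blocks=blocks,
            leaf_gene=T.leaf_gene, gene_leaves=T.gene_leaves, a_px=T.a_px,
        )
        assert not validate_template(corrupted)["disjoint"]

    @pytest.mark.parametrize("seed", [0, 7])
    def test_full_scale_rasterization_across_tree_compositions(self, seed):
        """Every leaf keeps >= 1 pixel at 175x175 regardless of how the
        17723 annotations are spread (near-capacity regions force the
        feasibility-aware boundary search)."""
        from gexmap.synthetic_data import reference_shape_tree

        tree = reference_shape_tree(seed=seed)
        genes = sorted({leaf.gene_id for leaf in tree.leaves()})
        means = pd.Series(np.random.default_rng(seed).normal(size=len(genes)),
                          index=genes)
        report = validate_template(build_template(tree, means, r=175, c=175))
        assert report["min_pixels"] >= 1 and report["disjoint"]

    def test_pixel_sizes_within_rounding_bound(self):
        cfg = SyntheticConfig(n_categories=2, hierarchies_per_category=5,
                              genes_per_hierarchy=10, seed=13)
        tree = simulate_hierarchy(cfg)
        genes = sorted({leaf.gene_id for leaf in tree.leaves()})
        means = pd.Series(np.random.default_rng(0).normal(size=len(genes)), index=genes)
        T = build_template(tree, means, r=40, c=40)
        # |pixels - a| bounded by the block perimeter in pixels
        for key, (r0, r1, c0, c1) in T.leaf_blocks.items():
            perim = 2 * ((r1 - r0) + (c1 - c0))
            assert abs(T.pixel_count(key) - T.a_px) <= perim
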