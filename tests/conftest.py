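import numpy as np
import pandas as pd
import pytest

from gexmap.brite_hierarchy import ROOT_NAME, HierarchyTree, TreeNode
from gexmap.expression_data import ExpressionMatrix
from gexmap.synthetic_data import SyntheticConfig, simulate_dataset


@pytest.fixture
def make_tree():
    """Factory building a HierarchyTree from {category: {hierarchy: [genes]}}."""

    def _make(structure: dict) -> HierarchyTree:
        root = TreeNode(name=ROOT_NAME, kind="root", key="root")
        for cat_name, hiers in structure.items():
            cat = TreeNode(name=cat_name, kind="category", key=f"cat:{cat_name}")
            for hier_name, genes in hiers.items():
                hier = TreeNode(name=hier_name, kind="hierarchy", key=hier_name)
                for gene in genes:
                    hier.children.append(
                        TreeNode(name=gene, kind="leaf",
                                 key=f"{hier_name}:{gene}", gene_id=gene)
                    )
                cat.children.append(hier)
            root.children.append(cat)
        return HierarchyTree(root)

    return _make


@pytest.fixture
def make_matrix():
    """Factory building an ExpressionMatrix from a nested dict or array."""

    def _make(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
        arr = np.asarray(values, dtype=float)
        gene_ids = gene_ids or [f"g{i + 1}" for i in range(arr.shape[0])]
        sample_ids = sample_ids or [f"s{j + 1}" for j in range(arr.shape[1])]
        return ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=sample_ids))

    return _make


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_categories=2,
        hierarchies_per_category=2,
        genes_per_hierarchy=10,
        n_samples=60,
        n_cohorts=2,
        n_signal_hierarchies=1,
        canvas=16,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)
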