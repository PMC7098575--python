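"""Synthetic hierarchy trees, expression matrices and censored outcomes.

The generator produces a miniature of the full study: a functional
hierarchy (root -> categories -> hierarchies -> gene leaves, with a
fraction of genes annotated under a second hierarchy), an expression
matrix whose outcome signal is concentrated in a few "signal" hierarchies
(a mean shift added to all of their genes for high-risk samples), and
right-censored progression outcomes whose event times are exponential with
a higher hazard in the high-risk group.  Because the signal lives at
hierarchy-block level, the hierarchy-driven image layout is genuinely
informative relative to a random gene arrangement — the mechanism the
image ablations probe.

Defaults are sized for desk-scale experiments: 4 categories x 3
hierarchies x 40 genes (480 genes), 4 cohorts x 120 samples, a 64 x 64
canvas, and outcome parameters giving roughly a 13% positive rate at the
default 230-day horizon (the full-scale cohorts report 9-12%).

A separate helper builds a tree with the published reference shape of the
full-scale functional catalogue (4 categories, 45 hierarchies of which the
metabolism category holds 9, 17723 leaves over 7509 distinct genes); apart
from those totals its composition is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .brite_hierarchy import ROOT_NAME, HierarchyTree, TreeNode
from .expression_data import ExpressionMatrix, PhenotypeTable

__all__ = [
    "SyntheticConfig",
    "SimulatedExpression",
    "simulate_hierarchy",
    "simulate_expression",
    "simulate_survival",
    "simulate_dataset",
    "reference_shape_tree",
    "write_expression_tsv",
    "write_phenotype_tsv",
    "write_brite_files",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the miniature simulation.

    ``effect_size`` is the mean log-expression shift added, for high-risk
    samples, to every gene of the ``n_signal_hierarchies`` signal
    hierarchies; ``noise_sd`` is the per-gene Gaussian noise SD in the same
    log units.  ``event_time_scale`` is the mean event time (days) of the
    low-risk group; high-risk hazards are ``hazard_ratio`` times larger.
    ``censoring_rate`` is the target fraction of censored records under
    independent uniform censoring.
    """

    n_categories: int = 4
    hierarchies_per_category: int = 3
    genes_per_hierarchy: int = 40
    multi_annotation_rate: float = 0.1
    n_samples: int = 120          # per cohort
    n_cohorts: int = 4
    n_signal_hierarchies: int = 2
    effect_size: float = 0.5
    noise_sd: float = 1.0
    risk_fraction: float = 0.3
    censoring_rate: float = 0.3
    event_time_scale: float = 4500.0
    hazard_ratio: float = 8.0
    horizon_days: float = 230.0
    canvas: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_categories, self.hierarchies_per_category,
                  self.genes_per_hierarchy, self.n_samples, self.n_cohorts,
                  self.n_signal_hierarchies)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for name in ("multi_annotation_rate", "censoring_rate", "risk_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0 or self.event_time_scale <= 0 or self.hazard_ratio <= 0:
            raise ValueError("noise_sd, event_time_scale, hazard_ratio must be positive")


def simulate_hierarchy(cfg: SyntheticConfig) -> HierarchyTree:
    """Build a random tree: categories, hierarchies and gene leaves.

    Every gene belongs to one home hierarchy; a ``multi_annotation_rate``
    fraction is additionally annotated under a second, randomly chosen
    hierarchy (one extra leaf each).
    """
    rng = np.random.default_rng(cfg.seed)
    root = TreeNode(name=ROOT_NAME, kind="root", key="root")
    hierarchy_nodes = []
    gene_counter = 0
    for ci in range(cfg.n_categories):
        cat = TreeNode(name=f"Category {ci + 1}", kind="category", key=f"cat:C{ci + 1}")
        for hi in range(cfg.hierarchies_per_category):
            hid = f"hs{ci + 1:02d}{hi + 1:02d}"
            hier = TreeNode(name=f"Hierarchy {hid}", kind="hierarchy", key=hid)
            for _ in range(cfg.genes_per_hierarchy):
                gene_counter += 1
                gid = f"G{gene_counter:05d}"
                hier.children.append(
                    TreeNode(name=gid, kind="leaf", key=f"{hid}:{gid}", gene_id=gid)
                )
            cat.children.append(hier)
            hierarchy_nodes.append(hier)
        root.children.append(cat)
    # second annotations
    n_hier = len(hierarchy_nodes)
    if n_hier > 1 and cfg.multi_annotation_rate > 0:
        for home_idx, hier in enumerate(list(hierarchy_nodes)):
            for leaf in list(hier.children):
                if rng.random() < cfg.multi_annotation_rate:
                    other_idx = int(rng.integers(n_hier - 1))
                    if other_idx >= home_idx:
                        other_idx += 1
                    other = hierarchy_nodes[other_idx]
                    if any(lf.gene_id == leaf.gene_id for lf in other.children):
                        continue
                    other.children.append(
                        TreeNode(name=leaf.gene_id, kind="leaf",
                                 key=f"{other.key}:{leaf.gene_id}", gene_id=leaf.gene_id)
                    )
    return HierarchyTree(root)


@dataclass(frozen=True)
class SimulatedExpression:
    """Expression matrix plus the latent generative state behind it."""

    matrix: ExpressionMatrix
    risk: np.ndarray            # 0/1 per sample
    cohorts: np.ndarray         # cohort label per sample
    signal_hierarchies: tuple   # hierarchy keys carrying the effect
    signal_genes: tuple         # gene ids carrying the effect
    baseline_means: pd.Series   # per-gene baseline mean


def simulate_expression(tree: HierarchyTree, cfg: SyntheticConfig) -> SimulatedExpression:
    """Draw log-scale expression values with hierarchy-localized risk signal.

    Baseline per-gene means are drawn once (so mean-expression ordering is
    non-trivial); per-sample values add Gaussian noise; high-risk samples
    receive ``effect_size`` on every signal-hierarchy gene.  All cohorts
    share the mechanism, so transfer from base to target cohorts is
    beneficial by construction.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    hierarchies = tree.hierarchies()
    genes = sorted({leaf.gene_id for leaf in tree.leaves()})
    n_genes = len(genes)
    n_total = cfg.n_samples * cfg.n_cohorts

    signal_idx = rng.choice(len(hierarchies), size=min(cfg.n_signal_hierarchies,
                                                       len(hierarchies)), replace=False)
    signal_keys = tuple(hierarchies[i].key for i in sorted(signal_idx))
    signal_genes = tuple(sorted({
        leaf.gene_id for i in signal_idx for leaf in hierarchies[i].children
    }))

    baseline = pd.Series(rng.normal(4.0, 1.5, size=n_genes), index=genes)
    risk = (rng.random(n_total) < cfg.risk_fraction).astype(int)
    cohorts = np.repeat([f"C{k + 1:02d}" for k in range(cfg.n_cohorts)], cfg.n_samples)
    values = baseline.to_numpy()[:, None] + rng.normal(0.0, cfg.noise_sd,
                                                       size=(n_genes, n_total))
    sig_rows = np.array([genes.index(g) for g in signal_genes], dtype=int)
    values[np.ix_(sig_rows, np.flatnonzero(risk == 1))] += cfg.effect_size

    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    return SimulatedExpression(
        matrix=matrix, risk=risk, cohorts=cohorts,
        signal_hierarchies=signal_keys, signal_genes=signal_genes,
        baseline_means=baseline,
    )


def _censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound of U(0, cmax) censoring achieving a target censoring rate.

    For event time T ~ Exp(rate) and C ~ U(0, cmax) the censoring
    probability is mean over subjects of (1 - exp(-rate*cmax))/(rate*cmax);
    solved for cmax by bisection.
    """

    def censor_prob(cmax: float) -> float:
        x = rates * cmax
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e9
    if target >= censor_prob(lo):
        return lo
    if target <= censor_prob(hi):
        return hi
    return float(optimize.brentq(lambda c: censor_prob(c) - target, lo, hi))


def simulate_survival(risk, cfg: SyntheticConfig, sample_ids=None,
                      cohorts=None) -> PhenotypeTable:
    """Right-censored progression outcomes driven by the latent risk flag.

    Event times are exponential with rate ``1/event_time_scale`` for
    low-risk samples and ``hazard_ratio``-fold higher for high-risk ones;
    censoring times are independent uniform, calibrated to the configured
    censoring rate.
    """
    risk = np.asarray(risk, dtype=int)
    n = len(risk)
    rng = np.random.default_rng(cfg.seed + 2)
    lam = (1.0 / cfg.event_time_scale) * np.where(risk == 1, cfg.hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        cmax = _censor_bound(lam, cfg.censoring_rate)
        censor_times = rng.uniform(0.0, cmax, size=n)
        observed = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        event = np.ones(n, dtype=int)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    if cohorts is None:
        cohorts = ["C01"] * n
    df = pd.DataFrame(
        {"cohort": list(cohorts), "pfi_event": event, "pfi_time": observed},
        index=pd.Index(sample_ids, name="sample"),
    )
    return PhenotypeTable(df)


def simulate_dataset(cfg: SyntheticConfig):
    """Full draw: (tree, SimulatedExpression, PhenotypeTable)."""
    tree = simulate_hierarchy(cfg)
    sim = simulate_expression(tree, cfg)
    pheno = simulate_survival(sim.risk, cfg, sample_ids=sim.matrix.sample_ids,
                              cohorts=sim.cohorts)
    return tree, sim, pheno


# per-category hierarchy counts of the reference-shaped tree; the metabolism
# category's 9 matches the published catalogue, the other splits are synthetic
_REFERENCE_CATEGORIES = (
    ("Orthologs and modules", 12),
    ("Protein families: metabolism", 9),
    ("Protein families: genetic information processing", 10),
    ("Protein families: signaling and cellular processes", 14),
)


def reference_shape_tree(n_leaves: int = 17723, n_genes: int = 7509,
                         seed: int = 0) -> HierarchyTree:
    """A synthetic tree with the reference shape of the full-scale catalogue.

    4 categories holding 45 hierarchies (9 of them under the metabolism
    category), ``n_leaves`` leaves drawn from ``n_genes`` distinct genes.
    Every gene has one home hierarchy; the surplus ``n_leaves - n_genes``
    annotations are spread deterministically (seeded) across the other
    hierarchies.
    """
    if n_leaves < n_genes:
        raise ValueError("n_leaves must be >= n_genes")
    rng = np.random.default_rng(seed)
    n_hier = sum(k for _, k in _REFERENCE_CATEGORIES)
    genes = [f"ENSG{i:011d}" for i in range(1, n_genes + 1)]
    # home hierarchy per gene: spread evenly
    home = np.arange(n_genes) % n_hier
    members: list = [set() for _ in range(n_hier)]
    for gi, hi in enumerate(home):
        members[hi].add(gi)
    extra = n_leaves - n_genes
    placed = 0
    while placed < extra:
        gi = int(rng.integers(n_genes))
        hi = int(rng.integers(n_hier))
        if gi in members[hi]:
            continue
        members[hi].add(gi)
        placed += 1

    root = TreeNode(name=ROOT_NAME, kind="root", key="root")
    hier_index = 0
    for cat_name, k in _REFERENCE_CATEGORIES:
        cat = TreeNode(name=cat_name, kind="category", key=f"cat:{cat_name}")
        for _ in range(k):
            hid = f"hs{hier_index + 1:05d}"
            hier = TreeNode(name=f"Hierarchy {hid}", kind="hierarchy", key=hid)
            for gi in sorted(members[hier_index]):
                hier.children.append(
                    TreeNode(name=genes[gi], kind="leaf",
                             key=f"{hid}:{genes[gi]}", gene_id=genes[gi])
                )
            cat.children.append(hier)
            hier_index += 1
        root.children.append(cat)
    return HierarchyTree(root)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> Path:
    """Write the genes x samples TSV dialect the expression reader consumes."""
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    return path


def write_phenotype_tsv(pheno: PhenotypeTable, path) -> Path:
    """Write the phenotype TSV dialect (sample, cohort, PFI, PFI.time)."""
    path = Path(path)
    df = pheno.data.rename(columns={"pfi_event": "PFI", "pfi_time": "PFI.time"})
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    return path


def write_brite_files(tree: HierarchyTree, directory) -> dict:
    """Emit BRITE-style reference, link, list and HGNC files for a tree.

    The four files round-trip through the real parsers and mapping chain:
    each synthetic gene id doubles as its own KEGG id, symbol and ENSEMBL
    id (one row per hop), so rebuilding the tree from these files recovers
    the input tree exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ref = directory / "brite_reference.txt"
    link = directory / "brite_link.tsv"
    lst = directory / "kegg_list.tsv"
    hgnc = directory / "hgnc_complete_set.tsv"

    with open(ref, "w") as fh:
        fh.write(f"A<b>{tree.root.name}</b>\n")
        for cat in tree.root.children:
            fh.write(f"B  {cat.name}\n")
            for hier in cat.children:
                fh.write(f"C    {hier.key}  {hier.name}\n")
    with open(link, "w") as fh:
        for hier in tree.hierarchies():
            for leaf in hier.children:
                fh.write(f"br:{hier.key}\thsa:{leaf.gene_id}\n")
    genes = sorted({leaf.gene_id for leaf in tree.leaves()})
    with open(lst, "w") as fh:
        for gene in genes:
            fh.write(f"hsa:{gene}\tSYM_{gene}; synthetic gene {gene}\n")
    with open(hgnc, "w") as fh:
        fh.write("hgnc_id\tsymbol\tensembl_gene_id\n")
        for i, gene in enumerate(genes, start=1):
            fh.write(f"HGNC:{i}\tSYM_{gene}\t{gene}\n")
    return {"reference": ref, "link": link, "list": lst, "hgnc": hgnc}
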