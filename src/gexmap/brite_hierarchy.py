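"""Functional-hierarchy tree construction from KEGG BRITE reference files.

The tree is rooted at "Genes and Proteins"; level 1 holds functional
categories, level 2 the individual BRITE hierarchies (each with a BRITE
identifier) and level 3 the gene leaves.  A gene annotated under several
hierarchies appears once per hierarchy, so the number of leaves can exceed
the number of distinct genes.  Connecting the hierarchies to the genes of
an expression matrix (ENSEMBL identifiers) requires a chain of mapping
tables: BRITE id -> KEGG human gene id -> HUGO symbol -> ENSEMBL id, with
the symbol hop served by the HGNC complete set.  All relations may be
many-to-many.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TreeNode",
    "HierarchyTree",
    "BriteCatalogue",
    "IdMapChain",
    "parse_brite_reference",
    "parse_link_table",
    "build_id_chain",
    "build_hierarchy_tree",
    "annotated_gene_set",
]

ROOT_NAME = "Genes and Proteins"


@dataclass
class TreeNode:
    """A node of the functional-hierarchy tree.

    ``kind`` is one of root/category/hierarchy/leaf; ``key`` is unique within
    a tree (leaves use "<hierarchy id>:<gene id>").  ``gene_id`` is set on
    leaves only.
    """

    name: str
    kind: str
    key: str
    children: list = field(default_factory=list)
    gene_id: str | None = None

    def leaf_count(self) -> int:
        if self.kind == "leaf":
            return 1
        return sum(c.leaf_count() for c in self.children)

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass
class HierarchyTree:
    """Rooted tree: root -> categories -> hierarchies -> gene leaves."""

    root: TreeNode

    def __post_init__(self) -> None:
        seen = set()
        for node in self.root.iter_nodes():
            if node.key in seen:
                raise ValueError(f"duplicate node key: {node.key!r}")
            seen.add(node.key)
        for hier in self.hierarchies():
            genes = [leaf.gene_id for leaf in hier.children]
            if len(genes) != len(set(genes)):
                raise ValueError(f"gene repeated under hierarchy {hier.key!r}")

    def categories(self) -> list:
        return list(self.root.children)

    def hierarchies(self) -> list:
        return [h for cat in self.root.children for h in cat.children]

    def leaves(self) -> list:
        return [leaf for h in self.hierarchies() for leaf in h.children]

    def descendant_leaf_counts(self) -> dict:
        """D(node) for every node key: the number of descendant leaves."""
        return {node.key: node.leaf_count() for node in self.root.iter_nodes()}

    def n_leaves(self) -> int:
        return self.root.leaf_count()


def annotated_gene_set(tree: HierarchyTree) -> set:
    """Distinct genes occurring among the leaves of the tree."""
    return {leaf.gene_id for leaf in tree.leaves()}


@dataclass(frozen=True)
class BriteCatalogue:
    """Hierarchy catalogue parsed from the BRITE reference flat file.

    ``categories`` preserves first-appearance order; ``entries`` maps BRITE
    id -> (name, category), insertion-ordered.
    """

    categories: tuple
    entries: dict

    def __len__(self) -> int:
        return len(self.entries)


def _strip_prefix(token: str) -> str:
    for prefix in ("br:", "hsa:", "ko:"):
        if token.startswith(prefix):
            return token[len(prefix):]
    return token


def _strip_markup(text: str) -> str:
    return text.replace("<b>", "").replace("</b>", "").strip()


def parse_brite_reference(path) -> BriteCatalogue:
    """Parse a BRITE reference flat file (br08902 dialect).

    Lines start with a level letter: ``A`` section (root group), ``B``
    category, ``C`` hierarchy entry "<BRITE id>  <name>".  Header lines
    (``#``, ``!``, ``+``, ``%``) and blanks are skipped.
    """
    categories: list = []
    entries: dict = {}
    current_category = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line[0] in "#!+%":
                continue
            marker, rest = line[0], line[1:].strip()
            if marker == "A":
                current_category = None  # new section; categories come from B lines
                continue
            if marker == "B":
                current_category = _strip_markup(rest)
                if current_category not in categories:
                    categories.append(current_category)
                continue
            if marker == "C":
                if current_category is None:
                    raise ValueError(
                        f"{path}:{lineno}: hierarchy entry before any category"
                    )
                parts = rest.split(None, 1)
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed hierarchy entry")
                brite_id = _strip_prefix(parts[0])
                entries[brite_id] = (parts[1].strip(), current_category)
                continue
            raise ValueError(f"{path}:{lineno}: unknown level marker {marker!r}")
    return BriteCatalogue(categories=tuple(categories), entries=entries)


def parse_link_table(path) -> list:
    """Parse a two-column KEGG link table into de-duplicated (BRITE id, gene id) pairs.

    ``br:``/``hsa:`` prefixes are stripped; row order of first appearance is kept.
    """
    pairs: list = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            pair = (_strip_prefix(cols[0].strip()), _strip_prefix(cols[1].strip()))
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    return pairs


@dataclass(frozen=True)
class IdMapChain:
    """Many-to-many identifier mappings KEGG gene <-> HUGO symbol <-> ENSEMBL.

    ``unmapped_symbols`` records HUGO symbols seen in the KEGG list that have
    no ENSEMBL id in the HGNC table (their genes drop out of the chain).
    """

    kegg_to_symbols: dict
    symbol_to_ensembl: dict
    ensembl_to_symbols: dict
    unmapped_symbols: frozenset

    def kegg_to_ensembl(self, kegg_gene_id: str) -> set:
        out = set()
        for sym in self.kegg_to_symbols.get(kegg_gene_id, ()):
            out.update(self.symbol_to_ensembl.get(sym, ()))
        return out


def _first_symbol(description: str) -> str:
    """Extract the primary HUGO symbol from a KEGG list-file description.

    The description's leading token up to the first comma or semicolon is
    taken as the symbol (e.g. "TP53, BCC7; tumor protein p53" -> "TP53").
    """
    head = description.split(";", 1)[0].split(",", 1)[0]
    return head.strip()


def build_id_chain(kegg_list_path, hgnc_path) -> IdMapChain:
    """Compose the KEGG-gene <-> HUGO <-> ENSEMBL mapping chain.

    ``kegg_list_path`` is the KEGG gene-list table (id TAB description);
    ``hgnc_path`` the HGNC complete-set TSV with ``symbol`` and
    ``ensembl_gene_id`` columns.
    """
    kegg_to_symbols: dict = {}
    with open(kegg_list_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(
                    f"{kegg_list_path}:{lineno}: expected at least 2 columns"
                )
            kegg_id = _strip_prefix(cols[0].strip())
            # some dialects interpose type/position columns; the description is last
            symbol = _first_symbol(cols[-1])
            if symbol:
                kegg_to_symbols.setdefault(kegg_id, []).append(symbol)

    hgnc = pd.read_csv(hgnc_path, sep="\t", dtype=str, low_memory=False)
    for col in ("symbol", "ensembl_gene_id"):
        if col not in hgnc.columns:
            raise ValueError(f"HGNC table {hgnc_path} missing column {col!r}")
    symbol_to_ensembl: dict = {}
    ensembl_to_symbols: dict = {}
    for sym, ens in zip(hgnc["symbol"], hgnc["ensembl_gene_id"]):
        if pd.isna(sym) or pd.isna(ens):
            continue
        for eid in str(ens).split("|"):
            eid = eid.strip()
            if not eid:
                continue
            symbol_to_ensembl.setdefault(sym, []).append(eid)
            ensembl_to_symbols.setdefault(eid, []).append(sym)

    symbols_seen = {s for syms in kegg_to_symbols.values() for s in syms}
    unmapped = frozenset(s for s in symbols_seen if s not in symbol_to_ensembl)
    return IdMapChain(
        kegg_to_symbols=kegg_to_symbols,
        symbol_to_ensembl=symbol_to_ensembl,
        ensembl_to_symbols=ensembl_to_symbols,
        unmapped_symbols=unmapped,
    )


def build_hierarchy_tree(
    catalogue: BriteCatalogue,
    links,
    chain: IdMapChain,
    gene_universe,
) -> HierarchyTree:
    """Assemble the annotated tree restricted to genes of ``gene_universe``.

    Leaves are exactly the (gene, hierarchy) pairs whose gene maps into the
    universe through the identifier chain; hierarchies without any mapped
    gene and categories without any hierarchy are pruned.  Category and
    hierarchy order follow the catalogue; genes keep first-mapped order and
    collapse to one leaf per (gene, hierarchy).
    """
    universe = set(gene_universe)
    hier_genes: dict = {bid: [] for bid in catalogue.entries}
    for brite_id, kegg_gene in links:
        if brite_id not in hier_genes:
            continue
        for gene in sorted(chain.kegg_to_ensembl(kegg_gene)):
            if gene in universe and gene not in hier_genes[brite_id]:
                hier_genes[brite_id].append(gene)

    root = TreeNode(name=ROOT_NAME, kind="root", key="root")
    for category in catalogue.categories:
        cat_node = TreeNode(name=category, kind="category", key=f"cat:{category}")
        for brite_id, (name, cat) in catalogue.entries.items():
            if cat != category or not hier_genes[brite_id]:
                continue
            hier_node = TreeNode(name=name, kind="hierarchy", key=brite_id)
            for gene in hier_genes[brite_id]:
                hier_node.children.append(
                    TreeNode(
                        name=gene,
                        kind="leaf",
                        key=f"{brite_id}:{gene}",
                        gene_id=gene,
                    )
                )
            cat_node.children.append(hier_node)
        if cat_node.children:
            root.children.append(cat_node)
    if not root.children:
        raise ValueError("no annotated genes: gene universe is disjoint from the mapping chain")
    return HierarchyTree(root)
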