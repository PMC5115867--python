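"""Homolog grouping, gene-tree/species-tree reconciliation and
duplication dating.

The chain: filter all-vs-all protein similarity hits on E-value, match
length, coverage and identity; cluster the resulting similarity graph
into homologous groups with the Markov cluster (MCL) iteration; reconcile
each rooted gene tree against the species tree by LCA mapping to label
internal nodes as duplications or speciations; date each gene's most
recent duplication onto a species-tree branch, accepting the call only
when the duplication node and its two children all carry branch support
above a threshold; and classify focal-species genes into
multi-copy / WGT-retained / lineage-duplication-retained categories with
a disjoint WGT pair list.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .trees import GeneTree, SpeciesTree, parse_gene_leaf

__all__ = [
    "SimilarityHit",
    "filter_hits",
    "mcl_cluster",
    "reconcile_lca",
    "call_most_recent_duplication",
    "classify_retention",
    "ReconciledTree",
    "DuplicationCall",
]


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    evalue: float
    length: int          # aligned amino acids
    coverage: float      # fraction of query covered
    identity: float      # fraction identical

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be nonnegative")
        if not (0 <= self.coverage <= 1 and 0 <= self.identity <= 1):
            raise ValueError("coverage and identity must lie in [0, 1]")


def filter_hits(
    hits: Iterable[SimilarityHit],
    e_max: float = 1e-20,
    len_min: int = 60,
    cov_min: float = 0.60,
    id_min: float = 0.50,
) -> Dict[Tuple[str, str], float]:
    """Filter hits into an undirected similarity graph.

    A hit survives iff E < ``e_max``, length > ``len_min``, coverage >
    ``cov_min`` and identity > ``id_min`` (all strict).  Self-hits are
    dropped; reciprocal hits are merged keeping the best (smallest)
    E-value.  Returns ``{(gene1, gene2): evalue}`` with sorted pairs.
    """
    graph: Dict[Tuple[str, str], float] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        if not (h.evalue < e_max and h.length > len_min
                and h.coverage > cov_min and h.identity > id_min):
            continue
        key = tuple(sorted((h.query, h.subject)))
        if key not in graph or h.evalue < graph[key]:
            graph[key] = h.evalue
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    graph: Dict[Tuple[str, str], float],
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    nodes: Optional[Sequence[str]] = None,
    evalue_weights: bool = True,
) -> List[Set[str]]:
    """Markov clustering of the similarity graph.

    Edge weight is ``-log10(E)`` capped at 200 when ``evalue_weights``
    (the graph values are then E-values), otherwise the raw value.
    Self-loops with each node's maximum incident weight are added, the
    matrix is made column-stochastic, and expansion (matrix squaring) and
    inflation (entrywise power + column renormalization) are iterated
    until the largest column change drops below ``tol``.  Clusters are the
    connected components of the limit matrix's support.  Deterministic for
    a fixed node order (sorted).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    node_set = set()
    for a, b in graph:
        node_set.update((a, b))
    if nodes is not None:
        node_set.update(nodes)
    names = sorted(node_set)
    if not names:
        return []
    idx = {g: i for i, g in enumerate(names)}
    n = len(names)
    M = np.zeros((n, n))
    for (a, b), val in graph.items():
        w = min(200.0, -np.log10(max(val, 1e-300))) if evalue_weights \
            else float(val)
        w = max(w, 0.0)
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated = inflated / inflated.sum(axis=0, keepdims=True)
        inflated[inflated < 1e-12] = 0.0
        inflated = inflated / inflated.sum(axis=0, keepdims=True)
        change = np.max(np.abs(inflated - M))
        M = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning current clustering")

    # connected components of the support
    support = (M > 1e-8) | (M.T > 1e-8)
    np.fill_diagonal(support, True)
    seen = np.zeros(n, dtype=bool)
    clusters: List[Set[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.add(names[u])
            for v in np.nonzero(support[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        clusters.append(comp)
    clusters.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return clusters


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReconciledTree:
    """Gene tree annotated with per-internal-node events.

    ``mapping`` sends each gene-tree node (by id) to a species-tree node;
    ``events`` labels internal nodes ``"duplication"`` or
    ``"speciation"``.
    """

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: Dict[int, object]
    events: Dict[int, str]

    def duplication_nodes(self):
        return [nid for nid, ev in self.events.items()
                if ev == "duplication"]


def _species_lca_tables(stree: SpeciesTree):
    """Depth and parent tables for iterative LCA on the species tree."""
    depth, parent = {}, {}
    for node in stree.tree.preorder_node_iter():
        p = node.parent_node
        parent[id(node)] = p
        depth[id(node)] = 0 if p is None else depth[id(p)] + 1
    return depth, parent


def _lca(a, b, depth, parent):
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = parent[id(b)]
        else:
            a = parent[id(a)]
    return a


def reconcile_lca(gene_tree: GeneTree, species_tree: SpeciesTree
                  ) -> ReconciledTree:
    """Standard LCA reconciliation.

    Each gene-tree node maps to the LCA of its children's mappings; a node
    is a duplication iff it maps to the same species-tree node as one of
    its children.
    """
    depth, parent = _species_lca_tables(species_tree)
    mapping: Dict[int, object] = {}
    events: Dict[int, str] = {}
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            sp, _ = parse_gene_leaf(node.taxon.label)
            try:
                mapping[id(node)] = species_tree.leaf_node(sp)
            except KeyError:
                raise ValueError(
                    f"leaf {node.taxon.label!r}: species {sp!r} missing "
                    "from species tree") from None
            continue
        kids = node.child_nodes()
        m = mapping[id(kids[0])]
        for c in kids[1:]:
            m = _lca(m, mapping[id(c)], depth, parent)
        mapping[id(node)] = m
        dup = any(mapping[id(c)] is m for c in kids)
        events[id(node)] = "duplication" if dup else "speciation"
    return ReconciledTree(gene_tree=gene_tree, species_tree=species_tree,
                          mapping=mapping, events=events)


# ---------------------------------------------------------------------------
# most-recent-duplication calls
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DuplicationCall:
    gene: str
    branch: Optional[str]      # species-tree branch label, None = no dup
    verdict: str               # "accepted" | "uncertain"


def call_most_recent_duplication(
    gene: str,
    rec: ReconciledTree,
    support_min: float = 0.9,
) -> DuplicationCall:
    """Date a gene's most recent duplication under the support rule.

    Walking from the leaf toward the root, the first duplication node is
    the candidate; the call is accepted iff the candidate's support and
    both its children's supports (leaves count 1.0) all strictly exceed
    ``support_min``.  The reported branch is the species-tree branch above
    the candidate's mapped node.  No duplication on the path gives
    ``(None, accepted)``.
    """
    leaf = None
    for lf in rec.gene_tree.tree.leaf_node_iter():
        if lf.taxon.label == gene:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"gene {gene!r} is not a leaf of the gene tree")
    node = leaf.parent_node
    while node is not None:
        if rec.events.get(id(node)) == "duplication":
            supports = [GeneTree.support_of(node)] + [
                GeneTree.support_of(c) for c in node.child_nodes()
            ]
            ok = all(np.isfinite(s) and s > support_min for s in supports)
            branch = rec.species_tree.branch_label(rec.mapping[id(node)])
            return DuplicationCall(
                gene=gene, branch=branch,
                verdict="accepted" if ok else "uncertain")
        node = node.parent_node
    return DuplicationCall(gene=gene, branch=None, verdict="accepted")


def call_all(rec: ReconciledTree, support_min: float = 0.9
             ) -> List[DuplicationCall]:
    return [call_most_recent_duplication(g, rec, support_min)
            for g in rec.gene_tree.gene_ids()]


# ---------------------------------------------------------------------------
# retention classification
# ---------------------------------------------------------------------------

def _tree_distance(gene_tree: GeneTree, a: str, b: str) -> int:
    """Topological (edge-count) distance between two leaves."""
    nodes = {lf.taxon.label: lf for lf in gene_tree.tree.leaf_node_iter()}
    anc_a = []
    node = nodes[a]
    while node is not None:
        anc_a.append(id(node))
        node = node.parent_node
    anc_a_pos = {nid: i for i, nid in enumerate(anc_a)}
    node, steps = nodes[b], 0
    while id(node) not in anc_a_pos:
        node = node.parent_node
        steps += 1
    return steps + anc_a_pos[id(node)]


def classify_retention(
    calls: Sequence[DuplicationCall],
    expressed: Set[str],
    wgt_branch: str,
    lineage_branches: Set[str],
    focal_species: str,
    families: Optional[Sequence[Tuple[str, Dict[str, str]]]] = None,
    gene_trees: Optional[Sequence[GeneTree]] = None,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Per-gene retention classes plus the disjoint WGT pair list.

    Genes with uncertain calls are excluded from the table.  WGT pairs are
    unordered pairs of focal-species genes from the same homolog group
    whose most recent duplication maps to the WGT branch and that are both
    in ``expressed``; each gene joins at most one pair, chosen greedily by
    gene-tree proximity (closest pairs first).
    """
    rows = []
    for call in calls:
        sp, _ = parse_gene_leaf(call.gene)
        if sp != focal_species or call.verdict != "accepted":
            continue
        multi = call.branch is not None
        wgt = multi and call.branch == wgt_branch
        nld = multi and call.branch in lineage_branches and not wgt
        rows.append((call.gene, multi, wgt, nld))
    table = pd.DataFrame(
        rows, columns=["gene", "multi_copy", "wgt_retained", "nld_retained"]
    ).set_index("gene")

    pairs: List[Tuple[str, str]] = []
    if families is not None:
        tree_of: Dict[str, GeneTree] = {}
        if gene_trees is not None:
            for gt in gene_trees:
                for g in gt.gene_ids():
                    tree_of[g] = gt
        eligible = set(table.index[table["wgt_retained"]]) & set(expressed)
        for fam_id, members in families:
            cand = sorted(g for g in members if g in eligible)
            if len(cand) < 2:
                continue
            scored = []
            for i in range(len(cand)):
                for j in range(i + 1, len(cand)):
                    a, b = cand[i], cand[j]
                    gt = tree_of.get(a)
                    d = _tree_distance(gt, a, b) if gt is not None else 2
                    scored.append((d, a, b))
            scored.sort()
            used: Set[str] = set()
            for _, a, b in scored:
                if a in used or b in used:
                    continue
                pairs.append((a, b))
                used.update((a, b))
    return table, pairs
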