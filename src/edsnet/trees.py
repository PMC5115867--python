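"""Rooted trees for the comparative pipeline.

Thin wrappers around :mod:`dendropy` trees fixing two conventions used
throughout the package:

* **Species trees** — every node label names the *branch above* that node
  (the root label names the stem branch).  Exactly one branch carries the
  whole-genome-triplication label (``SOL_WGT_STEM`` in the six-species
  preset), and a set of branches is designated as focal-lineage branches.
* **Gene trees** — leaves carry gene identifiers of the form
  ``<species>|<gene>``; internal node labels, when numeric in [0, 1], are
  branch supports (approximate-Bayes style).
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, List, Optional

import dendropy

__all__ = [
    "SpeciesTree",
    "GeneTree",
    "read_newick",
    "parse_gene_leaf",
    "make_gene_id",
]

GENE_SEP = "|"


class NewickParseError(ValueError):
    """Raised when newick text cannot be parsed."""


def _parse_tree(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickParseError(f"could not parse newick: {exc}") from exc
    return tree


def _write_tree(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_annotations=True,
    )
    return s.strip() + "\n"


def make_gene_id(species: str, gene: str) -> str:
    return f"{species}{GENE_SEP}{gene}"


def parse_gene_leaf(label: str) -> tuple:
    """Split a ``species|gene`` leaf label into (species, gene)."""
    if GENE_SEP not in label:
        raise ValueError(f"gene leaf label {label!r} lacks a species prefix")
    species, gene = label.split(GENE_SEP, 1)
    return species, gene


class SpeciesTree:
    """A rooted species tree with labelled branches.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  Node labels (and, for leaves,
        taxon labels) are interpreted as the label of the branch above the
        node; unlabelled internal branches are assigned ``B<i>`` labels.
    wgt_label:
        Label of the branch carrying the whole-genome triplication.
    focal_labels:
        Branch labels of the focal lineage (defaults to every branch below
        the root, i.e. lineage-specific branches).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        wgt_label: str = "SOL_WGT_STEM",
        focal_labels: Optional[Iterable[str]] = None,
    ):
        self.tree = tree
        self.wgt_label = wgt_label
        self._label_branches()
        if focal_labels is None:
            focal_labels = [
                self.branch_label(n)
                for n in tree.preorder_node_iter()
                if n is not tree.seed_node
            ]
        self.focal_labels = set(focal_labels)
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, **kwargs) -> "SpeciesTree":
        return cls(_parse_tree(text), **kwargs)

    def _label_branches(self) -> None:
        self._branch_of: Dict[int, str] = {}
        counter = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
            elif node.label:
                label = str(node.label)
            else:
                counter += 1
                label = f"B{counter}"
                node.label = label
            self._branch_of[id(node)] = label
        self._node_of = {
            self._branch_of[id(n)]: n for n in self.tree.preorder_node_iter()
        }

    def _validate(self) -> None:
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            raise ValueError("species tree leaf names are not unique")
        labels = list(self._branch_of.values())
        if len(labels) != len(set(labels)):
            raise ValueError("species tree branch labels are not unique")
        if sum(1 for v in labels if v == self.wgt_label) != 1:
            raise ValueError(
                f"species tree must carry exactly one {self.wgt_label!r} branch"
            )

    # -- queries -----------------------------------------------------------
    def leaf_names(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def branch_label(self, node: dendropy.Node) -> str:
        return self._branch_of[id(node)]

    def node_of_branch(self, label: str) -> dendropy.Node:
        return self._node_of[label]

    @property
    def wgt_node(self) -> dendropy.Node:
        return self._node_of[self.wgt_label]

    def leaf_node(self, species: str) -> dendropy.Node:
        node = self._node_of.get(species)
        if node is None or not node.is_leaf():
            raise KeyError(f"species {species!r} not in species tree")
        return node

    def branch_labels(self) -> List[str]:
        return [self._branch_of[id(n)] for n in self.tree.preorder_node_iter()]

    def to_newick(self) -> str:
        return _write_tree(self.tree)

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


class GeneTree:
    """A rooted gene tree whose leaves carry ``species|gene`` labels."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        for leaf in tree.leaf_node_iter():
            parse_gene_leaf(leaf.taxon.label)  # raises on malformed labels

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        return cls(_parse_tree(text))

    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def gene_ids(self) -> List[str]:
        return self.leaf_labels()

    def species_of(self, leaf_label: str) -> str:
        return parse_gene_leaf(leaf_label)[0]

    @staticmethod
    def support_of(node: dendropy.Node) -> float:
        """Branch support of an internal node; leaves count as 1.0."""
        if node.is_leaf():
            return 1.0
        if node.label is None:
            return float("nan")
        try:
            val = float(node.label)
        except ValueError:
            return float("nan")
        return val if 0.0 <= val <= 1.0 else float("nan")

    def to_newick(self) -> str:
        return _write_tree(self.tree)

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


def read_newick(source: str, kind: str = "auto"):
    """Parse newick text (or a path) into a :class:`SpeciesTree` or
    :class:`GeneTree`.

    ``kind`` is one of ``"species"``, ``"gene"`` or ``"auto"`` (gene when
    every leaf label contains the ``species|gene`` separator).
    """
    text = source
    if "(" not in source:  # treat as path
        with io.open(source) as fh:
            text = fh.read()
    tree = _parse_tree(text)
    if kind == "auto":
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        kind = "gene" if all(GENE_SEP in l for l in labels) else "species"
    if kind == "gene":
        return GeneTree(tree)
    if kind == "species":
        return SpeciesTree(tree)
    raise ValueError(f"unknown tree kind {kind!r}")
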