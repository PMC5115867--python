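"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the study design the pipeline targets: six closely
related species in a fixed rooted phylogeny whose stem branch carries a
whole-genome triplication (WGT); a two-treatment (control wounding ``WW``
vs elicitor ``FAC``) by three-replicate RNA-seq design per species with
negative-binomial counts, species-level batch effects and one planted
co-expression module whose induction covaries with a per-sample defense
hormone trait; gene families evolved by branch-wise birth/death
duplication and loss including the stem triplication; and pairwise codon
alignments diverged at a controlled synonymous distance and dN/dS ratio.

Everything is seeded and returns explicit truth objects so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trees import GeneTree, SpeciesTree, make_gene_id

__all__ = [
    "NICOTIANA6_NEWICK",
    "make_species_tree",
    "simulate_gene_families",
    "simulate_expression",
    "simulate_codon_pairs",
    "SimulatedFamilyTruth",
    "SimulatedExpressionTruth",
    "ExpressionDesign",
]

#: Fixed six-species preset: two non-responding species branch off first,
#: the stem branch above the crown carries the triplication label.
NICOTIANA6_NEWICK = (
    "(N_obtusifolia,(N_miersii,((N_linearis,N_acuminata)NIC_3,"
    "(N_pauciflora,N_attenuata)NIC_4)NIC_2)NIC_1)SOL_WGT_STEM;"
)

WGT_LABEL = "SOL_WGT_STEM"


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def make_species_tree(
    preset_or_n="nicotiana6", seed: int = 0
) -> SpeciesTree:
    """Build a species tree, either the fixed six-leaf preset or a random
    rooted topology with ``n`` leaves.

    The stem branch above the root is always the WGT branch; every branch
    below the root is a focal-lineage branch.
    """
    if preset_or_n == "nicotiana6":
        return SpeciesTree.from_newick(NICOTIANA6_NEWICK, wgt_label=WGT_LABEL)
    n = int(preset_or_n)
    if n < 2:
        raise ValueError(f"random species tree needs n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    # random rooted topology by sequential random attachment
    subtrees = [f"SP{i+1}" for i in range(n)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b})")
    newick = subtrees[0] + WGT_LABEL + ";"
    return SpeciesTree.from_newick(newick, wgt_label=WGT_LABEL)


# ---------------------------------------------------------------------------
# gene families on the species tree
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedFamilyTruth:
    """Ground truth for simulated gene families.

    ``mrd_branch`` maps each emitted gene to the species-tree branch label
    of its most recent duplication that survives in the emitted (pruned)
    gene tree, or ``None`` for single-lineage descent.  ``events`` maps
    each family to its surviving event list ``(branch, type)``.
    """

    mrd_branch: Dict[str, Optional[str]]
    events: Dict[str, List[Tuple[str, str]]]


class _Node:
    __slots__ = ("children", "kind", "branch", "gene")

    def __init__(self, kind, branch=None, gene=None, children=None):
        self.kind = kind  # "dup" | "spec" | "leaf"
        self.branch = branch
        self.gene = gene
        self.children = children or []


def simulate_gene_families(
    tree: SpeciesTree,
    n_families: int,
    dup_rate_per_branch: float = 0.05,
    wgt_retention_prob: float = 0.25,
    loss_prob: float = 0.0,
    support_model: Optional[Tuple[float, float]] = None,
    seed: int = 0,
):
    """Evolve gene families along the species tree.

    Each branch draws a Poisson number of binary duplications per incoming
    lineage; on the WGT stem branch every incoming lineage triplicates,
    with each of the two extra copies retained independently with
    ``wgt_retention_prob``.  A lineage entering a branch is lost with
    ``loss_prob``.  Branch supports on emitted gene trees are 1.0 when
    ``support_model`` is None, otherwise Beta(a, b) draws.

    Returns ``(gene_trees, families, truth)`` where ``families`` is a list
    of ``(family_id, {gene_id: species})`` homolog groups (single-gene
    families included; gene trees only for families with >= 2 genes).
    """
    if not (0.0 <= wgt_retention_prob <= 1.0 and 0.0 <= loss_prob <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if dup_rate_per_branch < 0:
        raise ValueError("duplication rate must be nonnegative")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    wgt_node = tree.wgt_node

    gene_trees: List[GeneTree] = []
    families: List[Tuple[str, Dict[str, str]]] = []
    mrd: Dict[str, Optional[str]] = {}
    all_events: Dict[str, List[Tuple[str, str]]] = {}

    for fam_idx in range(n_families):
        fam_id = f"F{fam_idx:05d}"
        counter = [0]
        events: List[Tuple[str, str]] = []

        def new_gene(species: str) -> str:
            counter[0] += 1
            return make_gene_id(species, f"{fam_id}.{counter[0]}")

        def continue_below(sp_node) -> Optional[_Node]:
            # a lineage that reached the bottom of the edge above sp_node
            if sp_node.is_leaf():
                return _Node("leaf", gene=new_gene(sp_node.taxon.label))
            kids = []
            for child in sp_node.child_nodes():
                sub = evolve_lineage(child)
                if sub is not None:
                    kids.append(sub)
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return _Node("spec", branch=tree.branch_label(sp_node),
                         children=kids)

        def evolve_lineage(sp_node) -> Optional[_Node]:
            # one lineage entering the edge above sp_node
            branch = tree.branch_label(sp_node)
            if loss_prob > 0 and rng.random() < loss_prob:
                events.append((branch, "loss"))
                return None
            n_extra = 0
            wgt_extra = 0
            if sp_node is wgt_node:
                wgt_extra = int(rng.binomial(2, wgt_retention_prob))
            if dup_rate_per_branch > 0:
                n_extra = int(rng.poisson(dup_rate_per_branch))
            subtrees = []
            for k in range(1 + wgt_extra + n_extra):
                sub = continue_below(sp_node)
                if sub is not None:
                    subtrees.append(sub)
            if wgt_extra:
                events.append((branch, "triplication"))
            events.extend([(branch, "duplication")] * n_extra)
            if not subtrees:
                return None
            # nest surviving copies as duplication nodes on this branch
            node = subtrees[0]
            for sub in subtrees[1:]:
                node = _Node("dup", branch=branch, children=[node, sub])
            return node

        root = evolve_lineage(tree.tree.seed_node)
        genes: Dict[str, str] = {}
        if root is not None:
            _collect(root, genes, mrd, ancestor_dup=None)
        families.append((fam_id, genes))
        all_events[fam_id] = events
        if len(genes) >= 2:
            newick = _to_newick(root, rng, support_model) + ";"
            gene_trees.append(GeneTree.from_newick(newick))

    truth = SimulatedFamilyTruth(mrd_branch=mrd, events=all_events)
    return gene_trees, families, truth


def _collect(node: _Node, genes, mrd, ancestor_dup):
    if node.kind == "leaf":
        species = node.gene.split("|", 1)[0]
        genes[node.gene] = species
        mrd[node.gene] = ancestor_dup
        return
    for child in node.children:
        _collect(child, genes, mrd,
                 node.branch if node.kind == "dup" else ancestor_dup)


def _to_newick(node: _Node, rng, support_model) -> str:
    if node.kind == "leaf":
        return node.gene
    inner = ",".join(_to_newick(c, rng, support_model)
                     for c in node.children)
    if support_model is None:
        support = 1.0
    else:
        a, b = support_model
        support = float(rng.beta(a, b))
    return f"({inner}){support:.4f}"


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionDesign:
    """Per-species treatment layout of the count experiment."""

    treatments: Tuple[str, str] = ("WW", "FAC")
    n_replicates: int = 3
    responsive_species: Optional[Sequence[str]] = None  # default: 4 of 6


@dataclasses.dataclass
class SimulatedExpressionTruth:
    """Planted structure of a simulated count experiment."""

    module_genes: List[str]
    effects: Dict[str, float]          # per planted gene, log2 induction
    trait: pd.Series                   # per-sample trait value
    responsive_species: List[str]
    batch_sd: float
    dispersion: float
    module_activity: pd.Series         # latent per-sample module state
    decoy_modules: Optional[Dict[int, List[str]]] = None


def simulate_expression(
    tree: SpeciesTree,
    n_genes: int = 2000,
    design: Optional[ExpressionDesign] = None,
    module_size: int = 100,
    n_decoy_modules: int = 4,
    decoy_size: int = 75,
    effect_log2: float = 2.0,
    batch_sd: float = 0.5,
    dispersion: float = 0.1,
    trait_amplitude: float = 100.0,
    trait_noise: float = 10.0,
    base_log2_mean: float = 7.0,
    base_log2_sd: float = 1.2,
    depth_sd: float = 0.15,
    seed: int = 0,
):
    """Simulate a gene x sample count table with one planted module.

    Counts are NB(mean, dispersion) with variance ``mu + phi * mu**2``.
    Planted-module genes receive their log2 induction effect only in
    (responsive species, elicited treatment) cells, modulated by a shared
    per-sample latent activity that also drives the trait (the analogue of
    the maximum induced JA level shortly after elicitation).  A further
    ``n_decoy_modules`` co-expression modules are driven by latent sample
    factors unrelated to treatment or trait, emulating the background
    modules of a real transcriptome.

    Returns ``(counts, lengths, metadata, truth)``.
    """
    if design is None:
        design = ExpressionDesign()
    if module_size + n_decoy_modules * decoy_size > n_genes:
        raise ValueError("planted modules larger than gene universe")
    if module_size < 0 or n_genes < 1:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)

    species = tree.leaf_names()
    responsive = design.responsive_species
    if responsive is None:
        # by default the two earliest-branching species do not respond
        responsive = species[2:] if len(species) > 2 else species
    responsive = list(responsive)

    rows = []
    for sp in species:
        for trt in design.treatments:
            for rep in range(1, design.n_replicates + 1):
                rows.append((f"{sp}.{trt}.{rep}", sp, trt, rep))
    meta = pd.DataFrame(rows, columns=["sample", "species", "treatment",
                                       "replicate"]).set_index("sample")
    n_samples = len(meta)
    elicited = meta["treatment"] == design.treatments[1]
    induced_cell = (elicited & meta["species"].isin(responsive)).to_numpy()

    genes = [f"G{i:05d}" for i in range(n_genes)]
    module_genes = genes[:module_size]
    effects = {
        g: float(effect_log2 * rng.uniform(0.9, 1.1)) for g in module_genes
    }

    # shared latent module activity: zero outside induced cells, jittered
    # amplitude inside them; drives both the planted module and the trait
    state = np.where(induced_cell, 1.0, 0.0)
    activity = state * (1.0 + rng.normal(0.0, 0.05, size=n_samples))
    trait = trait_amplitude * activity + rng.normal(
        0.0, trait_noise, size=n_samples
    )

    base = rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    batch = rng.normal(0.0, batch_sd, size=(n_genes, len(species)))
    sp_idx = {sp: j for j, sp in enumerate(species)}
    col_batch = np.array([sp_idx[s] for s in meta["species"]])
    depth = 2.0 ** rng.normal(0.0, depth_sd, size=n_samples)

    log2_mu = base[:, None] + batch[:, col_batch]
    eff = np.zeros((n_genes, n_samples))
    for i, g in enumerate(module_genes):
        eff[i] = effects[g] * activity
    # decoy modules: latent factors independent of treatment and trait
    decoys: Dict[int, List[str]] = {}
    offset = module_size
    for d in range(n_decoy_modules):
        members = genes[offset:offset + decoy_size]
        factor = rng.normal(0.0, 1.0, size=n_samples)
        loadings = rng.uniform(0.4, 0.7, size=decoy_size)
        eff[offset:offset + decoy_size] += loadings[:, None] * factor[None, :]
        decoys[d + 2] = list(members)
        offset += decoy_size
    log2_mu = log2_mu + eff
    mu = (2.0 ** log2_mu) * depth[None, :]

    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    counts = pd.DataFrame(counts, index=genes, columns=meta.index)
    lengths = pd.Series(rng.integers(500, 3001, size=n_genes),
                        index=genes, name="length")

    truth = SimulatedExpressionTruth(
        module_genes=list(module_genes),
        effects=effects,
        trait=pd.Series(trait, index=meta.index, name="trait"),
        responsive_species=responsive,
        batch_sd=batch_sd,
        dispersion=dispersion,
        module_activity=pd.Series(activity, index=meta.index,
                                  name="module_activity"),
        decoy_modules=decoys,
    )
    meta = meta.assign(trait=truth.trait)
    return counts, lengths, meta, truth


# ---------------------------------------------------------------------------
# codon pairs
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_table() -> Dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def simulate_codon_pairs(
    omega: float,
    target_ks: float,
    n_codons: int = 300,
    n_pairs: int = 100,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str]], float, float]:
    """Diverge codon-sequence pairs from random ancestors.

    Nucleotide positions receive Poisson(``target_ks`` / 2) mutation
    events on each of the two branches; synonymous changes are always
    accepted, nonsynonymous changes with probability ``omega``, and
    changes creating stop codons are rejected.  Under degeneracy-weighted
    site counting the expected synonymous divergence is ``target_ks`` and
    the nonsynonymous/synonymous rate ratio is ``omega``.

    Returns ``(pairs, omega, target_ks)`` with pairs as (seq1, seq2).
    """
    if n_codons < 50:
        raise ValueError("need at least 50 codons")
    if omega < 0 or target_ks < 0:
        raise ValueError("omega and target_ks must be nonnegative")
    rng = np.random.default_rng(seed)
    table = _codon_table()
    sense = sorted(c for c in table if table[c] != "*")
    lam = target_ks / 2.0

    pairs = []
    for _ in range(n_pairs):
        anc = list("".join(rng.choice(sense) for _ in range(n_codons)))
        seqs = []
        for _branch in range(2):
            seq = list("".join(anc))
            if lam > 0:
                n_events = rng.poisson(lam, size=len(seq))
                for pos in np.nonzero(n_events)[0]:
                    for _e in range(n_events[pos]):
                        _mutate(seq, int(pos), rng, table, omega)
            seqs.append("".join(seq))
        pairs.append((seqs[0], seqs[1]))
    return pairs, float(omega), float(target_ks)


def _mutate(seq, pos, rng, table, omega):
    old = seq[pos]
    alt = rng.choice([b for b in _BASES if b != old])
    c0 = pos - pos % 3
    codon = seq[c0:c0 + 3]
    new_codon = list(codon)
    new_codon[pos - c0] = alt
    old_aa = table["".join(codon)]
    new_aa = table["".join(new_codon)]
    if new_aa == "*":
        return  # rejected: never emit stop codons
    if old_aa == new_aa or rng.random() < omega:
        seq[pos] = str(alt)
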