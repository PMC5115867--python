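"""Weighted co-expression networks, module detection and preservation.

Implements the WGCNA-style chain: soft-threshold power selection by
scale-free topology fit, unsigned correlation adjacency, topological
overlap (TOM), average-linkage module detection on 1 - TOM, module
eigengenes / membership (kME) / intramodular connectivity (kIM), hub and
core-gene sets, module-trait coupling, permutation module preservation
(Z-density, Z-connectivity, Z-summary) and edge-list export.

Expression matrices are genes x samples DataFrames throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "ModuleSet",
    "PreservationResult",
    "select_top_connected",
    "pick_soft_power",
    "build_network",
    "detect_modules",
    "module_statistics",
    "module_trait_correlation",
    "module_preservation",
    "export_edges",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoexpressionNetwork:
    genes: pd.Index
    adjacency: np.ndarray          # symmetric, zero diagonal
    tom: np.ndarray                # symmetric, diagonal fixed at 1
    power: float
    signed: bool = False

    def connectivity(self) -> pd.Series:
        return pd.Series(self.adjacency.sum(axis=0), index=self.genes,
                         name="connectivity")


@dataclasses.dataclass
class ModuleSet:
    """Gene-to-module assignment plus per-gene network statistics.

    Module label 0 means unassigned; labels are ordered by decreasing
    module size.
    """

    labels: pd.Series                          # gene -> int label
    eigengenes: Optional[pd.DataFrame] = None  # samples x modules
    kme: Optional[pd.Series] = None
    kim: Optional[pd.Series] = None
    core: Optional[pd.Index] = None
    hubs: Optional[pd.Index] = None

    def module_genes(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def module_labels(self) -> List[int]:
        return sorted(l for l in self.labels.unique() if l != 0)


@dataclasses.dataclass
class PreservationResult:
    module: int
    z_density: float
    z_connectivity: float
    z_summary: float
    p_value: float
    n_permutations: int
    p_is_floor: bool = False


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _corr(expr: pd.DataFrame) -> np.ndarray:
    mat = expr.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[np.nonzero(sd == 0)[0][0]]
        raise ValueError(f"gene {bad!r} has zero variance")
    c = np.corrcoef(mat)
    return np.clip(c, -1.0, 1.0)


def _adjacency(cor: np.ndarray, power: float, signed: bool) -> np.ndarray:
    if signed:
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def select_top_connected(
    expr: pd.DataFrame, k: int = 5000, power: float = 6.0,
    signed: bool = False,
) -> pd.Index:
    """Rank genes by soft connectivity (adjacency row sums) and keep the
    top ``k``; ties break lexicographically by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = _adjacency(_corr(expr), power, signed)
    conn = pd.Series(adj.sum(axis=0), index=expr.index)
    order = sorted(expr.index, key=lambda g: (-conn[g], g))
    return pd.Index(order[: min(k, len(order))])


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned, log10 mean connectivity per bin is
    regressed against log10 frequency; the index is ``-sign(slope) * R^2``
    so only decaying degree laws score highly.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2), float(slope)


def pick_soft_power(
    expr: pd.DataFrame,
    candidates: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    Returns ``(power, table)`` where the table lists the fit index and
    slope per candidate.  If no candidate reaches the target the best
    fitting one is returned with a warning.  Constant genes are dropped
    with a warning before fitting.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to pick a power")
    if expr.shape[1] < 8:
        warnings.warn("fewer than 8 samples: power selection is unstable")
    sd = expr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant genes")
        expr = expr.loc[sd > 0]
    cor = _corr(expr)
    rows = []
    for beta in candidates:
        adj = _adjacency(cor, float(beta), signed)
        r2, slope = scale_free_fit(adj.sum(axis=0))
        rows.append((beta, r2, slope))
    table = pd.DataFrame(rows, columns=["power", "sft_r2", "slope"])
    ok = table[table["sft_r2"] >= r2_target]
    if len(ok):
        power = int(ok["power"].iloc[0])
    else:
        power = int(table.loc[table["sft_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate reached R^2 >= {r2_target}; using best ({power})")
    return power, table


def build_network(
    expr: pd.DataFrame, power: float, signed: bool = False
) -> CoexpressionNetwork:
    """Adjacency ``|cor|**power`` (or signed variant) and unsigned TOM.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_u a_iu a_uj``; the TOM diagonal is fixed at 1.
    """
    adj = _adjacency(_corr(expr), power, signed)
    tom = _tom(adj)
    return CoexpressionNetwork(genes=expr.index, adjacency=adj, tom=tom,
                               power=power, signed=signed)


def _tom(adj: np.ndarray) -> np.ndarray:
    k = adj.sum(axis=0)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection and statistics
# ---------------------------------------------------------------------------

def detect_modules(
    network: CoexpressionNetwork,
    min_module_size: int = 30,
    cut_height: float = 0.98,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Branches below ``cut_height`` with at least ``min_module_size`` leaves
    become modules (labelled by decreasing size); everything else gets
    label 0.
    """
    n = len(network.genes)
    labels = pd.Series(0, index=network.genes, dtype=int)
    if n >= 2:
        dissim = 1.0 - network.tom
        np.fill_diagonal(dissim, 0.0)
        link = average(squareform(dissim, checks=False))
        raw = fcluster(link, t=cut_height, criterion="distance")
        sizes = pd.Series(raw).value_counts()
        keep = sizes[sizes >= min_module_size]
        # order surviving clusters by decreasing size, ties by cluster id
        ordered = sorted(keep.index, key=lambda c: (-keep[c], c))
        mapping = {c: i + 1 for i, c in enumerate(ordered)}
        labels[:] = [mapping.get(c, 0) for c in raw]
    return ModuleSet(labels=labels)


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component over samples of the standardized module
    expression, unit norm, sign-oriented toward the module mean."""
    mat = expr.to_numpy(dtype=float)
    mat = (mat - mat.mean(axis=1, keepdims=True))
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    mat = mat / sd
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    eig = vt[0]
    mean_profile = mat.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def module_statistics(
    expr: pd.DataFrame,
    network: CoexpressionNetwork,
    modules: ModuleSet,
    kme_core: float = 0.75,
    hub_fraction: float = 0.05,
    hub_samples: Optional[Sequence[str]] = None,
) -> ModuleSet:
    """Attach eigengenes, kME, kIM, core sets and hub sets.

    Core genes have signed kME above ``kme_core`` in their own module.
    Hubs are the top ``ceil(hub_fraction * n)`` genes by connectivity on
    the network computed from ``hub_samples`` (e.g. elicited samples
    only); defaults to all samples.
    """
    labels = modules.labels
    eigs = {}
    kme = pd.Series(np.nan, index=labels.index)
    kim = pd.Series(0.0, index=labels.index)
    gene_pos = {g: i for i, g in enumerate(network.genes)}

    for lab in modules.module_labels:
        genes = modules.module_genes(lab)
        sub = expr.loc[genes]
        eig = module_eigengene(sub)
        eigs[lab] = eig
        if len(genes) == 1:
            kme[genes] = 1.0
        else:
            centered = sub.to_numpy(float)
            centered = centered - centered.mean(axis=1, keepdims=True)
            ev = eig.to_numpy() - eig.to_numpy().mean()
            num = centered @ ev
            den = np.sqrt((centered ** 2).sum(axis=1) * (ev ** 2).sum())
            kme[genes] = num / np.where(den == 0, 1.0, den)
        pos = [gene_pos[g] for g in genes]
        kim[genes] = network.adjacency[np.ix_(pos, pos)].sum(axis=0)

    core = labels.index[(labels > 0) & (kme > kme_core)]

    if hub_samples is not None:
        hub_net = build_network(expr.loc[network.genes, list(hub_samples)],
                                network.power, network.signed)
        conn = hub_net.connectivity()
    else:
        conn = network.connectivity()
    n_hubs = int(np.ceil(hub_fraction * len(conn)))
    hub_order = sorted(conn.index, key=lambda g: (-conn[g], g))
    hubs = pd.Index(hub_order[:n_hubs])

    eig_df = pd.DataFrame(eigs) if eigs else None
    return ModuleSet(labels=labels, eigengenes=eig_df, kme=kme, kim=kim,
                     core=core, hubs=hubs)


def intramodular_connectivity(
    expr: pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str],
    power: float,
    signed: bool = False,
) -> pd.Series:
    """kIM of ``genes`` on the network rebuilt from ``samples`` only."""
    net = build_network(expr.loc[list(genes), list(samples)], power, signed)
    return pd.Series(net.adjacency.sum(axis=0), index=net.genes, name="kim")


# ---------------------------------------------------------------------------
# module-trait coupling
# ---------------------------------------------------------------------------

def module_trait_correlation(
    expr: pd.DataFrame,
    modules: ModuleSet,
    trait: pd.Series,
) -> tuple:
    """Mean per-gene trait correlation per module plus a rank test.

    Each gene's Pearson correlation with the trait is averaged per module
    (with its standard error); the top-ranking module's member
    correlations are compared with all other modules' member correlations
    by the Wilcoxon-Mann-Whitney test.

    Returns ``(table, gene_correlations)``; the table carries the focal
    rank-test p in ``attrs['focal_p']``.
    """
    trait = trait.reindex(expr.columns)
    if trait.isna().any():
        raise ValueError("trait missing for some samples")
    if trait.std() == 0:
        raise ValueError("trait is constant")
    tv = trait.to_numpy(float)
    tv = tv - tv.mean()
    mat = expr.to_numpy(float)
    mat = mat - mat.mean(axis=1, keepdims=True)
    den = np.sqrt((mat ** 2).sum(axis=1) * (tv ** 2).sum())
    cors = pd.Series((mat @ tv) / np.where(den == 0, np.nan, den),
                     index=expr.index, name="trait_cor")

    rows = []
    for lab in modules.module_labels:
        vals = cors[modules.module_genes(lab)].dropna()
        rows.append((lab, len(vals), vals.mean(),
                     vals.std(ddof=1) / np.sqrt(len(vals))
                     if len(vals) > 1 else np.nan))
    table = pd.DataFrame(rows, columns=["module", "n_genes", "mean_cor",
                                        "se"]).set_index("module")
    focal_p = np.nan
    if len(table) >= 2:
        focal = table["mean_cor"].idxmax()
        x = cors[modules.module_genes(focal)].dropna()
        others = [cors[modules.module_genes(l)].dropna()
                  for l in modules.module_labels if l != focal]
        y = pd.concat(others)
        if len(x) and len(y):
            focal_p = float(stats.mannwhitneyu(
                x, y, alternative="greater").pvalue)
        table.attrs["focal_module"] = int(focal)
    table.attrs["focal_p"] = focal_p
    return table, cors


# ---------------------------------------------------------------------------
# module preservation
# ---------------------------------------------------------------------------

def _preservation_stats(ref_adj, test_adj, pos):
    sub_ref = ref_adj[np.ix_(pos, pos)]
    sub_test = test_adj[np.ix_(pos, pos)]
    iu = np.triu_indices(len(pos), k=1)
    density = sub_test[iu].mean()
    kim_ref = sub_ref.sum(axis=0)
    kim_test = sub_test.sum(axis=0)
    cor_kim = _safe_cor(kim_ref, kim_test)
    cor_adj = _safe_cor(sub_ref[iu], sub_test[iu])
    return density, cor_kim, cor_adj


def _safe_cor(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    modules: ModuleSet,
    power: float = 6.0,
    signed: bool = False,
    n_perm: int = 200,
    seed: int = 0,
    min_overlap: float = 0.8,
) -> Dict[int, PreservationResult]:
    """Permutation Z statistics for module preservation in a test dataset.

    Observed statistics per module: mean within-module test adjacency
    (density), and the correlations of (kIM_ref, kIM_test) and of
    ref/test adjacency entries (connectivity).  Each is standardized
    against ``n_perm`` equally sized random gene sets; Z-connectivity is
    the median of its two statistics and Z-summary the mean of Z-density
    and Z-connectivity.  The permutation p is the upper-tail empirical p
    of the density with add-one correction (reported as a floor when no
    permutation reaches the observed value).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    common = ref_expr.index.intersection(test_expr.index)
    ref_net = build_network(ref_expr.loc[common], power, signed)
    test_net = build_network(test_expr.loc[common], power, signed)
    pos_of = {g: i for i, g in enumerate(common)}
    rng = np.random.default_rng(seed)

    results: Dict[int, PreservationResult] = {}
    for lab in modules.module_labels:
        genes = modules.module_genes(lab)
        present = [g for g in genes if g in pos_of]
        if len(genes) and len(present) / len(genes) < min_overlap:
            warnings.warn(
                f"module {lab}: only {len(present)}/{len(genes)} genes in "
                "test data; skipped")
            continue
        if len(present) < 3:
            warnings.warn(f"module {lab} has < 3 genes in test data; skipped")
            continue
        pos = np.array([pos_of[g] for g in present])
        obs = _preservation_stats(ref_net.adjacency, test_net.adjacency, pos)
        perm = np.empty((n_perm, 3))
        n_common = len(common)
        for it in range(n_perm):
            rand_pos = rng.choice(n_common, size=len(pos), replace=False)
            perm[it] = _preservation_stats(
                ref_net.adjacency, test_net.adjacency, rand_pos)
        mu = perm.mean(axis=0)
        sd = perm.std(axis=0, ddof=1)
        # degenerate permutation distribution (e.g. identical ref/test
        # data make every connectivity correlation 1): no evidence, Z = 0
        diff = np.array(obs) - mu
        degenerate = sd < 1e-12
        sd[degenerate] = 1.0
        z = diff / sd
        z[degenerate & (np.abs(diff) < 1e-9)] = 0.0
        z_density = float(z[0])
        z_connectivity = float(np.median(z[1:3]))
        z_summary = 0.5 * (z_density + z_connectivity)
        n_ge = int(np.sum(perm[:, 0] >= obs[0]))
        p = (n_ge + 1) / (n_perm + 1)
        results[lab] = PreservationResult(
            module=int(lab), z_density=z_density,
            z_connectivity=z_connectivity, z_summary=float(z_summary),
            p_value=float(p), n_permutations=n_perm,
            p_is_floor=(n_ge == 0),
        )
    return results


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_edges(
    network: CoexpressionNetwork, weight_cutoff: float = 0.15
) -> pd.DataFrame:
    """Undirected TOM edges with weight strictly above the cutoff, each
    pair once in lexicographic order."""
    genes = list(network.genes)
    iu = np.triu_indices(len(genes), k=1)
    w = network.tom[iu]
    keep = w > weight_cutoff
    rows = []
    for a, b, weight in zip(iu[0][keep], iu[1][keep], w[keep]):
        g1, g2 = sorted((genes[a], genes[b]))
        rows.append((g1, g2, float(weight)))
    rows.sort()
    return pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
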