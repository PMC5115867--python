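"""Retention-enrichment statistics.

Category enrichment of a gene set against a genome-wide background with
the odds formula ``(p1/(1-p1)) / (p2/(1-p2))`` and an exact binomial
test; the chi-square test for preferential retention of duplicate pairs
in a module (observed 0/1/2-members-in-module counts against the
independent-recruitment null); and upstream transposable-element
insertion-window enrichment.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "PairRetentionResult",
    "category_odds_ratio",
    "binomial_enrichment",
    "pair_retention_chi2",
    "upstream_te_enrichment",
    "P_FLOOR",
    "format_p",
    "truncate2",
]

#: Reporting floor for vanishingly small p-values.
P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    return f"< {P_FLOOR:.1E}" if p < P_FLOOR else f"{p:.3G}"


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, the convention used in the
    human-readable enrichment report."""
    return np.floor(x * 100.0) / 100.0


@dataclasses.dataclass
class EnrichmentResult:
    k_cat_in_set: int
    n_set: int
    k_cat_genome: int
    n_genome: int
    p1: float
    p2: float
    odds: float
    p_value: float

    def as_row(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


def category_odds_ratio(
    k_cat_in_set: int, n_set: int, k_cat_genome: int, n_genome: int
) -> EnrichmentResult:
    """Enrichment of a category inside a gene set vs the genome.

    ``p1`` is the category fraction inside the set, ``p2`` genome-wide;
    ``odds = (p1/(1-p1)) / (p2/(1-p2))``, with an exact upper-tail
    binomial p for the set count at rate ``p2``.
    """
    if n_set <= 0 or n_genome <= 0:
        raise ValueError("set and genome sizes must be positive")
    p1 = k_cat_in_set / n_set
    p2 = k_cat_genome / n_genome
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("degenerate proportions: odds ratio undefined")
    odds = (p1 / (1 - p1)) / (p2 / (1 - p2))
    p = binomial_enrichment(k_cat_in_set, n_set, p2)
    return EnrichmentResult(
        k_cat_in_set=int(k_cat_in_set), n_set=int(n_set),
        k_cat_genome=int(k_cat_genome), n_genome=int(n_genome),
        p1=float(p1), p2=float(p2), odds=float(odds), p_value=float(p),
    )


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact one-sided (upper tail) binomial p: P(X >= k | n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("need 0 < p0 < 1")
    return float(stats.binom.sf(k - 1, n, p0))


@dataclasses.dataclass
class PairRetentionResult:
    n_pairs: int
    n_genes: int
    m_in_module: int
    observed_both: int
    observed_one: int
    observed_none: int
    expected_both: float
    expected_one: float
    expected_none: float
    chi2: float
    p_value: float
    exact_fallback: bool = False


def pair_retention_chi2(
    n_pairs: int, m_in_module: int, observed_both: int
) -> PairRetentionResult:
    """Chi-square test for co-retention of duplicate pairs in a module.

    Under independent recruitment each member of a pair enters the module
    with probability ``q = m / (2 * n_pairs)``; expected counts of pairs
    with 0/1/2 members in the module are Binomial(2, q) multiples of
    ``n_pairs``.  The Pearson chi-square (2 df) compares the observed
    category counts (observed one-member count = m - 2 * observed_both)
    to that expectation.  When an expected category drops below 1, an
    exact multinomial tail probability replaces the chi-square p.
    """
    if m_in_module > 2 * n_pairs:
        raise ValueError("module genes exceed the pair universe")
    if observed_both > min(n_pairs, m_in_module // 2):
        raise ValueError("more both-member pairs than possible")
    n_genes = 2 * n_pairs
    q = m_in_module / n_genes
    exp = n_pairs * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    obs_one = m_in_module - 2 * observed_both
    obs = np.array([n_pairs - observed_both - obs_one, obs_one,
                    observed_both], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    exact = False
    if exp.min() < 1.0:
        exact = True
        p = _multinomial_tail(n_pairs, exp / n_pairs, obs)
    else:
        p = float(stats.chi2.sf(chi2, df=2))
    return PairRetentionResult(
        n_pairs=int(n_pairs), n_genes=int(n_genes),
        m_in_module=int(m_in_module), observed_both=int(observed_both),
        observed_one=int(obs_one), observed_none=int(obs[0]),
        expected_none=float(exp[0]), expected_one=float(exp[1]),
        expected_both=float(exp[2]), chi2=chi2, p_value=float(p),
        exact_fallback=exact,
    )


def _multinomial_tail(n: int, probs: np.ndarray, obs: np.ndarray) -> float:
    """P(chi2 statistic >= observed) by exhaustive enumeration (only used
    for tiny expected counts, where n is small)."""
    obs_chi2 = np.sum((obs - n * probs) ** 2 / (n * probs))
    total = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            x = np.array([a, b, c], dtype=float)
            chi2 = np.sum((x - n * probs) ** 2 / (n * probs))
            if chi2 >= obs_chi2 - 1e-12:
                total += stats.multinomial.pmf([a, b, c], n, probs)
    return float(min(1.0, total))


# ---------------------------------------------------------------------------
# upstream TE-insertion enrichment
# ---------------------------------------------------------------------------

def upstream_te_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    insertions: pd.DataFrame,
    family: str,
    window_bp: int = 1000,
) -> Tuple[EnrichmentResult, Set[str]]:
    """Enrichment of upstream TE insertions within a gene set.

    ``insertions`` needs columns ``gene``, ``family`` and ``distance``
    (bp upstream of the transcription start, strand-aware, >= 0).  A gene
    is flagged when it has at least one insertion of ``family`` with
    distance <= ``window_bp`` (inclusive).  Enrichment of flagged genes
    in ``gene_set`` against the ``universe`` uses the category odds ratio
    and exact binomial test.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    if (insertions["distance"] < 0).any():
        raise ValueError("insertion distances must be nonnegative")
    sel = insertions[(insertions["family"] == family)
                     & (insertions["distance"] <= window_bp)]
    flagged = set(sel["gene"]) & universe
    k_set = len(flagged & gene_set)
    k_genome = len(flagged)
    if k_genome == 0:
        res = EnrichmentResult(
            k_cat_in_set=0, n_set=len(gene_set), k_cat_genome=0,
            n_genome=len(universe), p1=0.0, p2=0.0, odds=float("nan"),
            p_value=1.0,
        )
        return res, flagged
    res = category_odds_ratio(k_set, len(gene_set), k_genome, len(universe))
    return res, flagged


def rank_tests(
    groups: Sequence[Sequence[float]], kind: str = "kruskal"
) -> float:
    """Convenience Kruskal-Wallis / Wilcoxon-Mann-Whitney p for the
    distribution contrasts used in the reports."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if kind == "kruskal":
        return float(stats.kruskal(*arrays).pvalue)
    if kind == "mannwhitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney needs exactly two groups")
        return float(stats.mannwhitneyu(
            arrays[0], arrays[1], alternative="two-sided").pvalue)
    raise ValueError(f"unknown rank test {kind!r}")
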