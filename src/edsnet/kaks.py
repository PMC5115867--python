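"""Pairwise Ka/Ks (omega) estimation by codon counting.

Nei-Gojobori-style counting: synonymous and nonsynonymous *sites* are
scored by per-codon degeneracy (averaged over the two sequences);
*substitutions* between differing codons are averaged over all minimal
mutational pathways that avoid stop codons; both proportions receive the
Jukes-Cantor multiple-hit correction ``d = -3/4 ln(1 - 4p/3)``.  Pairs
with Ks < 0.02 are flagged as excluded (too little synonymous divergence
for a reliable ratio).  A one-sided Fisher exact test of omega < 1 and a
rank test for comparing two omega distributions are provided.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import standard_dna_table

__all__ = ["KaKsResult", "ng86_kaks", "omega_test", "compare_omega"]

KS_EXCLUSION = 0.02

_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _TABLE[_stop] = "*"
_BASES = "TCAG"


@dataclasses.dataclass
class KaKsResult:
    pair_id: str
    n_sites: float          # nonsynonymous sites N
    s_sites: float          # synonymous sites S
    n_subs: float           # nonsynonymous substitutions Nd
    s_subs: float           # synonymous substitutions Sd
    ka: float
    ks: float
    omega: Optional[float]
    excluded: bool          # Ks below the exclusion threshold
    saturated: bool = False
    codons_compared: int = 0
    codons_dropped: int = 0

    @property
    def usable(self) -> bool:
        return not (self.excluded or self.saturated)


def _codon_sites(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = _TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _TABLE[alt] == aa and aa != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_subs(c1: str, c2: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) substitutions between two codons,
    averaged over minimal pathways; pathways through stop codons are
    skipped unless every pathway passes through one."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _TABLE[nxt] == "*":
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if _TABLE[a] == _TABLE[b]:
                syn += 1.0
            else:
                nonsyn += 1.0
    k = float(len(usable))
    return syn / k, nonsyn / k


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(seq1: str, seq2: str, pair_id: str = "pair") -> KaKsResult:
    """Ka, Ks and omega for one pairwise codon alignment.

    Sequences must be equal-length codon alignments; codons containing
    gaps are dropped (and counted), stop codons are rejected.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length is not a multiple of 3")
    seq1, seq2 = seq1.upper().replace("U", "T"), \
        seq2.upper().replace("U", "T")

    s_sites = n_sites = s_subs = n_subs = 0.0
    compared = dropped = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if "-" in c1 or "-" in c2 or c1 not in _TABLE or c2 not in _TABLE:
            dropped += 1
            continue
        if _TABLE[c1] == "*" or _TABLE[c2] == "*":
            raise ValueError(f"stop codon at alignment position {i}")
        compared += 1
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = _pathway_subs(c1, c2)
        s_subs += sd
        n_subs += nd

    if compared == 0:
        raise ValueError("no comparable codons")
    ps = s_subs / s_sites if s_sites > 0 else 0.0
    pn = n_subs / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    saturated = not (np.isfinite(ka) and np.isfinite(ks))
    excluded = (not saturated) and ks < KS_EXCLUSION
    omega = None
    if not excluded and not saturated and ks > 0:
        omega = ka / ks
    return KaKsResult(
        pair_id=pair_id, n_sites=n_sites, s_sites=s_sites,
        n_subs=n_subs, s_subs=s_subs, ka=ka, ks=ks, omega=omega,
        excluded=excluded, saturated=saturated,
        codons_compared=compared, codons_dropped=dropped,
    )


def omega_test(result: KaKsResult) -> float:
    """One-sided Fisher exact p for omega < 1.

    2x2 table: rows (nonsynonymous, synonymous) x columns (substituted,
    unsubstituted sites), counts rounded to the nearest integer; under
    purifying selection the nonsynonymous substitution fraction is lower,
    so the alternative is odds ratio < 1.
    """
    if result.excluded or result.saturated:
        raise ValueError("omega test undefined for excluded/saturated pairs")

    def r(x):
        return int(np.floor(x + 0.5))

    nd, sd = r(result.n_subs), r(result.s_subs)
    n, s = r(result.n_sites), r(result.s_sites)
    table = [[nd, max(n - nd, 0)], [sd, max(s - sd, 0)]]
    if min(sum(table[0]), sum(table[1]),
           table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="less")[1])


def compare_omega(
    omegas1: Sequence[float], omegas2: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float, float]:
    """Wilcoxon-Mann-Whitney comparison of two omega distributions.

    Returns ``(median1, median2, p)`` — the convenience contrast of a
    module's omega values against the genome-wide background.
    """
    x = np.asarray([v for v in omegas1 if v is not None and np.isfinite(v)])
    y = np.asarray([v for v in omegas2 if v is not None and np.isfinite(v)])
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need nonempty omega samples")
    p = float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)
    return float(np.median(x)), float(np.median(y)), p
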