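"""Nei–Gojobori (1986-style) synonymous/nonsynonymous substitution rates.

Synonymous site counts are computed per codon as the fraction of one-step
nucleotide changes that preserve the encoded amino acid (changes to stop
codons count as nonsynonymous), averaged over the two sequences.  Observed
differences in codons differing at several positions are averaged with equal
weight over all substitution orderings, excluding pathways that pass through a
stop codon (all pathways are used if every one is blocked).  Proportions are
corrected with the Jukes–Cantor formula ``-(3/4) ln(1 - (4/3) p)``; a
proportion at or beyond 3/4 is saturated and reported as ``nan``.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations
from typing import NamedTuple

from Bio.Data import CodonTable

__all__ = ["KsResult", "ks_nei_gojobori", "syn_sites", "codon_path_counts"]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Each position contributes the fraction of its three alternative bases
    that leave the amino acid unchanged; mutations to stop codons are
    nonsynonymous.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _translate(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions with equal weight;
    orderings passing through a stop codon are excluded unless all are.
    """
    if c1 in _STOPS or c2 in _STOPS:
        raise ValueError("stop codons are not allowed")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                hit_stop = True
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if hit_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


class KsResult(NamedTuple):
    ks: float
    ka: float
    ps: float
    pn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _jc_correct(p: float) -> float:
    # the tolerance keeps proportions that are exactly 3/4 up to float
    # round-off from producing arbitrarily inflated corrected values
    if p >= 0.75 - 1e-9:
        return math.nan  # saturated
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0  # avoid -0.0


def ks_nei_gojobori(cds1: str, cds2: str) -> KsResult:
    """Ks and Ka for a pair of aligned coding sequences.

    Codon columns containing a gap in either sequence are dropped; internal
    stop codons raise.  The first two fields unpack as ``(ks, ka)``.
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned CDS pair must have equal length")
    if len(cds1) % 3:
        raise ValueError("aligned CDS length must be a multiple of 3")
    codons = []
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if "-" in a or "-" in b:
            continue
        if a in _STOPS or b in _STOPS:
            raise ValueError(f"internal stop codon at position {i}")
        codons.append((a, b))
    if not codons:
        raise ValueError("no gap-free codon columns to compare")
    s_sites = sum((syn_sites(a) + syn_sites(b)) / 2.0 for a, b in codons)
    n_sites = 3.0 * len(codons) - s_sites
    sd = nd = 0.0
    for a, b in codons:
        d_s, d_n = codon_path_counts(a, b)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return KsResult(
        ks=_jc_correct(ps),
        ka=_jc_correct(pn),
        ps=ps,
        pn=pn,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
    )
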