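"""Colinear (synteny) block detection between two gene orders.

Blocks are maximal chains of homologous gene pairs that advance strictly in
rank along both chromosomes (descending on the second chromosome for
antiparallel blocks), with at most ``max_gap`` intervening non-colinear genes
between consecutive pairs; chains shorter than ``min_block_genes`` are
discarded.  The "at most 50 intervening genes" convention is encoded as a rank
difference of at most ``max_gap + 1`` between consecutive pairs.

Block significance is assessed with a seeded within-chromosome
rank-permutation test: the gene order of the second chromosome is shuffled and
the best chain length recomputed, with add-one smoothing, so the null is a
random gene order on the same hit set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ColinearBlock",
    "filter_hits",
    "find_colinear_blocks",
    "block_pvalue",
]


@dataclass
class ColinearBlock:
    """An ordered chain of colinear gene pairs between two chromosomes."""

    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "parallel" | "antiparallel"
    pairs: List[Tuple[str, str]]
    p_value: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def filter_hits(
    hits: pd.DataFrame, evalue_cutoff: float, self_mode: bool = False
) -> pd.DataFrame:
    """Retain hits with ``evalue <= cutoff``; drop self-hits in self mode."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    kept = hits[hits["evalue"] <= evalue_cutoff]
    if self_mode:
        kept = kept[kept["query_id"] != kept["subject_id"]]
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# internal chaining machinery


def _gene_index(genes: pd.DataFrame) -> Dict[str, Tuple[str, int]]:
    return {
        g: (c, int(r))
        for g, c, r in zip(genes["gene_id"], genes["chromosome"], genes["rank"])
    }


@dataclass(frozen=True)
class _Pair:
    ra: int
    rb: int
    ga: str
    gb: str


def _longest_chain(
    pairs: Sequence[_Pair], orientation: str, max_gap: int
) -> List[_Pair]:
    """Longest valid chain over ``pairs``, deterministic tie-breaking.

    Uses a reverse DP (longest chain *starting* at each pair) so the chain
    with the lexicographically smallest first gene pair can be chosen among
    ties, then walks forward preferring the smallest next pair.
    """
    if not pairs:
        return []
    sign = 1 if orientation == "parallel" else -1
    window = max_gap + 1
    # sort by ra ascending, then oriented rb ascending, then gene ids
    order = sorted(pairs, key=lambda p: (p.ra, sign * p.rb, p.ga, p.gb))
    n = len(order)
    best = [1] * n  # longest chain starting at i
    # successors of i lie at j > i with 0 < ra_j - ra_i <= window
    for i in range(n - 1, -1, -1):
        pi = order[i]
        for j in range(i + 1, n):
            pj = order[j]
            da = pj.ra - pi.ra
            if da > window:
                break
            db = sign * (pj.rb - pi.rb)
            if da > 0 and 0 < db <= window:
                if best[j] + 1 > best[i]:
                    best[i] = best[j] + 1
    target = max(best)
    starts = [i for i in range(n) if best[i] == target]
    start = min(starts, key=lambda i: (order[i].ga, order[i].gb))
    chain = [order[start]]
    i = start
    remaining = target - 1
    while remaining > 0:
        pi = order[i]
        candidates = []
        for j in range(i + 1, n):
            pj = order[j]
            da = pj.ra - pi.ra
            if da > window:
                break
            db = sign * (pj.rb - pi.rb)
            if da > 0 and 0 < db <= window and best[j] == remaining:
                candidates.append(j)
        i = min(candidates, key=lambda j: (order[j].ga, order[j].gb))
        chain.append(order[i])
        remaining -= 1
    return chain


def _score_key(p: _Pair, hits_meta) -> Tuple[float, float, int]:
    bit, ident = hits_meta.get((p.ga, p.gb), (0.0, 0.0))
    return (bit, ident, -p.rb)


def _best_per(pairs: List[_Pair], keyfun, hits_meta) -> List[_Pair]:
    chosen: Dict[str, _Pair] = {}
    for p in pairs:
        k = keyfun(p)
        cur = chosen.get(k)
        if cur is None or _score_key(p, hits_meta) > _score_key(cur, hits_meta):
            chosen[k] = p
    kept = set(map(id, chosen.values()))
    return [p for p in pairs if id(p) in kept]


def _collapse_tandem(
    pairs: List[_Pair], hits_meta: Dict[Tuple[str, str], Tuple[float, float]]
) -> List[_Pair]:
    """Collapse tandem-array fan-outs on this chromosome pair.

    For each gene on either side only its best hit (by bitscore, then
    identity, then partner rank) enters the DP, so a single gene cannot
    inflate a chain through many near-identical partners.
    """
    kept = _best_per(pairs, lambda p: p.ga, hits_meta)
    return _best_per(kept, lambda p: p.gb, hits_meta)


def _group_pairs(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    hits: pd.DataFrame,
    self_mode: bool,
) -> Tuple[Dict[Tuple[str, str], List[_Pair]], Dict[Tuple[str, str], Tuple[float, float]]]:
    idx_a = _gene_index(genes_a)
    idx_b = _gene_index(genes_b)
    groups: Dict[Tuple[str, str], List[_Pair]] = {}
    meta: Dict[Tuple[str, str], Tuple[float, float]] = {}
    rows = zip(
        hits["query_id"],
        hits["subject_id"],
        hits.get("bitscore", pd.Series([0.0] * len(hits))),
        hits.get("percent_identity", pd.Series([0.0] * len(hits))),
    )
    for q, s, bit, ident in rows:
        oriented = [(q, s)]
        if self_mode:
            oriented.append((s, q))
        for ga, gb in oriented:
            if ga not in idx_a:
                if not self_mode:
                    raise ValueError(f"hit references unknown gene id: {ga}")
                continue
            if gb not in idx_b:
                if not self_mode:
                    raise ValueError(f"hit references unknown gene id: {gb}")
                continue
            ca, ra = idx_a[ga]
            cb, rb = idx_b[gb]
            if self_mode:
                # canonical chromosome pair; on the diagonal keep upper triangle
                if ca > cb or (ca == cb and ra >= rb):
                    continue
            p = _Pair(ra, rb, ga, gb)
            groups.setdefault((ca, cb), []).append(p)
            meta[(ga, gb)] = (float(bit), float(ident))
    return groups, meta


def find_colinear_blocks(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    hits: pd.DataFrame,
    min_block_genes: int = 5,
    max_gap: int = 50,
    self_mode: bool = False,
    collapse_tandem: bool = True,
) -> List[ColinearBlock]:
    """Detect colinear blocks between two gene orders from homology hits.

    ``hits`` should already be E-value filtered (:func:`filter_hits`).  Each
    hit pair is assigned to at most one reported block; blocks are extracted
    greedily by descending chain length with a lexicographic first-pair
    tie-break, separately per chromosome pair, searching both orientations.
    """
    genome_a = str(genes_a["genome"].iloc[0]) if len(genes_a) else "A"
    genome_b = str(genes_b["genome"].iloc[0]) if len(genes_b) else "B"
    groups, meta = _group_pairs(genes_a, genes_b, hits, self_mode)
    blocks: List[ColinearBlock] = []
    counter = 0
    for (ca, cb) in sorted(groups):
        pairs = groups[(ca, cb)]
        if collapse_tandem:
            pairs = _collapse_tandem(pairs, meta)
        remaining = list(pairs)
        while remaining:
            candidates = []
            for orientation in ("parallel", "antiparallel"):
                chain = _longest_chain(remaining, orientation, max_gap)
                if chain:
                    candidates.append((orientation, chain))
            if not candidates:
                break
            # longest chain wins; ties resolved by the lexicographically
            # smallest first gene pair, then parallel before antiparallel
            orientation, chain = min(
                candidates,
                key=lambda oc: (
                    -len(oc[1]),
                    oc[1][0].ga,
                    oc[1][0].gb,
                    oc[0] != "parallel",
                ),
            )
            if len(chain) < min_block_genes:
                break
            counter += 1
            blocks.append(
                ColinearBlock(
                    block_id=f"{genome_a}-{genome_b}.{ca}-{cb}.{counter:03d}",
                    genome_a=genome_a,
                    genome_b=genome_b,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    pairs=[(p.ga, p.gb) for p in chain],
                )
            )
            used = set(id(p) for p in chain)
            remaining = [p for p in remaining if id(p) not in used]
    return blocks


def block_pvalue(
    block: ColinearBlock,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    hits: pd.DataFrame,
    n_permutations: int = 1000,
    max_gap: int = 50,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation P-value for a block under a random-gene-order null.

    Permutes the rank assignment of the second chromosome's genes, recomputes
    the best chain length on the same chromosome pair (both orientations,
    same ``max_gap`` as block construction), and reports
    ``(1 + #{best >= n_pairs}) / (1 + n_permutations)``.
    """
    if n_permutations < 100:
        warnings.warn(
            "block_pvalue with fewer than 100 permutations is poorly resolved",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    groups, _ = _group_pairs(genes_a, genes_b, hits, self_mode=False)
    pairs = groups.get((block.chrom_a, block.chrom_b), [])
    if not pairs:
        return 1.0
    ranks_b = sorted(
        int(r)
        for c, r in zip(genes_b["chromosome"], genes_b["rank"])
        if c == block.chrom_b
    ) or sorted({p.rb for p in pairs})
    observed = block.n_pairs
    count = 0
    rank_positions = np.array(ranks_b)
    for _ in range(n_permutations):
        perm = rng.permutation(rank_positions)
        mapping = dict(zip(rank_positions.tolist(), perm.tolist()))
        shuffled = [_Pair(p.ra, mapping[p.rb], p.ga, p.gb) for p in pairs]
        best = 0
        for orientation in ("parallel", "antiparallel"):
            chain = _longest_chain(shuffled, orientation, max_gap)
            best = max(best, len(chain))
        if best >= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)
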