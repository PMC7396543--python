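"""Progressive protein alignment for homolog quartets.

A small internal progressive aligner: all six global pairwise alignments under
BLOSUM62 with affine gaps (open 10, extend 0.5) pick the guide pairing — the
two most-similar sequences are joined first, the remaining two second, and the
two profiles are merged.  Profile–profile scores are average-of-pairs BLOSUM62
(gap symbols contribute zero), and the dynamic programme is a Gotoh three-state
recursion vectorized row-wise with numpy.  The matching CDS is threaded
codon-by-codon through the protein alignment.

Determinism: ties in the DP traceback are resolved in a fixed state order
(match > gap-in-second > gap-in-first), so identical inputs always give
identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "ROLES",
    "QuartetAlignment",
    "align_quartet",
    "align_pair",
    "pairwise_identity",
]

#: fixed role order of a quartet alignment
ROLES = ("outgroup-X", "hexaploid-X", "outgroup-Y", "hexaploid-Y")

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_B62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_RESIDUES = _ALPHABET.replace("*", "")
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_SCORE = np.array(_B62, dtype=float)

_NEG = -1e30


class _Profile:
    """A set of aligned sequences as a (length x alphabet) count matrix."""

    __slots__ = ("names", "seqs", "counts")

    def __init__(self, names: List[str], seqs: List[str]):
        self.names = names
        self.seqs = seqs
        length = len(seqs[0]) if seqs else 0
        counts = np.zeros((length, len(_ALPHABET)), dtype=float)
        for s in seqs:
            for i, aa in enumerate(s):
                if aa != "-":
                    counts[i, _AA_INDEX[aa]] += 1.0
        self.counts = counts

    def __len__(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def _column_scores(a: _Profile, b: _Profile) -> np.ndarray:
    """Average-of-pairs BLOSUM62 score for every column pair (gaps score 0)."""
    n = len(a.seqs) * len(b.seqs)
    return (a.counts @ _SCORE @ b.counts.T) / n


def _gotoh(S: np.ndarray) -> Tuple[float, List[Tuple[int, int]]]:
    """Global affine-gap alignment over a precomputed column-score matrix.

    Returns the optimal score and the alignment path as (i, j) moves where
    i/j are 1 for consuming a column of the first/second profile and 0 for a
    gap.  Row-wise vectorized: the horizontal-gap state reduces to a running
    maximum because the extension penalty is linear.
    """
    la, lb = S.shape
    cols = np.arange(lb + 1, dtype=float)
    M = np.full((la + 1, lb + 1), _NEG)
    Ix = np.full((la + 1, lb + 1), _NEG)  # gap in second profile (consume i)
    Iy = np.full((la + 1, lb + 1), _NEG)  # gap in first profile (consume j)
    M[0, 0] = 0.0
    Iy[0, 1:] = -GAP_OPEN - GAP_EXTEND * (cols[1:] - 1)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        M[i, 0] = _NEG
        Ix[i, :] = np.maximum(M[i - 1, :] - GAP_OPEN, Ix[i - 1, :] - GAP_EXTEND)
        # Iy[i, j] = max_{k < j} M[i, k] - open - ext*(j-1-k)
        running = np.maximum.accumulate(M[i, :] + GAP_EXTEND * cols)
        Iy[i, 1:] = running[:-1] - GAP_OPEN - GAP_EXTEND * (cols[1:] - 1)
        Iy[i, 0] = _NEG
    end_scores = (M[la, lb], Ix[la, lb], Iy[la, lb])
    state = int(np.argmax(end_scores))
    score = float(end_scores[state])

    eps = 1e-9
    path: List[Tuple[int, int]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if state == 0:  # M: consumed both
            path.append((1, 1))
            i, j = i - 1, j - 1
            options = (M[i, j], Ix[i, j], Iy[i, j])
            state = int(np.argmax([v + eps * (k == 0) for k, v in enumerate(options)]))
            if i == 0 and j == 0:
                break
        elif state == 1:  # Ix: consumed i, gap in second
            path.append((1, 0))
            from_m = M[i - 1, j] - GAP_OPEN
            from_ix = Ix[i - 1, j] - GAP_EXTEND
            state = 0 if from_m >= from_ix - eps else 1
            i -= 1
        else:  # Iy: consumed j, gap in first
            path.append((0, 1))
            from_m = M[i, j - 1] - GAP_OPEN
            from_iy = Iy[i, j - 1] - GAP_EXTEND
            state = 0 if from_m >= from_iy - eps else 2
            j -= 1
    path.reverse()
    return score, path


def _merge(a: _Profile, b: _Profile) -> Tuple[float, _Profile]:
    score, path = _gotoh(_column_scores(a, b))
    out_a = ["" for _ in a.seqs]
    out_b = ["" for _ in b.seqs]
    ia = ib = 0
    for di, dj in path:
        if di:
            for k, s in enumerate(a.seqs):
                out_a[k] += s[ia]
            ia += 1
        else:
            for k in range(len(a.seqs)):
                out_a[k] += "-"
        if dj:
            for k, s in enumerate(b.seqs):
                out_b[k] += s[ib]
            ib += 1
        else:
            for k in range(len(b.seqs)):
                out_b[k] += "-"
    return score, _Profile(a.names + b.names, out_a + out_b)


def align_pair(seq1: str, seq2: str) -> Tuple[float, str, str]:
    """Optimal global pairwise alignment; returns (score, aligned1, aligned2)."""
    _validate_protein(seq1)
    _validate_protein(seq2)
    score, prof = _merge(_Profile(["a"], [seq1]), _Profile(["b"], [seq2]))
    return score, prof.seqs[0], prof.seqs[1]


def _validate_protein(seq: str) -> None:
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(_RESIDUES)
    if bad:
        raise ValueError(f"invalid residue symbols: {sorted(bad)}")


@dataclass
class QuartetAlignment:
    """Aligned proteins of a quartet plus the codon-threaded CDS alignment."""

    proteins: Dict[str, str]
    cds: Dict[str, str]

    @property
    def length(self) -> int:
        return len(next(iter(self.proteins.values())))

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.proteins.values()}
        if len(lengths) != 1:
            raise ValueError("aligned proteins must share one length")
        for role, prot in self.proteins.items():
            cds = self.cds[role]
            if len(cds) != 3 * len(prot):
                raise ValueError(f"CDS/protein length mismatch for {role}")


def align_quartet(
    proteins: Mapping[str, str], cds: Mapping[str, str]
) -> QuartetAlignment:
    """Progressively align the four quartet proteins and thread the CDS.

    The two sequences with the highest pairwise alignment score are joined
    first (ties: canonical role order), the remaining two form the second
    profile, and the two profiles are merged.
    """
    roles = [r for r in ROLES if r in proteins]
    if len(roles) != 4:
        raise ValueError(f"need all four roles {ROLES}, got {sorted(proteins)}")
    for role in roles:
        _validate_protein(proteins[role])
        if len(cds[role]) != 3 * len(proteins[role]):
            raise ValueError(f"CDS length of {role} is not 3x its protein length")
        translated = str(Seq(cds[role]).translate()).rstrip("*")
        if translated != proteins[role]:
            raise ValueError(f"CDS of {role} does not translate to its protein")

    scores: Dict[Tuple[str, str], float] = {}
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1:]:
            score, _, _ = align_pair(proteins[r1], proteins[r2])
            scores[(r1, r2)] = score
    first = max(sorted(scores), key=lambda k: scores[k])
    rest = tuple(r for r in roles if r not in first)
    _, p1 = _merge(
        _Profile([first[0]], [proteins[first[0]]]),
        _Profile([first[1]], [proteins[first[1]]]),
    )
    _, p2 = _merge(
        _Profile([rest[0]], [proteins[rest[0]]]),
        _Profile([rest[1]], [proteins[rest[1]]]),
    )
    _, merged = _merge(p1, p2)
    aligned = dict(zip(merged.names, merged.seqs))
    aligned_prot = {role: aligned[role] for role in ROLES}
    aligned_cds = {
        role: thread_cds(aligned_prot[role], cds[role]) for role in ROLES
    }
    return QuartetAlignment(proteins=aligned_prot, cds=aligned_cds)


def thread_cds(aligned_protein: str, cds: str) -> str:
    """Insert codon gaps into ``cds`` following the protein alignment."""
    out = []
    pos = 0
    for aa in aligned_protein:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[pos:pos + 3])
            pos += 3
    if pos != len(cds):
        raise ValueError("CDS longer than threaded protein alignment")
    return "".join(out)


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Matches over columns where both sequences are non-gap (0 if none)."""
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    both = matches = 0
    for a, b in zip(seq1, seq2):
        if a != "-" and b != "-":
            both += 1
            if a == b:
                matches += 1
    return matches / both if both else 0.0
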