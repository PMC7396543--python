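"""Per-quartet gene-conversion calling from protein tree topology.

A quartet holds two hexaploid homeologs and each one's diploid/tetraploid
outgroup ortholog.  Without conversion the neighbor-joining tree pairs each
hexaploid gene with its own outgroup (the *expected* split); a conversion
makes the two homeologs anomalously similar, pairing them together (the
*aberrant* split).  An aberrant split is only called converted when its
bootstrap support exceeds ``min_support``; the third (outgroup-crossing)
split, ties, and weakly supported aberrant splits are left unresolved.  The
donor is the homeolog whose outgroup the *other* homeolog has moved towards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Sequence, Tuple

import numpy as np

from .align import ROLES, QuartetAlignment, pairwise_identity
from .ks import ks_nei_gojobori

__all__ = [
    "PipelineParams",
    "ConversionCall",
    "Split",
    "EXPECTED_SPLIT",
    "ABERRANT_SPLIT",
    "CROSSED_SPLIT",
    "qc_filter",
    "distance_matrix",
    "nj_topology",
    "bootstrap_support",
    "assign_donor",
    "classify_call",
]

Split = FrozenSet[FrozenSet[str]]


def _split(pair1: Tuple[str, str], pair2: Tuple[str, str]) -> Split:
    return frozenset({frozenset(pair1), frozenset(pair2)})


#: each hexaploid gene with its own outgroup — no conversion
EXPECTED_SPLIT: Split = _split(
    ("outgroup-X", "hexaploid-X"), ("outgroup-Y", "hexaploid-Y")
)
#: the two hexaploid homeologs together — the conversion signature
ABERRANT_SPLIT: Split = _split(
    ("hexaploid-X", "hexaploid-Y"), ("outgroup-X", "outgroup-Y")
)
#: outgroup-crossing split — never interpreted as conversion
CROSSED_SPLIT: Split = _split(
    ("outgroup-X", "hexaploid-Y"), ("outgroup-Y", "hexaploid-X")
)

_SPLITS: Tuple[Split, Split, Split] = (EXPECTED_SPLIT, ABERRANT_SPLIT, CROSSED_SPLIT)
_SPLIT_NAMES = {
    EXPECTED_SPLIT: "expected",
    ABERRANT_SPLIT: "aberrant",
    CROSSED_SPLIT: "crossed",
}

#: Poisson-corrected distance is capped here when identity reaches zero
MAX_POISSON_DISTANCE = 10.0

# index pairs (into ROLES order) whose distances sum per split
_SPLIT_SUM_INDEX = {
    EXPECTED_SPLIT: ((0, 1), (2, 3)),
    ABERRANT_SPLIT: ((1, 3), (0, 2)),
    CROSSED_SPLIT: ((0, 3), (1, 2)),
}


@dataclass(frozen=True)
class PipelineParams:
    """Quartet QC and tree-test parameters.

    ``max_gap_fraction`` and ``min_identity`` mirror the alignment discard
    rule (any sequence >50% gaps, or any pairwise identity <40%);
    ``min_support`` is the strict bootstrap threshold an aberrant topology
    must exceed to be called converted.
    """

    max_gap_fraction: float = 0.5
    min_identity: float = 0.40
    bootstrap_replicates: int = 1000
    min_support: float = 0.70
    distance_model: str = "pdist"  # "pdist" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_gap_fraction", "min_identity", "min_support"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.distance_model not in ("pdist", "poisson"):
            raise ValueError("distance_model must be 'pdist' or 'poisson'")


@dataclass
class ConversionCall:
    """Verdict for one quartet."""

    quartet_id: str
    comparison: str
    status: str  # expected | converted | unresolved | filtered
    filter_reason: Optional[str] = None  # gap_fraction | low_identity
    topology: Optional[str] = None  # expected | aberrant | crossed
    tied: bool = False
    support: Optional[float] = None
    donor_role: Optional[str] = None
    acceptor_role: Optional[str] = None
    ks: Dict[str, float] = field(default_factory=dict)


def qc_filter(
    alignment: QuartetAlignment, params: PipelineParams
) -> Tuple[bool, Optional[str]]:
    """Alignment QC: returns (passed, reason-if-failed).

    Fails with ``gap_fraction`` when any sequence has more than
    ``max_gap_fraction`` of the alignment length gapped; with
    ``low_identity`` when the minimum of the six pairwise identities is
    below ``min_identity`` (the strictest reading of the per-pair rule).
    """
    length = alignment.length
    for role in ROLES:
        if alignment.proteins[role].count("-") > params.max_gap_fraction * length:
            return False, "gap_fraction"
    for i, r1 in enumerate(ROLES):
        for r2 in ROLES[i + 1:]:
            ident = pairwise_identity(
                alignment.proteins[r1], alignment.proteins[r2]
            )
            if ident < params.min_identity:
                return False, "low_identity"
    return True, None


def _identity_to_distance(identity: np.ndarray | float, model: str):
    p = 1.0 - np.asarray(identity, dtype=float)
    if model == "pdist":
        return p
    with np.errstate(divide="ignore"):
        d = -np.log(1.0 - p)
    capped = np.minimum(d, MAX_POISSON_DISTANCE)
    if np.any(d > MAX_POISSON_DISTANCE):
        warnings.warn(
            f"Poisson distance capped at {MAX_POISSON_DISTANCE}", stacklevel=3
        )
    return capped


def distance_matrix(
    alignment: QuartetAlignment, model: str = "pdist"
) -> np.ndarray:
    """4x4 symmetric protein distance matrix in canonical role order."""
    d = np.zeros((4, 4))
    for i, r1 in enumerate(ROLES):
        for j in range(i + 1, 4):
            ident = pairwise_identity(
                alignment.proteins[r1], alignment.proteins[ROLES[j]]
            )
            d[i, j] = d[j, i] = float(_identity_to_distance(ident, model))
    return d


def nj_topology(
    d: np.ndarray, labels: Sequence[str] = ROLES
) -> Tuple[Split, bool]:
    """Neighbor-joining split of a 4x4 distance matrix.

    For four taxa the NJ topology is the split minimizing the sum of
    within-pair distances (the four-point condition).  Exact ties are broken
    towards the split containing the lexicographically smallest pair and
    flagged.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (4, 4):
        raise ValueError("need a 4x4 distance matrix")
    pairings = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
    sums = [d[a, b] + d[c, e] for (a, b), (c, e) in pairings]
    best = min(sums)
    tied_idx = [i for i, s in enumerate(sums) if abs(s - best) <= 1e-12]
    tied = len(tied_idx) > 1

    def rep(i: int) -> Tuple[str, ...]:
        (a, b), (c, e) = pairings[i]
        return min(
            tuple(sorted((labels[a], labels[b]))),
            tuple(sorted((labels[c], labels[e]))),
        )

    winner = min(tied_idx, key=rep)
    (a, b), (c, e) = pairings[winner]
    return _split((labels[a], labels[b]), (labels[c], labels[e])), tied


def _pair_masks(alignment: QuartetAlignment) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column validity and match indicators for the six role pairs."""
    seqs = [np.frombuffer(alignment.proteins[r].encode(), dtype="S1") for r in ROLES]
    gap = np.bytes_(b"-")
    nongap = [s != gap for s in seqs]
    valid = []
    match = []
    for i in range(4):
        for j in range(i + 1, 4):
            v = nongap[i] & nongap[j]
            valid.append(v)
            match.append(v & (seqs[i] == seqs[j]))
    return np.array(valid, dtype=float), np.array(match, dtype=float)


_PAIR_INDEX = {}
_k = 0
for _i in range(4):
    for _j in range(_i + 1, 4):
        _PAIR_INDEX[(_i, _j)] = _k
        _k += 1


def bootstrap_support(
    alignment: QuartetAlignment,
    params: PipelineParams,
    target_split: Split,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction of column-resampled replicates recovering ``target_split``.

    Each replicate draws alignment-length columns with replacement,
    recomputes the distance matrix and the NJ split; tied replicates never
    support any split.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(rng)
    length = alignment.length
    reps = params.bootstrap_replicates
    valid, match = _pair_masks(alignment)
    counts = rng.multinomial(length, np.full(length, 1.0 / length), size=reps)
    valids = counts @ valid.T  # (reps, 6)
    matches = counts @ match.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(valids > 0, matches / np.maximum(valids, 1), 0.0)
    dist = _identity_to_distance(identity, params.distance_model)

    def pairsum(split: Split) -> np.ndarray:
        (i1, j1), (i2, j2) = _SPLIT_SUM_INDEX[split]
        return (
            dist[:, _PAIR_INDEX[tuple(sorted((i1, j1)))]]
            + dist[:, _PAIR_INDEX[tuple(sorted((i2, j2)))]]
        )

    sums = np.stack([pairsum(s) for s in _SPLITS], axis=1)  # (reps, 3)
    best = sums.min(axis=1)
    is_min = np.abs(sums - best[:, None]) <= 1e-12
    unique = is_min.sum(axis=1) == 1
    target_idx = _SPLITS.index(target_split)
    hits = is_min[:, target_idx] & unique
    return float(hits.mean())


def assign_donor(
    d: np.ndarray, labels: Sequence[str] = ROLES
) -> Tuple[Optional[str], Optional[str]]:
    """Donor/acceptor of an established aberrant split.

    The acceptor was overwritten by the donor, so it now resembles the
    donor's outgroup ortholog: hexaploid-X is the donor when
    d(hexaploid-Y, outgroup-X) < d(hexaploid-X, outgroup-Y).  Exact equality
    leaves the donor undetermined.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    d_hy_ox = d[idx["hexaploid-Y"], idx["outgroup-X"]]
    d_hx_oy = d[idx["hexaploid-X"], idx["outgroup-Y"]]
    if d_hy_ox < d_hx_oy:
        return "hexaploid-X", "hexaploid-Y"
    if d_hx_oy < d_hy_ox:
        return "hexaploid-Y", "hexaploid-X"
    return None, None


def classify_call(
    quartet_id: str,
    comparison: str,
    alignment: QuartetAlignment,
    params: PipelineParams,
    rng: np.random.Generator | int | None = None,
    compute_ks: bool = True,
) -> ConversionCall:
    """QC, tree test, bootstrap and donor assignment for one quartet."""
    passed, reason = qc_filter(alignment, params)
    if not passed:
        return ConversionCall(
            quartet_id=quartet_id,
            comparison=comparison,
            status="filtered",
            filter_reason=reason,
        )
    d = distance_matrix(alignment, params.distance_model)
    split, tied = nj_topology(d)
    support = bootstrap_support(alignment, params, split, rng)
    ks_values: Dict[str, float] = {}
    if compute_ks:
        for i, r1 in enumerate(ROLES):
            for r2 in ROLES[i + 1:]:
                res = ks_nei_gojobori(alignment.cds[r1], alignment.cds[r2])
                ks_values[f"{r1}|{r2}"] = res.ks
    call = ConversionCall(
        quartet_id=quartet_id,
        comparison=comparison,
        status="unresolved",
        topology=_SPLIT_NAMES[split],
        tied=tied,
        support=support,
        ks=ks_values,
    )
    if tied:
        return call
    if split == EXPECTED_SPLIT:
        call.status = "expected"
    elif split == ABERRANT_SPLIT and support > params.min_support:
        donor, acceptor = assign_donor(d)
        if donor is None:
            call.status = "unresolved"
        else:
            call.status = "converted"
            call.donor_role = donor
            call.acceptor_role = acceptor
    return call
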