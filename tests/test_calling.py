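"""Topology test, bootstrap and donor assignment.

The neighbor-joining split is checked against the four-point-condition oracle
and against an independent NJ implementation (scikit-bio) on random and
tree-additive matrices.
"""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from homeoconv import (
    ABERRANT_SPLIT,
    CROSSED_SPLIT,
    EXPECTED_SPLIT,
    PipelineParams,
    QuartetAlignment,
    assign_donor,
    bootstrap_support,
    classify_call,
    distance_matrix,
    nj_topology,
    qc_filter,
)
from homeoconv.align import ROLES

IDX = {r: i for i, r in enumerate(ROLES)}


def make_alignment(proteins):
    """QuartetAlignment from aligned proteins with a placeholder CDS."""
    cds = {
        r: "".join("---" if aa == "-" else "GCT" for aa in p)
        for r, p in proteins.items()
    }
    return QuartetAlignment(proteins=proteins, cds=cds)


def symmetric(entries):
    d = np.zeros((4, 4))
    for (a, b), v in entries.items():
        d[IDX[a], IDX[b]] = d[IDX[b], IDX[a]] = v
    return d


def four_point_oracle(d):
    """Independent minimizer over the three possible splits."""
    pairings = {
        EXPECTED_SPLIT: d[0, 1] + d[2, 3],
        ABERRANT_SPLIT: d[1, 3] + d[0, 2],
        CROSSED_SPLIT: d[0, 3] + d[1, 2],
    }
    best = min(pairings.values())
    winners = [s for s, v in pairings.items() if abs(v - best) < 1e-12]
    return winners


def skbio_split(d):
    """Split recovered by scikit-bio's full NJ implementation."""
    dm = DistanceMatrix(d, ids=list(ROLES))
    tree = skbio_nj(dm)
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if len(tips) == 2:
            rest = frozenset(ROLES) - tips
            return frozenset({tips, rest})
    return None


class TestQcFilter:
    def test_gap_fraction_failure(self):
        base = "M" * 45 + "-" * 55
        proteins = {r: "M" * 100 for r in ROLES}
        proteins["hexaploid-X"] = base
        ok, reason = qc_filter(make_alignment(proteins), PipelineParams())
        assert not ok and reason == "gap_fraction"

    def test_passes_clean_alignment(self):
        proteins = {r: "MKVLAWMKVL" for r in ROLES}
        ok, reason = qc_filter(make_alignment(proteins), PipelineParams())
        assert ok and reason is None

    def test_minimum_pairwise_identity_rule(self):
        # one pair below 40%, everything else identical
        proteins = {
            "outgroup-X": "AAAAAAAAAA",
            "hexaploid-X": "AAAAAAAAAA",
            "outgroup-Y": "AAAAAAAAAA",
            "hexaploid-Y": "RNDCQEGHIA",
        }
        ok, reason = qc_filter(make_alignment(proteins), PipelineParams())
        assert not ok and reason == "low_identity"


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = make_alignment({r: "MKVLA" for r in ROLES})
        assert np.allclose(distance_matrix(aln), 0.0)

    def test_p_distance_value(self):
        aln = make_alignment(
            {
                "outgroup-X": "AAAA",
                "hexaploid-X": "AATT",
                "outgroup-Y": "AAAA",
                "hexaploid-Y": "AAAA",
            }
        )
        d = distance_matrix(aln, "pdist")
        assert d[IDX["outgroup-X"], IDX["hexaploid-X"]] == pytest.approx(0.5)

    def test_poisson_correction_closed_form(self):
        aln = make_alignment(
            {
                "outgroup-X": "AAAA",
                "hexaploid-X": "AATT",
                "outgroup-Y": "AAAA",
                "hexaploid-Y": "AAAA",
            }
        )
        d = distance_matrix(aln, "poisson")
        assert d[IDX["outgroup-X"], IDX["hexaploid-X"]] == pytest.approx(
            -np.log(0.5)
        )

    def test_poisson_cap_on_zero_identity(self):
        aln = make_alignment(
            {
                "outgroup-X": "AAAA",
                "hexaploid-X": "RRRR",
                "outgroup-Y": "AAAA",
                "hexaploid-Y": "AAAA",
            }
        )
        with pytest.warns(UserWarning, match="capped"):
            d = distance_matrix(aln, "poisson")
        assert d[IDX["outgroup-X"], IDX["hexaploid-X"]] == 10.0


class TestNjTopology:
    def test_four_point_condition_basic(self):
        d = symmetric(
            {
                ("outgroup-X", "hexaploid-X"): 2,
                ("outgroup-Y", "hexaploid-Y"): 2,
                ("outgroup-X", "outgroup-Y"): 10,
                ("outgroup-X", "hexaploid-Y"): 10,
                ("hexaploid-X", "outgroup-Y"): 10,
                ("hexaploid-X", "hexaploid-Y"): 10,
            }
        )
        split, tied = nj_topology(d)
        assert split == EXPECTED_SPLIT and not tied

    def test_equidistant_matrix_is_tied(self):
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0.0)
        split, tied = nj_topology(d)
        assert tied
        # deterministic tie-break: the split holding the lexicographically
        # smallest role pair
        assert split == ABERRANT_SPLIT

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_fourpoint_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        d = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        vals = rng.uniform(0.05, 1.0, size=6)
        d[iu] = vals
        d += d.T
        split, tied = nj_topology(d)
        assert split in four_point_oracle(d)
        if not tied:
            assert [split] == four_point_oracle(d)

    @pytest.mark.parametrize("seed", range(25))
    def test_recovers_known_tree_and_matches_skbio(self, seed):
        # additive matrix from a known 4-leaf tree with positive internal
        # branch: topology must be recovered, and agree with scikit-bio NJ
        rng = np.random.default_rng(100 + seed)
        terminals = rng.uniform(0.05, 0.5, size=4)
        internal = rng.uniform(0.05, 0.5)
        pairing = [
            (EXPECTED_SPLIT, (("outgroup-X", "hexaploid-X"), ("outgroup-Y", "hexaploid-Y"))),
            (ABERRANT_SPLIT, (("hexaploid-X", "hexaploid-Y"), ("outgroup-X", "outgroup-Y"))),
            (CROSSED_SPLIT, (("outgroup-X", "hexaploid-Y"), ("hexaploid-X", "outgroup-Y"))),
        ][seed % 3]
        true_split, ((a, b), (c, e)) = pairing
        t = dict(zip((a, b, c, e), terminals))
        entries = {
            (a, b): t[a] + t[b],
            (c, e): t[c] + t[e],
        }
        for u in (a, b):
            for v in (c, e):
                entries[(u, v)] = t[u] + t[v] + internal
        d = symmetric(entries)
        split, tied = nj_topology(d)
        assert not tied
        assert split == true_split
        assert skbio_split(d) == true_split

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_skbio_on_random_matrices(self, seed):
        rng = np.random.default_rng(500 + seed)
        d = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        d[iu] = rng.uniform(0.1, 1.0, size=6)
        d += d.T
        split, tied = nj_topology(d)
        if not tied:
            assert skbio_split(d) == split


class TestBootstrapSupport:
    def test_strong_signal_gives_full_support(self):
        proteins = {
            "outgroup-X": "AAAAAAAAAA",
            "hexaploid-X": "AAAAAAAAAA",
            "outgroup-Y": "RRRRRRRRRR",
            "hexaploid-Y": "RRRRRRRRRR",
        }
        aln = make_alignment(proteins)
        params = PipelineParams(bootstrap_replicates=200)
        support = bootstrap_support(aln, params, EXPECTED_SPLIT, rng=0)
        assert support == pytest.approx(1.0)

    def test_uninformative_alignment_has_zero_support(self):
        aln = make_alignment({r: "MKVLA" for r in ROLES})
        params = PipelineParams(bootstrap_replicates=100)
        for split in (EXPECTED_SPLIT, ABERRANT_SPLIT, CROSSED_SPLIT):
            assert bootstrap_support(aln, params, split, rng=0) == 0.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(77)
        letters = "ARNDCQEGHILKMFPSTWYV"
        proteins = {
            r: "".join(rng.choice(list(letters), size=30)) for r in ROLES
        }
        aln = make_alignment(proteins)
        params = PipelineParams(bootstrap_replicates=150)
        s1 = bootstrap_support(aln, params, EXPECTED_SPLIT, rng=42)
        s2 = bootstrap_support(aln, params, EXPECTED_SPLIT, rng=42)
        assert s1 == s2

    def test_support_is_a_fraction(self):
        rng = np.random.default_rng(5)
        letters = "ARNDCQEGHILKMFPSTWYV"
        proteins = {r: "".join(rng.choice(list(letters), size=20)) for r in ROLES}
        aln = make_alignment(proteins)
        params = PipelineParams(bootstrap_replicates=50)
        total = sum(
            bootstrap_support(aln, params, s, rng=1)
            for s in (EXPECTED_SPLIT, ABERRANT_SPLIT, CROSSED_SPLIT)
        )
        assert 0.0 <= total <= 1.0


class TestAssignDonor:
    def base_matrix(self):
        return symmetric(
            {
                ("outgroup-X", "hexaploid-X"): 0.3,
                ("outgroup-Y", "hexaploid-Y"): 0.05,
                ("outgroup-X", "outgroup-Y"): 0.3,
                ("hexaploid-X", "hexaploid-Y"): 0.02,
                ("hexaploid-Y", "outgroup-X"): 0.05,
                ("hexaploid-X", "outgroup-Y"): 0.30,
            }
        )

    def test_acceptor_moved_toward_donor_outgroup(self):
        donor, acceptor = assign_donor(self.base_matrix())
        assert donor == "hexaploid-X" and acceptor == "hexaploid-Y"

    def test_mirrored_distances_swap_roles(self):
        d = self.base_matrix()
        i, j = IDX["hexaploid-Y"], IDX["outgroup-X"]
        k, l = IDX["hexaploid-X"], IDX["outgroup-Y"]
        d[i, j], d[k, l] = d[k, l], d[i, j]
        d[j, i], d[l, k] = d[i, j], d[k, l]
        donor, acceptor = assign_donor(d)
        assert donor == "hexaploid-Y" and acceptor == "hexaploid-X"

    def test_equal_cross_distances_undetermined(self):
        d = self.base_matrix()
        i, j = IDX["hexaploid-Y"], IDX["outgroup-X"]
        k, l = IDX["hexaploid-X"], IDX["outgroup-Y"]
        d[i, j] = d[j, i] = d[k, l] = d[l, k] = 0.1
        assert assign_donor(d) == (None, None)


class TestClassifyCall:
    def test_filtered_alignment_has_no_topology_fields(self):
        proteins = {r: "M" * 40 + "-" * 60 for r in ROLES}
        proteins["outgroup-X"] = "M" * 100
        call = classify_call(
            "q1", "A-D", make_alignment(proteins), PipelineParams(), rng=0
        )
        assert call.status == "filtered"
        assert call.filter_reason == "gap_fraction"
        assert call.topology is None and call.support is None

    def test_expected_topology_called_expected(self):
        # X group and Y group deeply split, slight terminal noise; a shared
        # stretch keeps every pair above the 40% identity filter
        shared = "K" * 20
        proteins = {
            "outgroup-X": shared + "AAAAAAAAAA" + "KK",
            "hexaploid-X": shared + "AAAAAAAAAA" + "KR",
            "outgroup-Y": shared + "RRRRRRRRRR" + "KK",
            "hexaploid-Y": shared + "RRRRRRRRRR" + "RK",
        }
        call = classify_call(
            "q1", "A-D", make_alignment(proteins),
            PipelineParams(bootstrap_replicates=100), rng=0,
        )
        assert call.status == "expected"
        assert call.topology == "expected"

    def test_converted_with_donor(self):
        # hexaploid pair identical and Y-like while outgroup-Y retains three
        # private residues: Y donated to X after their divergence
        shared = "K" * 27
        proteins = {
            "outgroup-X": shared + "AAAAAAAAAA" + "AAA",
            "hexaploid-X": shared + "RRRRRRRRRR" + "WWW",
            "outgroup-Y": shared + "RRRRRRRRRR" + "RRR",
            "hexaploid-Y": shared + "RRRRRRRRRR" + "WWW",
        }
        call = classify_call(
            "q1", "A-D", make_alignment(proteins),
            PipelineParams(bootstrap_replicates=200), rng=0,
        )
        assert call.status == "converted"
        assert call.topology == "aberrant"
        assert call.support > 0.70
        assert call.donor_role == "hexaploid-Y"
        assert call.acceptor_role == "hexaploid-X"

    def test_weak_support_is_unresolved(self):
        # aberrant split carried by a single column: bootstrap cannot
        # exceed the strict 70% threshold reliably
        proteins = {
            "outgroup-X": "AAAAAAAAAAAAAAAAAAAR",
            "hexaploid-X": "AAAAAAAAAAAAAAAAAAAW",
            "outgroup-Y": "AAAAAAAAAAAAAAAAAAAR",
            "hexaploid-Y": "AAAAAAAAAAAAAAAAAAAW",
        }
        call = classify_call(
            "q1", "A-D", make_alignment(proteins),
            PipelineParams(bootstrap_replicates=400), rng=0,
        )
        assert call.status in ("unresolved", "converted")
        if call.status == "unresolved":
            assert call.donor_role is None

    def test_min_support_monotonicity(self):
        # raising min_support never increases the converted count
        rng = np.random.default_rng(11)
        letters = "AR"
        alignments = []
        for _ in range(30):
            proteins = {
                r: "".join(rng.choice(list(letters), size=25)) for r in ROLES
            }
            alignments.append(make_alignment(proteins))
        counts = []
        for min_support in (0.5, 0.7, 0.9):
            params = PipelineParams(
                bootstrap_replicates=100, min_support=min_support
            )
            n = sum(
                classify_call(f"q{i}", "A-D", aln, params, rng=i).status
                == "converted"
                for i, aln in enumerate(alignments)
            )
            counts.append(n)
        assert counts == sorted(counts, reverse=True)
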