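"""Reference-anchored alignment table and homologous quartet extraction.

Every genome is aligned to one reference genome through its significant
colinear blocks; the table has one row per reference gene (in rank order) and
one column per genome, each cell a gene id or a gap.  Quartets are rows where
all four configured role columns are filled; rows with any gap (gene loss) are
never called.  Within-subgenome paralog pairs from a self-comparison yield
quartets by looking up each locus's outgroup ortholog in the same table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .colinearity import ColinearBlock

__all__ = [
    "GAP",
    "Comparison",
    "QuartetRecord",
    "build_alignment_table",
    "extract_quartets",
    "extract_paralog_quartets",
]

#: explicit gap marker in the alignment table
GAP = "."


@dataclass(frozen=True)
class Comparison:
    """Role wiring of one quartet comparison.

    ``roles`` maps each of the four quartet roles to an alignment-table
    column (a genome label).  Role wiring is data, not hard-coded taxa: e.g.
    the A–B comparison uses a tetraploid subgenome as the B-side outgroup
    because no diploid B genome exists.
    """

    label: str
    roles: Mapping[str, str]  # role -> table column

    def __post_init__(self) -> None:
        expected = {"outgroup-X", "hexaploid-X", "outgroup-Y", "hexaploid-Y"}
        if set(self.roles) != expected:
            raise ValueError(f"comparison must wire exactly the roles {expected}")


@dataclass(frozen=True)
class QuartetRecord:
    """Four genes in fixed roles, anchored at a reference-genome gene."""

    quartet_id: str
    comparison: str
    anchor: str  # reference gene of the table row
    genes: Mapping[str, str]  # role -> gene id

    def __post_init__(self) -> None:
        if len(set(self.genes.values())) != len(self.genes):
            raise ValueError("quartet genes must be pairwise distinct")


def build_alignment_table(
    reference_genes: pd.DataFrame,
    blocks_by_genome: Mapping[str, Sequence[ColinearBlock]],
    reference_genome: Optional[str] = None,
) -> pd.DataFrame:
    """One row per reference gene, one gene-id/gap column per aligned genome.

    ``blocks_by_genome`` maps each non-reference genome to its significant
    blocks against the reference.  When two blocks of the same genome claim
    one reference gene, the block with the smaller p-value wins (then more
    pairs, then lexicographic block id).  A non-reference gene claimed by two
    rows raises a consistency error.
    """
    if reference_genome is None:
        reference_genome = str(reference_genes["genome"].iloc[0])
    ref = reference_genes.sort_values(["chromosome", "rank"], kind="stable")
    ref_ids = list(ref["gene_id"])
    ref_set = set(ref_ids)
    table: Dict[str, Dict[str, str]] = {g: {} for g in blocks_by_genome}
    for genome, blocks in blocks_by_genome.items():
        # best block first; later (worse) blocks cannot overwrite a cell
        ranked = sorted(
            blocks,
            key=lambda b: (
                b.p_value if b.p_value is not None else 1.0,
                -b.n_pairs,
                b.block_id,
            ),
        )
        claimed: Dict[str, str] = {}  # other-genome gene -> reference row
        cells = table[genome]
        for block in ranked:
            for ga, gb in block.pairs:
                if ga in ref_set:
                    ref_gene, other = ga, gb
                elif gb in ref_set:
                    ref_gene, other = gb, ga
                else:
                    raise ValueError(
                        f"block {block.block_id} does not pair the reference genome"
                    )
                if ref_gene in cells:
                    continue  # a better block already filled this row
                owner = claimed.get(other)
                if owner is not None and owner != ref_gene:
                    raise ValueError(
                        f"gene {other} claimed by reference rows {owner} and {ref_gene}"
                    )
                cells[ref_gene] = other
                claimed[other] = ref_gene
    data = {reference_genome: ref_ids}
    for genome in blocks_by_genome:
        data[genome] = [table[genome].get(r, GAP) for r in ref_ids]
    out = pd.DataFrame(data, index=ref_ids)
    out.index.name = "reference_gene"
    return out


def extract_quartets(
    table: pd.DataFrame, comparison: Comparison
) -> List[QuartetRecord]:
    """One quartet per table row whose four role cells are all filled."""
    for role, column in comparison.roles.items():
        if column not in table.columns:
            raise ValueError(f"role {role} needs missing table column {column}")
    quartets: List[QuartetRecord] = []
    for anchor, row in table.iterrows():
        genes = {role: row[col] for role, col in comparison.roles.items()}
        if any(g == GAP for g in genes.values()):
            continue
        quartets.append(
            QuartetRecord(
                quartet_id=f"{comparison.label}:{anchor}",
                comparison=comparison.label,
                anchor=str(anchor),
                genes=genes,
            )
        )
    return quartets


def extract_paralog_quartets(
    self_blocks: Iterable[ColinearBlock],
    table: pd.DataFrame,
    subgenome: str,
    outgroup: str,
    label: Optional[str] = None,
) -> List[QuartetRecord]:
    """Quartets of ancient within-subgenome paralog pairs plus their outgroups.

    For each colinear paralog pair (locus1, locus2) of ``subgenome`` found in
    self-comparison mode, the outgroup ortholog of each locus is looked up in
    the alignment table; a quartet is emitted only when both exist.
    """
    if label is None:
        label = f"cWGD-{subgenome}"
    if subgenome not in table.columns or outgroup not in table.columns:
        raise ValueError("table lacks the subgenome or outgroup column")
    # gene -> outgroup ortholog through its table row
    ortholog: Dict[str, str] = {}
    for _, row in table.iterrows():
        gene, out = row[subgenome], row[outgroup]
        if gene != GAP and out != GAP:
            ortholog[gene] = out
    quartets: List[QuartetRecord] = []
    n = 0
    for block in self_blocks:
        for locus1, locus2 in block.pairs:
            o1, o2 = ortholog.get(locus1), ortholog.get(locus2)
            if o1 is None or o2 is None:
                continue
            n += 1
            quartets.append(
                QuartetRecord(
                    quartet_id=f"{label}:{locus1}|{locus2}",
                    comparison=label,
                    anchor=locus1,
                    genes={
                        "outgroup-X": o1,
                        "hexaploid-X": locus1,
                        "outgroup-Y": o2,
                        "hexaploid-Y": locus2,
                    },
                )
            )
    return quartets
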