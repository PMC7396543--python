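"""End-to-end orchestration: simulate -> blocks -> quartets -> calls -> summary.

The pipeline aligns every genome to the reference through significant colinear
blocks, extracts the three subgenome-pair quartet comparisons, calls
conversion per quartet, and summarizes.  All randomness (simulation, block
permutation tests, bootstrap) derives from explicit seeds, so a fixed config
yields byte-identical output tables across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .align import align_quartet
from .calling import ConversionCall, PipelineParams, classify_call
from .colinearity import ColinearBlock, block_pvalue, filter_hits, find_colinear_blocks
from .quartets import (
    Comparison,
    QuartetRecord,
    build_alignment_table,
    extract_quartets,
)
from .synth import (
    HEXAPLOID_PAIRS,
    REFERENCE_GENOME,
    SimulationConfig,
    SyntheticDataset,
    evaluate_calls,
    simulate_dataset,
)

__all__ = [
    "PipelineResult",
    "default_comparisons",
    "reference_blocks",
    "call_quartets",
    "run_pipeline",
]

EVALUE_CUTOFF = 1e-5
ALPHA = 0.05


def default_comparisons() -> List[Comparison]:
    """The three subgenome-pair comparisons of the synthetic genome layout."""
    out = []
    for label, ((out_x, hex_x), (out_y, hex_y)) in HEXAPLOID_PAIRS.items():
        out.append(
            Comparison(
                label=label,
                roles={
                    "outgroup-X": out_x,
                    "hexaploid-X": hex_x,
                    "outgroup-Y": out_y,
                    "hexaploid-Y": hex_y,
                },
            )
        )
    return out


def reference_blocks(
    dataset: SyntheticDataset,
    n_permutations: int = 200,
    evalue_cutoff: float = EVALUE_CUTOFF,
    seed: Optional[int] = None,
) -> Dict[str, List[ColinearBlock]]:
    """Blocks (with permutation p-values) of each genome vs the reference.

    The dataset's hit table spans all genome pairs; each comparison keeps
    only its own pair, with the reference genome on the query side.
    """
    if seed is None:
        seed = dataset.config.seed + 2
    hits = filter_hits(dataset.hits, evalue_cutoff)
    ref_genes = dataset.genes[REFERENCE_GENOME]
    ref_ids = set(ref_genes["gene_id"])
    others = [g for g in dataset.genes if g != REFERENCE_GENOME]
    perm_seeds = np.random.SeedSequence(seed).spawn(len(others))
    blocks: Dict[str, List[ColinearBlock]] = {}
    for genome, child in zip(others, perm_seeds):
        other_ids = set(dataset.genes[genome]["gene_id"])
        fwd = hits["query_id"].isin(ref_ids) & hits["subject_id"].isin(other_ids)
        rev = hits["query_id"].isin(other_ids) & hits["subject_id"].isin(ref_ids)
        pair_hits = pd.concat(
            [
                hits[fwd],
                hits[rev].rename(
                    columns={"query_id": "subject_id", "subject_id": "query_id"}
                ),
            ],
            ignore_index=True,
        )
        found = find_colinear_blocks(ref_genes, dataset.genes[genome], pair_hits)
        rng = np.random.default_rng(child)
        for block in found:
            block.p_value = block_pvalue(
                block,
                ref_genes,
                dataset.genes[genome],
                pair_hits,
                n_permutations=n_permutations,
                rng=rng,
            )
        blocks[genome] = found
    return blocks


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    blocks: Dict[str, List[ColinearBlock]]
    table: pd.DataFrame
    quartets: List[QuartetRecord]
    calls: List[ConversionCall]
    calls_frame: pd.DataFrame
    summary: pd.DataFrame
    evaluation: Dict[str, float | int]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.write(out / "dataset")
        for genome, blocks in self.blocks.items():
            hio.write_blocks(
                blocks,
                out / f"blocks_{genome}.tsv",
                out / f"block_pairs_{genome}.tsv",
            )
        self.table.to_csv(out / "alignment_table.tsv", sep="\t")
        hio.quartets_to_frame(self.quartets).to_csv(
            out / "quartets.tsv", sep="\t", index=False
        )
        self.calls_frame.to_csv(out / "calls.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        pd.DataFrame([self.evaluation]).to_csv(
            out / "evaluation.tsv", sep="\t", index=False
        )


def call_quartets(
    quartets: Sequence[QuartetRecord],
    proteins: Mapping[str, Mapping[str, str]],
    cds: Mapping[str, Mapping[str, str]],
    genome_of_role: Mapping[str, Mapping[str, str]],
    params: PipelineParams,
    compute_ks: bool = True,
) -> List[ConversionCall]:
    """Align and classify every quartet; deterministic given ``params.seed``.

    ``proteins``/``cds`` map genome -> gene id -> sequence; ``genome_of_role``
    maps comparison label -> role -> genome.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(len(quartets))
    calls = []
    for quartet, seed in zip(quartets, seeds):
        roles = genome_of_role[quartet.comparison]
        prot = {r: proteins[roles[r]][g] for r, g in quartet.genes.items()}
        nuc = {r: cds[roles[r]][g] for r, g in quartet.genes.items()}
        alignment = align_quartet(prot, nuc)
        calls.append(
            classify_call(
                quartet.quartet_id,
                quartet.comparison,
                alignment,
                params,
                rng=np.random.default_rng(seed),
                compute_ks=compute_ks,
            )
        )
    return calls


def run_pipeline(
    config: SimulationConfig,
    params: Optional[PipelineParams] = None,
    n_permutations: int = 200,
    alpha: float = ALPHA,
    evalue_cutoff: float = EVALUE_CUTOFF,
    compute_ks: bool = True,
    dataset: Optional[SyntheticDataset] = None,
) -> PipelineResult:
    """Simulate (or reuse) a dataset and run every downstream stage."""
    if params is None:
        params = PipelineParams(seed=config.seed + 1)
    if dataset is None:
        dataset = simulate_dataset(config)
    ref_genes = dataset.genes[REFERENCE_GENOME]
    blocks = reference_blocks(
        dataset, n_permutations=n_permutations, evalue_cutoff=evalue_cutoff,
        seed=config.seed + 2,
    )
    significant = {
        genome: [b for b in found if b.p_value <= alpha]
        for genome, found in blocks.items()
    }
    table = build_alignment_table(ref_genes, significant, REFERENCE_GENOME)

    comparisons = default_comparisons()
    genome_of_role = {c.label: dict(c.roles) for c in comparisons}
    quartets: List[QuartetRecord] = []
    for comparison in comparisons:
        quartets.extend(extract_quartets(table, comparison))

    calls = call_quartets(
        quartets, dataset.proteins, dataset.cds, genome_of_role, params,
        compute_ks=compute_ks,
    )
    calls_frame = hio.calls_to_frame(calls)
    quartet_frame = hio.quartets_to_frame(quartets)
    merged = calls_frame.merge(
        quartet_frame[["quartet_id", "anchor"]], on="quartet_id"
    )
    from .summaries import summarize_by_comparison

    summary = summarize_by_comparison(calls)
    evaluation = evaluate_calls(merged, dataset.truth)
    return PipelineResult(
        dataset=dataset,
        blocks=blocks,
        table=table,
        quartets=quartets,
        calls=calls,
        calls_frame=merged,
        summary=summary,
        evaluation=evaluation,
    )
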