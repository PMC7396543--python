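"""Tabular readers/writers for pipeline artifacts (all plain TSV)."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .calling import ConversionCall
from .colinearity import ColinearBlock
from .quartets import QuartetRecord

__all__ = [
    "read_gene_table",
    "read_hits",
    "write_blocks",
    "read_blocks",
    "quartets_to_frame",
    "frame_to_quartets",
    "calls_to_frame",
]

GENE_COLUMNS = ["gene_id", "genome", "chromosome", "start", "end", "strand", "rank"]
HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "evalue", "bitscore"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns {sorted(missing)}")
    return df


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} lacks columns {sorted(missing)}")
    return df


def write_blocks(
    blocks: Sequence[ColinearBlock],
    block_path: str | Path,
    pairs_path: str | Path,
) -> None:
    """Block-level TSV plus the pair-level TSV listing member gene pairs."""
    block_rows = [
        {
            "block_id": b.block_id,
            "genome_a": b.genome_a,
            "genome_b": b.genome_b,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "n_pairs": b.n_pairs,
            "p_value": b.p_value if b.p_value is not None else "",
        }
        for b in blocks
    ]
    pair_rows = [
        {"block_id": b.block_id, "gene_a": ga, "gene_b": gb}
        for b in blocks
        for ga, gb in b.pairs
    ]
    pd.DataFrame(
        block_rows,
        columns=[
            "block_id",
            "genome_a",
            "genome_b",
            "chrom_a",
            "chrom_b",
            "orientation",
            "n_pairs",
            "p_value",
        ],
    ).to_csv(block_path, sep="\t", index=False)
    pd.DataFrame(pair_rows, columns=["block_id", "gene_a", "gene_b"]).to_csv(
        pairs_path, sep="\t", index=False
    )


def read_blocks(block_path: str | Path, pairs_path: str | Path) -> List[ColinearBlock]:
    blocks_df = pd.read_csv(block_path, sep="\t")
    pairs_df = pd.read_csv(pairs_path, sep="\t")
    grouped: Dict[str, List[tuple[str, str]]] = {}
    for bid, ga, gb in zip(pairs_df["block_id"], pairs_df["gene_a"], pairs_df["gene_b"]):
        grouped.setdefault(bid, []).append((ga, gb))
    out = []
    for _, row in blocks_df.iterrows():
        p = row["p_value"]
        out.append(
            ColinearBlock(
                block_id=row["block_id"],
                genome_a=row["genome_a"],
                genome_b=row["genome_b"],
                chrom_a=row["chrom_a"],
                chrom_b=row["chrom_b"],
                orientation=row["orientation"],
                pairs=grouped.get(row["block_id"], []),
                p_value=None if pd.isna(p) or p == "" else float(p),
            )
        )
    return out


def quartets_to_frame(quartets: Iterable[QuartetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "quartet_id": q.quartet_id,
                "comparison": q.comparison,
                "anchor": q.anchor,
                "outgroup_x": q.genes["outgroup-X"],
                "hexaploid_x": q.genes["hexaploid-X"],
                "outgroup_y": q.genes["outgroup-Y"],
                "hexaploid_y": q.genes["hexaploid-Y"],
            }
            for q in quartets
        ],
        columns=[
            "quartet_id",
            "comparison",
            "anchor",
            "outgroup_x",
            "hexaploid_x",
            "outgroup_y",
            "hexaploid_y",
        ],
    )


def frame_to_quartets(df: pd.DataFrame) -> List[QuartetRecord]:
    return [
        QuartetRecord(
            quartet_id=row["quartet_id"],
            comparison=row["comparison"],
            anchor=row["anchor"],
            genes={
                "outgroup-X": row["outgroup_x"],
                "hexaploid-X": row["hexaploid_x"],
                "outgroup-Y": row["outgroup_y"],
                "hexaploid-Y": row["hexaploid_y"],
            },
        )
        for _, row in df.iterrows()
    ]


def calls_to_frame(calls: Iterable[ConversionCall]) -> pd.DataFrame:
    """Flatten calls; per-pair Ks values become ``ks_<role1>__<role2>`` columns."""
    rows = []
    for c in calls:
        row = {
            "quartet_id": c.quartet_id,
            "comparison": c.comparison,
            "status": c.status,
            "filter_reason": c.filter_reason or "",
            "topology": c.topology or "",
            "tied": c.tied,
            "support": "" if c.support is None else round(c.support, 6),
            "donor_role": c.donor_role or "",
            "acceptor_role": c.acceptor_role or "",
        }
        for key, value in c.ks.items():
            col = "ks_" + key.replace("|", "__")
            row[col] = "" if value != value else round(value, 6)  # nan -> ""
        rows.append(row)
    return pd.DataFrame(rows)
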