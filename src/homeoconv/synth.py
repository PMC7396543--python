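"""Synthetic allopolyploid genome simulator with known gene-conversion truth.

Emulates the genome layout of hexaploid bread wheat and its relatives: a
reference diploid (``Dd``), a second diploid outgroup (``Ad``), one tetraploid
subgenome (``Bt``) and the three hexaploid subgenomes (``Ah``, ``Bh``, ``Dh``).
Each ancestral locus evolves along a star phylogeny of three lineages (A, B, D)
separated by ``deep_divergence`` expected substitutions/site; within a lineage
the outgroup copy and the hexaploid copy are separated by
``shallow_divergence``.  Full-gene conversion events are imposed between
hexaploid homeolog pairs after their divergence, with a configurable donor
bias, and recorded in a ground-truth table so every downstream stage of the
pipeline can be scored.

The substitution process is Jukes–Cantor-like: a Poisson number of events per
branch, uniform site choice, uniform alternative base, with events that would
create an internal stop codon rejected and resampled.  There are no indels:
orthologous copies stay the same length, which keeps colinearity exact and
lets homology hits be emitted from known ancestry (running an actual protein
search is out of scope).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "GENOMES",
    "REFERENCE_GENOME",
    "HEXAPLOID_PAIRS",
    "random_coding_sequence",
    "mutate_sequence",
    "impose_conversion",
    "simulate_dataset",
    "evaluate_calls",
]

#: genome labels in fixed emission order; ``Dd`` plays the reference role
GENOMES = ("Dd", "Ad", "Bt", "Ah", "Bh", "Dh")
REFERENCE_GENOME = "Dd"

#: lineage -> (outgroup genome, hexaploid genome)
LINEAGES = {"A": ("Ad", "Ah"), "B": ("Bt", "Bh"), "D": ("Dd", "Dh")}

#: comparison label -> ((outgroup-X, hexaploid-X), (outgroup-Y, hexaploid-Y))
HEXAPLOID_PAIRS = {
    "A-B": (("Ad", "Ah"), ("Bt", "Bh")),
    "A-D": (("Ad", "Ah"), ("Dd", "Dh")),
    "B-D": (("Bt", "Bh"), ("Dd", "Dh")),
}

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

#: synthetic homology hits are emitted below the pipeline's E-value cutoff
_SYNTH_EVALUE = 1e-20


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Divergences are expected substitutions per nucleotide site separating the
    two endpoints of the labelled contrast (they are split evenly over the two
    branches involved).  Defaults encode the wheat-like scenario the pipeline
    is designed for: deeply diverged parental lineages, recently diverged
    diploid/tetraploid relatives, and near-zero divergence accrued since the
    conversion events themselves.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 250
    codons_per_gene: int = 300
    deep_divergence: float = 0.3
    shallow_divergence: float = 0.02
    conversion_rate: float = 0.10
    donor_bias: float = 0.62
    post_conversion_divergence: float = 0.005
    gene_loss_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.codons_per_gene < 30:
            raise ValueError(
                "codons_per_gene must be >= 30 so identity/gap filters are meaningful"
            )
        if not self.shallow_divergence < self.deep_divergence:
            raise ValueError("shallow_divergence must be < deep_divergence")
        for name in ("conversion_rate", "donor_bias", "gene_loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "deep_divergence",
            "shallow_divergence",
            "post_conversion_divergence",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random sequence of ``n_codons`` sense codons (no stops)."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def mutate_sequence(cds: str, branch_length: float, rng: np.random.Generator) -> str:
    """Evolve ``cds`` along a branch of ``branch_length`` substitutions/site.

    Draws a Poisson(branch_length * L) number of substitution events; each
    event picks a uniform site and a uniform alternative base.  Events that
    would create a stop codon anywhere in the sequence are rejected and
    resampled, keeping the product translatable.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if branch_length < 0:
        raise ValueError("branch_length must be non-negative")
    if branch_length == 0 or not cds:
        return cds
    seq = list(cds)
    n_events = int(rng.poisson(branch_length * len(seq)))
    for _ in range(n_events):
        while True:
            site = int(rng.integers(len(seq)))
            current = seq[site]
            alt = _BASES.replace(current, "")[int(rng.integers(3))]
            codon_start = site - site % 3
            codon = seq[codon_start:codon_start + 3]
            codon[site - codon_start] = alt
            if "".join(codon) in _STOPS:
                continue  # resample site and base
            seq[site] = alt
            break
    return "".join(seq)


def impose_conversion(donor_cds: str, acceptor_cds: str) -> str:
    """Full-gene conversion: the acceptor is overwritten by the donor copy.

    The caller applies any post-conversion divergence to both copies
    afterwards.  Partial (tract-level) conversion is deliberately not
    modelled.
    """
    if len(donor_cds) != len(acceptor_cds):
        raise ValueError("full-gene conversion requires equal-length sequences")
    return donor_cds


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: gene tables, sequences, hits and truth."""

    config: SimulationConfig
    genes: Dict[str, pd.DataFrame]
    cds: Dict[str, Dict[str, str]]
    proteins: Dict[str, Dict[str, str]]
    hits: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for genome in GENOMES:
            self.genes[genome].to_csv(
                out / f"genes_{genome}.tsv", sep="\t", index=False
            )
            _write_fasta(out / f"cds_{genome}.fasta", self.cds[genome])
            _write_fasta(out / f"protein_{genome}.fasta", self.proteins[genome])
        self.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        cfg = dataclasses.asdict(self.config)
        with open(out / "config.tsv", "w") as fh:
            fh.write("parameter\tvalue\n")
            for key, value in cfg.items():
                fh.write(f"{key}\t{value}\n")

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticDataset":
        indir = Path(indir)
        cfg_df = pd.read_csv(indir / "config.tsv", sep="\t", dtype=str)
        raw = dict(zip(cfg_df["parameter"], cfg_df["value"]))
        kwargs = {
            f.name: _coerce(f, raw[f.name])
            for f in dataclasses.fields(SimulationConfig)
        }
        config = SimulationConfig(**kwargs)
        genes, cds, proteins = {}, {}, {}
        for genome in GENOMES:
            genes[genome] = pd.read_csv(indir / f"genes_{genome}.tsv", sep="\t")
            cds[genome] = _read_fasta(indir / f"cds_{genome}.fasta")
            proteins[genome] = _read_fasta(indir / f"protein_{genome}.fasta")
        hits = pd.read_csv(indir / "hits.tsv", sep="\t")
        truth = pd.read_csv(indir / "truth.tsv", sep="\t")
        return cls(config, genes, cds, proteins, hits, truth)


def _coerce(f: dataclasses.Field, value: str):
    return int(value) if f.type == "int" else float(value)


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def _read_fasta(path: Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _locus_id(chrom: int, idx: int) -> str:
    return f"c{chrom:02d}g{idx:04d}"


def gene_id(genome: str, chrom: int, idx: int) -> str:
    """Synthetic gene-id convention: ``<genome>_c<chrom>g<locus>``."""
    return f"{genome}_{_locus_id(chrom, idx)}"


def locus_of(gene: str) -> str:
    """Inverse of :func:`gene_id`: the locus key shared across genomes."""
    return gene.split("_", 1)[1]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate the six-genome dataset with imposed conversions and truth.

    Deterministic for a fixed config (including its seed): two calls yield
    identical tables and sequences.
    """
    rng = np.random.default_rng(config.seed)
    half_deep = config.deep_divergence / 2.0
    half_shallow = config.shallow_divergence / 2.0

    seqs: Dict[str, Dict[str, str]] = {g: {} for g in GENOMES}
    strands: Dict[str, str] = {}
    truth_rows = []
    pair_labels = tuple(HEXAPLOID_PAIRS)

    for chrom in range(1, config.n_chromosomes + 1):
        for idx in range(1, config.genes_per_chromosome + 1):
            locus = _locus_id(chrom, idx)
            ancestral = random_coding_sequence(config.codons_per_gene, rng)
            strands[locus] = "+" if rng.random() < 0.5 else "-"
            locus_seqs: Dict[str, str] = {}
            for lineage in ("A", "B", "D"):
                root = mutate_sequence(ancestral, half_deep, rng)
                out_g, hex_g = LINEAGES[lineage]
                locus_seqs[out_g] = mutate_sequence(root, half_shallow, rng)
                locus_seqs[hex_g] = mutate_sequence(root, half_shallow, rng)

            # conversion decisions: one Bernoulli per hexaploid pair, applied
            # in a random order; a gene already involved in a conversion at
            # this locus cannot enter a second one
            conv_draw = rng.random(len(pair_labels)) < config.conversion_rate
            donor_draw = rng.random(len(pair_labels))
            order = rng.permutation(len(pair_labels))
            involved: set[str] = set()
            converted: Dict[str, tuple[str, str, str, str]] = {}
            for k in order:
                label = pair_labels[k]
                if not conv_draw[k]:
                    continue
                (_, hex_x), (_, hex_y) = HEXAPLOID_PAIRS[label]
                if hex_x in involved or hex_y in involved:
                    continue
                if donor_draw[k] < config.donor_bias:
                    donor_role, acceptor_role = "hexaploid-Y", "hexaploid-X"
                    donor_g, acceptor_g = hex_y, hex_x
                else:
                    donor_role, acceptor_role = "hexaploid-X", "hexaploid-Y"
                    donor_g, acceptor_g = hex_x, hex_y
                locus_seqs[acceptor_g] = impose_conversion(
                    locus_seqs[donor_g], locus_seqs[acceptor_g]
                )
                locus_seqs[donor_g] = mutate_sequence(
                    locus_seqs[donor_g], config.post_conversion_divergence, rng
                )
                locus_seqs[acceptor_g] = mutate_sequence(
                    locus_seqs[acceptor_g], config.post_conversion_divergence, rng
                )
                involved.update((hex_x, hex_y))
                converted[label] = (donor_role, acceptor_role, donor_g, acceptor_g)

            for label in pair_labels:
                if label in converted:
                    donor_role, acceptor_role, donor_g, acceptor_g = converted[label]
                    truth_rows.append(
                        {
                            "anchor_id": gene_id(REFERENCE_GENOME, chrom, idx),
                            "locus": locus,
                            "comparison": label,
                            "converted": True,
                            "donor_role": donor_role,
                            "acceptor_role": acceptor_role,
                            "donor_gene": gene_id(donor_g, chrom, idx),
                            "acceptor_gene": gene_id(acceptor_g, chrom, idx),
                        }
                    )
                else:
                    truth_rows.append(
                        {
                            "anchor_id": gene_id(REFERENCE_GENOME, chrom, idx),
                            "locus": locus,
                            "comparison": label,
                            "converted": False,
                            "donor_role": "",
                            "acceptor_role": "",
                            "donor_gene": "",
                            "acceptor_gene": "",
                        }
                    )

            for genome in GENOMES:
                seqs[genome][locus] = locus_seqs[genome]

    # gene loss, position tables and final sequence dictionaries
    spacing = 3 * config.codons_per_gene + 2000
    genes: Dict[str, pd.DataFrame] = {}
    cds_out: Dict[str, Dict[str, str]] = {}
    prot_out: Dict[str, Dict[str, str]] = {}
    surviving: Dict[str, set[str]] = {}
    for genome in GENOMES:
        rows = []
        cds_d: Dict[str, str] = {}
        prot_d: Dict[str, str] = {}
        alive: set[str] = set()
        for chrom in range(1, config.n_chromosomes + 1):
            rank = 0
            for idx in range(1, config.genes_per_chromosome + 1):
                lost = rng.random() < config.gene_loss_rate
                if lost:
                    continue
                locus = _locus_id(chrom, idx)
                gid = gene_id(genome, chrom, idx)
                rank += 1
                start = (idx - 1) * spacing + 1
                end = start + 3 * config.codons_per_gene - 1
                rows.append(
                    {
                        "gene_id": gid,
                        "genome": genome,
                        "chromosome": f"chr{chrom}",
                        "start": start,
                        "end": end,
                        "strand": strands[locus],
                        "rank": rank,
                    }
                )
                cds_d[gid] = seqs[genome][locus]
                prot_d[gid] = str(Seq(seqs[genome][locus]).translate())
                alive.add(locus)
        genes[genome] = pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "genome",
                "chromosome",
                "start",
                "end",
                "strand",
                "rank",
            ],
        )
        cds_out[genome] = cds_d
        prot_out[genome] = prot_d
        surviving[genome] = alive

    # homology hits from known ancestry, one row per surviving cross-genome
    # pair at each locus, with identity computed from the protein sequences
    hit_rows = []
    for chrom in range(1, config.n_chromosomes + 1):
        for idx in range(1, config.genes_per_chromosome + 1):
            locus = _locus_id(chrom, idx)
            present = [g for g in GENOMES if locus in surviving[g]]
            for i, ga in enumerate(present):
                for gb in present[i + 1:]:
                    qa, qb = gene_id(ga, chrom, idx), gene_id(gb, chrom, idx)
                    pa, pb = prot_out[ga][qa], prot_out[gb][qb]
                    matches = sum(x == y for x, y in zip(pa, pb))
                    ident = 100.0 * matches / len(pa)
                    hit_rows.append(
                        {
                            "query_id": qa,
                            "subject_id": qb,
                            "percent_identity": round(ident, 2),
                            "evalue": _SYNTH_EVALUE,
                            "bitscore": round(2.0 * matches, 1),
                        }
                    )
    hits = pd.DataFrame(
        hit_rows,
        columns=["query_id", "subject_id", "percent_identity", "evalue", "bitscore"],
    )

    truth = pd.DataFrame(truth_rows)
    # a truth row is intact when all genes a quartet would need survive loss
    intact = []
    for row in truth_rows:
        locus = row["locus"]
        (out_x, hex_x), (out_y, hex_y) = HEXAPLOID_PAIRS[row["comparison"]]
        ok = all(
            locus in surviving[g]
            for g in {REFERENCE_GENOME, out_x, hex_x, out_y, hex_y}
        )
        intact.append(ok)
    truth["intact"] = intact

    return SyntheticDataset(config, genes, cds_out, prot_out, hits, truth)


def evaluate_calls(
    calls: pd.DataFrame, truth: pd.DataFrame
) -> Dict[str, float | int]:
    """Score conversion calls against the simulator's ground truth.

    ``calls`` must carry ``anchor``, ``comparison``, ``status`` and
    ``donor_role`` columns (the call table written by the pipeline).  Only
    intact truth rows that produced a quartet (i.e. appear in ``calls``) enter
    the denominators: a conversion whose genes were lost can never be
    observed.
    """
    t = truth[truth["intact"]] if "intact" in truth.columns else truth
    merged = calls.merge(
        t,
        left_on=["anchor", "comparison"],
        right_on=["anchor_id", "comparison"],
        how="inner",
        suffixes=("", "_truth"),
    )
    pos = merged[merged["converted"]]
    neg = merged[~merged["converted"]]
    tp = pos[pos["status"] == "converted"]
    fp = neg[neg["status"] == "converted"]
    donor_correct = tp[tp["donor_role"] == tp["donor_role_truth"]]
    called_conv = merged[merged["status"] == "converted"]
    n_donor_y = int((called_conv["donor_role"] == "hexaploid-Y").sum())
    return {
        "n_scored": int(len(merged)),
        "n_true_converted": int(len(pos)),
        "n_true_nonconverted": int(len(neg)),
        "n_called_converted": int(len(called_conv)),
        "true_positives": int(len(tp)),
        "false_positives": int(len(fp)),
        "sensitivity": float(len(tp) / len(pos)) if len(pos) else float("nan"),
        "false_call_rate": float(len(fp) / len(neg)) if len(neg) else float("nan"),
        "donor_accuracy": (
            float(len(donor_correct) / len(tp)) if len(tp) else float("nan")
        ),
        "donor_fraction_y": (
            float(n_donor_y / len(called_conv)) if len(called_conv) else float("nan")
        ),
    }
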