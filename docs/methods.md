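# Methods

This note records the models, parameter choices and numerical conventions
behind `homeoconv`, in the order data flows through the pipeline.

## The synthetic allopolyploid model

The simulator emulates the genome layout of hexaploid wheat and its
relatives: a reference diploid (`Dd`), a second diploid (`Ad`), one
tetraploid subgenome (`Bt`) and three hexaploid subgenomes (`Ah`, `Bh`,
`Dh`).  Each ancestral locus evolves along a star phylogeny of three
lineages (A, B, D), each `deep_divergence/2` from the root, so every pair
of lineages is separated by `deep_divergence` expected substitutions per
nucleotide site; within a lineage, the outgroup copy and the hexaploid
copy each accrue `shallow_divergence/2` from the lineage root.  Any quartet
drawn from two lineages therefore has exactly the four-taxon topology the
calling stage assumes.

Substitution process: a Poisson(branch length × sequence length) number of
events per branch, uniform site, uniform alternative base — a
Jukes–Cantor-like process, sufficient to create the distance contrasts the
topology test relies on.  Events creating a stop codon anywhere are
rejected and resampled, keeping translation valid for the alignment stage.
There are no indels (tract-level conversion, transposons and rearrangement
are out of scope), so orthologous copies remain equal-length and colinear.

Conversion is **whole-gene**: with probability `conversion_rate` per locus
per hexaploid pair, the acceptor's sequence is replaced by the donor's at
the hexaploid-formation point (i.e. after the full outgroup–subgenome
divergence has accrued), after which both copies independently accrue
`post_conversion_divergence`.  The donor is the Y-role copy with
probability `donor_bias`.  When two conversions at one locus would involve
the same gene, the later one (in a seeded random order) is skipped; at the
default rate this affects well under 1% of loci.  Gene loss deletes each
gene independently with probability `gene_loss_rate`; ranks are recomputed
so they stay consecutive.  Homology hits are emitted from known ancestry
(identity computed from the protein sequences, E-value fixed far below the
pipeline cutoff) — running an actual protein search adds nothing the truth
table does not already fix.

Default conditions (the study conditions all end-to-end numbers refer to):

| parameter | default | rationale |
| --- | --- | --- |
| `deep_divergence` | 0.3 subs/site | deeply diverged parental lineages (Myr-scale separation); keeps cross-lineage protein identity near 55–60%, above the QC floor |
| `shallow_divergence` | 0.02 | recently diverged diploid/tetraploid relatives of the subgenomes |
| `post_conversion_divergence` | 0.005 | conversions are recent relative to species divergences |
| `conversion_rate` | 0.10 | an appreciable minority of loci |
| `donor_bias` | 0.62 | one subgenome preferentially donates |
| `gene_loss_rate` | 0.03 | sparse fractionation |
| `codons_per_gene` | 300 | a realistic average plant CDS (~0.9 kb) |
| `n_chromosomes × genes_per_chromosome` | 2 × 250 | 500 quartet loci |

What passing tests on this generator do **not** show about real data: real
genes vary in length and rate, alignments contain indels, conversion can be
partial (tract-level), homology searches add noise the emitted hits lack,
and real subgenome histories are not a star phylogeny.  The simulator
establishes that the machinery recovers a known signal under its stated
model, not that the biological error rates transfer.

## Colinearity

Blocks are maximal chains of homologous gene pairs advancing strictly in
rank on both chromosomes (descending on the second for antiparallel
blocks).  "At most 50 intervening non-colinear genes" is encoded as a rank
difference ≤ `max_gap + 1` between consecutive pairs; chains shorter than
`min_block_genes = 5` are discarded.  Chain score is pair count, not
bitscore — blocks are defined by gene counts.  Hits are E-value filtered at
1e−5 first.  Tandem fan-outs are collapsed before chaining: per gene and
partner chromosome only its best hit (bitscore, then identity, then
partner rank) enters the DP; this rule is query-side dependent, so exact
A↔B symmetry holds for the chaining itself (and is tested there) rather
than for the collapse heuristic.  Each hit pair joins at most one block:
blocks are extracted greedily by descending chain length with a
lexicographic first-pair tie-break.

Significance uses a seeded within-chromosome rank-permutation test: the
second chromosome's gene order is shuffled, the best chain length (both
orientations) recomputed, and `p = (1 + #{best ≥ observed}) /
(1 + n_permutations)` with add-one smoothing.  The null — random gene
order on the same hit set — matches what an analytic block P-value
expresses, without an external formula dependency.  Fewer than 100
permutations triggers a warning.  Self-comparison mode drops self-hits,
mirrors each hit, and canonicalizes chromosome pairs (c1 ≤ c2; on the
diagonal only rank_a < rank_b) to avoid mirror-image duplicate blocks.

## Alignment table and quartets

Every genome is aligned to the reference through its significant blocks
(p ≤ 0.05): one row per reference gene in rank order, one cell per genome.
When two blocks of one genome claim the same reference gene, the block
with the smaller p-value wins, then the larger block, then the
lexicographically smaller block id.  A non-reference gene claimed by two
rows is a consistency error.  Quartets are rows with all four role cells
filled; rows with any gap (gene loss) are skipped — triplets are never
called.  Role wiring is configuration, not hard-coded taxa: the A–B
comparison uses the tetraploid `Bt` as the B-side outgroup because no
diploid B genome exists.  Ancient within-subgenome paralog pairs (from
self-comparison blocks) form quartets by looking up each paralog's
outgroup ortholog in the same table; pairs with a missing ortholog are
skipped.  Ortho-group co-membership is recorded as an annotation
(support percentage), never used as a filter.

## Conversion calling

The four proteins are aligned progressively: all six global pairwise
alignments under BLOSUM62 with affine gaps (open 10, extend 0.5) choose
the guide pairing — the two highest-scoring sequences are joined first,
the remaining two second, then the profiles merge.  Profile–profile column
scores are average-of-pairs BLOSUM62 with gap symbols contributing zero.
The Gotoh three-state recursion is vectorized row-wise (the
horizontal-gap state reduces to a running maximum because extension is
linear); traceback ties resolve in a fixed state order, so alignment is
deterministic.  The CDS is threaded codon-by-codon through the protein
alignment.  Externally produced alignments can be supplied by
constructing `QuartetAlignment` directly.

QC discards a quartet when any sequence is gapped over more than 50% of
the alignment length, or when the **minimum** of the six pairwise
identities falls below 40% — the strictest reading of the per-pair rule.
Identity counts matches over columns where both sequences are non-gap
(0 when no such column exists).

Distances are protein p-distances by default; a Poisson-corrected variant
(−ln(identity), capped at 10 with a warning when identity reaches 0) is
available by flag.  Trees are built on proteins; Ks is a reported
annotation, not a calling criterion.  For four taxa the NJ split is the
four-point-condition minimizer (this equals the full NJ Q-criterion at
n=4; tests cross-check against an independent NJ implementation).  Exact
ties break towards the split holding the lexicographically smallest role
pair and are flagged; tied quartets are never called converted.

Bootstrap resamples alignment columns with replacement (alignment-length
draws per replicate, 1,000 replicates by default; the bundled end-to-end
runs use 200, which changes support estimates by at most a few percent at
the 0.70 threshold), recomputing distances and the NJ split per replicate;
tied replicates support no split.  A quartet is **converted** only when
the aberrant split wins with support strictly greater than 0.70; the
expected split yields **expected**; everything else — weak support, the
outgroup-crossing split, ties, or an undecidable donor — is
**unresolved**.  The donor rule compares the two cross distances
(acceptor ≈ donor's outgroup); exact equality downgrades the call.

## Nei–Gojobori Ks

Synonymous sites per codon are the fraction of one-step changes preserving
the amino acid (changes to stop codons count as nonsynonymous), averaged
over the two sequences.  Observed differences average over all
substitution orderings with equal weight; orderings passing through a stop
codon are excluded unless all are.  Codon columns containing a gap in
either sequence are dropped before counting; internal stops are an input
error.  Proportions are Jukes–Cantor corrected,
Ks = −(3/4)·ln(1 − (4/3)·p<sub>s</sub>); a proportion at or above 3/4 is
saturated and reported as NaN.  The saturation test uses a 1e−9 tolerance
so proportions that equal 3/4 exactly up to float round-off do not produce
arbitrarily inflated corrected values.

## Summaries and enrichment

Percentages are rounded half-away-from-zero to two decimals, matching the
printed tables this machinery reproduces.  One published ratio
(253/12,770 printed as 1.99%) recomputes to 1.98% under any standard
rounding; the package reports the recomputed value and this note flags the
discrepancy rather than chasing it.  Quartet denominators count
non-filtered quartets that entered calling.  Enrichment scores each GO
category's 2×2 table (converted vs not × in-category vs not) with the
two-sided Fisher exact test — for fixed margins, the hypergeometric
convention summing all tables with probability at most the observed one.
Raw p-values are the headline output (no correction is part of the core
procedure); a Benjamini–Hochberg column is emitted as a clearly labelled
extension.  The background set is a parameter (all colinear genes, all
quartet genes, or any caller-supplied set).

## Problem sizes and determinism

The bundled end-to-end analyses simulate 500 quartet loci with 200
bootstrap replicates and 200 block permutations — sizes at which the
recovery estimates are stable to a few percent while a full run completes
in minutes on one CPU.  All randomness (simulation, permutation tests,
bootstrap) flows from explicit integer seeds through `numpy`'s
`SeedSequence` spawning, one child stream per quartet/genome, so a fixed
configuration reproduces byte-identical output tables.

## Known limitations

Whole-gene conversion only (no tract boundaries); no indel evolution, so
the aligner's gap handling is exercised mainly by its own unit tests; the
permutation P-value is approximate at small permutation counts; the
identity-based protein distances ignore rate heterogeneity across sites;
paralog (within-subgenome) quartets require the caller to supply
self-comparison blocks, since the simulator does not model the ancient
whole-genome duplication; and sensitivity degrades for short genes (few
informative columns), which is why gene length is a first-class simulator
parameter.
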