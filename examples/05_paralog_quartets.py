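"""Quartets from ancient within-subgenome paralogs (whole-genome duplication).

A subgenome compared against itself yields colinear paralog pairs descending
from an ancient duplication; pairing each paralog with its diploid ortholog
builds a quartet that is tested for conversion exactly like the
between-subgenome ones.  The default simulator does not model the ancient
duplication, so this example wires a miniature table by hand.
"""

import pandas as pd

from homeoconv.colinearity import ColinearBlock
from homeoconv.quartets import GAP, extract_paralog_quartets

# alignment table: reference genes anchor the hexaploid-A and diploid-A copies
table = pd.DataFrame(
    {
        "Dd": [f"Dd{i}" for i in range(1, 9)],
        "Ad": [f"Ad{i}" if i != 6 else GAP for i in range(1, 9)],
        "Ah": [f"Ah{i}" for i in range(1, 9)],
    },
    index=[f"Dd{i}" for i in range(1, 9)],
)

# self-comparison of the Ah subgenome found two colinear paralog regions
self_blocks = [
    ColinearBlock(
        block_id="Ah-self.1",
        genome_a="Ah",
        genome_b="Ah",
        chrom_a="chr1",
        chrom_b="chr2",
        orientation="parallel",
        pairs=[("Ah1", "Ah5"), ("Ah2", "Ah6"), ("Ah3", "Ah7")],
        p_value=0.001,
    )
]

quartets = extract_paralog_quartets(self_blocks, table, subgenome="Ah", outgroup="Ad")
print(f"{len(quartets)} paralog quartets extracted:")
for q in quartets:
    print(f"  {q.quartet_id}: {q.genes}")
# Ah2~Ah6 is skipped: Ah6's diploid ortholog is missing from the table
# (gene loss), and a quartet needs all four members.  The survivors go
# through align_quartet/classify_call unchanged — the 'X' side is one
# paralog with its ortholog, the 'Y' side the other.
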