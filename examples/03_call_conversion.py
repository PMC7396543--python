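"""Run the full pipeline on a simulated dataset and score it against truth.

Simulates 120 loci under the default wheat-like conditions, detects blocks,
builds the reference-anchored alignment table, extracts the three
subgenome-pair quartet comparisons, calls conversion per quartet from the
NJ topology with bootstrap support, and compares the calls with the
simulator's truth table.
"""

from homeoconv import PipelineParams, SimulationConfig, run_pipeline

config = SimulationConfig(
    n_chromosomes=1,
    genes_per_chromosome=120,
    seed=5,
)
params = PipelineParams(bootstrap_replicates=200, seed=6)
result = run_pipeline(config, params, n_permutations=200)

print("per-comparison summary (quartets, converted, donor split):")
print(result.summary.to_string(index=False))

ev = result.evaluation
print(
    f"\nagainst simulator truth ({ev['n_true_converted']} imposed conversions "
    f"among {ev['n_scored']} scored quartets):"
)
print(f"  sensitivity      {ev['sensitivity']:.3f}")
print(f"  donor accuracy   {ev['donor_accuracy']:.3f}")
print(f"  false-call rate  {ev['false_call_rate']:.4f}")
print(f"  Y-donor fraction {ev['donor_fraction_y']:.3f} (bias set to 0.62)")

# A converted call means the quartet's NJ tree paired the two hexaploid
# homeologs together (the aberrant topology) with bootstrap support > 70%,
# and the donor is the homeolog whose outgroup the other copy now resembles.
ks_example = next(
    c for c in result.calls if c.status == "converted" and c.ks
)
print(
    f"\nKs annotation of converted quartet {ks_example.quartet_id} "
    f"(donor {ks_example.donor_role}, support {ks_example.support:.2f}):"
)
for pair, ks in sorted(ks_example.ks.items()):
    print(f"  {pair}: {ks:.4f}")
print(
    "the homeolog pair's Ks sits far below the Ks separating the parental"
    " lineages — the copies were homogenized by conversion long after the"
    " lineages split, and the acceptor now tracks the donor's outgroup"
)
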