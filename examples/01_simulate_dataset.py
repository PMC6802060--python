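"""Generate a small synthetic genome with retrotransposition ground truth.

The simulator emits a multi-chromosome genome carrying multi-exon genes,
inserts intronless retrocopies of their spliced CDSs (with substitutions,
frameshifts, premature stops, chimeric intronic insertions and poly-A
tails), samples error-bearing ESTs from expressed loci, and records every
event in a truth table.
"""

from retroforge import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    seed=7,
    n_chromosomes=3,
    chromosome_length=120_000,
    n_genes=8,
    n_retro_events=6,
    n_ests=40,
)
ds = simulate_dataset(cfg)

print(f"genome: {len(ds.genome.sequences)} chromosomes, "
      f"{sum(ds.genome.lengths.values()):,} bp total")
print(f"genes: {len(ds.models)}  proteins: {len(ds.proteins)}  ESTs: {len(ds.ests)}")
print("\ntruth table (one row per retrotransposition event):")
print(ds.truth_frame()[["event_id", "parent_gene", "chrom", "start", "end",
                        "strand", "intended_class", "chimeric", "expressed"]].to_string(index=False))
print("\nintended_class says whether the copy kept its parent's ORF (intact)")
print("or carries an injected frameshift/premature stop (pseudogene).")
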