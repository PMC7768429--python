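"""Genome-level descriptive statistics: GC content, GC skew track, gene tally.

Builds a small synthetic genome and prints the numbers a Table-1-style
summary and a circular-plot track export are made of.
"""

from strainscope.genome_stats import gc_skew_track, genome_summary
from strainscope.simulate import SimulationConfig, make_genome

syn = make_genome(SimulationConfig(rng_seed=7, genome_length_bp=60_000, n_genes=45,
                                   n_puls=2, n_background_cazy=2))
summary = genome_summary(syn.genome.sequence, syn.features)
print(f"genome size (bp):  {summary.length_bp}")
print(f"GC content (%):    {summary.gc_percent:.2f}")
print(f"protein genes:     {summary.n_features_by_type.get('CDS', 0)}")

skew = gc_skew_track(syn.genome.sequence, window=10_000, step=10_000)
print("\nGC skew per 10 kb window ((G-C)/(G+C); sign flips mark strand asymmetry):")
for start, end, value in skew.values:
    print(f"  [{start:>6}-{end:>6}]  {value:+.4f}")
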