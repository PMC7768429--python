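"""Fragment recruitment: estimate a strain's abundance in a community.

Simulates a community read pool in which 5% of reads derive from the
reference genome (with 1% sequencing error), maps every read with the
q-gram-seeded recruiter, and prints the abundance estimate next to the
planted truth.
"""

from strainscope.recruitment import RecruitmentParams, recruit_all
from strainscope.simulate import SimulationConfig, make_community_reads, make_genome

config = SimulationConfig(rng_seed=42, genome_length_bp=60_000, n_genes=45,
                          n_puls=2, n_background_cazy=2,
                          n_reads=5_000, target_read_fraction=0.05)
syn = make_genome(config)
reads, truth = make_community_reads(syn.genome, config)

report = recruit_all(reads, syn.genome, RecruitmentParams(rng_seed=1, sample_size=10**9))
print(f"reads sampled:      {report.n_sampled}")
print(f"reads recruited:    {report.n_recruited}")
print(f"abundance:          {report.abundance_percent:.2f}%  (planted truth: "
      f"{100 * truth.target_fraction:.2f}%)")
print(f"detected (>=0.1%):  {report.detected}")
print(f"high (>1%):         {report.high_abundance}")
print("\nAbundance is the recruited fraction of the sampled pool — the same")
print("statistic used to survey a genome across public metagenomes.")
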