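# Methods

This note records the models behind each analysis stage, the parameters
that matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Fragment recruitment

**Model.** Recruitment treats taxon abundance as the fraction of a
community read pool whose best alignment to the reference genome exceeds a
permissive identity threshold.  The estimator is per-read and best-hit-only:
each sampled read contributes at most one count, so the abundance is a
binomial proportion of the sampled pool.  Subsampling (default 2,000,000
reads, uniform without replacement, seeded) bounds cost per dataset and
makes abundances comparable across datasets of different depth.

**Algorithm.** The genome's forward strand is indexed by exact q-grams
(default q = 11; q-grams containing N are skipped); each read is looked up
in both orientations, which is equivalent to indexing both strands.  Seed
hits are grouped by alignment diagonal into bands of width `band_width`
(default 15); a band becomes a candidate only if it holds at least
`min_seed_count` (default 3) **non-overlapping** seeds.  Two design points
here were calibrated once on seeded nulls (random reads vs a 200 kb random
genome) and then frozen:

- *Non-overlapping seed counting.*  Overlapping q-grams are not independent
  evidence: one shared 12-mer — expected more than once per random
  150-mer against 200 kb — produces two overlapping 11-gram seeds on the
  same diagonal.  Counting raw seeds made 73% of random reads candidates;
  counting non-overlapping seeds removes that failure mode.
- *Seed support of 3.*  At support 2 the null recruitment rate was
  12/30,000 random reads; at 3 it was 0/30,000, while genome-derived reads
  at 1% error remain recruited at rate 1.0 and reads at 10% divergence at
  0.998.  Support 3 therefore keeps a target-free community at exactly 0%
  recruited.

Each candidate band is scored by a semi-global alignment (global in the
read, free end-gaps in the genome window; the seeded window realizes the
band).  Scoring is +1 match, −1 mismatch, −4 linear gap.  The mild
mismatch penalty keeps the mapper permissive down to the 50% identity gate;
the stiff gap penalty is deliberate: objectives that spend gaps freely
(e.g. minimum edit distance) push the match fraction of *random* alignments
above 0.5 — under edit-distance scoring, 91% of random reads exceeded the
gate — whereas with −4 gaps random alignments stay near the ungapped 25%
floor.  Identity is matches / alignment columns with gap columns counting
as non-matches and N never matching; a hit is kept only if identity is
**strictly** greater than the threshold (default 0.50, following the
"greater than 50%" phrasing of the protocol this reimplements).  Ties break
to the leftmost genome position, then forward orientation.

**Sensitivity trade-off.**  Exact q-gram seeding bounds sensitivity at high
divergence: a read at divergence d retains ≈ (1−d)^q of its q-grams, so at
d = 0.2 recruitment is ≈ 0.5 and at d ≥ 0.45 effectively 0, even though the
identity gate alone would admit alignments down to 50%.  The recruitment
rate is monotone in divergence, which is the property the abundance
statistic relies on; the same limitation applies to the q-gram filter
tools this stage models.

**Detection flags.** detected = abundance ≥ 0.1%, high = abundance > 1%,
evaluated by integer cross-multiplication (`1000·k ≥ n`), so the boundary
at exactly 2 recruited of 2,000 sampled is not subject to float round-off.
Coverage tracks bin hit midpoints into fixed windows (default 10 kb),
matching ring-plot granularity at a fraction of per-base depth cost.

## Transcript quantification

**Classification.** A contig is assigned to the strain when its single
best alignment (highest identity, ties to longest span, then leftmost)
covers ≥ 99% of the contig length at identity ≥ 97%.  Coverage is taken
from one alignment, not summed over HSPs: the gates describe one
near-full-length match, and summing HSPs would let chimeric contigs pass.
Both thresholds are sharp — synthetic contigs at identity 0.969/0.970 and
coverage 0.989/0.990 flip assignment exactly at the gates.

**Apportionment.** A contig's count X is split over the CDSs it overlaps
(≥ 1 bp, strand-agnostic) proportionally to *full* CDS lengths, exactly as
the length-weight formula states — not overlap lengths.  The alternative
(overlap-length weighting) is arguably more natural when a contig barely
clips a gene, but full-length weighting is what the formula literally
prescribes; the choice only matters for contigs that partially overlap
genes.  Counts are real-valued throughout (upstream quantifiers emit
fractional counts).  Contigs passing the gates but overlapping no CDS
route X to an explicit intergenic sink, making conservation
(Σ X_i + sink = Σ X) an exactly testable invariant; it holds to ~1e-15
relative on randomized fixtures.

**TPM.** tpm_i = 10⁶·(X_i/l_i)/Σ_j(X_j/l_j) with the denominator restricted
to the strain-assigned gene set, so TPMs are comparable within the strain
regardless of how much of the community the strain represents.  TPM is
invariant under uniform scaling of counts and sums to 10⁶ whenever any
count is positive; the all-zero case yields zeros with a warning.  Printed
TPMs in the published ranking this module mirrors are reproducible from
printed counts and lengths to within 1%, the residual being rounding of
printed fractional counts.

## PUL calling

The caller is deliberately rule-based and fully parameterized, because the
locus definitions behind published PUL sets are version- and
database-dependent; transparency was preferred over mimicking a specific
predictor.  Anchors are susC genes followed by a susD gene within
`max_anchor_gap_genes` (default 1) intervening genes, same strand, susC
upstream in transcription order (tandem operon architecture); pairing is
greedy left-to-right with each gene in at most one pair.  Extension walks
outward including genes that carry an extendable label (any well-formed
CAZy family label GH/PL/CE/GT/AA/CBM+number, "regulator", "peptidase",
susC/susD) while the gap since the last included gene stays within
`max_extension_gap_bp` (default 2,000) and `max_extension_gap_genes`
(default 2); genes skipped inside the locus span become members, keeping
membership contiguous.  Loci with shared or adjacent members merge and
keep all anchor pairs — this is how double-susCD loci arise.  susC/susD
and CAZy labels are consumed as annotation input, never predicted from
sequence.

**Substrate classification** is a majority vote of member families'
substrate classes; ties resolve to the lexicographically first class with
a tie flag, and loci without classifiable families are "unassigned".  The
default family→class map assigns the pectin set
{GH28, GH2, GH43, GH78, GH105, GH106, CE8, CE12, PL1} and the
hemicellulose/cellulose set {GH5, GH16, GH53, GH141}.  GH28 sits at the
intersection of pectin and hemicellulose chemistry; it is classed as
pectin because polygalacturonases are the canonical pectin backbone
hydrolases.  The map is configurable; genome-level summary fractions count
distinct families (families-in-PULs over families-in-genome) and genes
(pectin-class CAZyme genes in PULs over all CAZyme genes in PULs).

## Genome statistics

GC content is 100·(G+C)/(A+C+G+T) with ambiguous bases excluded from both
numerator and denominator — the full-length-denominator alternative was
rejected because it breaks exact reverse-complement invariance.  GC skew
is (G−C)/(G+C) in sliding windows (default 10 kb / 10 kb for track export),
the final partial window included; windows with G+C = 0 are emitted as 0
and flagged.  Coordinates are 1-based inclusive at every file boundary
(GFF3/BLAST convention) and converted once, centrally, to 0-based
half-open for slicing.

## Synthetic data

The generator emulates the *outputs* of the upstream tool chain (trimming,
rRNA filtering, assembly, pseudo-alignment), not the tools themselves.
All randomness flows from one root seed with per-stage derived generators;
regeneration is byte-identical.

- **Genome** (default 200 kb, 150 non-overlapping CDSs, GC 0.48): planted
  PUL blocks (tandem susCD plus 2–6 CAZyme flanks drawn from one substrate
  class; one block carries two anchor pairs) and isolated background
  CAZyme genes, separated by at least four unlabeled genes so planted loci
  are unambiguous under the default gap rules.
- **Community reads** (default 50,000 × 150 bp): a deterministic rounded
  fraction from the target genome (substitution errors, default 1%), an
  optional fraction from a relative derived by seeded substitution at
  divergence d, and random background at the genome's GC.  Substitution-only
  by default so alignment identity is analytically predictable; an indel
  rate can be enabled to exercise gapped alignment.
- **Transcriptome:** contigs partition the gene list into runs of 1–3
  consecutive CDSs (probabilities 0.6/0.3/0.1) with small UTR margins.  A
  multi-CDS contig is one polycistronic transcript, so molar expression is
  drawn per *transcript* (log-normal, μ = 1.0, σ = 1.5) and member-gene
  expected counts are expression·(l/1000) modulated by a within-operon
  log-normal factor (σ = 0.3, plausible polar-effect noise).  Under
  independent per-gene expression, length-weight apportionment provably
  cannot recover truth inside multi-CDS contigs (measured Spearman ≈ 0.72);
  under the transcript-level model recovery is ≈ 0.99, and the residual
  distortion is confined to multi-CDS contigs as intended.  Decoy contigs
  are planted at exact-count substitution identities below 0.97 or
  alignment spans below 0.99 coverage; off-species contigs have no
  alignment.  The generator writes the alignment table itself (it knows the
  true coordinates); emitting FASTA for a real aligner is possible but not
  used in tests, which keeps the suite dependency-free.

**What passing on synthetic data does not show:** real metagenomes contain
conserved inter-species sequence (rRNA operons, mobile elements) that
recruits at intermediate identity, and real assemblies contain chimeras and
strain mixtures; the random-background null is therefore optimistic about
specificity, and the clean contig partition is optimistic about
apportionment.  The tests demonstrate correctness of the statistics under
their stated models, not field performance.

## Problem sizes

Default test and acceptance runs use a 200 kb genome, 50,000-read
communities, and 150-gene transcriptomes — sizes chosen so the full
pipeline exercises every code path in well under a minute per run while
keeping binomial standard errors small relative to the tested effect
sizes (3 SE ≈ 0.19 percentage points at 2% abundance).  All sizes scale
by configuration.
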