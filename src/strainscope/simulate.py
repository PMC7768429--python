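"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the upstream world of the analysis: a finished
reference genome with annotated CDSs and planted susCD-anchored PULs; a
community read pool holding a known fraction of genome-derived reads next
to reads from a diverged relative and random background; and assembled
transcript contigs spanning 1-3 consecutive CDSs with known per-gene
expression, per-contig read counts, and contig-vs-genome alignments.

Everything flows from one root seed (sub-generators are derived per stage),
so regenerating with the same configuration is byte-identical.  Errors and
divergence are substitution-only by default, which keeps alignment identity
analytically predictable for threshold tests; an indel rate can be enabled
to exercise gapped alignment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AlignmentRecord,
    CountRecord,
    FeatureRecord,
    SequenceRecord,
    write_counts,
    write_fasta,
    write_fastq,
    write_gff_features,
    write_tabular_alignments,
)
from .pul import DEFAULT_SUBSTRATE_MAP

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    rng_seed: int
    genome_length_bp: int = 200_000
    n_genes: int = 150
    mean_gene_length: int = 900
    gc_target: float = 0.48
    n_puls: int = 5
    include_double_anchor: bool = True
    n_background_cazy: int = 8
    # community read pool
    n_reads: int = 50_000
    target_read_fraction: float = 0.02
    relative_read_fraction: float = 0.0
    relative_divergence: float = 0.2
    read_length: int = 150
    read_error_rate: float = 0.01
    indel_rate: float = 0.0
    # transcriptome: expression is drawn per transcript (= per contig, since
    # a multi-CDS contig is one polycistronic transcript); genes within an
    # operon are modulated around the transcript level
    expression_mu: float = 1.0
    expression_sigma: float = 1.5
    operon_noise_sigma: float = 0.3
    contig_span_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    utr_margin_max: int = 40
    decoy_fraction: float = 0.1
    offspecies_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "gc_target",
            "target_read_fraction",
            "relative_read_fraction",
            "relative_divergence",
            "read_error_rate",
            "indel_rate",
            "decoy_fraction",
            "offspecies_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_read_fraction + self.relative_read_fraction > 1.0:
            raise ValueError("target + relative read fractions exceed 1")
        if min(self.genome_length_bp, self.n_genes, self.mean_gene_length, self.read_length) < 1:
            raise ValueError("lengths and counts must be positive")
        if abs(sum(self.contig_span_probs) - 1.0) > 1e-9:
            raise ValueError("contig_span_probs must sum to 1")


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    target_fraction: float | None = None
    read_origins: dict[str, str] = field(default_factory=dict)
    read_loci: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_expression: dict[str, float] = field(default_factory=dict)
    contig_genes: dict[str, list[str]] = field(default_factory=dict)
    decoy_contigs: list[str] = field(default_factory=list)
    offspecies_contigs: list[str] = field(default_factory=list)
    pul_members: list[list[str]] = field(default_factory=list)
    pul_substrates: list[str] = field(default_factory=list)
    pul_anchor_counts: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, sort_keys=True, indent=1)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stage])


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def _substitute(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    """Substitute given positions to a guaranteed-different base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(256, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    old = code[arr[positions]]
    new = (old + rng.integers(1, 4, size=len(positions))) % 4
    arr[positions] = _BASES[new]
    return arr.tobytes().decode()


def mutate_at_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    return _substitute(seq, np.nonzero(mask)[0], rng)


def mutate_exact(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions, so identity (len-n)/len is exact."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    return _substitute(seq, positions, rng)


def _with_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if r > 1 - rate / 2:
            out.append("ACGT"[rng.integers(4)])  # insertion
    return "".join(out)


# ---------------------------------------------------------------------------
# genome with planted PULs


@dataclass
class SyntheticGenome:
    genome: SequenceRecord
    features: list[FeatureRecord]
    truth: GroundTruth


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random genome with non-overlapping CDSs and planted susCD PULs.

    PUL blocks (and isolated background CAZyme genes) are separated by at
    least four unlabeled genes so the planted loci are unambiguous under
    the default caller gap rules.  One planted locus carries two tandem
    susCD pairs when ``include_double_anchor`` is set, exercising locus
    merging.
    """
    rng = _rng(config, 1)
    # gene layout
    lengths = np.clip(
        rng.normal(config.mean_gene_length, config.mean_gene_length / 3, config.n_genes),
        300,
        int(config.mean_gene_length * 2.5),
    ).astype(int)
    lengths -= lengths % 3
    gaps = rng.integers(80, 300, size=config.n_genes + 1)
    needed = int(lengths.sum() + gaps.sum())
    if needed > config.genome_length_bp:
        raise ValueError(
            f"cannot fit {config.n_genes} genes in {config.genome_length_bp} bp; "
            "increase genome_length_bp"
        )
    starts = np.empty(config.n_genes, dtype=int)
    cursor = int(gaps[0])
    for i in range(config.n_genes):
        starts[i] = cursor + 1  # 1-based
        cursor += int(lengths[i]) + int(gaps[i + 1])

    # plan labeled blocks: PULs then isolated background CAZy genes
    classes: dict[str, list[str]] = {}
    for fam, cls in DEFAULT_SUBSTRATE_MAP.items():
        classes.setdefault(cls, []).append(fam)
    for fams in classes.values():
        fams.sort()
    class_names = sorted(classes)

    blocks: list[tuple[list[set[str]], str, int]] = []  # (per-gene labels, substrate, n_anchors)
    for p in range(config.n_puls):
        substrate = class_names[p % len(class_names)]
        fams = classes[substrate]
        if p == 0 and config.include_double_anchor:
            pattern: list[set[str]] = [
                {fams[rng.integers(len(fams))]},
                {"susC"},
                {"susD"},
                {fams[rng.integers(len(fams))]},
                {"susC"},
                {"susD"},
                {fams[rng.integers(len(fams))]},
            ]
            n_anchors = 2
        else:
            n_flank = int(rng.integers(2, 7))
            flank = [{fams[rng.integers(len(fams))]} for _ in range(n_flank)]
            split = n_flank // 2
            pattern = flank[:split] + [{"susC"}, {"susD"}] + flank[split:]
            if p == 1:
                pattern.append({"regulator"})
            n_anchors = 1
        blocks.append((pattern, substrate, n_anchors))
    # background CAZy singletons, drawn partly from families outside the map
    extra_families = ["GH109", "GH92", "GH127", "GT2", "GH13", "CBM50"]
    all_fams = sorted(DEFAULT_SUBSTRATE_MAP) + extra_families
    for b in range(config.n_background_cazy):
        blocks.append(([{all_fams[rng.integers(len(all_fams))]}], "", 0))

    sep = 4  # unlabeled genes between labeled blocks; > caller gene-gap limit
    needed_genes = sum(len(b[0]) for b in blocks) + sep * (len(blocks) + 1)
    if needed_genes > config.n_genes:
        raise ValueError(
            f"cannot place {len(blocks)} labeled blocks in {config.n_genes} genes; "
            "increase n_genes"
        )
    slack = config.n_genes - needed_genes
    extra = rng.multinomial(slack, np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))

    labels: list[set[str]] = [set() for _ in range(config.n_genes)]
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    truth = GroundTruth()
    pointer = sep + int(extra[0])
    for bi, (pattern, substrate, n_anchors) in enumerate(blocks):
        members: list[str] = []
        for k, labelset in enumerate(pattern):
            gi = pointer + k
            labels[gi] = set(labelset)
            strands[gi] = "+"
            members.append(f"SYN_{gi + 1:04d}")
        if n_anchors > 0:
            truth.pul_members.append(members)
            truth.pul_substrates.append(substrate)
            truth.pul_anchor_counts.append(n_anchors)
        pointer += len(pattern) + sep + int(extra[bi + 1])

    features = [
        FeatureRecord(
            locus_tag=f"SYN_{i + 1:04d}",
            feature_type="CDS",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i] - 1),
            strand=str(strands[i]),
            function_labels=frozenset(labels[i]),
        )
        for i in range(config.n_genes)
    ]
    sequence = random_sequence(config.genome_length_bp, config.gc_target, rng)
    genome = SequenceRecord("synthetic_genome", sequence, "synthetic reference genome")
    return SyntheticGenome(genome=genome, features=features, truth=truth)


# ---------------------------------------------------------------------------
# community read pool


def make_community_reads(
    genome: SequenceRecord | str, config: SimulationConfig
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Reads from the target genome, a diverged relative, and background.

    Per-read origin and (for target reads) the true source locus are
    recorded.  Origin counts are deterministic (rounded fractions), so the
    planted target abundance is exact up to rounding.
    """
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    L = len(seq)
    if config.read_length > L:
        raise ValueError("read_length exceeds genome length")
    rng = _rng(config, 2)
    comp = str.maketrans("ACGTN", "TGCAN")
    n = config.n_reads
    n_target = round(config.target_read_fraction * n)
    n_rel = round(config.relative_read_fraction * n)
    n_bg = n - n_target - n_rel
    relative = mutate_at_rate(seq, config.relative_divergence, rng) if n_rel else seq

    reads: list[SequenceRecord] = []
    truth = GroundTruth(target_fraction=config.target_read_fraction)

    def _draw(source: str, origin: str, i: int) -> SequenceRecord:
        pos = int(rng.integers(0, len(source) - config.read_length + 1))
        frag = source[pos : pos + config.read_length]
        frag = mutate_at_rate(frag, config.read_error_rate, rng)
        if config.indel_rate:
            frag = _with_indels(frag, config.indel_rate, rng)
        if rng.random() < 0.5:
            frag = frag.translate(comp)[::-1]
        rid = f"read_{i:06d}"
        truth.read_origins[rid] = origin
        if origin == "target":
            truth.read_loci[rid] = (pos + 1, pos + config.read_length)
        return SequenceRecord(rid, frag)

    i = 0
    for _ in range(n_target):
        reads.append(_draw(seq, "target", i))
        i += 1
    for _ in range(n_rel):
        reads.append(_draw(relative, "relative", i))
        i += 1
    for _ in range(n_bg):
        rid = f"read_{i:06d}"
        reads.append(SequenceRecord(rid, random_sequence(config.read_length, config.gc_target, rng)))
        truth.read_origins[rid] = "background"
        i += 1
    order = rng.permutation(n)
    return [reads[k] for k in order], truth


# ---------------------------------------------------------------------------
# transcriptome: contigs + alignments + counts


@dataclass
class SyntheticTranscriptome:
    contigs: list[SequenceRecord]
    alignments: list[AlignmentRecord]
    counts: dict[str, float]
    truth: GroundTruth


def make_transcriptome(
    genome: SequenceRecord | str,
    features: list[FeatureRecord],
    config: SimulationConfig,
) -> SyntheticTranscriptome:
    """Contigs spanning 1-3 consecutive CDSs plus decoy and off-species contigs.

    Each contig is one assembled transcript: a log-normal molar expression
    is drawn per transcript, and the expected read count of each member
    gene is expression * (length/1000) modulated by a milder log-normal
    within-operon factor (polar effects, internal promoters).  The contig's
    count is the sum of its member genes' expected counts (fractional).
    Decoys fail either the identity gate (exact-count substitutions) or the
    coverage gate (partial alignment span); off-species contigs have no
    alignment at all.
    """
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    rng = _rng(config, 3)
    genes = sorted(
        (f for f in features if f.feature_type == "CDS"), key=lambda f: f.start
    )
    truth = GroundTruth()
    contigs: list[SequenceRecord] = []
    alignments: list[AlignmentRecord] = []
    counts: dict[str, float] = {}

    i = 0
    cn = 0
    while i < len(genes):
        span = int(rng.choice([1, 2, 3], p=config.contig_span_probs))
        span = min(span, len(genes) - i)
        members = genes[i : i + span]
        margin_l = int(rng.integers(5, config.utr_margin_max + 1))
        margin_r = int(rng.integers(5, config.utr_margin_max + 1))
        prev_end = genes[i - 1].end if i > 0 else 0
        next_start = genes[i + span].start if i + span < len(genes) else len(seq) + 1
        start = max(members[0].start - margin_l, prev_end + 1, 1)
        end = min(members[-1].end + margin_r, next_start - 1, len(seq))
        cn += 1
        cid = f"contig_{cn:04d}"
        contigs.append(SequenceRecord(cid, seq[start - 1 : end]))
        clen = end - start + 1
        alignments.append(
            AlignmentRecord(
                query_id=cid,
                subject_id="synthetic_genome",
                identity=1.0,
                aln_length=clen,
                q_start=1,
                q_end=clen,
                s_start=start,
                s_end=end,
                orientation="forward",
                score=2.0 * clen,
            )
        )
        transcript_level = rng.lognormal(config.expression_mu, config.expression_sigma)
        total = 0.0
        for m in members:
            ci = (
                transcript_level
                * (m.length_nt / 1000.0)
                * rng.lognormal(0.0, config.operon_noise_sigma)
            )
            truth.gene_expression[m.locus_tag] = ci
            total += ci
        counts[cid] = total
        truth.contig_genes[cid] = [m.locus_tag for m in members]
        i += span

    n_real = cn
    n_decoys = round(config.decoy_fraction * n_real)
    for d in range(n_decoys):
        dlen = int(rng.integers(500, 2001))
        start = int(rng.integers(1, len(seq) - dlen + 1))
        frag = seq[start - 1 : start + dlen - 1]
        cn += 1
        cid = f"decoy_{cn:04d}"
        if d % 2 == 0:
            # identity decoy: exact substitution count below the 0.97 gate
            ident = float(rng.uniform(0.90, 0.965))
            k = max(1, round((1.0 - ident) * dlen))
            frag = mutate_exact(frag, k, rng)
            identity = (dlen - k) / dlen
            q_end = dlen
        else:
            # coverage decoy: perfect identity, span below the 0.99 gate
            identity = 1.0
            q_end = int(dlen * rng.uniform(0.90, 0.985))
        contigs.append(SequenceRecord(cid, frag))
        alignments.append(
            AlignmentRecord(
                query_id=cid,
                subject_id="synthetic_genome",
                identity=identity,
                aln_length=q_end,
                q_start=1,
                q_end=q_end,
                s_start=start,
                s_end=start + q_end - 1,
                orientation="forward",
                score=2.0 * q_end,
            )
        )
        counts[cid] = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        truth.decoy_contigs.append(cid)

    n_off = round(config.offspecies_fraction * n_real)
    for _ in range(n_off):
        olen = int(rng.integers(500, 2001))
        cn += 1
        cid = f"offspecies_{cn:04d}"
        contigs.append(SequenceRecord(cid, random_sequence(olen, config.gc_target, rng)))
        counts[cid] = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        truth.offspecies_contigs.append(cid)

    return SyntheticTranscriptome(
        contigs=contigs, alignments=alignments, counts=counts, truth=truth
    )


def make_decoy_with_identity(
    genome: SequenceRecord | str,
    start: int,
    length: int,
    identity: float,
    rng: np.random.Generator,
    contig_id: str = "boundary_contig",
    coverage: float = 1.0,
) -> tuple[SequenceRecord, AlignmentRecord]:
    """A contig at an exact alignment identity and coverage, for boundary tests.

    ``identity * length`` and ``coverage * length`` must be integral so the
    emitted alignment record sits exactly on the requested values.
    """
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    k = round((1.0 - identity) * length)
    span = round(coverage * length)
    frag = seq[start - 1 : start + length - 1]
    if k:
        frag = mutate_exact(frag, k, rng)
    contig = SequenceRecord(contig_id, frag)
    aln = AlignmentRecord(
        query_id=contig_id,
        subject_id="synthetic_genome",
        identity=(length - k) / length,
        aln_length=span,
        q_start=1,
        q_end=span,
        s_start=start,
        s_end=start + span - 1,
        orientation="forward",
        score=2.0 * span,
    )
    return contig, aln


# ---------------------------------------------------------------------------
# one-call emitter


def simulate_all(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate genome, annotation, reads, and transcriptome under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = make_genome(config)
    write_fasta([syn.genome], outdir / "genome.fasta")
    write_gff_features(syn.features, outdir / "ann.gff3", seqid=syn.genome.id)
    with open(outdir / "functions.tsv", "w") as fh:
        for f in syn.features:
            if f.function_labels:
                fh.write(f"{f.locus_tag}\t{';'.join(sorted(f.function_labels))}\n")
    reads, read_truth = make_community_reads(syn.genome, config)
    write_fastq(reads, outdir / "reads.fastq")
    tx = make_transcriptome(syn.genome, syn.features, config)
    write_fasta(tx.contigs, outdir / "contigs.fasta")
    write_tabular_alignments(tx.alignments, outdir / "contigs_vs_genome.tsv")
    write_counts(
        [CountRecord(c, x) for c, x in tx.counts.items()], outdir / "contig_counts.tsv"
    )
    truth = GroundTruth(
        target_fraction=read_truth.target_fraction,
        read_origins=read_truth.read_origins,
        read_loci=read_truth.read_loci,
        gene_expression=tx.truth.gene_expression,
        contig_genes=tx.truth.contig_genes,
        decoy_contigs=tx.truth.decoy_contigs,
        offspecies_contigs=tx.truth.offspecies_contigs,
        pul_members=syn.truth.pul_members,
        pul_substrates=syn.truth.pul_substrates,
        pul_anchor_counts=syn.truth.pul_anchor_counts,
    )
    truth.to_json(outdir / "truth.json")
    return truth
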