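import json

import numpy as np
import pytest

from strainscope import recruitment as rec
from strainscope import transcript_quant as tq
from strainscope.genome_stats import gc_content
from strainscope.io_formats import read_tabular_alignments, write_tabular_alignments
from strainscope.simulate import (
    SimulationConfig,
    make_community_reads,
    make_genome,
    make_transcriptome,
    mutate_exact,
    simulate_all,
)


def _small_config(**kw):
    kw.setdefault("rng_seed", 7)
    kw.setdefault("genome_length_bp", 60_000)
    kw.setdefault("n_genes", 45)
    kw.setdefault("n_puls", 2)
    kw.setdefault("n_background_cazy", 2)
    kw.setdefault("n_reads", 1_000)
    return SimulationConfig(**kw)


class TestConfig:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            _small_config(target_read_fraction=1.5)

    def test_fractions_must_not_exceed_one(self):
        with pytest.raises(ValueError):
            _small_config(target_read_fraction=0.6, relative_read_fraction=0.6)

    def test_span_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            _small_config(contig_span_probs=(0.5, 0.5, 0.5))


class TestGenome:
    def test_determinism_in_memory(self):
        a = make_genome(_small_config())
        b = make_genome(_small_config())
        assert a.genome.sequence == b.genome.sequence
        assert a.features == b.features
        assert a.truth.pul_members == b.truth.pul_members

    def test_emitted_files_byte_identical(self, tmp_path):
        simulate_all(_small_config(), tmp_path / "a")
        simulate_all(_small_config(), tmp_path / "b")
        for name in (
            "genome.fasta",
            "ann.gff3",
            "functions.tsv",
            "reads.fastq",
            "contigs.fasta",
            "contigs_vs_genome.tsv",
            "contig_counts.tsv",
            "truth.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_realized_gc_close_to_target(self, default_sim):
        assert gc_content(default_sim.genome.sequence) == pytest.approx(48.0, abs=1.0)

    def test_genes_non_overlapping_and_within_genome(self, default_sim):
        feats = sorted(default_sim.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end < b.start
        assert feats[-1].end <= len(default_sim.genome.sequence)

    def test_too_many_genes_is_error(self):
        with pytest.raises(ValueError, match="genome_length_bp"):
            make_genome(_small_config(genome_length_bp=10_000, n_genes=45))

    def test_planted_double_anchor_present(self, default_sim):
        assert 2 in default_sim.truth.pul_anchor_counts


class TestCommunityReads:
    def test_origin_counts_match_rounded_fractions(self):
        cfg = _small_config(target_read_fraction=0.1, relative_read_fraction=0.05)
        syn = make_genome(cfg)
        reads, truth = make_community_reads(syn.genome, cfg)
        origins = list(truth.read_origins.values())
        assert origins.count("target") == 100
        assert origins.count("relative") == 50
        assert origins.count("background") == 850
        assert len(reads) == 1000

    def test_read_length_exceeding_genome_is_error(self):
        cfg = _small_config(read_length=70_000)
        syn = make_genome(_small_config())
        with pytest.raises(ValueError):
            make_community_reads(syn.genome, cfg)

    def test_pure_error_free_target_pool_reaches_full_abundance(self):
        cfg = _small_config(
            target_read_fraction=1.0, read_error_rate=0.0, n_reads=300
        )
        syn = make_genome(cfg)
        reads, _ = make_community_reads(syn.genome, cfg)
        report = rec.recruit_all(
            reads, syn.genome, rec.RecruitmentParams(rng_seed=1, sample_size=10**9)
        )
        assert report.abundance_percent == 100.0

    def test_distant_relative_pool_stays_below_detection(self):
        cfg = _small_config(
            target_read_fraction=0.0,
            relative_read_fraction=1.0,
            relative_divergence=0.6,
            n_reads=300,
        )
        syn = make_genome(cfg)
        reads, _ = make_community_reads(syn.genome, cfg)
        report = rec.recruit_all(
            reads, syn.genome, rec.RecruitmentParams(rng_seed=1, sample_size=10**9)
        )
        assert report.abundance_percent <= 2.0

    def test_target_read_loci_recorded_consistently(self):
        cfg = _small_config(target_read_fraction=0.2, read_error_rate=0.0)
        syn = make_genome(cfg)
        reads, truth = make_community_reads(syn.genome, cfg)
        seq = syn.genome.sequence
        checked = 0
        for r in reads:
            if truth.read_origins[r.id] != "target":
                continue
            s, e = truth.read_loci[r.id]
            frag = seq[s - 1 : e]
            assert r.sequence in (frag, rec.reverse_complement(frag))
            checked += 1
        assert checked == 200


class TestTranscriptome:
    def test_contig_counts_equal_sum_of_member_gene_truth(self):
        cfg = _small_config()
        syn = make_genome(cfg)
        tx = make_transcriptome(syn.genome, syn.features, cfg)
        for cid, genes in tx.truth.contig_genes.items():
            expected = sum(tx.truth.gene_expression[g] for g in genes)
            assert tx.counts[cid] == pytest.approx(expected, rel=1e-12)

    def test_alignment_records_pass_format_validators(self, tmp_path):
        cfg = _small_config()
        syn = make_genome(cfg)
        tx = make_transcriptome(syn.genome, syn.features, cfg)
        path = tmp_path / "aln.tsv"
        write_tabular_alignments(tx.alignments, path)
        back = read_tabular_alignments(path)
        assert len(back) == len(tx.alignments)
        assert all(0.0 <= a.identity <= 1.0 for a in back)

    def test_decoys_fail_a_classification_gate(self):
        cfg = _small_config()
        syn = make_genome(cfg)
        tx = make_transcriptome(syn.genome, syn.features, cfg)
        lengths = {c.id: len(c) for c in tx.contigs}
        by_query = {a.query_id: a for a in tx.alignments}
        assert tx.truth.decoy_contigs
        for cid in tx.truth.decoy_contigs:
            a = by_query[cid]
            coverage = (a.q_end - a.q_start + 1) / lengths[cid]
            assert a.identity < 0.97 or coverage < 0.99

    def test_offspecies_contigs_have_no_alignment(self):
        cfg = _small_config()
        syn = make_genome(cfg)
        tx = make_transcriptome(syn.genome, syn.features, cfg)
        aligned = {a.query_id for a in tx.alignments}
        assert tx.truth.offspecies_contigs
        assert not aligned & set(tx.truth.offspecies_contigs)

    def test_single_cds_contigs_recover_truth_exactly(self):
        cfg = _small_config(contig_span_probs=(1.0, 0.0, 0.0), decoy_fraction=0.0,
                            offspecies_fraction=0.0)
        syn = make_genome(cfg)
        tx = make_transcriptome(syn.genome, syn.features, cfg)
        lengths = {c.id: len(c) for c in tx.contigs}
        assigned = tq.classify_contigs(
            tx.alignments, lengths, tq.ClassificationParams(), tx.counts
        )
        rows, sink = tq.aggregate_counts(assigned, syn.features)
        assert sink == 0.0
        for r in rows:
            assert r.count == pytest.approx(
                tx.truth.gene_expression[r.locus_tag], rel=1e-9
            )

    def test_exact_mutation_count(self, rng):
        seq = "ACGT" * 250
        mutated = mutate_exact(seq, 31, rng)
        diffs = sum(a != b for a, b in zip(seq, mutated))
        assert diffs == 31


class TestEmitter:
    def test_truth_json_recountable(self, tmp_path):
        cfg = _small_config()
        simulate_all(cfg, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        fastq_reads = (tmp_path / "reads.fastq").read_text().count("@read_")
        assert fastq_reads == cfg.n_reads
        origins = list(truth["read_origins"].values())
        assert origins.count("target") == round(cfg.target_read_fraction * cfg.n_reads)
        counts = dict(
            line.split("\t")
            for line in (tmp_path / "contig_counts.tsv").read_text().splitlines()
        )
        for cid, genes in truth["contig_genes"].items():
            expected = sum(truth["gene_expression"][g] for g in genes)
            assert float(counts[cid]) == pytest.approx(expected, rel=1e-9)
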