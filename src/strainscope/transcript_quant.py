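"""Metatranscriptome quantification restricted to one target species.

Assembled transcript contigs are classified as originating from the target
genome when their best alignment covers at least 99% of the contig length
at 97% identity or more.  Each classified contig's read count X is then
apportioned onto the coding sequences it overlaps using full CDS lengths as
weights:

    X_i = X * l_i / sum_j l_j

over the CDSs j overlapping the contig.  TPM is computed over the
species-assigned gene set only, so the per-million normalization is
species-restricted:

    tpm_i = 1e6 * (X_i / l_i) / sum_j (X_j / l_j)

Counts are real-valued throughout (upstream quantifiers emit fractional
counts).  Contigs passing the filters but overlapping zero CDSs route
their counts to an explicit intergenic sink so count conservation is an
exactly testable invariant.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import AlignmentRecord, FeatureRecord, interval_0h

logger = logging.getLogger(__name__)


@dataclass
class ClassificationParams:
    """Thresholds for calling a contig a target-species transcript."""

    min_contig_coverage: float = 0.99
    min_identity: float = 0.97

    def __post_init__(self) -> None:
        for name in ("min_contig_coverage", "min_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class AssignedContig:
    """A contig classified as a target transcript, with its placement."""

    contig_id: str
    contig_length: int
    s_start: int
    s_end: int
    identity: float
    read_count: float = 0.0


@dataclass
class GeneExpressionRow:
    locus_tag: str
    length_nt: int
    count: float = 0.0
    tpm: float | None = None


INTERGENIC = "__intergenic__"


def _best_alignment(alignments: Sequence[AlignmentRecord]) -> AlignmentRecord:
    """Highest identity; ties broken by longest alignment, then leftmost."""
    return min(
        alignments,
        key=lambda a: (-a.identity, -(a.q_end - a.q_start + 1), a.s_start),
    )


def classify_contigs(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    params: ClassificationParams | None = None,
    counts: Mapping[str, float] | None = None,
) -> list[AssignedContig]:
    """Keep contigs whose best alignment passes coverage and identity gates.

    Coverage is the aligned query span of the single best alignment divided
    by the contig length (HSPs are not summed).  If *counts* is given, each
    kept contig carries its read count.
    """
    params = params or ClassificationParams()
    by_contig: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_contig[a.query_id].append(a)
    kept: list[AssignedContig] = []
    for contig_id in by_contig:
        if contig_id not in contig_lengths:
            raise KeyError(f"contig {contig_id} present in alignments but has no length")
    for contig_id, alns in sorted(by_contig.items()):
        best = _best_alignment(alns)
        length = contig_lengths[contig_id]
        coverage = (best.q_end - best.q_start + 1) / length
        if coverage >= params.min_contig_coverage and best.identity >= params.min_identity:
            kept.append(
                AssignedContig(
                    contig_id=contig_id,
                    contig_length=length,
                    s_start=best.s_start,
                    s_end=best.s_end,
                    identity=best.identity,
                    read_count=0.0 if counts is None else float(counts.get(contig_id, 0.0)),
                )
            )
    return kept


def _cds_tree(features: Iterable[FeatureRecord]) -> IntervalTree:
    tree = IntervalTree()
    for f in features:
        if f.feature_type == "CDS":
            lo, hi = interval_0h(f.start, f.end)
            tree.addi(lo, hi, f)
    return tree


def overlapping_cds(
    genome_interval: tuple[int, int], features: Iterable[FeatureRecord]
) -> list[FeatureRecord]:
    """CDS features intersecting a 1-based inclusive interval by >= 1 bp,
    in genome order.  Strand-agnostic."""
    lo, hi = interval_0h(*genome_interval)
    tree = _cds_tree(features)
    found = [iv.data for iv in tree.overlap(lo, hi)]
    found.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return found


def apportion_counts(
    X: float, overlapped_features: Sequence[FeatureRecord]
) -> dict[str, float]:
    """Split a contig count over its overlapping CDSs by full CDS length."""
    if X < 0:
        raise ValueError("contig count must be >= 0")
    if not overlapped_features:
        raise ValueError(
            "no overlapping CDS; route the count to the intergenic sink instead"
        )
    total = sum(f.length_nt for f in overlapped_features)
    return {f.locus_tag: X * f.length_nt / total for f in overlapped_features}


def aggregate_counts(
    assigned_contigs: Iterable[AssignedContig],
    features: Sequence[FeatureRecord],
) -> tuple[list[GeneExpressionRow], float]:
    """Sum apportioned counts per gene over all assigned contigs.

    Returns one row per CDS (zero for unexpressed genes) plus the
    intergenic sink, so that sum(rows) + sink == sum(contig counts).
    """
    tree = _cds_tree(features)
    totals: dict[str, float] = defaultdict(float)
    sink = 0.0
    for contig in assigned_contigs:
        lo, hi = interval_0h(contig.s_start, contig.s_end)
        overlapped = sorted(
            (iv.data for iv in tree.overlap(lo, hi)),
            key=lambda f: (f.start, f.end, f.locus_tag),
        )
        if not overlapped:
            sink += contig.read_count
            continue
        for locus, xi in apportion_counts(contig.read_count, overlapped).items():
            totals[locus] += xi
    rows = [
        GeneExpressionRow(f.locus_tag, f.length_nt, totals.get(f.locus_tag, 0.0))
        for f in features
        if f.feature_type == "CDS"
    ]
    return rows, sink


def compute_tpm(rows: Sequence[GeneExpressionRow]) -> list[GeneExpressionRow]:
    """Fill TPM over the species-assigned gene set (rows as given)."""
    rates = [r.count / r.length_nt for r in rows]
    total = sum(rates)
    if total == 0.0:
        logger.warning("all counts zero: TPM set to zero for every gene")
        return [replace_row(r, tpm=0.0) for r in rows]
    return [
        replace_row(r, tpm=1e6 * rate / total) for r, rate in zip(rows, rates)
    ]


def replace_row(row: GeneExpressionRow, **kw) -> GeneExpressionRow:
    return replace(row, **kw)


def rank_genes(
    rows: Sequence[GeneExpressionRow],
    function_filter: set[str] | None = None,
    features: Mapping[str, FeatureRecord] | None = None,
) -> list[GeneExpressionRow]:
    """Rank genes by TPM, highest first; stable tie-break by locus tag.

    With *function_filter*, only genes carrying at least one of the given
    function labels are kept (requires *features* keyed by locus tag).
    """
    if function_filter is not None:
        if features is None:
            raise ValueError("function_filter requires a features mapping")
        rows = [
            r
            for r in rows
            if r.locus_tag in features
            and features[r.locus_tag].function_labels & function_filter
        ]
    return sorted(rows, key=lambda r: (-(r.tpm if r.tpm is not None else 0.0), r.locus_tag))
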