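"""Readers and writers for the external formats the pipeline touches.

All coordinates at file boundaries are 1-based inclusive (GFF3 / BLAST
tabular conventions).  Conversion to Python's 0-based half-open indexing is
centralized in :func:`interval_0h` and performed exactly once at the point
of sequence slicing, never ad hoc.

Sequences are uppercased on read; characters outside {A, C, G, T, N} are
mapped to N (with a logged warning) and N never counts as a match anywhere
downstream.  FASTQ is accepted read-only; qualities are ignored because no
downstream procedure uses them.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "other")

_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def interval_0h(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


@dataclass
class SequenceRecord:
    """A nucleotide sequence (genome, contig, or read)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated genome feature with 1-based inclusive coordinates."""

    locus_tag: str
    feature_type: str
    start: int
    end: int
    strand: str
    function_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            object.__setattr__(self, "feature_type", "other")
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"feature {self.locus_tag}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature {self.locus_tag}: strand must be + or -")
        if self.feature_type == "CDS" and self.length_nt < 3:
            raise FormatError(f"CDS {self.locus_tag} shorter than 3 nt")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignmentRecord:
    """One query-vs-genome alignment (BLAST outfmt-6 contract).

    ``identity`` is a fraction in [0, 1]; subject coordinates are stored
    normalized (``s_start <= s_end``) with the original orientation kept in
    ``orientation`` ("forward" or "reverse").
    """

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str = "forward"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise FormatError(f"identity {self.identity} outside [0, 1]")
        if self.q_start > self.q_end:
            raise FormatError("q_start > q_end after normalization")
        if self.s_start > self.s_end:
            raise FormatError("s_start > s_end after normalization")
        if self.orientation not in ("forward", "reverse"):
            raise FormatError(f"bad orientation {self.orientation!r}")
        if self.score < 0:
            raise FormatError("negative alignment score")


@dataclass(frozen=True)
class CountRecord:
    """Per-contig read count; fractional counts are legitimate."""

    contig_id: str
    count: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise FormatError(f"negative count for {self.contig_id}")


# ---------------------------------------------------------------------------
# sequence I/O


def _sanitize(seq: str, record_id: str) -> str:
    seq = seq.upper()
    n_bad = len(_NON_ACGTN.findall(seq))
    if n_bad:
        logger.warning(
            "record %s: %d non-ACGTN characters mapped to N", record_id, n_bad
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects, order preserved."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        # Biopython silently skips leading junk; enforce the dialect here.
        head = fh.read(1)
        if head not in (">", ""):
            raise FormatError(f"{path}: sequence data before any FASTA header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(
                SequenceRecord(rec.id, _sanitize(str(rec.seq), rec.id), rec.description)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ (optionally gzipped); qualities are discarded."""
    with _open_text(path) as fh:
        return [
            SequenceRecord(rec.id, _sanitize(str(rec.seq), rec.id), rec.description)
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with flat placeholder qualities (phred 40)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# GFF3 features

_LABEL_SPLIT = re.compile(r"[;,]")


def read_gff_features(
    path: str | Path,
    label_key: str = "function_labels",
    genome_length: int | None = None,
) -> list[FeatureRecord]:
    """Parse a GFF3 annotation into validated :class:`FeatureRecord` rows.

    Function labels are taken from *label_key* (comma- or
    semicolon-separated).  Duplicate locus tags and inverted intervals are
    format errors naming the offending line.
    """
    features: list[FeatureRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF fields, got {len(fields)}")
            try:
                gff = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions on bad coords
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if gff.start > gff.end:
                raise FormatError(f"{path}:{lineno}: start {gff.start} > end {gff.end}")
            attrs = gff.attributes
            locus = (attrs.get("locus_tag") or attrs.get("ID") or [None])[0]
            if locus is None:
                raise FormatError(f"{path}:{lineno}: no locus_tag or ID attribute")
            if locus in seen:
                raise FormatError(f"{path}:{lineno}: duplicate locus_tag {locus}")
            seen.add(locus)
            labels: set[str] = set()
            for raw in attrs.get(label_key, []):
                labels.update(x.strip() for x in _LABEL_SPLIT.split(raw) if x.strip())
            ftype = gff.featuretype if gff.featuretype in FEATURE_TYPES else "other"
            if genome_length is not None and gff.end > genome_length:
                raise FormatError(
                    f"{path}:{lineno}: feature end {gff.end} beyond genome length {genome_length}"
                )
            try:
                features.append(
                    FeatureRecord(
                        locus_tag=locus,
                        feature_type=ftype,
                        start=gff.start,
                        end=gff.end,
                        strand=gff.strand if gff.strand in "+-" else "+",
                        function_labels=frozenset(labels),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return features


def write_gff_features(
    features: Iterable[FeatureRecord],
    path: str | Path,
    seqid: str = "genome",
    source: str = "strainscope",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.function_labels:
                attrs += ";function_labels=" + ",".join(sorted(f.function_labels))
            fh.write(
                f"{seqid}\t{source}\t{f.feature_type}\t{f.start}\t{f.end}\t.\t{f.strand}\t"
                f"{'0' if f.feature_type == 'CDS' else '.'}\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BLAST-style 12-column tabular alignments

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read 12-column tabular alignments (BLAST ``-outfmt 6`` dialect)."""
    records: list[AlignmentRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            (qseqid, sseqid, pident, length, _mismatch, _gapopen,
             qstart, qend, sstart, send, _evalue, bitscore) = fields
            s_start, s_end = int(sstart), int(send)
            orientation = "forward"
            if s_start > s_end:
                s_start, s_end = s_end, s_start
                orientation = "reverse"
            try:
                records.append(
                    AlignmentRecord(
                        query_id=qseqid,
                        subject_id=sseqid,
                        identity=float(pident) / 100.0,
                        aln_length=int(length),
                        q_start=int(qstart),
                        q_end=int(qend),
                        s_start=s_start,
                        s_end=s_end,
                        orientation=orientation,
                        score=float(bitscore),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_tabular_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records back to the 12-column dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for r in records:
            s1, s2 = r.s_start, r.s_end
            if r.orientation == "reverse":
                s1, s2 = s2, s1
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{100.0 * r.identity:.3f}\t{r.aln_length}\t"
                f"0\t0\t{r.q_start}\t{r.q_end}\t{s1}\t{s2}\t0.0\t{r.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# count tables


def read_counts(path: str | Path) -> list[CountRecord]:
    """Read a 2-column TSV of contig_id, count (fractional allowed)."""
    records: list[CountRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            try:
                records.append(CountRecord(fields[0], float(fields[1])))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_counts(records: Iterable[CountRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig_id}\t{r.count:.12g}\n")


def counts_as_mapping(records: Iterable[CountRecord]) -> dict[str, float]:
    return {r.contig_id: r.count for r in records}


# ---------------------------------------------------------------------------
# tracks (Circos-compatible 4-column TSV)

Track = Sequence[tuple[int, int, float]]


def _validate_track(track: Track) -> None:
    prev_end = 0
    for start, end, _value in track:
        if start > end:
            raise FormatError(f"track window [{start}, {end}] inverted")
        if start <= prev_end:
            raise FormatError(
                f"track windows must be sorted and non-overlapping (window at {start})"
            )
        prev_end = end


def write_track(track: Track, path: str | Path, seqid: str = "genome") -> None:
    """Export (start, end, value) windows as ``seqid start end value`` rows."""
    _validate_track(track)
    with open(path, "w") as fh:
        fh.write("#seqid\tstart\tend\tvalue\n")
        for start, end, value in track:
            fh.write(f"{seqid}\t{start}\t{end}\t{value:.12g}\n")


def read_track(path: str | Path) -> list[tuple[int, int, float]]:
    rows: list[tuple[int, int, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            rows.append((int(fields[1]), int(fields[2]), float(fields[3])))
    _validate_track(rows)
    return rows
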