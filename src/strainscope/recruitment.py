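"""Fragment recruitment: mapping community reads onto one reference genome.

The recruited fraction of a (sub)sampled read pool is used as an abundance
proxy for the reference taxon.  The mapper is deliberately permissive: reads
are seeded with exact q-grams (default q = 11), candidate loci are grouped
by alignment diagonal, and each candidate is scored with a banded
semi-global alignment (global in the read, free end-gaps in the genome
window).  A read is recruited when its best alignment identity is strictly
greater than the identity threshold (default 0.50), so even quite diverged
relatives of the reference are counted.

Identity is matches / alignment columns, with gap columns counting as
non-matches and N never matching.  The alignment objective is unit-cost
edit distance, so the reported identity is that of a minimum-edit-distance
alignment within the seeded band.

Detection rules on the report: a taxon is *detected* when recruited reads
are at least 0.1% of the sampled pool and *high-abundance* when they exceed
1%.  Both flags are evaluated with exact integer arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass
class RecruitmentParams:
    """Tunables of the recruitment protocol.

    ``sample_size`` reads are drawn uniformly without replacement from the
    pool before mapping; ``identity_threshold`` is applied strictly
    (identity must exceed it).  ``band_width`` bounds the diagonal drift
    allowed during gapped extension and sizes the genome window around each
    seeded locus.  ``min_seed_count`` q-gram hits must fall on the same
    diagonal band before a candidate is aligned at all.
    """

    rng_seed: int
    sample_size: int = 2_000_000
    qgram_size: int = 11
    identity_threshold: float = 0.50
    band_width: int = 15
    min_read_length: int = 50
    min_seed_count: int = 3
    max_candidates: int = 8
    coverage_window: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.qgram_size < 8:
            raise ValueError("qgram_size must be >= 8")
        if self.sample_size < 0:
            raise ValueError("sample_size must be >= 0")
        if self.band_width < 1 or self.min_seed_count < 1 or self.max_candidates < 1:
            raise ValueError("band_width, min_seed_count, max_candidates must be >= 1")


@dataclass(frozen=True)
class RecruitmentHit:
    """Best placement of one recruited read (1-based inclusive genome coords)."""

    read_id: str
    s_start: int
    s_end: int
    identity: float
    orientation: str


@dataclass
class RecruitmentReport:
    n_sampled: int
    n_recruited: int
    abundance_percent: float
    detected: bool
    high_abundance: bool
    coverage_track: list[tuple[int, int, float]] = field(default_factory=list)
    hits: list[RecruitmentHit] = field(default_factory=list)
    abundance_undefined: bool = False

    @classmethod
    def from_hits(
        cls,
        hits: list[RecruitmentHit],
        n_sampled: int,
        genome_length: int,
        coverage_window: int = 10_000,
    ) -> "RecruitmentReport":
        n_rec = len(hits)
        if n_sampled == 0:
            logger.warning("empty read pool: abundance undefined")
            abundance = 0.0
            detected = high = False
            undefined = True
        else:
            abundance = 100.0 * n_rec / n_sampled
            # integer cross-multiplication keeps the 0.1% / 1% boundaries exact
            detected = 1000 * n_rec >= n_sampled
            high = 100 * n_rec > n_sampled
            undefined = False
        track = _midpoint_coverage(hits, genome_length, coverage_window)
        return cls(
            n_sampled=n_sampled,
            n_recruited=n_rec,
            abundance_percent=abundance,
            detected=detected,
            high_abundance=high,
            coverage_track=track,
            hits=hits,
            abundance_undefined=undefined,
        )


def _midpoint_coverage(
    hits: list[RecruitmentHit], genome_length: int, window: int
) -> list[tuple[int, int, float]]:
    """Bin hit midpoints into fixed windows (ring-plot granularity)."""
    n_windows = max(1, -(-genome_length // window))
    counts = np.zeros(n_windows, dtype=np.int64)
    for h in hits:
        mid = (h.s_start + h.s_end) // 2
        counts[min((mid - 1) // window, n_windows - 1)] += 1
    return [
        (i * window + 1, min((i + 1) * window, genome_length), float(c))
        for i, c in enumerate(counts)
    ]


# ---------------------------------------------------------------------------
# sampling


def sample_reads(
    reads: list[SequenceRecord], params: RecruitmentParams
) -> list[SequenceRecord]:
    """Uniform sample without replacement of min(sample_size, pool) reads.

    Deterministic for a fixed ``rng_seed``; pool order is preserved in the
    returned subset.
    """
    n = len(reads)
    if params.sample_size >= n:
        return list(reads)
    rng = np.random.default_rng(params.rng_seed)
    idx = rng.choice(n, size=params.sample_size, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


# ---------------------------------------------------------------------------
# q-gram index


class QGramIndex:
    """Exact q-gram -> genome positions, forward strand.

    Reads are looked up in both orientations against this single-strand
    index, which is equivalent to indexing both strands.  q-grams containing
    N are skipped.
    """

    def __init__(self, genome: str, q: int):
        if len(genome) < q:
            raise ValueError(f"genome shorter than q-gram size {q}")
        self.q = q
        self.genome = genome.upper()
        self.codes_genome = encode(self.genome)
        codes, valid = _qgram_codes(self.codes_genome, q)
        positions = np.nonzero(valid)[0]
        if positions.size == 0:
            logger.warning("no indexable q-grams (all-N genome?): index is empty")
        keys = codes[positions]
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._positions = positions[order].astype(np.int64)

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For an array of q-gram codes, return (genome_pos0, code_index) pairs."""
        lo = np.searchsorted(self._keys, codes, side="left")
        hi = np.searchsorted(self._keys, codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        out_pos = np.empty(total, dtype=np.int64)
        out_idx = np.empty(total, dtype=np.int64)
        at = 0
        for i in np.nonzero(counts)[0]:
            c = counts[i]
            out_pos[at : at + c] = self._positions[lo[i] : hi[i]]
            out_idx[at : at + c] = i
            at += c
        return out_pos, out_idx

    def positions_of(self, qgram: str) -> list[int]:
        """1-based genome positions of an exact q-gram (for inspection/tests)."""
        codes, valid = _qgram_codes(encode(qgram), self.q)
        if len(qgram) != self.q or not valid[0]:
            raise ValueError("qgram must be an N-free string of length q")
        pos, _ = self.lookup(codes[:1])
        return sorted(int(p) + 1 for p in pos)


def _qgram_codes(codes: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes for every length-q window, plus validity (no N) mask."""
    n = len(codes)
    if n < q:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, q)
    weights = (4 ** np.arange(q - 1, -1, -1)).astype(np.int64)
    vals = windows.astype(np.int64) @ weights
    valid = ~np.any(windows == _N_CODE, axis=1)
    return vals, valid


def build_index(genome: str | SequenceRecord, params: RecruitmentParams) -> QGramIndex:
    seq = genome.sequence if isinstance(genome, SequenceRecord) else genome
    return QGramIndex(seq, params.qgram_size)


# ---------------------------------------------------------------------------
# banded semi-global alignment (the band is realized by the seeded window)


_MATCH = 1
_MISMATCH = -1
_GAP = -4


def _semiglobal_align(read: np.ndarray, window: np.ndarray) -> tuple[int, int, int, int]:
    """Score-optimal alignment of ``read`` inside ``window``.

    Global in the read; leading/trailing window overhang is free and not
    counted as columns.  Linear scoring (+1 match, -1 mismatch, -4 gap):
    the mild mismatch penalty keeps the mapper permissive down to ~50%
    identity, while the stiff gap penalty keeps random-sequence alignments
    near the ungapped 25% identity floor (gap-happy objectives such as edit
    distance push random "identity" above 0.5 and would recruit noise).
    Returns (matches, columns, w_start0, w_end0) where the window slice
    [w_start0, w_end0) is consumed by the alignment.
    """
    m, n = len(read), len(window)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    H[0, :] = 0
    gap_ramp = _GAP * np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        a = read[i - 1]
        mism = (window != a) | (window == _N_CODE) | (a == _N_CODE)
        sub = np.where(mism, _MISMATCH, _MATCH).astype(np.int32)
        tmp = np.empty(n + 1, dtype=np.int32)
        tmp[0] = _GAP * i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + _GAP, out=tmp[1:])
        # resolve the left-to-right gap dependency with a prefix-max
        H[i] = np.maximum.accumulate(tmp - gap_ramp) + gap_ramp
    j = int(np.argmax(H[m]))
    i = m
    matches = 0
    columns = 0
    w_end0 = j
    while i > 0:
        a = read[i - 1]
        if j > 0:
            mism = (window[j - 1] != a) | (window[j - 1] == _N_CODE) | (a == _N_CODE)
            s = _MISMATCH if mism else _MATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                matches += 0 if mism else 1
                i -= 1
                j -= 1
                columns += 1
                continue
        if H[i, j] == H[i - 1, j] + _GAP:
            i -= 1
            columns += 1
            continue
        j -= 1
        columns += 1
    return matches, columns, j, w_end0


def _nonoverlapping_count(offsets: np.ndarray, q: int) -> int:
    """Greedy count of q-gram seeds with non-overlapping read offsets."""
    count = 0
    next_free = -1
    for off in np.sort(offsets):
        if off >= next_free:
            count += 1
            next_free = off + q
    return count


def recruit_read(
    read: SequenceRecord, index: QGramIndex, params: RecruitmentParams
) -> RecruitmentHit | None:
    """Map one read; return its best hit or None.

    Candidate loci are diagonal bands holding at least ``min_seed_count``
    shared q-grams; the ``max_candidates`` best-seeded bands per orientation
    are aligned.  The highest-identity alignment wins, with ties broken by
    leftmost genome position, then forward orientation.  A hit is returned
    only if identity strictly exceeds ``identity_threshold``.
    """
    seq = read.sequence.upper()
    m = len(seq)
    if m < params.min_read_length:
        return None
    genome_codes = index.codes_genome
    L = len(genome_codes)
    best: tuple[float, int, int, int, str] | None = None  # (-id, s_start, s_end, _, orient)
    for orientation, oriented in (("forward", seq), ("reverse", reverse_complement(seq))):
        codes, valid = _qgram_codes(encode(oriented), index.q)
        offsets = np.nonzero(valid)[0]
        if offsets.size == 0:
            continue
        pos, idx_in = index.lookup(codes[offsets])
        if pos.size == 0:
            continue
        read_offs = offsets[idx_in]
        diags = pos - read_offs
        order = np.argsort(diags, kind="stable")
        diags_sorted = diags[order]
        offs_sorted = read_offs[order]
        # group diagonals into bands: a gap > band_width starts a new group
        breaks = np.nonzero(np.diff(diags_sorted) > params.band_width)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [diags_sorted.size]])
        groups = []
        for k in range(starts.size):
            sl = slice(starts[k], ends[k])
            # overlapping q-grams from one longer shared word are not
            # independent evidence: count non-overlapping seeds only
            support = _nonoverlapping_count(offs_sorted[sl], index.q)
            if support >= params.min_seed_count:
                groups.append(
                    (support, int(diags_sorted[sl][0]), int(diags_sorted[sl][-1]))
                )
        groups.sort(key=lambda g: (-g[0], g[1]))
        read_codes = encode(oriented)
        for _count, dlo, dhi in groups[: params.max_candidates]:
            w_start = max(0, dlo - params.band_width)
            w_end = min(L, dhi + m + params.band_width)
            if w_end - w_start < params.min_read_length:
                continue
            matches, columns, j0, j1 = _semiglobal_align(
                read_codes, genome_codes[w_start:w_end]
            )
            if columns == 0:
                continue
            identity = matches / columns
            s_start = w_start + j0 + 1
            s_end = w_start + j1
            cand = (-identity, s_start, s_end, 0 if orientation == "forward" else 1, orientation)
            if best is None or cand < best:
                best = cand
    if best is None or -best[0] <= params.identity_threshold:
        return None
    return RecruitmentHit(
        read_id=read.id,
        s_start=best[1],
        s_end=max(best[1], best[2]),
        identity=-best[0],
        orientation=best[4],
    )


def recruit_all(
    reads: list[SequenceRecord],
    genome: str | SequenceRecord,
    params: RecruitmentParams,
) -> RecruitmentReport:
    """Subsample the pool, map every sampled read, and tally the report."""
    index = build_index(genome, params)
    sampled = sample_reads(reads, params)
    hits = []
    for read in sampled:
        hit = recruit_read(read, index, params)
        if hit is not None:
            hits.append(hit)
    return RecruitmentReport.from_hits(
        hits, len(sampled), len(index.genome), params.coverage_window
    )
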