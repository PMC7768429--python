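"""Genome-level descriptive statistics: GC content, GC skew, feature tallies.

Ambiguous bases (N) are excluded from both the numerator and the
denominator of GC content.  This keeps the reverse-complement invariance of
GC content exact (a denominator of "full length" would not), and makes
``gc_content + at_content == 100`` hold for N-free sequences.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import FeatureRecord

logger = logging.getLogger(__name__)

DEFAULT_SKEW_WINDOW = 10_000
DEFAULT_SKEW_STEP = 10_000


@dataclass
class GenomeSummary:
    length_bp: int
    gc_percent: float
    n_features_by_type: dict[str, int] = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        return sum(self.n_features_by_type.values())


@dataclass
class SkewTrack:
    """Sliding-window (G-C)/(G+C); windows with G+C = 0 are emitted as 0 and
    flagged in ``undefined_windows`` (indices into ``values``)."""

    window: int
    step: int
    values: list[tuple[int, int, float]]
    undefined_windows: list[int] = field(default_factory=list)


def gc_content(sequence: str) -> float:
    """GC percent: 100 * (G+C) / (A+C+G+T); N ignored entirely."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    gc = counts["G"] + counts["C"]
    denom = gc + counts["A"] + counts["T"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / denom


def at_content(sequence: str) -> float:
    """AT percent over unambiguous bases (complement of :func:`gc_content`)."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    at = counts["A"] + counts["T"]
    denom = at + counts["G"] + counts["C"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * at / denom


def gc_skew_track(
    sequence: str,
    window: int = DEFAULT_SKEW_WINDOW,
    step: int = DEFAULT_SKEW_STEP,
) -> SkewTrack:
    """Sliding-window GC skew (G-C)/(G+C), final partial window included.

    A window longer than the sequence degrades to a single whole-sequence
    window (with a warning).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if window > n:
        logger.warning("skew window %d exceeds sequence length %d; using one window", window, n)
        window = n
        step = n
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    values: list[tuple[int, int, float]] = []
    undefined: list[int] = []
    for i, start0 in enumerate(range(0, n, step)):
        end0 = min(start0 + window, n)
        g = int(is_g[end0] - is_g[start0])
        c = int(is_c[end0] - is_c[start0])
        if g + c == 0:
            skew = 0.0
            undefined.append(i)
        else:
            skew = (g - c) / (g + c)
        values.append((start0 + 1, end0, skew))
        if end0 == n:
            break
    return SkewTrack(window=window, step=step, values=values, undefined_windows=undefined)


def feature_summary(features: Iterable[FeatureRecord]) -> dict[str, int]:
    """Count features per type (CDS / tRNA / rRNA / other)."""
    counts: Counter[str] = Counter(f.feature_type for f in features)
    return dict(counts)


def genome_summary(sequence: str, features: Iterable[FeatureRecord] = ()) -> GenomeSummary:
    return GenomeSummary(
        length_bp=len(sequence),
        gc_percent=gc_content(sequence),
        n_features_by_type=feature_summary(features),
    )
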