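"""Coverage-based screening for mutant-specific large deletions.

A control strain and a mutant strain sequenced with the same capture design
should accumulate reads over the same regions; a homozygous deletion in the
mutant leaves a control-only covered segment. The screen calls covered
segments in each track (maximal runs of depth >= min_depth, joining runs
separated by <= max_gap, discarding segments < min_len), subtracts the
mutant's segments from the control's, and ranks the surviving candidate
intervals by the ratio of control to mutant read-equivalent counts
(depth integral / nominal read length, with a pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

from .capture import CoverageTrack
from .intervals import GenomeInterval, GenomeIntervalSet

__all__ = [
    "CoveredSegment",
    "DeletionCall",
    "call_covered_segments",
    "sample_specific_deletions",
    "mutant_only_segments",
    "rank_deletions",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_GAP",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_READ_LENGTH",
]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_LEN = 500
DEFAULT_MAX_GAP = 200
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_READ_LENGTH = 100


@dataclass(frozen=True)
class CoveredSegment:
    """A contiguous well-covered stretch of one sample's coverage track."""

    interval: GenomeInterval
    mean_depth: float
    read_equiv: float


@dataclass(frozen=True)
class DeletionCall:
    """A control-only interval scored by control vs mutant read counts."""

    interval: GenomeInterval
    control_reads: float
    mutant_reads: float
    ratio: float
    rank: Optional[int] = None


def call_covered_segments(
    cov: CoverageTrack,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    read_length: int = DEFAULT_READ_LENGTH,
) -> List[CoveredSegment]:
    """Maximal depth >= min_depth runs, gap-joined, length-filtered."""
    segments: List[CoveredSegment] = []
    for contig in cov.contigs():
        raw = [(s, e) for _, s, e, d in cov.runs(contig) if d >= min_depth]
        joined: List[Tuple[int, int]] = []
        for s, e in raw:
            if joined and s - joined[-1][1] <= max_gap:
                joined[-1] = (joined[-1][0], max(joined[-1][1], e))
            else:
                joined.append((s, e))
        for s, e in joined:
            if e - s < min_len:
                continue
            integral = cov.integral(contig, s, e)
            segments.append(
                CoveredSegment(
                    interval=GenomeInterval(contig, s, e),
                    mean_depth=integral / (e - s),
                    read_equiv=integral / read_length,
                )
            )
    return segments


def _segments_to_set(segments: List[CoveredSegment]) -> GenomeIntervalSet:
    return GenomeIntervalSet(seg.interval for seg in segments)


def sample_specific_deletions(
    control: List[CoveredSegment],
    mutant: List[CoveredSegment],
    control_cov: CoverageTrack,
    mutant_cov: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_len: int = DEFAULT_MIN_LEN,
    read_length: int = DEFAULT_READ_LENGTH,
) -> List[DeletionCall]:
    """Control-only covered intervals, scored as candidate mutant deletions.

    Candidates are the base-level subtraction of mutant segments from
    control segments, kept when >= min_len. Each is scored with
    read-equivalent counts over the interval in both tracks;
    ratio = (control + pseudocount) / (mutant + pseudocount).
    """
    candidates = _segments_to_set(control).subtract(_segments_to_set(mutant))
    calls: List[DeletionCall] = []
    for iv in candidates:
        if len(iv) < min_len:
            continue
        c_reads = control_cov.integral(iv.contig, iv.start, iv.end) / read_length
        m_reads = mutant_cov.integral(iv.contig, iv.start, iv.end) / read_length
        calls.append(
            DeletionCall(
                interval=iv,
                control_reads=c_reads,
                mutant_reads=m_reads,
                ratio=(c_reads + pseudocount) / (m_reads + pseudocount),
            )
        )
    return calls


def mutant_only_segments(
    control: List[CoveredSegment], mutant: List[CoveredSegment]
) -> GenomeIntervalSet:
    """Mutant-only covered intervals (gains relative to control); unranked."""
    return _segments_to_set(mutant).subtract(_segments_to_set(control))


def rank_deletions(
    calls: List[DeletionCall], locus: Optional[GenomeInterval] = None
) -> List[DeletionCall]:
    """Sort calls by descending ratio (ties: control count, then coordinate).

    With a locus, only calls overlapping it are ranked. Ranks are 1-based.
    """
    pool = calls
    if locus is not None:
        pool = [c for c in calls if c.interval.overlaps(locus)]
    ordered = sorted(
        pool,
        key=lambda c: (
            -c.ratio,
            -c.control_reads,
            c.interval.contig,
            c.interval.start,
            c.interval.end,
        ),
    )
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]
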