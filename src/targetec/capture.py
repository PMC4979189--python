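"""Capture-design power and sequencing-performance evaluation.

Two questions about a capture design are answered here. First, design
power: what fraction of the genome would reveal a large deletion of length
L, where a deletion is visible if it removes at least one targeted base?
This is formalised as the fraction of valid placements — start positions p
with [p, p+L) inside a contig — that overlap the target set, computed in
closed form from the interval union of per-target detection windows.
Second, capture performance from sequencing output: 3'-quality trimming of
reads, the on-target read count (>= 1 bp overlap, duplicates excluded), and
per-base depth statistics over the target (mean depth, fraction covered at
each threshold, uncovered fraction).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .errors import (
    EmptyInputError,
    MalformedTrackError,
    NoValidPlacementError,
)
from .intervals import ContigSpace, GenomeInterval, GenomeIntervalSet

__all__ = [
    "DetectabilityPoint",
    "ReadRecord",
    "CoverageTrack",
    "DepthStatistics",
    "ProximityResult",
    "deletion_detectable_fraction",
    "detectability_curve",
    "cns_exon_proximity",
    "trim_read_3prime",
    "on_target_count",
    "depth_statistics",
    "read_fastq",
    "write_fastq",
    "reads_from_alignments",
]


# -- deletion detectability ---------------------------------------------------


@dataclass(frozen=True)
class DetectabilityPoint:
    length: int
    fraction: float


def deletion_detectable_fraction(
    targets: GenomeIntervalSet, space: ContigSpace, length: int
) -> float:
    """Fraction of valid deletion placements of ``length`` that hit a target.

    A placement is a start p with 0 <= p <= contigLen - length; it detects
    the design if [p, p+length) overlaps >= 1 target base. Contigs shorter
    than ``length`` admit no placement and are excluded from the
    denominator. The set of detecting starts for a target [s, e) is
    [s - length + 1, e) clipped to the valid range, so the numerator is the
    length of an interval union.
    """
    if length < 1:
        raise NoValidPlacementError(f"deletion length must be >= 1, got {length}")
    denom = 0
    numer = 0
    for contig, clen in space.items():
        if clen < length:
            continue
        valid = clen - length + 1
        denom += valid
        windows = GenomeIntervalSet(
            (contig, max(0, s - length + 1), min(e, valid))
            for s, e in targets.per_contig(contig)
            if min(e, valid) > max(0, s - length + 1)
        )
        numer += windows.total_length()
    if denom == 0:
        raise NoValidPlacementError(
            f"no contig admits a deletion of length {length}"
        )
    return numer / denom


def detectability_curve(
    targets: GenomeIntervalSet, space: ContigSpace, lengths: Sequence[int]
) -> List[DetectabilityPoint]:
    """Detectable fraction at each deletion length (lengths sorted ascending)."""
    return [
        DetectabilityPoint(L, deletion_detectable_fraction(targets, space, L))
        for L in sorted(lengths)
    ]


def detectability_table(
    designs: Dict[str, GenomeIntervalSet],
    space: ContigSpace,
    lengths: Sequence[int],
):
    """Side-by-side detectability of several designs as a DataFrame."""
    import pandas as pd

    data = {"length": sorted(lengths)}
    for name, targets in designs.items():
        data[name] = [
            p.fraction for p in detectability_curve(targets, space, lengths)
        ]
    return pd.DataFrame(data)


# -- CNS proximity to exons ---------------------------------------------------


@dataclass(frozen=True)
class ProximityResult:
    fraction: float
    within: int
    total: int


def cns_exon_proximity(
    cns: GenomeIntervalSet, exons: GenomeIntervalSet, threshold: int = 250
) -> ProximityResult:
    """Fraction of CNS *regions* whose gap to the nearest exon is <= threshold.

    Gap distance is 0 for overlapping or abutting regions; regions on
    contigs with no exon are never within reach.
    """
    total = len(cns)
    if total == 0:
        raise EmptyInputError("proximity fraction undefined for an empty CNS set")
    within = 0
    for contig in cns.contigs():
        ex = exons.per_contig(contig)
        starts = [s for s, _ in ex]
        for s, e in cns.per_contig(contig):
            if not ex:
                continue
            i = bisect_right(starts, s)
            gap = None
            # nearest exon starting at or after the CNS start
            if i < len(ex):
                gap = max(0, ex[i][0] - e)
            # nearest exon before it
            if i > 0:
                left_gap = max(0, s - ex[i - 1][1])
                if ex[i - 1][1] > s:  # overlap
                    left_gap = 0
                gap = left_gap if gap is None else min(gap, left_gap)
            if gap is not None and gap <= threshold:
                within += 1
    return ProximityResult(fraction=within / total, within=within, total=total)


# -- reads: trimming and on-target counting -----------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read, optionally with its alignment."""

    read_id: str
    bases: str
    qualities: Tuple[int, ...]
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    is_mapped: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise MalformedTrackError(
                f"{self.read_id}: {len(self.bases)} bases vs "
                f"{len(self.qualities)} qualities"
            )
        if self.is_mapped and (
            self.start is None or self.end is None or self.end <= self.start
        ):
            raise MalformedTrackError(f"{self.read_id}: invalid alignment span")

    def __len__(self) -> int:
        return len(self.bases)


def trim_read_3prime(
    read: ReadRecord, min_q: int = 30, min_len: int = 30
) -> Optional[ReadRecord]:
    """Strip low-quality 3' tail; drop (return None) if the read gets short.

    Trailing bases with quality < ``min_q`` are removed until the terminal
    base has quality >= ``min_q`` (no sliding window). A read shorter than
    ``min_len`` after trimming — or an empty read — is dropped.
    """
    n = len(read)
    while n > 0 and read.qualities[n - 1] < min_q:
        n -= 1
    if n < min_len:
        return None
    if n == len(read):
        return read
    return replace(read, bases=read.bases[:n], qualities=read.qualities[:n])


def on_target_count(
    reads: Iterable[ReadRecord], targets: GenomeIntervalSet
) -> int:
    """Aligned, non-duplicate reads overlapping a target by >= 1 bp."""
    count = 0
    for r in reads:
        if not r.is_mapped or r.is_duplicate:
            continue
        if targets.overlaps(r.contig, r.start, r.end):
            count += 1
    return count


# -- coverage -----------------------------------------------------------------


class CoverageTrack:
    """Per-base read depth as sorted disjoint runs; absent positions are 0."""

    def __init__(self, runs: Iterable[Tuple[str, int, int, int]] = ()):
        raw: Dict[str, List[Tuple[int, int, int]]] = {}
        for contig, s, e, depth in runs:
            if s < 0 or e <= s or depth < 0:
                raise MalformedTrackError(
                    f"malformed coverage run {contig}:{s}-{e} depth {depth}"
                )
            if depth > 0:
                raw.setdefault(str(contig), []).append((int(s), int(e), int(depth)))
        self._runs: Dict[str, List[Tuple[int, int, int]]] = {}
        for contig in sorted(raw):
            rs = sorted(raw[contig])
            for prev, cur in zip(rs, rs[1:]):
                if cur[0] < prev[1]:
                    raise MalformedTrackError(
                        f"overlapping coverage runs on {contig}"
                    )
            self._runs[contig] = rs

    @classmethod
    def from_array(cls, contig: str, depths) -> "CoverageTrack":
        """Run-length encode a per-base depth array starting at position 0."""
        import numpy as np

        arr = np.asarray(depths, dtype=np.int64)
        if arr.size == 0:
            return cls()
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        return cls(
            (contig, int(s), int(e), int(arr[s]))
            for s, e in zip(starts, ends)
            if arr[s] > 0
        )

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        runs: List[Tuple[str, int, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                runs.append((f[0], int(f[1]), int(f[2]), int(float(f[3]))))
        return cls(runs)

    @classmethod
    def from_alignments(cls, path) -> "CoverageTrack":
        """Pile up aligned, non-duplicate reads from SAM/BAM into depth runs."""
        import numpy as np
        import pysam

        depths: Dict[str, "np.ndarray"] = {}
        with pysam.AlignmentFile(str(path), require_index=False) as af:
            lengths = dict(zip(af.references, af.lengths))
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_duplicate:
                    continue
                contig = read.reference_name
                if contig not in depths:
                    depths[contig] = np.zeros(lengths[contig], dtype=np.int64)
                for bs, be in read.get_blocks():
                    depths[contig][bs:be] += 1
        runs: List[Tuple[str, int, int, int]] = []
        for contig, arr in depths.items():
            for c, s, e, d in cls.from_array(contig, arr).runs():
                runs.append((c, s, e, d))
        return cls(runs)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e, d in self.runs():
                fh.write(f"{c}\t{s}\t{e}\t{d}\n")

    def runs(self, contig: Optional[str] = None) -> Iterator[Tuple[str, int, int, int]]:
        contigs = [contig] if contig is not None else list(self._runs)
        for c in contigs:
            for s, e, d in self._runs.get(c, []):
                yield (c, s, e, d)

    def contigs(self) -> List[str]:
        return list(self._runs)

    def __eq__(self, other) -> bool:
        return isinstance(other, CoverageTrack) and self._runs == other._runs

    def depth_at(self, contig: str, pos: int) -> int:
        rs = self._runs.get(contig)
        if not rs:
            return 0
        i = bisect_right(rs, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and rs[i][0] <= pos < rs[i][1]:
            return rs[i][2]
        return 0

    def integral(self, contig: str, start: int, end: int) -> int:
        """Sum of depth over [start, end) (depth-bp)."""
        total = 0
        for s, e, d in self._runs.get(contig, []):
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                total += d * (hi - lo)
            if s >= end:
                break
        return total

    def thresholded(self, min_depth: int) -> GenomeIntervalSet:
        """Positions with depth >= min_depth, as a canonical interval set."""
        return GenomeIntervalSet(
            (c, s, e) for c, s, e, d in self.runs() if d >= min_depth
        )


@dataclass(frozen=True)
class DepthStatistics:
    mean_depth: float
    fraction_at_least: Dict[int, float]
    uncovered_fraction: float


def depth_statistics(
    cov: CoverageTrack,
    targets: GenomeIntervalSet,
    thresholds: Sequence[int] = (10, 20, 50),
) -> DepthStatistics:
    """Per-base depth statistics over target bases only."""
    target_bp = targets.total_length()
    if target_bp == 0:
        raise EmptyInputError("depth statistics undefined for an empty target set")
    depth_bp = 0
    at_least = {d: 0 for d in thresholds}
    covered_bp = 0
    for contig in targets.contigs():
        tivs = targets.per_contig(contig)
        rs = list(cov.runs(contig))
        i = j = 0
        while i < len(tivs) and j < len(rs):
            ts, te = tivs[i]
            _, s, e, d = rs[j]
            lo, hi = max(ts, s), min(te, e)
            if lo < hi:
                ov = hi - lo
                depth_bp += d * ov
                covered_bp += ov
                for t in thresholds:
                    if d >= t:
                        at_least[t] += ov
            if te < e:
                i += 1
            else:
                j += 1
    return DepthStatistics(
        mean_depth=depth_bp / target_bp,
        fraction_at_least={t: n / target_bp for t, n in at_least.items()},
        uncovered_fraction=(target_bp - covered_bp) / target_bp,
    )


# -- FASTQ / SAM I/O ----------------------------------------------------------


def read_fastq(path) -> List[ReadRecord]:
    import pysam

    reads: List[ReadRecord] = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            reads.append(
                ReadRecord(
                    read_id=entry.name,
                    bases=entry.sequence,
                    qualities=tuple(entry.get_quality_array()),
                )
            )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{quals}\n")


def reads_from_alignments(path) -> List[ReadRecord]:
    """Load SAM/BAM records (mapped and unmapped) as ReadRecords."""
    import pysam

    reads: List[ReadRecord] = []
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            seq = read.query_sequence or ""
            quals = tuple(read.query_qualities) if read.query_qualities is not None else tuple([0] * len(seq))
            mapped = not read.is_unmapped
            reads.append(
                ReadRecord(
                    read_id=read.query_name,
                    bases=seq,
                    qualities=quals,
                    contig=read.reference_name if mapped else None,
                    start=read.reference_start if mapped else None,
                    end=read.reference_end if mapped else None,
                    is_mapped=mapped,
                    is_duplicate=read.is_duplicate,
                )
            )
    return reads
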