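"""Genomic interval algebra and text-format I/O.

All coordinates are 0-based half-open (BED convention). Interval sets are
kept canonical at all times: per contig, sorted by start, pairwise disjoint,
with abutting intervals joined — the same normal form ``bedtools merge``
produces with its default gap of 0. Every other module builds on the three
set operations here (union via re-merge, subtraction, intersection), the
minimum-length expansion used in capture design, and the conservation-score
track from which highly conserved elements are extracted.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple, Union

from .errors import (
    MalformedIntervalError,
    MalformedTrackError,
    UnknownContigError,
)

__all__ = [
    "GenomeInterval",
    "ContigSpace",
    "GenomeIntervalSet",
    "ConservationTrack",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise MalformedIntervalError(
                f"malformed interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class ContigSpace:
    """Ordered map of contig name to length in bp; the genome being analysed."""

    def __init__(self, entries: Union[Mapping[str, int], Iterable[Tuple[str, int]]]):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._lengths: Dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise MalformedIntervalError(f"duplicate contig name {name!r}")
            if int(length) < 1:
                raise MalformedIntervalError(
                    f"contig {name!r} has non-positive length {length}"
                )
            self._lengths[str(name)] = int(length)

    @classmethod
    def from_chrom_sizes(cls, path) -> "ContigSpace":
        return cls(read_chrom_sizes(path))

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise UnknownContigError(f"unknown contig {name!r}") from None

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def items(self) -> Iterator[Tuple[str, int]]:
        return iter(self._lengths.items())

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")

    def __eq__(self, other) -> bool:
        return isinstance(other, ContigSpace) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"ContigSpace({self._lengths!r})"


IntervalLike = Union[GenomeInterval, Tuple[str, int, int]]


def _canonicalize(raw: Dict[str, List[Tuple[int, int]]]) -> Dict[str, List[Tuple[int, int]]]:
    """Sort and merge (joining abutting intervals) per contig."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for contig in sorted(raw):
        ivs = sorted(raw[contig])
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                if e > merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        if merged:
            out[contig] = merged
    return out


class GenomeIntervalSet:
    """A canonical (sorted, disjoint, non-adjacent) set of genomic intervals.

    The constructor accepts intervals in any order, overlapping or abutting,
    and merges them — so construction *is* the ``merge`` operation. All
    operations return new canonical sets.
    """

    def __init__(self, intervals: Iterable[IntervalLike] = ()):
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            if isinstance(iv, GenomeInterval):
                contig, s, e = iv.contig, iv.start, iv.end
            else:
                contig, s, e = iv
            if s < 0 or e <= s:
                raise MalformedIntervalError(
                    f"malformed interval {contig}:{s}-{e} (need 0 <= start < end)"
                )
            raw.setdefault(str(contig), []).append((int(s), int(e)))
        self._ivs = _canonicalize(raw)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_canonical(cls, ivs: Dict[str, List[Tuple[int, int]]]) -> "GenomeIntervalSet":
        obj = cls.__new__(cls)
        obj._ivs = {c: v for c, v in sorted(ivs.items()) if v}
        return obj

    @classmethod
    def from_bed(cls, path) -> "GenomeIntervalSet":
        """Read BED3+ (extra columns ignored; track/browser/# lines skipped)."""
        ivs: List[Tuple[str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if (
                    not line.strip()
                    or line.startswith(("track", "browser", "#"))
                ):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                ivs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")

    # -- basic protocol -------------------------------------------------------

    def __iter__(self) -> Iterator[GenomeInterval]:
        for contig, ivs in self._ivs.items():
            for s, e in ivs:
                yield GenomeInterval(contig, s, e)

    def __len__(self) -> int:
        """Number of regions."""
        return sum(len(v) for v in self._ivs.values())

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:
        n = len(self)
        return f"<GenomeIntervalSet: {n} regions, {self.total_length()} bp>"

    def contigs(self) -> List[str]:
        return list(self._ivs)

    def per_contig(self, contig: str) -> List[Tuple[int, int]]:
        return list(self._ivs.get(contig, []))

    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    # -- membership -----------------------------------------------------------

    def contains(self, contig: str, pos: int) -> bool:
        ivs = self._ivs.get(contig)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """True if [start, end) shares >= 1 bp with the set."""
        ivs = self._ivs.get(contig)
        if not ivs:
            return False
        i = bisect_right(ivs, (start, float("inf"))) - 1
        if i >= 0 and ivs[i][1] > start:
            return True
        return i + 1 < len(ivs) and ivs[i + 1][0] < end

    # -- set algebra ----------------------------------------------------------

    def union(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for src in (self._ivs, other._ivs):
            for contig, ivs in src.items():
                raw.setdefault(contig, []).extend(ivs)
        return GenomeIntervalSet._from_canonical(_canonicalize(raw))

    __or__ = union

    def subtract(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        """Base-level set difference self \\ other."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for contig, ivs in self._ivs.items():
            cuts = other._ivs.get(contig, [])
            kept: List[Tuple[int, int]] = []
            j = 0
            for s, e in ivs:
                cur = s
                while j < len(cuts) and cuts[j][1] <= cur:
                    j += 1
                k = j
                while k < len(cuts) and cuts[k][0] < e:
                    cs, ce = cuts[k]
                    if cs > cur:
                        kept.append((cur, cs))
                    cur = max(cur, ce)
                    if ce >= e:
                        break
                    k += 1
                if cur < e:
                    kept.append((cur, e))
            if kept:
                out[contig] = kept
        return GenomeIntervalSet._from_canonical(out)

    __sub__ = subtract

    def intersect(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        out: Dict[str, List[Tuple[int, int]]] = {}
        for contig, a in self._ivs.items():
            b = other._ivs.get(contig)
            if not b:
                continue
            res: List[Tuple[int, int]] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    res.append((s, e))
                if a[i][1] < b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[contig] = res
        return GenomeIntervalSet._from_canonical(out)

    __and__ = intersect

    # -- capture-design expansion ---------------------------------------------

    def expand_to_min_length(self, min_len: int, space: ContigSpace) -> "GenomeIntervalSet":
        """Grow every region shorter than ``min_len`` symmetrically.

        Ties (odd deficits) give the extra base to the right (floor-left /
        ceil-right). Extension clipped at contig bounds pushes its deficit to
        the other side when room allows, so the target length is reached
        whenever the contig permits. The result is re-merged: expansion can
        make neighbours overlap.
        """
        if min_len < 1:
            raise MalformedIntervalError(f"min_len must be >= 1, got {min_len}")
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for contig, ivs in self._ivs.items():
            clen = space[contig]
            target = min(min_len, clen)
            grown: List[Tuple[int, int]] = []
            for s, e in ivs:
                if e - s < target:
                    deficit = target - (e - s)
                    left = deficit // 2
                    s -= left
                    e += deficit - left
                    if s < 0:
                        e += -s
                        s = 0
                    if e > clen:
                        s -= e - clen
                        e = clen
                        s = max(s, 0)
                grown.append((s, e))
            raw[contig] = grown
        return GenomeIntervalSet._from_canonical(_canonicalize(raw))


class ConservationTrack:
    """Run-length conservation scores (phastCons-style, in [0, 1]).

    Positions not covered by any run carry no score. Runs with identical
    scores may abut; runs never overlap.
    """

    def __init__(self, runs: Iterable[Tuple[str, int, int, float]] = ()):
        raw: Dict[str, List[Tuple[int, int, float]]] = {}
        for contig, s, e, score in runs:
            if s < 0 or e <= s:
                raise MalformedTrackError(
                    f"malformed run {contig}:{s}-{e}"
                )
            if not (0.0 <= score <= 1.0):
                raise MalformedTrackError(
                    f"score {score} at {contig}:{s}-{e} outside [0, 1]"
                )
            raw.setdefault(str(contig), []).append((int(s), int(e), float(score)))
        self._runs: Dict[str, List[Tuple[int, int, float]]] = {}
        for contig in sorted(raw):
            rs = sorted(raw[contig])
            for prev, cur in zip(rs, rs[1:]):
                if cur[0] < prev[1]:
                    raise MalformedTrackError(
                        f"overlapping runs on {contig}: "
                        f"[{prev[0]},{prev[1]}) and [{cur[0]},{cur[1]})"
                    )
            self._runs[contig] = rs

    def runs(self, contig: Optional[str] = None) -> Iterator[Tuple[str, int, int, float]]:
        contigs = [contig] if contig is not None else list(self._runs)
        for c in contigs:
            for s, e, score in self._runs.get(c, []):
                yield (c, s, e, score)

    def contigs(self) -> List[str]:
        return list(self._runs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._runs.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, ConservationTrack) and self._runs == other._runs

    def covered(self) -> GenomeIntervalSet:
        """All positions carrying any score, as a canonical set."""
        return GenomeIntervalSet(
            (c, s, e) for c, s, e, _ in self.runs()
        )

    def score_at(self, contig: str, pos: int) -> Optional[float]:
        rs = self._runs.get(contig)
        if not rs:
            return None
        i = bisect_right(rs, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and rs[i][0] <= pos < rs[i][1]:
            return rs[i][2]
        return None

    def extract_conserved(self, threshold: float) -> GenomeIntervalSet:
        """Canonical set of all runs with score >= threshold."""
        if not (0.0 <= threshold <= 1.0):
            raise MalformedTrackError(
                f"threshold {threshold} outside [0, 1]"
            )
        return GenomeIntervalSet(
            (c, s, e) for c, s, e, score in self.runs() if score >= threshold
        )

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        runs: List[Tuple[str, int, int, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                runs.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        return cls(runs)

    @classmethod
    def from_wiggle(cls, path) -> "ConservationTrack":
        """Parse fixedStep wiggle (any step/span) into score runs.

        Per-base values are run-length compressed; equal-valued adjacent
        stretches collapse into one run.
        """
        runs: List[Tuple[str, int, int, float]] = []
        chrom = None
        pos = step = span = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(
                        part.split("=", 1) for part in line.split()[1:]
                    )
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    continue
                if line.startswith("variableStep"):
                    raise MalformedTrackError(
                        "variableStep wiggle is not supported; use bedGraph"
                    )
                if chrom is None:
                    raise MalformedTrackError(
                        f"wiggle data line before any fixedStep header: {line!r}"
                    )
                value = float(line)
                runs.append((chrom, pos, pos + span, value))
                pos += step
        # compress equal-adjacent runs
        merged: List[Tuple[str, int, int, float]] = []
        for run in sorted(runs):
            if (
                merged
                and merged[-1][0] == run[0]
                and merged[-1][2] == run[1]
                and merged[-1][3] == run[3]
            ):
                merged[-1] = (run[0], merged[-1][1], run[2], run[3])
            else:
                merged.append(run)
        return cls(merged)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e, score in self.runs():
                fh.write(f"{c}\t{s}\t{e}\t{score!r}\n")

    def write_wiggle(self, path) -> None:
        """Write one fixedStep block per run (step = span = run length)."""
        with open(path, "w") as fh:
            for c, s, e, score in self.runs():
                length = e - s
                fh.write(
                    f"fixedStep chrom={c} start={s + 1} step={length} span={length}\n"
                )
                fh.write(f"{score!r}\n")


def read_chrom_sizes(path) -> List[Tuple[str, int]]:
    """Read a two-column chrom.sizes file (name, length)."""
    out: List[Tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            out.append((f[0], int(f[1])))
    return out
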