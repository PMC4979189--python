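"""Independent brute-force oracles used to check the interval algebra.

Everything here works per base on small contigs, deliberately ignoring the
sweep-line implementations under test.
"""

from typing import Dict, Iterable, List, Set, Tuple

from targetec.intervals import GenomeIntervalSet


def base_set(intervals: Iterable[Tuple[str, int, int]]) -> Set[Tuple[str, int]]:
    """Expand raw (contig, start, end) triples to their member bases."""
    out: Set[Tuple[str, int]] = set()
    for contig, s, e in intervals:
        for pos in range(s, e):
            out.add((contig, pos))
    return out


def set_bases(ivset: GenomeIntervalSet) -> Set[Tuple[str, int]]:
    return base_set((iv.contig, iv.start, iv.end) for iv in ivset)


def from_base_set(bases: Set[Tuple[str, int]]) -> GenomeIntervalSet:
    """Rebuild a canonical interval set from individual bases."""
    return GenomeIntervalSet((c, p, p + 1) for c, p in bases)


def brute_detectable_fraction(
    targets: GenomeIntervalSet, contigs: Dict[str, int], length: int
) -> float:
    """Enumerate every deletion placement and test overlap base by base."""
    target_bases = set_bases(targets)
    numer = denom = 0
    for contig, clen in contigs.items():
        if clen < length:
            continue
        has_target = [(contig, p) in target_bases for p in range(clen)]
        # prefix sums make the window test O(1) without touching the
        # implementation under test
        prefix = [0]
        for b in has_target:
            prefix.append(prefix[-1] + int(b))
        for p in range(clen - length + 1):
            denom += 1
            if prefix[p + length] - prefix[p] > 0:
                numer += 1
    return numer / denom
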