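"""Capture target design from gene annotation plus conserved elements.

A capture design that covers both exons and highly conserved non-coding
sequence (CNS) is built in three steps: union all annotated exons across
annotation sources, union in all highly conserved elements (score 1.0 in a
phastCons-style track), then expand every region to a minimum probe-friendly
length (default 100 bp) and re-merge. The resulting target set is afterwards
partitioned into the classes CDS, UTR, CNS and OTHER for reporting: a base
coding in any transcript is CDS; UTR is exonic-with-CDS-transcript minus
CDS; conserved non-exonic bases are CNS; expansion flanks and unannotated
bases are OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import (
    InternalConsistencyError,
    MalformedIntervalError,
    OutOfBoundsError,
)
from .intervals import ContigSpace, GenomeInterval, GenomeIntervalSet

__all__ = [
    "GeneModel",
    "RegionClassMap",
    "DesignSummary",
    "read_genepred",
    "read_bed12",
    "write_genepred",
    "exon_union",
    "cds_utr_sets",
    "build_target_regions",
    "classify_regions",
    "design_summary",
    "CLASS_LABELS",
]

CLASS_LABELS = ("CDS", "UTR", "CNS", "OTHER")


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon blocks plus an optional CDS span.

    ``cds`` is the half-open (cdsStart, cdsEnd) span in genomic coordinates;
    ``None`` marks a non-coding transcript. Exons must be sorted and
    disjoint.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds: Optional[Tuple[int, int]] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedIntervalError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise MalformedIntervalError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise MalformedIntervalError(
                    f"{self.transcript_id}: malformed exon [{s},{e})"
                )
            if s < prev_end:
                raise MalformedIntervalError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if ce <= cs:
                raise MalformedIntervalError(
                    f"{self.transcript_id}: malformed CDS span [{cs},{ce})"
                )
            if cs < self.exons[0][0] or ce > self.exons[-1][1]:
                raise MalformedIntervalError(
                    f"{self.transcript_id}: CDS span outside transcript extent"
                )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]


# -- genePred / BED12 I/O -----------------------------------------------------


def read_genepred(path, source: str = "") -> List[GeneModel]:
    """Read refFlat-style genePred: geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (comma lists,
    trailing comma tolerated). cdsStart == cdsEnd marks a non-coding
    transcript.
    """
    models: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            gene, name, chrom, strand = f[0], f[1], f[2], f[3]
            cds_start, cds_end = int(f[6]), int(f[7])
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = tuple(zip(starts, ends))
            cds = None if cds_start == cds_end else (cds_start, cds_end)
            models.append(
                GeneModel(gene, name, chrom, strand, exons, cds, source=source)
            )
    return models


def write_genepred(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            cs, ce = m.cds if m.cds is not None else (m.tx_end, m.tx_end)
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_id,
                        m.transcript_id,
                        m.contig,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(cs),
                        str(ce),
                        str(len(m.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def read_bed12(path, source: str = "") -> List[GeneModel]:
    """Read BED12 gene models (thickStart/thickEnd as the CDS span)."""
    models: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            )
            cds = None if thick_start == thick_end else (thick_start, thick_end)
            models.append(
                GeneModel(name, name, chrom, strand, exons, cds, source=source)
            )
    return models


# -- design operations --------------------------------------------------------


def exon_union(
    models: Iterable[GeneModel], space: Optional[ContigSpace] = None
) -> GenomeIntervalSet:
    """Canonical union of every exon across all transcripts and sources."""
    ivs: List[Tuple[str, int, int]] = []
    for m in models:
        for s, e in m.exons:
            if space is not None and e > space[m.contig]:
                raise OutOfBoundsError(
                    f"{m.transcript_id}: exon [{s},{e}) beyond "
                    f"{m.contig} length {space[m.contig]}"
                )
            ivs.append((m.contig, s, e))
    return GenomeIntervalSet(ivs)


def cds_utr_sets(
    models: Iterable[GeneModel],
) -> Tuple[GenomeIntervalSet, GenomeIntervalSet]:
    """Decompose coding transcripts into CDS and UTR base sets.

    CDS = union over transcripts of (exons ∩ CDS span). UTR = union of
    (exons \\ CDS span) over coding transcripts, minus CDS — a base coding
    in any isoform counts as CDS. Non-coding transcripts contribute to
    neither set.
    """
    cds_ivs: List[Tuple[str, int, int]] = []
    utr_ivs: List[Tuple[str, int, int]] = []
    for m in models:
        if m.cds is None:
            continue
        cs, ce = m.cds
        for s, e in m.exons:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                cds_ivs.append((m.contig, lo, hi))
            if s < cs:
                utr_ivs.append((m.contig, s, min(e, cs)))
            if e > ce:
                utr_ivs.append((m.contig, max(s, ce), e))
    cds = GenomeIntervalSet(cds_ivs)
    utr = GenomeIntervalSet(utr_ivs).subtract(cds)
    return cds, utr


def build_target_regions(
    exons: GenomeIntervalSet,
    conserved: GenomeIntervalSet,
    min_len: int = 100,
    space: Optional[ContigSpace] = None,
) -> GenomeIntervalSet:
    """Union exons with conserved elements, expand to ``min_len``, re-merge."""
    if space is None:
        raise MalformedIntervalError("a ContigSpace is required for expansion")
    merged = exons.union(conserved)
    return merged.expand_to_min_length(min_len, space)


@dataclass
class RegionClassMap:
    """Disjoint partition of a target set into CDS / UTR / CNS / OTHER."""

    targets: GenomeIntervalSet
    cds: GenomeIntervalSet
    utr: GenomeIntervalSet
    cns: GenomeIntervalSet
    other: GenomeIntervalSet

    def __post_init__(self) -> None:
        union = self.cds.union(self.utr).union(self.cns).union(self.other)
        if union != self.targets:
            raise InternalConsistencyError(
                "class sets do not exactly cover the target set"
            )
        total = self.targets.total_length()
        parts = sum(s.total_length() for s in self.class_sets().values())
        if parts != total:
            raise InternalConsistencyError(
                f"class sets overlap: {parts} classified bp vs {total} target bp"
            )

    def class_sets(self) -> Dict[str, GenomeIntervalSet]:
        return {
            "CDS": self.cds,
            "UTR": self.utr,
            "CNS": self.cns,
            "OTHER": self.other,
        }

    def class_of(self, contig: str, pos: int) -> Optional[str]:
        """Class label of a target base, or None if off-target."""
        for label, s in self.class_sets().items():
            if s.contains(contig, pos):
                return label
        return None


def classify_regions(
    targets: GenomeIntervalSet,
    cds: GenomeIntervalSet,
    utr: GenomeIntervalSet,
    conserved: GenomeIntervalSet,
) -> RegionClassMap:
    """Priority partition of target bases: CDS, then UTR, then CNS, then OTHER."""
    cds_c = targets.intersect(cds)
    utr_c = targets.intersect(utr).subtract(cds_c)
    exonic = cds_c.union(utr_c)
    cns_c = targets.intersect(conserved).subtract(exonic)
    other = targets.subtract(exonic.union(cns_c))
    return RegionClassMap(targets=targets, cds=cds_c, utr=utr_c, cns=cns_c, other=other)


@dataclass
class DesignSummary:
    """Region count, total bp, and per-class / per-source bp of a design."""

    region_count: int
    total_bp: int
    class_bp: Dict[str, int]
    source_bp: Dict[str, int] = field(default_factory=dict)


def design_summary(
    targets: GenomeIntervalSet,
    classes: RegionClassMap,
    source_sets: Optional[Dict[str, GenomeIntervalSet]] = None,
) -> DesignSummary:
    """Summarise a design; per-class bp must sum exactly to the total."""
    class_bp = {
        label: s.total_length() for label, s in classes.class_sets().items()
    }
    total = targets.total_length()
    if sum(class_bp.values()) != total:
        raise InternalConsistencyError(
            "per-class bp does not sum to target bp"
        )
    source_bp = {}
    if source_sets:
        source_bp = {
            name: targets.intersect(s).total_length()
            for name, s in source_sets.items()
        }
    return DesignSummary(
        region_count=len(targets),
        total_bp=total,
        class_bp=class_bp,
        source_bp=source_bp,
    )
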