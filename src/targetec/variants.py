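"""Variant ingestion, filtering, triage, and summary statistics.

The candidate-mutation triage mirrors a forward-genetics workflow on inbred
strains: keep calls with supporting depth (default >= 10), drop known
variants (position-based by default, matching coordinate subtraction with
BED tools; allele-aware on request), then restrict to the linkage interval
the phenotype maps to. Summary statistics cover per-region-class SNV/INDEL
counts with transition/transversion ratios, shared-variant overlap between
strains, and SNV density as a function of conservation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .design import CLASS_LABELS, RegionClassMap
from .errors import VcfParseError
from .intervals import ConservationTrack, GenomeInterval, GenomeIntervalSet

__all__ = [
    "Variant",
    "FilterResult",
    "VariantClassTable",
    "DensityBin",
    "SharedCounts",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "subtract_known",
    "restrict_to_locus",
    "titv_ratio",
    "titv_counts",
    "class_table",
    "shared_variant_counts",
    "snv_density_by_score",
    "TRANSITIONS",
]

#: Transition substitutions (purine<->purine, pyrimidine<->pyrimidine).
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

GENOTYPE_CLASSES = ("hom-ref", "het", "hom-alt", "unknown")


@dataclass(frozen=True)
class Variant:
    """One called variant; position is 0-based (converted from VCF on ingest)."""

    contig: str
    pos: int
    ref: str
    alt: str
    depth: Optional[int] = None
    genotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VcfParseError(
                f"{self.contig}:{self.pos}: ref equals alt ({self.ref})"
            )
        if self.genotype not in GENOTYPE_CLASSES:
            raise VcfParseError(f"unknown genotype class {self.genotype!r}")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "INS"
        if len(self.ref) > len(self.alt):
            return "DEL"
        return "MNV"

    @property
    def is_snv(self) -> bool:
        return self.kind == "SNV"

    @property
    def is_indel(self) -> bool:
        return self.kind in ("INS", "DEL")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def _genotype_class(gt: Optional[Tuple], alt_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return "unknown"
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return "hom-ref"
    if all(a == alt_index for a in alleles):
        return "hom-alt"
    return "het"


def read_vcf(path) -> List[Variant]:
    """Read a VCF 4.x file; multi-allelic records split per alt allele.

    Positions become 0-based. Depth comes from the first sample's DP when
    present, else INFO/DP. Genotype class is judged per split alt allele.
    """
    import pysam

    variants: List[Variant] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            depth = None
            gt = None
            if rec.samples:
                sample = rec.samples[0]
                if "DP" in sample and sample["DP"] is not None:
                    depth = int(sample["DP"])
                gt = sample.get("GT")
            if depth is None and "DP" in rec.info:
                info_dp = rec.info["DP"]
                depth = int(info_dp[0] if isinstance(info_dp, tuple) else info_dp)
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                variants.append(
                    Variant(
                        contig=rec.contig,
                        pos=rec.start,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        genotype=_genotype_class(gt, alt_index),
                    )
                )
    return variants


_GT_CODE = {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1", "unknown": "./."}


def write_vcf(variants: Iterable[Variant], path, contig_lengths=None, sample: str = "S1") -> None:
    """Write a minimal single-sample VCF 4.2 (GT:DP per sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths is not None:
            for name, length in contig_lengths:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in sorted(variants, key=lambda v: v.key):
            dp = "." if v.depth is None else str(v.depth)
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"GT:DP\t{_GT_CODE[v.genotype]}:{dp}\n"
            )


# -- triage funnel ------------------------------------------------------------


@dataclass
class FilterResult:
    """Variants passing a filter plus a tally of depth-less records skipped."""

    kept: List[Variant]
    skipped_missing_depth: int = 0

    def __iter__(self):
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)


def filter_variants(
    variants: Iterable[Variant],
    min_depth: int = 10,
    targets: Optional[GenomeIntervalSet] = None,
    hom_only: bool = False,
) -> FilterResult:
    """Depth / on-target / homozygosity filter.

    Variants without a recorded depth are excluded (and tallied) whenever
    ``min_depth`` > 0.
    """
    kept: List[Variant] = []
    skipped = 0
    for v in variants:
        if min_depth > 0:
            if v.depth is None:
                skipped += 1
                continue
            if v.depth < min_depth:
                continue
        if targets is not None and not targets.contains(v.contig, v.pos):
            continue
        if hom_only and v.genotype != "hom-alt":
            continue
        kept.append(v)
    return FilterResult(kept=kept, skipped_missing_depth=skipped)


def subtract_known(
    variants: Iterable[Variant],
    known: Union[GenomeIntervalSet, Iterable[Variant]],
    allele_aware: bool = False,
) -> List[Variant]:
    """Remove known variants.

    Position mode (default): a variant is dropped when its position falls in
    the known set — the behaviour of coordinate subtraction between a call
    set and a known-sites BED. Allele-aware mode drops only exact
    (contig, pos, ref, alt) matches and requires ``known`` to be variants.
    """
    if allele_aware:
        if isinstance(known, GenomeIntervalSet):
            raise VcfParseError(
                "allele-aware subtraction needs known variants, not intervals"
            )
        known_keys = {v.key for v in known}
        return [v for v in variants if v.key not in known_keys]
    if isinstance(known, GenomeIntervalSet):
        known_set = known
    else:
        known_set = GenomeIntervalSet(
            (v.contig, v.pos, v.pos + 1) for v in known
        )
    return [v for v in variants if not known_set.contains(v.contig, v.pos)]


def restrict_to_locus(
    variants: Iterable[Variant], locus: GenomeInterval
) -> List[Variant]:
    """Keep variants whose (half-open) position lies inside the linkage locus."""
    return [
        v
        for v in variants
        if v.contig == locus.contig and locus.start <= v.pos < locus.end
    ]


# -- Ti/Tv --------------------------------------------------------------------


def titv_counts(variants: Iterable[Variant]) -> Tuple[int, int]:
    """(transitions, transversions) over the SNVs in the input."""
    ti = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if (v.ref.upper(), v.alt.upper()) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    return ti, tv


def titv_ratio(variants: Iterable[Variant]) -> Optional[float]:
    """Transition/transversion ratio; None when no transversion is present."""
    ti, tv = titv_counts(variants)
    if tv == 0:
        return None
    return ti / tv


# -- per-class tabulation -----------------------------------------------------


@dataclass
class VariantClassTable:
    """SNV/INDEL counts and Ti/Tv per target-region class plus TOTAL.

    TOTAL counts every input variant regardless of target membership; the
    class rows count only variants falling in that class's target bases.
    """

    snv: Dict[str, int]
    indel: Dict[str, int]
    titv: Dict[str, Optional[float]]

    def to_frame(self):
        import pandas as pd

        rows = []
        for label in ("TOTAL",) + CLASS_LABELS:
            rows.append(
                {
                    "class": label,
                    "snv": self.snv[label],
                    "indel": self.indel[label],
                    "titv": self.titv[label],
                }
            )
        return pd.DataFrame(rows)


def class_table(
    variants: Iterable[Variant], classes: RegionClassMap
) -> VariantClassTable:
    """Tabulate SNV/INDEL counts and Ti/Tv per region class.

    INDELs are assigned by their anchor-base position. MNVs count in
    neither column.
    """
    labels = ("TOTAL",) + CLASS_LABELS
    snv = {lb: 0 for lb in labels}
    indel = {lb: 0 for lb in labels}
    per_class_snvs: Dict[str, List[Variant]] = {lb: [] for lb in labels}
    for v in variants:
        targets_label = classes.class_of(v.contig, v.pos)
        if v.is_snv:
            snv["TOTAL"] += 1
            per_class_snvs["TOTAL"].append(v)
            if targets_label is not None:
                snv[targets_label] += 1
                per_class_snvs[targets_label].append(v)
        elif v.is_indel:
            indel["TOTAL"] += 1
            if targets_label is not None:
                indel[targets_label] += 1
    titv = {lb: titv_ratio(per_class_snvs[lb]) for lb in labels}
    return VariantClassTable(snv=snv, indel=indel, titv=titv)


# -- strain comparison --------------------------------------------------------


@dataclass(frozen=True)
class SharedCounts:
    only_a: int
    shared: int
    only_b: int

    @property
    def pct_shared_a(self) -> float:
        """Shared variants as a percentage of set a."""
        n = self.only_a + self.shared
        return 100.0 * self.shared / n if n else 0.0

    @property
    def pct_shared_b(self) -> float:
        n = self.only_b + self.shared
        return 100.0 * self.shared / n if n else 0.0


def shared_variant_counts(
    a: Iterable[Variant], b: Iterable[Variant]
) -> SharedCounts:
    """Venn triple over (contig, pos, ref, alt) identity."""
    ka = {v.key for v in a}
    kb = {v.key for v in b}
    shared = len(ka & kb)
    return SharedCounts(only_a=len(ka) - shared, shared=shared, only_b=len(kb) - shared)


# -- SNV density vs conservation ----------------------------------------------


@dataclass(frozen=True)
class DensityBin:
    lo: float
    hi: float
    bp: int
    count: int

    @property
    def density(self) -> Optional[float]:
        return self.count / self.bp if self.bp > 0 else None

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


def snv_density_by_score(
    variants: Iterable[Variant],
    track: ConservationTrack,
    targets: GenomeIntervalSet,
    bin_width: float = 0.05,
) -> List[DensityBin]:
    """SNV density per conservation-score bin over scored target bases.

    Bins tile [0, 1] at ``bin_width`` with the last bin closed at 1.0.
    Unscored bases (and SNVs at them) contribute to no bin. A bin with 0 bp
    reports density None rather than 0.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin width {bin_width} does not tile [0, 1]")

    def bin_index(score: float) -> int:
        return min(int(score / bin_width), n_bins - 1)

    bp = [0] * n_bins
    counts = [0] * n_bins
    for contig in track.contigs():
        tivs = targets.per_contig(contig)
        rs = list(track.runs(contig))
        i = j = 0
        while i < len(tivs) and j < len(rs):
            ts, te = tivs[i]
            _, s, e, score = rs[j]
            lo, hi = max(ts, s), min(te, e)
            if lo < hi:
                bp[bin_index(score)] += hi - lo
            if te < e:
                i += 1
            else:
                j += 1
    for v in variants:
        if not v.is_snv:
            continue
        if not targets.contains(v.contig, v.pos):
            continue
        score = track.score_at(v.contig, v.pos)
        if score is None:
            continue
        counts[bin_index(score)] += 1
    return [
        DensityBin(
            lo=i * bin_width,
            hi=min((i + 1) * bin_width, 1.0),
            bp=bp[i],
            count=counts[i],
        )
        for i in range(n_bins)
    ]
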