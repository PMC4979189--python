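"""Seeded synthetic fixtures: annotation, conservation, variants, coverage.

Everything the other modules consume can be generated here at toy scale,
deterministically from a single integer seed, with no external downloads.
The generators emulate the study conditions of an exon + conserved-element
capture design: gene models with lognormal exon lengths (median ~132 bp,
typical of RefSeq exons), fully conserved (score 1.0) elements that are
short (geometric, median ~5 bp) and occur both inside exons and in
intergenic space, SNVs whose per-base rate decreases linearly with
conservation score, and Poisson read depth over targets with a control /
mutant pair carrying engineered deletions.

Each generator draws from its own ``numpy`` Generator seeded from
``(spec.seed, stream-id)``; no global random state is touched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .capture import CoverageTrack
from .design import GeneModel
from .errors import FixtureError
from .intervals import ConservationTrack, ContigSpace, GenomeIntervalSet
from .variants import Variant

__all__ = [
    "FixtureSpec",
    "make_annotation_fixture",
    "make_variant_fixture",
    "make_coverage_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study; all generators are pure in this."""

    seed: int = 1
    contigs: Tuple[Tuple[str, int], ...] = (
        ("chr1", 100_000),
        ("chr2", 100_000),
        ("chr3", 100_000),
    )
    gene_count: int = 60
    mean_exons_per_gene: float = 5.0
    exon_length_median: float = 132.0
    exon_length_sigma: float = 0.6
    intron_length_mean: float = 300.0
    intergenic_gap_mean: float = 1200.0
    noncoding_transcript_fraction: float = 0.1
    conserved_run_p: float = 0.14  # geometric success prob; median run ~5 bp
    exon_conserved_prob: float = 0.6
    intergenic_conserved_per_kb: float = 0.8
    background_run_mean: float = 40.0
    unscored_run_prob: float = 0.05
    snv_rate_scale: float = 0.02  # per-base SNV prob = scale * (1 - score)
    indel_rate: float = 5e-4
    known_fraction: float = 0.6
    deletions: Tuple[Tuple[str, int, int], ...] = ()  # (contig, start, length)
    nominal_depth: float = 50.0
    flank_length: int = 150
    flank_decay: float = 60.0

    def __post_init__(self) -> None:
        if self.gene_count < 0 or self.nominal_depth <= 0:
            raise FixtureError("counts and depth must be positive")
        lengths = dict(self.contigs)
        for contig, start, dlen in self.deletions:
            if contig not in lengths or start < 0 or start + dlen > lengths[contig]:
                raise FixtureError(
                    f"engineered deletion {contig}:{start}+{dlen} outside contigs"
                )

    def space(self) -> ContigSpace:
        return ContigSpace(self.contigs)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), stream])


# -- annotation + conservation ------------------------------------------------


def make_annotation_fixture(
    spec: FixtureSpec,
) -> Tuple[ContigSpace, List[GeneModel], ConservationTrack]:
    """Generate non-overlapping gene models and a conservation-score track.

    Genes are laid left-to-right with exponential intergenic gaps; each
    transcript gets lognormal exon lengths and exponential introns, and 90%
    (by default) receive a CDS span leaving UTR stubs in the flanking
    exons. Score-1.0 conservation runs are planted inside exons and in
    intergenic space; all other positions receive background scores drawn
    uniformly below 1.0 in variable-length runs, with occasional unscored
    gaps.
    """
    space = spec.space()
    rng = _rng(spec, 0)
    mu = math.log(spec.exon_length_median)

    models: List[GeneModel] = []
    conserved_ivs: List[Tuple[str, int, int]] = []
    contig_names = [c for c, _ in spec.contigs]
    cursors = {c: 0 for c in contig_names}
    ci = 0
    exhausted = 0
    gi = 0
    while gi < spec.gene_count:
        if exhausted >= len(contig_names):
            raise FixtureError(
                f"could not place {spec.gene_count} genes in the given contigs"
            )
        contig = contig_names[ci % len(contig_names)]
        clen = space[contig]
        gap = int(rng.exponential(spec.intergenic_gap_mean)) + 200
        start = cursors[contig] + gap
        n_exons = 1 + int(rng.poisson(max(spec.mean_exons_per_gene - 1.0, 0.0)))
        exon_lens = [
            max(10, int(round(v)))
            for v in rng.lognormal(mu, spec.exon_length_sigma, n_exons)
        ]
        intron_lens = [
            60 + int(rng.exponential(spec.intron_length_mean))
            for _ in range(n_exons - 1)
        ]
        exons: List[Tuple[int, int]] = []
        pos = start
        for k, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if k < n_exons - 1:
                pos += intron_lens[k]
        if pos >= clen - 200:
            ci += 1
            exhausted += 1
            continue
        exhausted = 0
        cursors[contig] = pos
        cds: Optional[Tuple[int, int]] = None
        if rng.random() >= spec.noncoding_transcript_fraction:
            fs, fe = exons[0]
            ls, le = exons[-1]
            cds_start = int(rng.integers(fs, fe))
            cds_end = int(rng.integers(ls + 1, le + 1))
            if cds_end <= cds_start:  # single short exon: force a 1-bp CDS
                cds_start, cds_end = fs, fs + 1
            cds = (cds_start, cds_end)
        source = "setA" if gi % 2 == 0 else "setB"
        models.append(
            GeneModel(
                gene_id=f"gene{gi:04d}",
                transcript_id=f"tx{gi:04d}",
                contig=contig,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                cds=cds,
                source=source,
            )
        )
        # conserved elements inside the exons
        for es, ee in exons:
            if rng.random() < spec.exon_conserved_prob:
                rlen = min(int(rng.geometric(spec.conserved_run_p)), ee - es)
                roff = int(rng.integers(es, ee - rlen + 1))
                conserved_ivs.append((contig, roff, roff + rlen))
        gi += 1
        ci += 1

    # intergenic conserved elements over the gene-free space
    gene_span = GenomeIntervalSet(
        (m.contig, m.tx_start, m.tx_end) for m in models
    )
    whole = GenomeIntervalSet((c, 0, l) for c, l in spec.contigs)
    for iv in whole.subtract(gene_span):
        n = rng.poisson(spec.intergenic_conserved_per_kb * len(iv) / 1000.0)
        for _ in range(n):
            rlen = min(int(rng.geometric(spec.conserved_run_p)), len(iv))
            roff = int(rng.integers(iv.start, iv.end - rlen + 1))
            conserved_ivs.append((iv.contig, roff, roff + rlen))

    conserved = GenomeIntervalSet(conserved_ivs)
    runs: List[Tuple[str, int, int, float]] = [
        (iv.contig, iv.start, iv.end, 1.0) for iv in conserved
    ]
    # background scores over everything not fully conserved
    for iv in whole.subtract(conserved):
        pos = iv.start
        while pos < iv.end:
            rlen = min(
                1 + int(rng.exponential(spec.background_run_mean)), iv.end - pos
            )
            if rng.random() >= spec.unscored_run_prob:
                score = float(rng.uniform(0.0, 0.999))
                runs.append((iv.contig, pos, pos + rlen, score))
            pos += rlen
    return space, models, ConservationTrack(runs)


# -- variants -----------------------------------------------------------------


def make_variant_fixture(
    spec: FixtureSpec,
    track: ConservationTrack,
    snv_rate: Optional[Callable[[float], float]] = None,
) -> Tuple[List[Variant], List[Variant]]:
    """Plant homozygous SNVs and INDELs over the scored genome.

    The per-base SNV probability is ``snv_rate(score)`` (default
    ``scale * (1 - score)``), so density falls linearly with conservation.
    A ``known_fraction`` subset is returned separately to stand in for a
    known-variant registry. Depths are Poisson around the nominal depth.
    """
    rng = _rng(spec, 1)
    if snv_rate is None:
        snv_rate = lambda score: spec.snv_rate_scale * (1.0 - score)

    variants: List[Variant] = []
    used = set()
    for contig, s, e, score in track.runs():
        p = min(max(snv_rate(score), 0.0), 1.0)
        if p <= 0.0:
            continue
        n = int(rng.binomial(e - s, p))
        if n == 0:
            continue
        positions = rng.choice(np.arange(s, e), size=n, replace=False)
        for pos in sorted(int(x) for x in positions):
            if (contig, pos) in used:
                continue
            used.add((contig, pos))
            ref = _BASES[rng.integers(4)]
            alt = rng.choice([b for b in _BASES if b != ref])
            variants.append(
                Variant(
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alt=str(alt),
                    depth=int(rng.poisson(spec.nominal_depth)),
                    genotype="hom-alt",
                )
            )
    # INDELs scattered uniformly, independent of conservation
    for contig, clen in spec.contigs:
        for _ in range(int(rng.poisson(spec.indel_rate * clen))):
            pos = int(rng.integers(0, clen - 10))
            if (contig, pos) in used:
                continue
            used.add((contig, pos))
            anchor = _BASES[rng.integers(4)]
            tail = "".join(_BASES[i] for i in rng.integers(0, 4, int(rng.integers(1, 6))))
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + tail
            else:
                ref, alt = anchor + tail, anchor
            variants.append(
                Variant(
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    depth=int(rng.poisson(spec.nominal_depth)),
                    genotype="hom-alt",
                )
            )
    variants.sort(key=lambda v: v.key)
    known = [v for v in variants if rng.random() < spec.known_fraction]
    return variants, known


# -- coverage -----------------------------------------------------------------


def make_coverage_fixture(
    spec: FixtureSpec, targets: GenomeIntervalSet
) -> Tuple[CoverageTrack, CoverageTrack]:
    """Poisson depth over targets (with decaying flanks); mutant deletions.

    The mutant shares the control's base depth and is zeroed inside every
    engineered deletion, so with no deletions the two tracks are identical.
    """
    rng = _rng(spec, 2)
    arrays: Dict[str, np.ndarray] = {
        c: np.zeros(l, dtype=np.int64) for c, l in spec.contigs
    }
    for iv in targets:
        arr = arrays[iv.contig]
        arr[iv.start : iv.end] = rng.poisson(spec.nominal_depth, len(iv))
        for off in range(1, spec.flank_length + 1):
            lam = spec.nominal_depth * math.exp(-off / spec.flank_decay)
            lpos, rpos = iv.start - off, iv.end - 1 + off
            if lpos >= 0 and arr[lpos] == 0:
                arr[lpos] = rng.poisson(lam)
            if rpos < arr.size and arr[rpos] == 0:
                arr[rpos] = rng.poisson(lam)

    control_runs = []
    for contig, arr in arrays.items():
        control_runs.extend(CoverageTrack.from_array(contig, arr).runs())
    control = CoverageTrack(control_runs)

    for contig, start, dlen in spec.deletions:
        if not targets.overlaps(contig, start, start + dlen):
            warnings.warn(
                f"engineered deletion {contig}:{start}+{dlen} overlaps no target",
                stacklevel=2,
            )
        arrays[contig][start : start + dlen] = 0
    mutant_runs = []
    for contig, arr in arrays.items():
        mutant_runs.extend(CoverageTrack.from_array(contig, arr).runs())
    return control, CoverageTrack(mutant_runs)
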