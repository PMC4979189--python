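"""Variant ingestion, triage funnel, Ti/Tv, class tables, density bins."""

import itertools
import random

import pytest

from targetec.design import classify_regions
from targetec.errors import VcfParseError
from targetec.intervals import (
    ConservationTrack,
    GenomeInterval,
    GenomeIntervalSet,
)
from targetec.variants import (
    Variant,
    class_table,
    filter_variants,
    read_vcf,
    restrict_to_locus,
    shared_variant_counts,
    snv_density_by_score,
    subtract_known,
    titv_ratio,
    write_vcf,
)


def snv(pos, ref="A", alt="G", depth=40, genotype="hom-alt", contig="c"):
    return Variant(contig, pos, ref, alt, depth=depth, genotype=genotype)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t101\t.\tA\tG\t.\tPASS\t.\tGT:DP\t1/1:40
chr1\t201\t.\tCTT\tC\t.\tPASS\t.\tGT:DP\t0/1:25
chr1\t301\t.\tA\tG,T\t.\tPASS\tDP=33\tGT\t1/2
"""


def test_read_vcf(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(VCF_TEXT)
    vs = read_vcf(path)
    assert len(vs) == 4  # multi-allelic record split into two
    assert vs[0] == Variant("chr1", 100, "A", "G", depth=40, genotype="hom-alt")
    assert vs[1].kind == "DEL" and vs[1].pos == 200 and vs[1].genotype == "het"
    # INFO DP used when the sample carries no DP; 1/2 is het for both alts
    assert vs[2].depth == 33 and vs[3].depth == 33
    assert vs[2].genotype == "het" and vs[3].genotype == "het"
    assert (vs[2].alt, vs[3].alt) == ("G", "T")


def test_read_vcf_rejects_garbage(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text("this is not a vcf\n")
    with pytest.raises(VcfParseError):
        read_vcf(path)


def test_variant_validation():
    with pytest.raises(VcfParseError):
        Variant("c", 0, "A", "A")
    with pytest.raises(VcfParseError):
        Variant("c", 0, "A", "G", genotype="homz")


def test_write_read_round_trip(tmp_path):
    vs = [snv(10), snv(20, "C", "CAT", genotype="het"), snv(30, "GG", "G")]
    path = tmp_path / "rt.vcf"
    write_vcf(vs, path, contig_lengths=[("c", 1000)])
    assert [v.key for v in read_vcf(path)] == [v.key for v in vs]


def test_filter_variants():
    targets = GenomeIntervalSet([("c", 0, 100)])
    vs = [
        snv(10, depth=9),  # below depth cutoff
        snv(20, depth=10),  # kept
        snv(150, depth=40),  # off target
        snv(30, depth=40, genotype="het"),  # dropped under hom_only
        snv(40, depth=None),  # no depth: skipped and tallied
    ]
    res = filter_variants(vs, min_depth=10, targets=targets, hom_only=True)
    assert [v.pos for v in res.kept] == [20]
    assert res.skipped_missing_depth == 1
    # depth filter off: missing depth passes through
    res2 = filter_variants(vs, min_depth=0)
    assert len(res2) == 5 and res2.skipped_missing_depth == 0


def test_subtract_known_position_and_allele_modes():
    vs = [snv(500, "A", "G"), snv(600, "A", "G")]
    # position mode drops any co-located variant
    assert subtract_known(vs, GenomeIntervalSet([("c", 499, 500)])) == vs
    kept = subtract_known(vs, GenomeIntervalSet([("c", 500, 501)]))
    assert [v.pos for v in kept] == [600]
    # known given as variants, position mode: alleles ignored
    kept = subtract_known(vs, [snv(500, "A", "T")])
    assert [v.pos for v in kept] == [600]
    # allele-aware keeps the A->G when only A->T is known
    kept = subtract_known(vs, [snv(500, "A", "T")], allele_aware=True)
    assert kept == vs
    kept = subtract_known(vs, [snv(500, "A", "G")], allele_aware=True)
    assert [v.pos for v in kept] == [600]
    with pytest.raises(VcfParseError):
        subtract_known(vs, GenomeIntervalSet(), allele_aware=True)


def test_restrict_to_locus_boundaries():
    locus = GenomeInterval("c", 100, 200)
    vs = [snv(99), snv(100), snv(199), snv(200), snv(150, contig="d")]
    assert [v.pos for v in restrict_to_locus(vs, locus)] == [100, 199]
    assert restrict_to_locus([], locus) == []


def test_funnel_order_invariance():
    targets = GenomeIntervalSet([("c", 0, 1000)])
    known = GenomeIntervalSet([("c", 300, 301)])
    locus = GenomeInterval("c", 200, 800)
    rng = random.Random(2)
    vs = [
        snv(p, depth=rng.choice([5, 15, 40]), genotype=rng.choice(["het", "hom-alt"]))
        for p in rng.sample(range(1000), 80)
    ]
    a = restrict_to_locus(
        subtract_known(filter_variants(vs, 10, targets, True).kept, known), locus
    )
    b = subtract_known(
        filter_variants(restrict_to_locus(vs, locus), 10, targets, True).kept, known
    )
    assert sorted(v.key for v in a) == sorted(v.key for v in b)


def test_titv_examples():
    assert titv_ratio([snv(1, "A", "G"), snv(2, "C", "T"), snv(3, "A", "C")]) == 2.0
    assert titv_ratio([snv(1, "A", "G")]) is None  # no transversion
    assert titv_ratio([]) is None
    # INDELs ignored
    assert titv_ratio([snv(1, "A", "G"), snv(2, "A", "AT"), snv(3, "A", "C")]) == 1.0


def test_titv_full_substitution_matrix():
    # all 12 ordered substitutions once: 4 transitions, 8 transversions
    vs = [
        snv(i, r, a)
        for i, (r, a) in enumerate(
            (r, a) for r, a in itertools.product("ACGT", repeat=2) if r != a
        )
    ]
    assert titv_ratio(vs) == pytest.approx(0.5)


@pytest.fixture()
def toy_classes():
    targets = GenomeIntervalSet([("c", 0, 400)])
    return classify_regions(
        targets,
        GenomeIntervalSet([("c", 0, 100)]),
        GenomeIntervalSet([("c", 100, 200)]),
        GenomeIntervalSet([("c", 200, 300)]),
    )


def test_class_table(toy_classes):
    vs = [
        snv(50, "A", "G"),  # CDS transition
        snv(150, "A", "C"),  # UTR transversion
        snv(250, "C", "CAT"),  # CNS insertion
        snv(350, "A", "G"),  # OTHER
        snv(900, "A", "G"),  # off target: TOTAL only
        snv(60, "AT", "GC"),  # MNV: counted nowhere
    ]
    table = class_table(vs, toy_classes)
    assert table.snv["TOTAL"] == 4  # the insertion and the MNV are not SNVs
    assert table.snv["CDS"] == 1 and table.titv["CDS"] is None
    assert table.snv["UTR"] == 1 and table.titv["UTR"] == 0.0
    assert table.indel["CNS"] == 1 and table.indel["TOTAL"] == 1
    assert table.snv["OTHER"] == 1
    frame = table.to_frame()
    assert list(frame["class"]) == ["TOTAL", "CDS", "UTR", "CNS", "OTHER"]


def test_class_table_matches_per_variant_oracle(toy_classes):
    rng = random.Random(9)
    vs = []
    for p in rng.sample(range(500), 60):
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        if rng.random() < 0.3:
            alt = alt + "T"  # insertion
        vs.append(snv(p, ref, alt))
    table = class_table(vs, toy_classes)
    for label, s in toy_classes.class_sets().items():
        exp_snv = sum(1 for v in vs if v.is_snv and s.contains("c", v.pos))
        exp_indel = sum(1 for v in vs if v.is_indel and s.contains("c", v.pos))
        assert table.snv[label] == exp_snv
        assert table.indel[label] == exp_indel
    assert table.snv["TOTAL"] == sum(1 for v in vs if v.is_snv)


def test_shared_variant_counts():
    a = [snv(1), snv(2), snv(3)]
    b = [snv(2), snv(3), snv(4)]
    counts = shared_variant_counts(a, b)
    assert (counts.only_a, counts.shared, counts.only_b) == (1, 2, 1)
    assert counts.pct_shared_a == pytest.approx(66.6667, abs=1e-3)
    swapped = shared_variant_counts(b, a)
    assert (swapped.only_a, swapped.only_b) == (counts.only_b, counts.only_a)
    assert swapped.shared == counts.shared
    disjoint = shared_variant_counts(a, [snv(9)])
    assert (disjoint.only_a, disjoint.shared, disjoint.only_b) == (3, 0, 1)
    same = shared_variant_counts(a, a)
    assert (same.only_a, same.shared, same.only_b) == (0, 3, 0)


def test_snv_density_by_score():
    track = ConservationTrack([("c", 0, 100, 1.0), ("c", 100, 150, 0.42)])
    targets = GenomeIntervalSet([("c", 0, 120)])
    vs = [snv(10), snv(110), snv(130), snv(500)]  # 130 off-target... see below
    bins = snv_density_by_score(vs, track, targets)
    top = bins[-1]
    assert top.lo == pytest.approx(0.95) and top.hi == 1.0
    assert top.bp == 100 and top.count == 1
    assert top.density == pytest.approx(0.01)
    mid = bins[8]  # [0.40, 0.45)
    assert mid.bp == 20 and mid.count == 1  # only the on-target part of the run
    # SNV at 130 is off-target, SNV at 500 unscored: neither binned
    assert sum(b.count for b in bins) == 2
    empty = bins[0]
    assert empty.bp == 0 and empty.density is None


def test_snv_density_unscored_base_excluded():
    track = ConservationTrack([("c", 0, 10, 0.5)])
    targets = GenomeIntervalSet([("c", 0, 100)])
    bins = snv_density_by_score([snv(50)], track, targets)
    assert sum(b.count for b in bins) == 0
    assert sum(b.bp for b in bins) == 10
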