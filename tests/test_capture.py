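"""Detectability, CNS proximity, read trimming, on-target and depth QC."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetec.capture import (
    CoverageTrack,
    ReadRecord,
    cns_exon_proximity,
    deletion_detectable_fraction,
    depth_statistics,
    detectability_curve,
    detectability_table,
    on_target_count,
    read_fastq,
    reads_from_alignments,
    trim_read_3prime,
    write_fastq,
)
from targetec.errors import EmptyInputError, NoValidPlacementError
from targetec.intervals import ContigSpace, GenomeIntervalSet

from oracles import brute_detectable_fraction


def test_detectable_fraction_worked_example():
    space = ContigSpace({"c": 1000})
    targets = GenomeIntervalSet([("c", 400, 500)])
    frac = deletion_detectable_fraction(targets, space, 100)
    assert frac == pytest.approx(199 / 901, abs=1e-12)
    assert frac == pytest.approx(
        brute_detectable_fraction(targets, {"c": 1000}, 100), abs=1e-12
    )


def test_detectable_fraction_edge_cases():
    space = ContigSpace({"c": 1000})
    targets = GenomeIntervalSet([("c", 400, 500)])
    # full-length deletion always hits any target on that contig
    assert deletion_detectable_fraction(targets, space, 1000) == 1.0
    assert deletion_detectable_fraction(GenomeIntervalSet(), space, 100) == 0.0
    with pytest.raises(NoValidPlacementError):
        deletion_detectable_fraction(targets, space, 1001)
    # contigs shorter than L drop out of the denominator
    space2 = ContigSpace({"c": 1000, "short": 50})
    assert deletion_detectable_fraction(
        targets, space2, 100
    ) == pytest.approx(199 / 901, abs=1e-12)


def test_detectable_fraction_matches_brute_force_random_designs():
    rng = random.Random(3)
    for _ in range(6):
        contigs = {"c1": rng.randint(500, 4000), "c2": rng.randint(500, 4000)}
        space = ContigSpace(contigs)
        targets = GenomeIntervalSet(
            [
                ("c1", s, s + rng.randint(1, 120))
                for s in rng.sample(range(contigs["c1"] - 150), 5)
            ]
            + [
                ("c2", s, s + rng.randint(1, 120))
                for s in rng.sample(range(contigs["c2"] - 150), 3)
            ]
        )
        for L in (1, 7, 100):
            assert deletion_detectable_fraction(
                targets, space, L
            ) == pytest.approx(
                brute_detectable_fraction(targets, contigs, L), abs=1e-12
            )


def test_detectable_fraction_closed_form_single_interior_target():
    G, t = 50_000, 137
    space = ContigSpace({"c": G})
    targets = GenomeIntervalSet([("c", 20_000, 20_000 + t)])
    for L in (1, 7, 100, 1333):
        expected = min(t + L - 1, G - L + 1) / (G - L + 1)
        assert deletion_detectable_fraction(
            targets, space, L
        ) == pytest.approx(expected, abs=1e-12)


def test_detectability_curve_monotone_and_dominant():
    space = ContigSpace({"c": 20_000})
    full = GenomeIntervalSet(
        [("c", s, s + 100) for s in range(1000, 19_000, 2500)]
    )
    subset = GenomeIntervalSet([("c", 1000, 1100), ("c", 11_000, 11_100)])
    lengths = [10, 100, 1000, 5000]
    curve_full = detectability_curve(full, space, lengths)
    curve_sub = detectability_curve(subset, space, lengths)
    fr_full = [p.fraction for p in curve_full]
    fr_sub = [p.fraction for p in curve_sub]
    assert fr_full == sorted(fr_full)
    assert fr_sub == sorted(fr_sub)
    assert all(f >= s for f, s in zip(fr_full, fr_sub))
    table = detectability_table({"full": full, "subset": subset}, space, lengths)
    assert list(table["full"]) == fr_full


@pytest.mark.parametrize(
    "cns, exon, within",
    [
        ((100, 110), (300, 400), True),  # gap 190 <= 250
        ((100, 110), (1000, 1100), False),  # gap 890
        ((100, 110), (105, 200), True),  # overlap -> distance 0
        ((100, 110), (110, 200), True),  # abutting -> distance 0
        ((500, 510), (240, 250), True),  # exon on the left, gap 250 exactly
    ],
)
def test_cns_exon_proximity_cases(cns, exon, within):
    res = cns_exon_proximity(
        GenomeIntervalSet([("c", *cns)]),
        GenomeIntervalSet([("c", *exon)]),
        threshold=250,
    )
    assert res.total == 1
    assert (res.within == 1) is within


def test_cns_proximity_counts_regions_not_bases():
    cns = GenomeIntervalSet([("c", 100, 110), ("c", 5000, 5500), ("d", 0, 10)])
    exons = GenomeIntervalSet([("c", 200, 300)])  # contig d has no exon
    res = cns_exon_proximity(cns, exons, threshold=250)
    assert (res.within, res.total) == (1, 3)
    assert res.fraction == pytest.approx(1 / 3)
    with pytest.raises(EmptyInputError):
        cns_exon_proximity(GenomeIntervalSet(), exons, 250)


def make_read(quals, **kw):
    return ReadRecord("r", "A" * len(quals), tuple(quals), **kw)


@pytest.mark.parametrize(
    "quals, expected_len",
    [
        ([35] * 30 + [35, 29, 28], 31),  # strip two trailing low-quality bases
        ([35] * 40, 40),  # all good: unchanged
        ([35] * 25 + [10] * 15, None),  # trimmed to 25 < 30: dropped
        ([], None),  # empty read: dropped
        ([29] * 40, None),  # everything low quality
        ([35] * 29 + [29], None),  # 29 remaining: one short of the cutoff
        ([35] * 30 + [29], 30),  # exactly the minimum survives
        ([35, 10, 35] + [35] * 27, 30),  # interior low quality is kept
    ],
)
def test_trim_read_3prime(quals, expected_len):
    out = trim_read_3prime(make_read(quals), min_q=30, min_len=30)
    if expected_len is None:
        assert out is None
    else:
        assert len(out) == expected_len
        assert out.qualities[-1] >= 30


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=0, max_value=41), max_size=60))
def test_trim_never_lengthens_and_is_idempotent(quals):
    out = trim_read_3prime(make_read(quals), min_q=30, min_len=1)
    if out is not None:
        assert len(out) <= len(quals)
        assert trim_read_3prime(out, min_q=30, min_len=1) == out


def test_on_target_count():
    targets = GenomeIntervalSet([("c", 100, 200)])
    mk = lambda s, e, **kw: make_read(
        [30] * 5, contig="c", start=s, end=e, is_mapped=True, **kw
    )
    reads = [
        mk(95, 105),  # 5-bp overlap: on target
        mk(0, 95),  # off target
        mk(199, 250),  # 1-bp overlap: on target
        mk(95, 105, is_duplicate=True),  # duplicate: excluded
        make_read([30] * 5),  # unmapped: excluded silently
    ]
    assert on_target_count(reads, targets) == 2


def test_depth_statistics_uniform():
    cov = CoverageTrack([("c", 0, 100, 12)])
    targets = GenomeIntervalSet([("c", 0, 100)])
    ds = depth_statistics(cov, targets, [10, 20])
    assert ds.mean_depth == pytest.approx(12.0)
    assert ds.fraction_at_least == {10: 1.0, 20: 0.0}
    assert ds.uncovered_fraction == 0.0


def test_depth_statistics_half_covered():
    cov = CoverageTrack([("c", 50, 100, 20)])
    targets = GenomeIntervalSet([("c", 0, 100)])
    ds = depth_statistics(cov, targets, [10])
    assert ds.mean_depth == pytest.approx(10.0)
    assert ds.fraction_at_least[10] == pytest.approx(0.5)
    assert ds.uncovered_fraction == pytest.approx(0.5)
    with pytest.raises(EmptyInputError):
        depth_statistics(cov, GenomeIntervalSet(), [10])


def test_depth_statistics_matches_per_base_oracle():
    rng = random.Random(5)
    depths = [rng.choice([0, 0, 3, 8, 15, 40]) for _ in range(2000)]
    cov = CoverageTrack.from_array("c", depths)
    targets = GenomeIntervalSet(
        [("c", s, s + rng.randint(10, 100)) for s in rng.sample(range(1800), 8)]
    )
    thresholds = [5, 10, 20]
    ds = depth_statistics(cov, targets, thresholds)
    tbases = [
        p for iv in targets for p in range(iv.start, iv.end)
    ]
    assert ds.mean_depth == pytest.approx(sum(depths[p] for p in tbases) / len(tbases))
    for t in thresholds:
        assert ds.fraction_at_least[t] == pytest.approx(
            sum(depths[p] >= t for p in tbases) / len(tbases)
        )
    assert ds.uncovered_fraction == pytest.approx(
        sum(depths[p] == 0 for p in tbases) / len(tbases)
    )
    assert all(0 <= f <= 1 for f in ds.fraction_at_least.values())
    ordered = [ds.fraction_at_least[t] for t in thresholds]
    assert ordered == sorted(ordered, reverse=True)


def test_fastq_round_trip_and_trim(tmp_path):
    path = tmp_path / "in.fq"
    reads = [
        ReadRecord("keep", "ACGTACGTAC" * 4, tuple([38] * 40)),
        ReadRecord("trim", "ACGT" * 10, tuple([38] * 35 + [20] * 5)),
        ReadRecord("drop", "ACGT" * 10, tuple([38] * 20 + [10] * 20)),
    ]
    write_fastq(reads, path)
    back = read_fastq(path)
    assert back == reads
    kept = [
        t for r in back if (t := trim_read_3prime(r, 30, 30)) is not None
    ]
    assert [r.read_id for r in kept] == ["keep", "trim"]
    assert len(kept[1]) == 35


SAM_TEXT = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:c\tLN:1000
r1\t0\tc\t96\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII
r2\t1024\tc\t96\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII
r3\t0\tc\t300\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII
r4\t4\t*\t0\t0\t*\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII
"""


def test_sam_ingest_and_pileup(tmp_path):
    path = tmp_path / "toy.sam"
    path.write_text(SAM_TEXT)
    reads = reads_from_alignments(path)
    assert len(reads) == 4
    targets = GenomeIntervalSet([("c", 100, 200)])
    # r1 overlaps by 5 bp; r2 is a duplicate; r3 off target; r4 unmapped
    assert on_target_count(reads, targets) == 1
    cov = CoverageTrack.from_alignments(path)
    assert cov.depth_at("c", 95) == 1  # only r1 (r2 flagged duplicate)
    assert cov.depth_at("c", 298) == 0
    assert cov.depth_at("c", 299) == 1  # SAM POS 300 is 1-based
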