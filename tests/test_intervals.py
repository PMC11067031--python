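"""Interval model, BED I/O, and set-algebra oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from bindweave.intervals import (
    FeatureClassScheme,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    classify_feature_distribution,
    count_overlapping,
    genes_within,
    intersect_consensus,
    read_bed,
    shared_and_specific,
    write_bed,
)

from conftest import (
    bf_consensus,
    bf_count_overlapping,
    bf_genes_within,
    bf_merge,
    bf_shared_specific,
    random_peakset,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 50)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 50)

    def test_half_open_adjacent_intervals_never_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 100, 200)
        assert a.overlap(b) == 0
        assert a.gap_to(b) == 0  # abutting: zero gap, zero overlap


class TestBedIO:
    def test_round_trip(self, tmp_path):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 10, 50, name="p1", score=3.5, strand="+"),
                GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr2", 0, 7, strand="-"),
            ],
            label="x",
        )
        path = tmp_path / "x.bed"
        write_bed(ps, path)
        back = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end, iv.strand) for iv in back] == [
            (iv.chrom, iv.start, iv.end, iv.strand) for iv in ps
        ]
        # write-read is idempotent
        write_bed(back, tmp_path / "y.bed")
        assert (tmp_path / "x.bed").read_text() != ""  # sanity
        assert read_bed(tmp_path / "y.bed") == back

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t50", "chr1\t100", "chr1\tabc\t200", "chr1\t-5\t10"],
        ids=["inverted", "too-few-fields", "non-numeric", "negative"],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    def test_three_line_bed3(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t0\t10\nchr1\t20\t30\nchr2\t5\t9\n")
        assert len(read_bed(path)) == 3


class TestIntersectConsensus:
    def test_self_intersection_equals_merge(self, rng, toy_genome_sizes):
        s = random_peakset(rng, 200, toy_genome_sizes)
        cons = intersect_consensus(s, s)
        assert len(cons) == len(s.merge())

    def test_halfopen_boundary_is_empty(self):
        a = PeakSet([GenomicInterval("chr1", 100, 200)])
        b = PeakSet([GenomicInterval("chr1", 200, 300)])
        assert len(intersect_consensus(a, b)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed, toy_genome_sizes):
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, 500, toy_genome_sizes)
        b = random_peakset(rng, 500, toy_genome_sizes)
        got = [(iv.chrom, iv.start, iv.end) for iv in intersect_consensus(a, b)]
        assert got == bf_consensus(a, b)

    def test_min_overlap_threshold(self):
        rng = np.random.default_rng(7)
        a = random_peakset(rng, 150, {"chr1": 20_000}, max_width=120)
        b = random_peakset(rng, 150, {"chr1": 20_000}, max_width=120)
        for m in (1, 10, 50):
            got = [(iv.chrom, iv.start, iv.end) for iv in intersect_consensus(a, b, m)]
            assert got == bf_consensus(a, b, m)

    def test_symmetric_cluster_count(self, rng, toy_genome_sizes):
        a = random_peakset(rng, 300, toy_genome_sizes)
        b = random_peakset(rng, 300, toy_genome_sizes)
        assert len(intersect_consensus(a, b)) == len(intersect_consensus(b, a))


class TestCountOverlapping:
    def test_empty_reference(self):
        q = PeakSet([GenomicInterval("chr1", 0, 10)])
        n, flags = count_overlapping(q, PeakSet([]))
        assert n == 0 and not flags.any()

    def test_query_subset_of_reference(self):
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(10)]
        q = PeakSet(ivs[:5])
        r = PeakSet(ivs)
        n, flags = count_overlapping(q, r)
        assert n == 5 and flags.all()

    @pytest.mark.parametrize("min_overlap", [1, 25])
    def test_matches_bruteforce_oracle(self, min_overlap, toy_genome_sizes):
        rng = np.random.default_rng(11)
        q = random_peakset(rng, 400, toy_genome_sizes)
        r = random_peakset(rng, 400, toy_genome_sizes)
        n, flags = count_overlapping(q, r, min_overlap)
        bn, bflags = bf_count_overlapping(q, r, min_overlap)
        assert n == bn
        assert flags.tolist() == bflags


class TestSharedSpecific:
    def test_identical_sets_all_shared(self, rng, toy_genome_sizes):
        s = random_peakset(rng, 100, toy_genome_sizes)
        shared, a_only, b_only = shared_and_specific(s, s)
        assert len(a_only) == 0 and len(b_only) == 0
        assert len(shared) == len(s.merge())

    def test_disjoint_sets(self):
        a = PeakSet([GenomicInterval("chr1", 0, 10)])
        b = PeakSet([GenomicInterval("chr1", 50, 60)])
        shared, a_only, b_only = shared_and_specific(a, b)
        assert len(shared) == 0 and len(a_only) == 1 and len(b_only) == 1

    def test_partition_matches_oracle_and_is_exhaustive(self, toy_genome_sizes):
        rng = np.random.default_rng(5)
        a = random_peakset(rng, 300, toy_genome_sizes)
        b = random_peakset(rng, 300, toy_genome_sizes)
        shared, a_only, b_only = shared_and_specific(a, b)
        bshared, ba_only, bb_only = bf_shared_specific(a, b)
        assert [(iv.chrom, iv.start, iv.end) for iv in shared] == bshared
        assert list(a_only) == ba_only and list(b_only) == bb_only
        # exhaustive assignment: every input interval is either a shared-
        # cluster member (cross-set overlap) or in its set-specific output
        n_shared_members_a, _ = count_overlapping(a, b)
        n_shared_members_b, _ = count_overlapping(b, a)
        assert n_shared_members_a + len(a_only) == len(a)
        assert n_shared_members_b + len(b_only) == len(b)
        # and every shared member is contained in some shared cluster span
        for iv, flag in zip(a, count_overlapping(a, b)[1]):
            if flag:
                assert any(
                    iv.chrom == c and iv.start >= s and iv.end <= e
                    for c, s, e in bshared
                )


def _toy_annotation():
    return GeneAnnotation.from_records(
        [
            ("geneA", "chr1", "+", 5_000, 7_000, 5_000),
            ("geneB", "chr1", "-", 20_000, 22_000, 22_000),
            ("geneC", "chr2", "+", 1_000, 1_500, 1_000),
        ]
    )


class TestGenesWithin:
    def test_peak_inside_gene_body_distance_zero(self):
        ann = _toy_annotation()
        peaks = PeakSet([GenomicInterval("chr1", 5_500, 5_600)])
        assert genes_within(peaks, ann) == {"geneA": 0}

    def test_boundary_exclusion_at_1001bp(self):
        ann = _toy_annotation()
        # peak ends exactly 1,001 bp before geneA start
        peaks = PeakSet([GenomicInterval("chr1", 3_000, 5_000 - 1_001)])
        assert genes_within(peaks, ann, max_distance=1_000) == {}
        # one base closer: included at distance 1,000
        peaks = PeakSet([GenomicInterval("chr1", 3_000, 5_000 - 1_000)])
        assert genes_within(peaks, ann, max_distance=1_000) == {"geneA": 1_000}

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(9)
        records = []
        for i in range(200):
            chrom = "chr1" if i % 2 else "chr2"
            start = int(rng.integers(0, 95_000))
            end = start + int(rng.integers(200, 3_000))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((f"g{i}", chrom, strand, start, end, start if strand == "+" else end))
        ann = GeneAnnotation.from_records(records)
        peaks = random_peakset(rng, 300, {"chr1": 100_000, "chr2": 100_000})
        assert genes_within(peaks, ann, 1_000) == bf_genes_within(peaks, ann, 1_000)

    def test_monotone_in_max_distance(self):
        rng = np.random.default_rng(13)
        records = [
            (f"g{i}", "chr1", "+", int(s), int(s) + 500, int(s))
            for i, s in enumerate(rng.integers(0, 90_000, 50))
        ]
        ann = GeneAnnotation.from_records(records)
        peaks = random_peakset(rng, 60, {"chr1": 100_000})
        prev: set = set()
        for d in (0, 100, 1_000, 10_000):
            cur = set(genes_within(peaks, ann, d))
            assert prev <= cur
            prev = cur

    def test_unknown_chromosome_skipped(self, caplog):
        ann = _toy_annotation()
        peaks = PeakSet([GenomicInterval("chrX", 0, 100), GenomicInterval("chr1", 5_100, 5_200)])
        assert genes_within(peaks, ann) == {"geneA": 0}


class TestGeneAnnotation:
    def test_tss_invariant_enforced(self):
        with pytest.raises(ValueError, match="TSS"):
            GeneAnnotation.from_records([("g", "chr1", "+", 10, 20, 20)])
        with pytest.raises(ValueError, match="TSS"):
            GeneAnnotation.from_records([("g", "chr1", "-", 10, 20, 10)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneAnnotation.from_records(
                [("g", "chr1", "+", 10, 20, 10), ("g", "chr1", "+", 30, 40, 30)]
            )

    def test_tsv_round_trip(self, tmp_path):
        ann = _toy_annotation()
        ann.write_tsv(tmp_path / "genes.tsv")
        back = GeneAnnotation.read_tsv(tmp_path / "genes.tsv")
        pd.testing.assert_frame_equal(ann.table, back.table)


class TestFeatureDistribution:
    def test_all_peaks_at_tss(self):
        ann = _toy_annotation()
        scheme = FeatureClassScheme(tss_halfwidth=100)
        peaks = PeakSet(
            [GenomicInterval("chr1", 4_990, 5_010), GenomicInterval("chr2", 990, 1_010)]
        )
        table = classify_feature_distribution(
            peaks, ann, scheme, {"chr1": 100_000, "chr2": 100_000}
        )
        tss = table.set_index("feature_class").loc["tss"]
        assert tss["observed_fraction"] == 1.0

    def test_uniform_peaks_match_background(self):
        # genome where promoter territory is ~10%; uniform peaks should show
        # ~10% promoter fraction and a non-significant test
        rng = np.random.default_rng(3)
        records = [
            (f"g{i}", "chr1", "+", 1_200 + i * 12_000, 1_700 + i * 12_000, 1_200 + i * 12_000)
            for i in range(8)
        ]
        ann = GeneAnnotation.from_records(records)
        scheme = FeatureClassScheme(promoter_upstream=1_000, promoter_downstream=200)
        sizes = {"chr1": 96_000}
        peaks = PeakSet(
            [GenomicInterval("chr1", int(s), int(s) + 1) for s in rng.integers(0, 95_999, 1_000)]
        )
        table = classify_feature_distribution(peaks, ann, scheme, sizes).set_index("feature_class")
        prom = table.loc["promoter"]
        assert prom["background_fraction"] == pytest.approx(0.1, abs=0.001)
        assert abs(prom["observed_fraction"] - prom["background_fraction"]) < 0.03
        assert prom["p_value"] > 0.05

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError, match="empty"):
            classify_feature_distribution(
                PeakSet([]), _toy_annotation(), FeatureClassScheme(), {"chr1": 1_000}
            )


# ---------------------------------------------------------------------------
# Property-based invariants


from hypothesis import given, settings, strategies as st


@st.composite
def interval_lists(draw, max_n=60):
    n = draw(st.integers(1, max_n))
    ivs = []
    for _ in range(n):
        chrom = draw(st.sampled_from(["chr1", "chr2"]))
        start = draw(st.integers(0, 5_000))
        width = draw(st.integers(1, 400))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(ivs)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(interval_lists(), interval_lists())
def test_consensus_invariants(a, b):
    """Consensus output is sorted, non-overlapping, symmetric in count,
    and contains only territory covered by the input union."""
    cons = intersect_consensus(a, b)
    assert len(cons) == len(intersect_consensus(b, a))
    prev = None
    union = PeakSet(list(a) + list(b)).merge()
    for iv in cons:
        if prev is not None and prev.chrom == iv.chrom:
            assert prev.end < iv.start or prev.end == iv.start  # no overlap
        prev = iv
        assert any(
            u.chrom == iv.chrom and u.start <= iv.start and iv.end <= u.end
            for u in union
        )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(interval_lists(), interval_lists())
def test_shared_specific_is_a_partition(a, b):
    shared, a_only, b_only = shared_and_specific(a, b)
    n_a, _ = count_overlapping(a, b)
    n_b, _ = count_overlapping(b, a)
    assert n_a + len(a_only) == len(a)
    assert n_b + len(b_only) == len(b)
    if n_a == 0 and n_b == 0:
        assert len(shared) == 0
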