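"""Fragment ingestion, wrapping classification, filtering, depth matching."""

import numpy as np
import pytest

from wrapstate.fragments import (
    FragmentSet,
    WrappingClass,
    assign_unique_region,
    classify_lengths,
    classify_wrapping,
    count_fragments_per_region,
    filter_by_regions,
    length_histogram,
    merge_fragment_sets,
    partition_by_class,
    read_fragments,
    subsample_to_depth,
    write_fragments_tsv,
)
from wrapstate.genome import GenomicInterval

from conftest import random_fragset, random_intervals


class TestReadFragments:
    def test_bedpe_outer_span(self, tmp_path):
        p = tmp_path / "f.bedpe"
        p.write_text("chr1\t100\t150\tchr1\t220\t270\tfrag\t.\t+\t-\n")
        fs, report = read_fragments(p, format="bedpe")
        assert fs.n == 1 and fs.starts[0] == 100 and fs.ends[0] == 270
        assert fs.lengths[0] == 170
        assert report == {"kept": 1, "skipped_interchrom": 0, "dropped_long": 0}

    def test_interchromosomal_pair_skipped_with_count(self, tmp_path):
        p = tmp_path / "f.bedpe"
        p.write_text(
            "chr1\t100\t150\tchr2\t220\t270\tx\t.\t+\t-\n"
            "chr1\t10\t60\tchr1\t90\t140\ty\t.\t+\t-\n"
        )
        fs, report = read_fragments(p, format="bedpe")
        assert fs.n == 1 and report["skipped_interchrom"] == 1

    def test_fragments_tsv_and_qc_length(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t100\t180\nchr1\t0\t5000\n")
        fs, report = read_fragments(p, format="fragments_tsv")
        assert fs.n == 1 and fs.lengths[0] == 80
        assert report["dropped_long"] == 1

    def test_inverted_mate_errors(self, tmp_path):
        p = tmp_path / "f.bedpe"
        p.write_text("chr1\t150\t100\tchr1\t220\t270\tx\t.\t+\t-\n")
        with pytest.raises(ValueError, match=":1"):
            read_fragments(p, format="bedpe")

    def test_tsv_round_trip(self, tmp_path, genome):
        fs = random_fragset(np.random.default_rng(0), genome, 200)
        path = tmp_path / "rt.tsv"
        write_fragments_tsv(fs, path)
        back, _ = read_fragments(path, format="fragments_tsv")
        assert np.array_equal(back.starts, fs.starts)
        assert np.array_equal(back.ends, fs.ends)
        assert list(back.chroms) == list(fs.chroms)


class TestClassify:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (99, WrappingClass.UNWRAPPED),
            (100, WrappingClass.PARTIAL),
            (150, WrappingClass.PARTIAL),
            (151, WrappingClass.FULL),
            (1, WrappingClass.UNWRAPPED),
            (1000, WrappingClass.FULL),
        ],
    )
    def test_boundaries(self, length, expected):
        assert classify_wrapping(length) is expected

    def test_non_positive_length_errors(self):
        with pytest.raises(ValueError):
            classify_wrapping(0)

    def test_vectorised_agrees_with_scalar(self):
        lengths = np.arange(1, 400)
        vec = classify_lengths(lengths)
        assert all(v is classify_wrapping(int(l)) for v, l in zip(vec, lengths))


class TestPartition:
    def test_three_way_example(self):
        fs = FragmentSet("c", "r", np.asarray(["chr1"] * 3, dtype=object),
                         np.asarray([0, 0, 0]), np.asarray([80, 120, 200]))
        parts = partition_by_class(fs)
        assert [parts[c].n for c in WrappingClass] == [1, 1, 1]

    def test_empty_set(self):
        parts = partition_by_class(FragmentSet.empty())
        assert all(p.n == 0 for p in parts.values())

    def test_partition_property_and_membership(self, genome):
        fs = random_fragset(np.random.default_rng(1), genome, 10_000)
        parts = partition_by_class(fs)
        assert sum(p.n for p in parts.values()) == fs.n
        for cls, part in parts.items():
            assert all(c is cls for c in classify_lengths(part.lengths))
        # sizes equal a direct counting oracle
        lengths = fs.lengths
        assert parts[WrappingClass.UNWRAPPED].n == int((lengths < 100).sum())
        assert parts[WrappingClass.PARTIAL].n == int(((lengths >= 100) & (lengths <= 150)).sum())
        assert parts[WrappingClass.FULL].n == int((lengths > 150).sum())


class TestFilterByRegions:
    def test_overlap_and_half_open_boundary(self):
        fs = FragmentSet("c", "r", np.asarray(["chr1", "chr1"], dtype=object),
                         np.asarray([950, 0]), np.asarray([1200, 100]))
        regions = [GenomicInterval("chr1", 1000, 3000), GenomicInterval("chr1", 100, 200)]
        kept = filter_by_regions(fs, regions)
        assert kept.n == 1 and kept.starts[0] == 950

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_and_idempotent(self, genome, seed):
        rng = np.random.default_rng(seed)
        fs = random_fragset(rng, genome, 10_000)
        regions = random_intervals(rng, genome, 200, max_len=2000)
        kept = filter_by_regions(fs, regions)
        expected = [
            i
            for i in range(fs.n)
            if any(
                r.chrom == fs.chroms[i] and fs.starts[i] < r.end and r.start < fs.ends[i]
                for r in regions
            )
        ]
        assert np.array_equal(kept.starts, fs.starts[expected])
        twice = filter_by_regions(kept, regions)
        assert np.array_equal(twice.starts, kept.starts) and twice.n == kept.n


class TestSubsample:
    def _sets(self, genome, sizes):
        rng = np.random.default_rng(7)
        return [
            random_fragset(rng, genome, n, condition=f"cond{i}", replicate="r")
            for i, n in enumerate(sizes)
        ]

    def test_min_rule_and_exactness(self, genome):
        sets = self._sets(genome, [1000, 800, 1200])
        out = subsample_to_depth(sets, seed=3)
        assert [s.n for s in out] == [800, 800, 800]

    def test_output_is_subset_and_deterministic(self, genome):
        sets = self._sets(genome, [500, 400])
        out1 = subsample_to_depth(sets, seed=9)
        out2 = subsample_to_depth(sets, seed=9)
        for a, b, src in zip(out1, out2, sets):
            assert np.array_equal(a.starts, b.starts)
            pool = set(zip(src.chroms.tolist(), src.starts.tolist(), src.ends.tolist()))
            assert set(zip(a.chroms.tolist(), a.starts.tolist(), a.ends.tolist())) <= pool

    def test_target_above_depth_names_set(self, genome):
        sets = self._sets(genome, [300, 200])
        with pytest.raises(ValueError, match="cond1"):
            subsample_to_depth(sets, seed=0, target=250)

    def test_class_proportions_preserved_hypergeometric(self, genome):
        """Subsampling 50k of a 20%-unwrapped pool stays within 3 binomial SD."""
        rng = np.random.default_rng(21)
        n = 200_000
        unwrapped = rng.random(n) < 0.2
        lengths = np.where(unwrapped, 60, 200)
        fs = FragmentSet("c", "r", np.asarray(["chr1"] * n, dtype=object),
                         np.zeros(n, dtype=np.int64), lengths.astype(np.int64))
        (out,) = subsample_to_depth([fs], seed=5, target=50_000)
        frac = float((out.lengths < 100).mean())
        sd = np.sqrt(0.2 * 0.8 / 50_000)
        assert abs(frac - 0.2) < 3 * sd


class TestRegionCounting:
    def test_count_spanning_fragment_in_both(self):
        fs = FragmentSet("c", "r", np.asarray(["chr1"], dtype=object),
                         np.asarray([90]), np.asarray([210]))
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 300)]
        assert list(count_fragments_per_region(fs, regions)) == [1, 1]

    def test_unique_assignment_is_leftmost(self):
        fs = FragmentSet("c", "r", np.asarray(["chr1", "chr1"], dtype=object),
                         np.asarray([90, 400]), np.asarray([210, 450]))
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 300)]
        assert list(assign_unique_region(fs, regions)) == [0, -1]

    def test_unique_assignment_with_nested_regions(self):
        # a narrow region hides inside a broad one; leftmost start wins
        fs = FragmentSet("c", "r", np.asarray(["chr1"], dtype=object),
                         np.asarray([10]), np.asarray([20]))
        regions = [GenomicInterval("chr1", 90, 100), GenomicInterval("chr1", 0, 200)]
        assert list(assign_unique_region(fs, regions)) == [1]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_counts_match_brute_force(self, genome, seed):
        rng = np.random.default_rng(seed)
        fs = random_fragset(rng, genome, 5000)
        regions = random_intervals(rng, genome, 150, max_len=3000)
        counts = count_fragments_per_region(fs, regions)
        for j, r in enumerate(regions):
            expected = int(
                np.sum((fs.chroms == r.chrom) & (fs.starts < r.end) & (fs.ends > r.start))
            )
            assert counts[j] == expected


class TestHistogram:
    def test_counts_and_overflow(self):
        fs = FragmentSet("c", "r", np.asarray(["chr1"] * 3, dtype=object),
                         np.asarray([0, 0, 0]), np.asarray([80, 80, 120]))
        hist = length_histogram(fs, 100)
        assert hist[80] == 2 and hist[100] == 1 and hist.sum() == 3

    def test_empty_and_conservation(self, genome):
        assert length_histogram(FragmentSet.empty(), 50).sum() == 0
        fs = random_fragset(np.random.default_rng(2), genome, 5000)
        assert length_histogram(fs, 1000).sum() == fs.n


def test_merge_fragment_sets_concatenates(genome):
    rng = np.random.default_rng(4)
    a = random_fragset(rng, genome, 100, condition="wt", replicate="r1")
    b = random_fragset(rng, genome, 50, condition="wt", replicate="r2")
    merged = merge_fragment_sets([a, b])
    assert merged.n == 150 and merged.condition == "wt"
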