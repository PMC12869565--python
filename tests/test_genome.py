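"""Interval engine: BED I/O, promoters, overlap classification, Fisher."""

import math

import numpy as np
import pytest
from scipy import stats

from wrapstate.genome import (
    BedParseError,
    ContingencyTable2x2,
    GeneRecord,
    Genome,
    GenomicInterval,
    annotate_genomic_distribution,
    fisher_exact_2x2,
    fisher_overlap,
    intersect_classify,
    merge_intervals,
    promoters_from_genes,
    random_regions,
    read_bed,
    read_genes,
    write_bed,
    write_genes,
)

from conftest import random_intervals


class TestBedIO:
    def test_parse_basic_and_strand(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\n# comment\ntrack name=x\nchr1\t300\t400\tpk\t5.0\t-\n")
        ivs = read_bed(p)
        assert len(ivs) == 2
        assert (ivs[0].chrom, ivs[0].start, ivs[0].end, ivs[0].strand) == ("chr1", 100, 200, ".")
        assert ivs[1].strand == "-" and ivs[1].name == "pk" and ivs[1].score == 5.0

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="bad.bed:2"):
            read_bed(p)

    def test_round_trip_random_intervals(self, tmp_path, genome):
        rng = np.random.default_rng(11)
        ivs = random_intervals(rng, genome, 100)
        for i, iv in enumerate(ivs):  # decorate some records
            if i % 3 == 0:
                iv.score = float(rng.integers(0, 1000))
            if i % 2 == 0:
                iv.strand = "-"
        path = tmp_path / "rt.bed"
        write_bed(ivs, path)
        assert read_bed(path) == ivs

    def test_empty_write(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        assert path.read_text() == ""
        assert read_bed(path) == []

    def test_gene_table_round_trip(self, tmp_path, genes):
        path = tmp_path / "genes.tsv"
        write_genes(genes, path)
        assert read_genes(path) == genes


class TestGenome:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Genome({"chr1": 0})
        with pytest.raises(ValueError):
            Genome([("chr1", 10), ("chr1", 20)])
        g = Genome({"chr2": 10, "chr1": 20})
        assert g.names == ["chr2", "chr1"]  # insertion order kept

    def test_chrom_sizes_round_trip(self, tmp_path, genome):
        path = tmp_path / "g.chrom.sizes"
        genome.to_chrom_sizes(path)
        assert Genome.from_chrom_sizes(path) == genome

    def test_interval_validation(self, genome):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 50, 50)
        iv = GenomicInterval("chr1", 0, 200_000)
        with pytest.raises(ValueError):
            iv.validate(genome)


class TestPromoters:
    def test_window_strand_and_clipping(self, genome):
        genes = [
            GeneRecord("a", "chr1", 5000, "+"),
            GeneRecord("b", "chr1", 300, "+"),
            GeneRecord("c", "chr1", 5000, "-"),
        ]
        proms = promoters_from_genes(genes, 1000, genome)
        assert (proms[0].start, proms[0].end) == (4000, 6000)
        assert (proms[1].start, proms[1].end) == (0, 1300)
        assert (proms[2].start, proms[2].end, proms[2].strand) == (4000, 6000, "-")
        assert proms[0].name == "a"

    def test_lengths_equal_twice_flank_unless_clipped(self, genome):
        rng = np.random.default_rng(3)
        genes = [
            GeneRecord(f"g{i}", "chr1", int(t), "+")
            for i, t in enumerate(rng.integers(0, 100_000, size=200))
        ]
        for p, g in zip(promoters_from_genes(genes, 750, genome), genes):
            clipped = g.tss < 750 or g.tss + 750 > 100_000
            assert (p.length == 1500) != clipped

    def test_tss_outside_genome(self, genome):
        with pytest.raises(ValueError):
            promoters_from_genes([GeneRecord("z", "chr2", 60_000, "+")], 100, genome)


def brute_force_classify(a, b):
    """All-pairs overlap oracle for intersect_classify."""
    def hits(xs, ys):
        return [any(x.overlaps(y) for y in ys) for x in xs]

    a_hit = hits(a, b)
    b_hit = hits(b, a)
    a_only = [iv for iv, h in zip(a, a_hit) if not h]
    b_only = [iv for iv, h in zip(b, b_hit) if not h]
    contributing = [iv for iv, h in zip(a, a_hit) if h] + [iv for iv, h in zip(b, b_hit) if h]
    # independent merge: repeated pairwise merging to a fixed point
    spans = [[iv.chrom, iv.start, iv.end] for iv in contributing]
    changed = True
    while changed:
        changed = False
        out = []
        for sp in spans:
            for o in out:
                if o[0] == sp[0] and sp[1] < o[2] and o[1] < sp[2]:
                    o[1], o[2] = min(o[1], sp[1]), max(o[2], sp[2])
                    changed = True
                    break
            else:
                out.append(sp)
        spans = out
    return a_only, {tuple(s) for s in spans}, b_only


class TestIntersectClassify:
    def test_single_overlap_merges(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        res = intersect_classify(a, b)
        assert res.a_only == [] and res.b_only == []
        assert [(s.start, s.end) for s in res.shared] == [(0, 150)]

    def test_book_ended_do_not_overlap(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 100, 200)]
        res = intersect_classify(a, b)
        assert res.a_only == a and res.b_only == b and res.shared == []

    def test_empty_inputs(self):
        res = intersect_classify([], [])
        assert res.a_only == res.shared == res.b_only == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, genome, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, genome, 300)
        b = random_intervals(rng, genome, 300)
        res = intersect_classify(a, b)
        a_only, shared_spans, b_only = brute_force_classify(a, b)
        assert res.a_only == a_only and res.b_only == b_only
        assert {(s.chrom, s.start, s.end) for s in res.shared} == shared_spans


class TestRandomRegions:
    def test_counts_length_and_determinism(self, genome):
        regs = random_regions(genome, 500, 250, seed=5)
        assert len(regs) == 500 and all(r.length == 250 for r in regs)
        assert regs == random_regions(genome, 500, 250, seed=5)
        assert regs != random_regions(genome, 500, 250, seed=6)

    def test_single_placement(self):
        g = Genome({"only": 1000})
        regs = random_regions(g, 20, 1000, seed=0)
        assert all(r.start == 0 and r.end == 1000 for r in regs)

    def test_too_long_errors(self, genome):
        with pytest.raises(ValueError):
            random_regions(genome, 5, 200_000, seed=0)

    def test_start_uniformity_chi_square(self):
        g = Genome({"c": 100_000})
        starts = np.asarray([r.start for r in random_regions(g, 100_000, 1, seed=42)])
        counts, _ = np.histogram(starts, bins=100, range=(0, 100_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001


class TestFisher:
    def test_odds_ratio_arithmetic(self):
        odds, log2_odds, _, _ = fisher_exact_2x2(ContingencyTable2x2(10, 5, 2, 8))
        assert odds == 8.0 and log2_odds == 3.0

    def test_haldane_keeps_log2_finite(self):
        odds, log2_odds, _, _ = fisher_exact_2x2(ContingencyTable2x2(10, 0, 2, 8))
        assert math.isfinite(log2_odds) and odds == (10.5 * 8.5) / (0.5 * 2.5)

    @pytest.mark.parametrize("table", [(3, 7, 6, 2), (10, 0, 2, 8), (1, 1, 1, 1), (12, 3, 4, 9)])
    def test_one_sided_matches_scipy(self, table):
        mine = fisher_exact_2x2(ContingencyTable2x2(*table))[3]
        a, b, c, d = table
        ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_null_query_log2_odds_near_zero(self, genome):
        """Query drawn from the same distribution as the null: OR ~ 1."""
        proms = promoters_from_genes(
            [GeneRecord(f"g{i}", "chr1", 2000 + 4000 * i, "+") for i in range(20)],
            1000,
            genome,
        )
        log2s = []
        for seed in range(20):
            query = random_regions(genome, 400, 250, seed=1000 + seed)
            _, _, log2_odds, _, _ = fisher_overlap(
                query, proms, genome, n_random=4000, random_length=250, seed=seed
            )
            log2s.append(log2_odds)
        assert abs(np.mean(log2s)) < 0.2

    def test_empty_query_errors(self, genome):
        with pytest.raises(ValueError):
            fisher_overlap([], [], genome)


class TestAnnotate:
    def test_priority_and_partition(self, genome, genes):
        bodies = [GenomicInterval("chr1", 5000, 15_000), GenomicInterval("chr2", 10_000, 20_000)]
        peaks = [
            GenomicInterval("chr1", 4900, 5100),   # midpoint in promoter AND body
            GenomicInterval("chr1", 9000, 9100),   # body only
            GenomicInterval("chr1", 40_000, 40_100),  # nothing
        ]
        counts = annotate_genomic_distribution(peaks, genes, 1000, bodies, genome)
        assert counts == {"promoter": 1, "gene_body": 1, "intergenic": 1}

    def test_counts_sum_to_input(self, genome, genes):
        rng = np.random.default_rng(9)
        peaks = random_intervals(rng, genome, 1000)
        bodies = random_intervals(rng, genome, 50, max_len=5000)
        counts = annotate_genomic_distribution(peaks, genes, 1000, bodies, genome)
        assert sum(counts.values()) == 1000

    def test_unannotated_chromosome_is_intergenic(self, genome):
        peaks = [GenomicInterval("chr2", 0, 100)]
        counts = annotate_genomic_distribution(peaks, [], 1000, [], genome)
        assert counts == {"promoter": 0, "gene_body": 0, "intergenic": 1}


def test_merge_intervals_keeps_book_ended_separate():
    merged = merge_intervals(
        [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20), GenomicInterval("c", 15, 30)]
    )
    assert [(m.start, m.end) for m in merged] == [(0, 10), (10, 30)]
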