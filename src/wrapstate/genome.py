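"""Genomic coordinate system, interval I/O, and overlap statistics.

Coordinates are 0-based half-open ``[start, end)`` throughout (BED
convention): an interval of length 1 at position *p* is ``[p, p+1)`` and
book-ended intervals such as ``[0, 100)`` / ``[100, 200)`` do **not**
overlap. Strand is carried along but ignored for every overlap computation,
matching the unstranded nature of tagmentation-based chromatin profiling.

The module covers the interval plumbing of a peak co-occupancy analysis:
BED and chrom.sizes I/O, promoter derivation from TSS annotations,
three-way overlap classification of two peak sets (A-only / shared /
B-only), uniform random-region nulls, Fisher's exact association of a peak
set with a reference set against that null, and a coarse genomic-
distribution annotation (promoter / gene body / intergenic).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A BED-like file could not be parsed; the message names the line."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class Genome:
    """Ordered mapping of chromosome name to length in bp.

    Chromosome names are unique and lengths are positive integers. The
    insertion order is the canonical chromosome order for every track and
    file this package writes.
    """

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = sizes.items() if isinstance(sizes, Mapping) else sizes
        self._sizes: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            length = int(length)
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[name] = length
        if not self._sizes:
            raise ValueError("a genome needs at least one chromosome")

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    def items(self):
        return self._sizes.items()

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:
        return f"Genome({self._sizes!r})"

    def total_length(self) -> int:
        return sum(self._sizes.values())

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Read a two-column (name, length) chrom.sizes file."""
        pairs = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{lineno}: expected 2 columns")
                try:
                    pairs.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
        return cls(pairs)

    def to_chrom_sizes(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class GenomicInterval:
    """A half-open genomic interval with optional BED6 decoration."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, genome: Genome) -> None:
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {genome[self.chrom]}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneRecord:
    """A gene reduced to its TSS anchor: id, chromosome, TSS (0-based), strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        self.tss = int(self.tss)
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass
class ContingencyTable2x2:
    """Non-negative 2x2 counts with a positive grand total."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("contingency counts must be non-negative integers")
        self.a, self.b, self.c, self.d = (int(self.a), int(self.b), int(self.c), int(self.d))
        if self.total < 1:
            raise ValueError("contingency table grand total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class OverlapClassification:
    """Three-way split of two peak sets: exclusive peaks and merged shared regions."""

    a_only: list[GenomicInterval]
    shared: list[GenomicInterval]
    b_only: list[GenomicInterval]


# ---------------------------------------------------------------------------
# BED / gene-table I/O


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    return repr(float(score))


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, in file order.

    Track/browser/comment lines are skipped; columns beyond 6 are ignored.
    Malformed coordinates raise :class:`BedParseError` naming the line.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = None
            score: float | None = None
            strand = "."
            if len(fields) > 3 and fields[3] != ".":
                name = fields[3]
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            if len(fields) > 5:
                strand = fields[5]
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write BED6; round-trips through :func:`read_bed` on the first 6 columns."""
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.name if iv.name is not None else '.'}\t"
                f"{_format_score(iv.score)}\t{iv.strand}\n"
            )


def read_genes(path) -> list[GeneRecord]:
    """Read a minimal TSV gene table: gene_id, chrom, tss, strand."""
    out: list[GeneRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                tss = int(fields[2])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise BedParseError(f"{path}:{lineno}: non-integer TSS {fields[2]!r}")
            out.append(GeneRecord(fields[0], fields[1], tss, fields[3]))
    return out


def write_genes(genes: Sequence[GeneRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Overlap machinery (sorted merged arrays + searchsorted)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge strictly overlapping intervals per chromosome.

    Book-ended intervals stay separate (half-open convention). Output is
    ordered by first appearance of the chromosome, then by start.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s < cur_e:  # strict overlap only
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


class RegionIndex:
    """Merged, sorted per-chromosome interval arrays for fast any-overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        merged = merge_intervals(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in merged:
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        for chrom in starts:
            self._by_chrom[chrom] = (
                np.asarray(starts[chrom], dtype=np.int64),
                np.asarray(ends[chrom], dtype=np.int64),
            )

    def overlaps_arrays(
        self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised: does each [start, end) on chrom overlap any region?"""
        out = np.zeros(len(starts), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in set(chroms.tolist()):
            if chrom not in self._by_chrom:
                continue
            rs, re = self._by_chrom[chrom]
            mask = chroms == chrom
            s = np.asarray(starts)[mask]
            e = np.asarray(ends)[mask]
            # last merged region starting before e; merged regions are
            # disjoint with strictly increasing ends, so it is the only
            # candidate that can reach past s.
            j = np.searchsorted(rs, e, side="left") - 1
            hit = (j >= 0) & (re[np.clip(j, 0, len(re) - 1)] > s)
            out[mask] = hit
        return out

    def overlaps(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        if not intervals:
            return np.zeros(0, dtype=bool)
        chroms = np.asarray([iv.chrom for iv in intervals], dtype=object)
        starts = np.asarray([iv.start for iv in intervals], dtype=np.int64)
        ends = np.asarray([iv.end for iv in intervals], dtype=np.int64)
        return self.overlaps_arrays(chroms, starts, ends)


# ---------------------------------------------------------------------------
# Promoters, co-occupancy, random nulls, Fisher


def promoters_from_genes(
    genes: Sequence[GeneRecord], flank_bp: int, genome: Genome
) -> list[GenomicInterval]:
    """Promoter windows ``[tss - flank, tss + flank)`` clipped to the chromosome.

    Strand and gene id are carried onto the promoter interval.
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    out = []
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        length = genome[g.chrom]
        if not 0 <= g.tss < length:
            raise ValueError(f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom} [0, {length})")
        out.append(
            GenomicInterval(
                g.chrom,
                max(0, g.tss - flank_bp),
                min(length, g.tss + flank_bp),
                g.strand,
                g.gene_id,
            )
        )
    return out


def intersect_classify(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> OverlapClassification:
    """Classify two peak sets into A-only, shared, and B-only.

    Overlap means >= 1 bp on the same chromosome, strand ignored. ``shared``
    is the union-merge of every A and B peak that overlaps the other set,
    each merged region counted once; ``a_only``/``b_only`` keep the original
    peak records.
    """
    index_a = RegionIndex(a) if a else None
    index_b = RegionIndex(b) if b else None
    a_hits = index_b.overlaps(a) if (index_b and a) else np.zeros(len(a), dtype=bool)
    b_hits = index_a.overlaps(b) if (index_a and b) else np.zeros(len(b), dtype=bool)
    a_only = [iv for iv, hit in zip(a, a_hits) if not hit]
    b_only = [iv for iv, hit in zip(b, b_hits) if not hit]
    contributing = [iv for iv, hit in zip(a, a_hits) if hit] + [
        iv for iv, hit in zip(b, b_hits) if hit
    ]
    shared = merge_intervals(contributing) if contributing else []
    return OverlapClassification(a_only=a_only, shared=shared, b_only=b_only)


def random_regions(
    genome: Genome, n: int, length_bp: int, seed: int
) -> list[GenomicInterval]:
    """Draw ``n`` fixed-length regions uniformly over valid genome positions.

    Chromosomes are chosen proportionally to their number of valid start
    positions (length - length_bp + 1); starts are uniform within a
    chromosome. Regions may overlap each other. Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = [c for c in genome if genome[c] >= length_bp]
    if not names:
        raise ValueError(f"no chromosome is >= {length_bp} bp")
    n_pos = np.asarray([genome[c] - length_bp + 1 for c in names], dtype=np.float64)
    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(names), size=n, p=n_pos / n_pos.sum())
    highs = n_pos.astype(np.int64)[chrom_idx]
    starts = rng.integers(0, highs)
    return [
        GenomicInterval(names[ci], int(s), int(s) + length_bp, name=f"random_{i}")
        for i, (ci, s) in enumerate(zip(chrom_idx, starts))
    ]


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float, float, float]:
    """Exact Fisher test on a 2x2 table.

    Returns ``(odds_ratio, log2_odds, p_two_sided, p_greater)``. The odds
    ratio is ``(a*d)/(b*c)`` with a Haldane 0.5 correction applied to every
    cell when any cell is zero, so the log2 is always finite. P-values come
    from the hypergeometric distribution at fixed margins, computed with
    exact integer arithmetic: the two-sided p sums every table whose point
    weight is <= the observed weight (exact integer comparison, so ties are
    unambiguous), the one-sided "greater" p sums tables with a >= observed.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = table.total
    r1 = a + b
    c1 = a + c
    k_min = max(0, r1 + c1 - n_total)
    k_max = min(r1, c1)
    weights = [
        math.comb(r1, k) * math.comb(n_total - r1, c1 - k) for k in range(k_min, k_max + 1)
    ]
    total_w = sum(weights)
    w_obs = weights[a - k_min]
    p_two = sum(w for w in weights if w <= w_obs) / total_w
    p_greater = sum(weights[a - k_min :]) / total_w
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return odds, math.log2(odds), float(p_two), float(p_greater)


def fisher_overlap(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    genome: Genome,
    n_random: int = 55_000,
    random_length: int = 250,
    seed: int = 0,
) -> tuple[ContingencyTable2x2, float, float, float, float]:
    """Fisher association of a query peak set with a reference set.

    The 2x2 table contrasts the query against a matched random-region null:
    rows are (query, random), columns are (overlaps reference, does not).
    A positive log2 odds ratio means the query overlaps the reference more
    often than length-matched random regions do.
    """
    if not query:
        raise ValueError("fisher_overlap: query peak set is empty")
    ref_index = RegionIndex(reference)
    a = int(ref_index.overlaps(query).sum())
    b = len(query) - a
    rand = random_regions(genome, n_random, random_length, seed)
    c = int(ref_index.overlaps(rand).sum())
    d = n_random - c
    table = ContingencyTable2x2(a, b, c, d)
    odds, log2_odds, p_two, p_greater = fisher_exact_2x2(table)
    return table, odds, log2_odds, p_two, p_greater


def annotate_genomic_distribution(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    promoter_flank: int,
    gene_bodies: Sequence[GenomicInterval],
    genome: Genome,
) -> dict[str, int]:
    """Assign each peak one category by midpoint: promoter > gene_body > intergenic.

    Coarse three-class annotation for distribution pie charts; counts always
    sum to the number of peaks.
    """
    promoters = promoters_from_genes(genes, promoter_flank, genome) if genes else []
    prom_index = RegionIndex(promoters) if promoters else None
    body_index = RegionIndex(gene_bodies) if gene_bodies else None
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    mids = [GenomicInterval(p.chrom, p.midpoint, p.midpoint + 1) for p in peaks]
    in_prom = prom_index.overlaps(mids) if (prom_index and mids) else np.zeros(len(mids), bool)
    in_body = body_index.overlaps(mids) if (body_index and mids) else np.zeros(len(mids), bool)
    for p_hit, b_hit in zip(in_prom, in_body):
        if p_hit:
            counts["promoter"] += 1
        elif b_hit:
            counts["gene_body"] += 1
        else:
            counts["intergenic"] += 1
    return counts
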