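"""Binned genome coverage tracks, bedGraph I/O, and threshold peak calling.

A :class:`CoverageTrack` holds one value per fixed-width bin per
chromosome (the final bin may be short). Raw coverage counts, for every
bin, the number of fragments overlapping it by >= 1 bp — full-fragment
counting, the fragment analogue of extending reads to their template
length. RPKM rescales raw counts to reads-per-kilobase-per-million:

    rpkm = raw * 1e9 / (total_fragments * bin_size)

bedGraph (4 columns, 0-based half-open) is the canonical on-disk format.
The writer emits one line per maximal run of equal-valued adjacent bins and
omits zero runs, which makes write→read round-trips bit-exact and easy to
test. The peak caller applies three rules over a bedGraph-style track:
threshold runs, gap merging, and a minimum-length filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import Genome, GenomicInterval, _open_text
from .fragments import FragmentSet


def n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)  # ceil division


@dataclass
class CoverageTrack:
    """Per-chromosome binned signal with a normalization tag."""

    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str  # raw | rpkm | merged | log2ratio
    total_fragments: int = 0

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom in self.genome:
            expect = n_bins(self.genome[chrom], self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(expect, dtype=np.float64)
            elif len(self.values[chrom]) != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {len(self.values[chrom])}"
                )

    def same_binning(self, other: "CoverageTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def copy_with(self, values: dict[str, np.ndarray], normalization: str) -> "CoverageTrack":
        return CoverageTrack(
            self.genome, self.bin_size, values, normalization, self.total_fragments
        )

    def flat(self) -> np.ndarray:
        """All bin values concatenated in genome chromosome order."""
        return np.concatenate([self.values[c] for c in self.genome])

    @classmethod
    def zeros(cls, genome: Genome, bin_size: int, normalization: str = "raw") -> "CoverageTrack":
        return cls(genome, bin_size, {}, normalization)


@dataclass
class Peak:
    """A called peak: interval, summit (leftmost max position), max score."""

    interval: GenomicInterval
    summit: int
    score: float

    def __post_init__(self):
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError("summit must lie within the peak interval")


def coverage_track(
    fragset: FragmentSet,
    genome: Genome,
    bin_size: int = 10,
    normalization: str = "raw",
) -> CoverageTrack:
    """Binned fragment-overlap coverage, raw or RPKM-normalised.

    A fragment increments every bin it overlaps by >= 1 bp. Fragments
    extending past chromosome bounds are clipped (with a warning); fragments
    on unknown chromosomes are dropped (with a warning). RPKM requires a
    non-empty fragment set.
    """
    if normalization not in ("raw", "rpkm"):
        raise ValueError(f"normalization must be raw or rpkm, got {normalization!r}")
    if normalization == "rpkm" and fragset.n == 0:
        raise ValueError("cannot RPKM-normalise an empty fragment set")
    values: dict[str, np.ndarray] = {}
    n_clipped = 0
    n_dropped = 0
    for chrom in genome:
        length = genome[chrom]
        nb = n_bins(length, bin_size)
        mask = fragset.chroms == chrom
        starts = np.clip(fragset.starts[mask], 0, length)
        ends = np.clip(fragset.ends[mask], 0, length)
        n_clipped += int(
            np.sum((fragset.starts[mask] != starts) | (fragset.ends[mask] != ends))
        )
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        first = starts // bin_size
        last = (ends - 1) // bin_size
        diff = np.zeros(nb + 1, dtype=np.int64)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        values[chrom] = np.cumsum(diff)[:-1].astype(np.float64)
    known = set(genome.names)
    n_dropped = int(np.sum([c not in known for c in fragset.chroms.tolist()]))
    if n_clipped or n_dropped:
        warnings.warn(
            f"coverage_track: clipped {n_clipped} and dropped {n_dropped} "
            "out-of-genome fragments"
        )
    track = CoverageTrack(genome, bin_size, values, "raw", total_fragments=fragset.n)
    if normalization == "rpkm":
        factor = 1e9 / (fragset.n * bin_size)
        track.values = {c: v * factor for c, v in track.values.items()}
        track.normalization = "rpkm"
    return track


def merge_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Element-wise sum of replicate tracks; tag becomes ``merged``."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_binning(t):
            raise ValueError("merge_tracks: tracks differ in genome or bin size")
    values = {
        c: np.sum([t.values[c] for t in tracks], axis=0).astype(np.float64)
        for c in first.genome
    }
    out = first.copy_with(values, "merged")
    out.total_fragments = sum(t.total_fragments for t in tracks)
    return out


def compare_tracks_log2(
    t1: CoverageTrack, t2: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin ``log2((v1 + pc) / (v2 + pc))``; tag becomes ``log2ratio``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not t1.same_binning(t2):
        raise ValueError("compare_tracks_log2: tracks differ in genome or bin size")
    values = {
        c: np.log2((t1.values[c] + pseudocount) / (t2.values[c] + pseudocount))
        for c in t1.genome
    }
    return t1.copy_with(values, "log2ratio")


# ---------------------------------------------------------------------------
# bedGraph I/O


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write 4-column bedGraph: one line per equal-valued run, zero runs omitted."""
    with _open_text(path, "wt") as fh:
        for chrom in track.genome:
            vals = track.values[chrom]
            length = track.genome[chrom]
            if len(vals) == 0:
                continue
            # boundaries of maximal equal-valued runs
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for b0, b1 in zip(starts, ends):
                v = vals[b0]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{b0 * track.bin_size}\t"
                    f"{min(b1 * track.bin_size, length)}\t{float(v)!r}\n"
                )


def read_bedgraph(path, genome: Genome, bin_size: int) -> CoverageTrack:
    """Read a bin-aligned bedGraph into a track.

    Interval boundaries must be multiples of ``bin_size`` (or the chromosome
    end); within a chromosome intervals must be sorted and non-overlapping.
    Uncovered bins are zero. The normalization tag is ``raw`` — callers that
    know better can retag.
    """
    values = {c: np.zeros(n_bins(genome[c], bin_size), dtype=np.float64) for c in genome}
    last_end: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom = fields[0]
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
            length = genome[chrom]
            if end <= start or end > length:
                raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end})")
            if start < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: unsorted or overlapping intervals")
            last_end[chrom] = end
            if start % bin_size or (end % bin_size and end != length):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) not aligned to "
                    f"{bin_size} bp bins"
                )
            values[chrom][start // bin_size : -(-end // bin_size)] = value
    return CoverageTrack(genome, bin_size, values, "raw")


# ---------------------------------------------------------------------------
# Threshold peak calling


def call_peaks_bedgraph(
    track: CoverageTrack, cutoff: float, min_length: int, max_gap: int
) -> list[Peak]:
    """Call peaks by threshold, gap-merge, and minimum length.

    Candidate regions are maximal runs of bins with value >= cutoff;
    candidates separated by <= ``max_gap`` bp merge; merged regions shorter
    than ``min_length`` bp are discarded. The summit is the start position
    of the leftmost bin attaining the peak's maximum value.
    """
    if min_length < 0 or max_gap < 0:
        raise ValueError("min_length and max_gap must be >= 0")
    peaks: list[Peak] = []
    bs = track.bin_size
    for chrom in track.genome:
        vals = track.values[chrom]
        length = track.genome[chrom]
        above = vals >= cutoff
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        run_starts = edges[0::2]  # in bins
        run_ends = edges[1::2]
        # merge candidate runs separated by <= max_gap bp
        merged: list[tuple[int, int]] = [(int(run_starts[0]), int(run_ends[0]))]
        for b0, b1 in zip(run_starts[1:], run_ends[1:]):
            prev0, prev1 = merged[-1]
            gap_bp = (b0 - prev1) * bs
            if gap_bp <= max_gap:
                merged[-1] = (prev0, int(b1))
            else:
                merged.append((int(b0), int(b1)))
        for b0, b1 in merged:
            start_bp = b0 * bs
            end_bp = min(b1 * bs, length)
            if end_bp - start_bp < min_length:
                continue
            window = vals[b0:b1]
            top = int(np.argmax(window))  # leftmost maximum
            summit = (b0 + top) * bs
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start_bp, end_bp, name=f"peak_{len(peaks)}"),
                    summit,
                    float(window[top]),
                )
            )
    return peaks


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """narrowPeak-flavoured BED6+: name, score=max, strand '.', summit offset col 10."""
    with _open_text(path, "wt") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{p.score!r}\t.\t.\t.\t.\t{p.summit - iv.start}\n"
            )
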