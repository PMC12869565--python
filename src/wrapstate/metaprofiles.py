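"""Reference-point signal matrices and region summary statistics.

A :class:`SignalMatrix` is a regions × bins array anchored at a reference
point — a gene's TSS or a peak's midpoint — covering ``upstream_bp`` to
``downstream_bp`` around it in ``bin_width`` windows. Minus-strand anchors
are orientation-flipped so that "downstream" always means downstream in
gene direction; windows that fall off the chromosome are missing (NaN) and
excluded from means rather than zero-filled, avoiding edge artifacts.

Window values are bp-weighted means of the underlying track, so matrix bin
width need not equal (or align with) the track's bin size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .genome import GeneRecord, GenomicInterval
from .tracks import CoverageTrack


@dataclass
class Anchor:
    """A reference point: id, chromosome, position (bp), strand."""

    region_id: str
    chrom: str
    point: int
    strand: str = "."


def as_anchor(obj, index: int = 0) -> Anchor:
    """Coerce a GeneRecord (TSS) or GenomicInterval (midpoint) to an anchor."""
    if isinstance(obj, Anchor):
        return obj
    if isinstance(obj, GeneRecord):
        return Anchor(obj.gene_id, obj.chrom, obj.tss, obj.strand)
    if isinstance(obj, GenomicInterval):
        return Anchor(obj.name or f"region_{index}", obj.chrom, obj.midpoint, obj.strand)
    raise TypeError(f"cannot anchor object of type {type(obj).__name__}")


@dataclass
class SignalMatrix:
    region_ids: list[str]
    upstream_bp: int
    downstream_bp: int
    bin_width: int
    values: np.ndarray  # regions x bins, NaN = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expect = (self.upstream_bp + self.downstream_bp) // self.bin_width
        if self.values.ndim != 2 or self.values.shape != (len(self.region_ids), expect):
            raise ValueError(
                f"values must be {len(self.region_ids)} x {expect}, got {self.values.shape}"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def offsets(self) -> np.ndarray:
        """Bin-center offsets in bp relative to the anchor."""
        return -self.upstream_bp + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def reorder(self, order: np.ndarray) -> "SignalMatrix":
        order = np.asarray(order)
        return SignalMatrix(
            [self.region_ids[i] for i in order],
            self.upstream_bp,
            self.downstream_bp,
            self.bin_width,
            self.values[order],
        )


def reference_point_matrix(
    track: CoverageTrack,
    anchors: Sequence,
    upstream: int,
    downstream: int,
    bin_width: int = 10,
) -> SignalMatrix:
    """Signal around each anchor, one row per region, left-to-right 5'→3'.

    Row r, column j is the bp-weighted mean track value over the j-th
    ``bin_width`` window, laid out from ``point - upstream`` for +/.
    anchors and flipped for − anchors. Windows reaching outside the
    chromosome are NaN.
    """
    if bin_width < 1 or upstream % bin_width or downstream % bin_width:
        raise ValueError("bin_width must divide both upstream and downstream extents")
    anchors = [as_anchor(a, i) for i, a in enumerate(anchors)]
    ncol = (upstream + downstream) // bin_width
    out = np.full((len(anchors), ncol), np.nan)

    # Per-chromosome prefix integral of the stepwise bin function:
    # F(x) = integral of track value over [0, x); window mean is then
    # (F(b) - F(a)) / (b - a).
    bs = track.bin_size
    prefix: dict[str, np.ndarray] = {}
    for chrom in track.genome:
        vals = track.values[chrom]
        widths = np.full(len(vals), bs, dtype=np.float64)
        if len(vals):
            widths[-1] = track.genome[chrom] - (len(vals) - 1) * bs
        prefix[chrom] = np.concatenate(([0.0], np.cumsum(vals * widths)))

    def F(chrom: str, x: np.ndarray) -> np.ndarray:
        vals = track.values[chrom]
        i = np.minimum(x // bs, len(vals) - 1).astype(np.int64)
        return prefix[chrom][i] + vals[i] * (x - i * bs)

    for r, a in enumerate(anchors):
        if a.chrom not in track.genome:
            continue  # whole row stays missing
        length = track.genome[a.chrom]
        if a.strand == "-":
            # genomic span [point - downstream, point + upstream), columns
            # run from the gene-upstream (genomically right) side leftwards
            edges = a.point - downstream + np.arange(ncol + 1) * bin_width
            flip = True
        else:
            edges = a.point - upstream + np.arange(ncol + 1) * bin_width
            flip = False
        lo, hi = edges[:-1], edges[1:]
        valid = (lo >= 0) & (hi <= length)
        if valid.any():
            cl = np.clip(edges, 0, length)
            integ = F(a.chrom, cl)
            means = (integ[1:] - integ[:-1]) / bin_width
            row = np.where(valid, means, np.nan)
            out[r] = row[::-1] if flip else row
    return SignalMatrix([a.region_id for a in anchors], upstream, downstream, bin_width, out)


def mean_profile(matrix: SignalMatrix) -> np.ndarray:
    """Missing-aware per-column mean; all-missing columns stay NaN."""
    if len(matrix.region_ids) < 1:
        raise ValueError("mean_profile needs at least one region")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(matrix.values, axis=0)


def sort_regions_by_mean(matrix: SignalMatrix) -> np.ndarray:
    """Stable region order by descending row mean (NaN rows last).

    The returned order is an index permutation; apply it to any matrix over
    the identical region list with :func:`apply_region_order`.
    """
    if len(matrix.region_ids) < 1:
        raise ValueError("sort_regions_by_mean needs at least one region")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(matrix.values, axis=1)
    key = np.where(np.isnan(means), -np.inf, means)
    return np.argsort(-key, kind="stable")


def apply_region_order(matrix: SignalMatrix, order: np.ndarray, reference: SignalMatrix) -> SignalMatrix:
    """Permute ``matrix`` rows by an order derived from ``reference``.

    Errors if the two matrices do not cover the identical region list — the
    shared-order contract behind multi-mark heatmaps.
    """
    if matrix.region_ids != reference.region_ids:
        raise ValueError("region lists differ; cannot share a sort order")
    return matrix.reorder(order)


def quantile_partition(values: Sequence[float], k: int) -> np.ndarray:
    """Partition values into k groups (labels 1..k) by ascending value.

    Group sizes differ by at most one (lower groups take the remainder);
    ties keep input order.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of values {n}")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, k)
    sizes = [base + 1 if i < rem else base for i in range(k)]
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[pos : pos + size]] = g
        pos += size
    return labels


def region_score(track: CoverageTrack, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Per-region mean of the bin values the region overlaps (bins weighted equally)."""
    bs = track.bin_size
    out = np.full(len(regions), np.nan)
    for i, iv in enumerate(regions):
        if iv.chrom not in track.genome:
            continue
        vals = track.values[iv.chrom]
        b0 = iv.start // bs
        b1 = min((iv.end - 1) // bs, len(vals) - 1)
        out[i] = float(np.mean(vals[b0 : b1 + 1]))
    return out


def replicate_correlation(
    tracks: Sequence[CoverageTrack], method: str = "pearson"
) -> np.ndarray:
    """Pairwise correlation of replicate tracks over concatenated bin vectors.

    Symmetric with unit diagonal; a zero-variance track gets NaN
    off-diagonal entries and a warning.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_binning(t):
            raise ValueError("tracks differ in genome or bin size")
    data = np.vstack([t.flat() for t in tracks])
    degenerate = np.isclose(data.std(axis=1), 0.0)
    if degenerate.any():
        warnings.warn("replicate_correlation: zero-variance track(s); entries set to NaN")
    k = len(tracks)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate[i] or degenerate[j]:
                out[i, j] = out[j, i] = np.nan
                continue
            if method == "pearson":
                r = float(np.corrcoef(data[i], data[j])[0, 1])
            else:
                r = float(_stats.spearmanr(data[i], data[j]).statistic)
            out[i, j] = out[j, i] = r
    return out


def write_matrix_tsv(matrix: SignalMatrix, path) -> None:
    """TSV export: header of bin-center offsets, one row per region."""
    offsets = matrix.offsets()
    with open(path, "wt") as fh:
        fh.write("region\t" + "\t".join(f"{o:g}" for o in offsets) + "\n")
        for rid, row in zip(matrix.region_ids, matrix.values):
            fh.write(
                rid + "\t" + "\t".join("nan" if np.isnan(v) else repr(float(v)) for v in row) + "\n"
            )


def write_profile_tsv(offsets: np.ndarray, profile: np.ndarray, path, header: str = "mean") -> None:
    with open(path, "wt") as fh:
        fh.write(f"offset\t{header}\n")
        for o, v in zip(offsets, profile):
            fh.write(f"{o:g}\t{'nan' if np.isnan(v) else repr(float(v))}\n")
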