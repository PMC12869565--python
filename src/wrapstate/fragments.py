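"""Paired-end fragment handling and nucleosome wrapping-state classification.

A sequenced paired-end fragment is the outer span of its two mates; its
length is the amount of DNA the transposase released, which proxies the
wrapping state of the underlying nucleosome:

* ``UNWRAPPED`` — sub-nucleosomal, length < 100 bp
* ``PARTIAL``   — partially unwrapped, 100 <= length <= 150 bp
* ``FULL``      — fully wrapped nucleosomal DNA, length > 150 bp

Lengths exactly 100 and 150 fall in ``PARTIAL`` (the inclusive reading of
the 100–150 bp band). Fragment sets are stored as parallel numpy arrays so
that filtering, partitioning, and subsampling stay vectorised at realistic
depths.

Depth matching — subsampling every condition's promoter-restricted fragment
set to a common exact count — is the step that lets downstream per-class
comparisons reflect composition rather than sequencing depth.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, RegionIndex, _open_text

DEFAULT_BOUNDARIES = (100, 150)
DEFAULT_MAX_LENGTH = 1000


class WrappingClass(enum.Enum):
    UNWRAPPED = "unwrapped"
    PARTIAL = "partial"
    FULL = "full"

    def __str__(self) -> str:  # tidy labels in tables and filenames
        return self.value


WRAPPING_CLASSES = (WrappingClass.UNWRAPPED, WrappingClass.PARTIAL, WrappingClass.FULL)


@dataclass
class Fragment:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentSet:
    """Fragments of one (condition, replicate), stored as parallel arrays."""

    condition: str
    replicate: str
    chroms: np.ndarray  # object dtype
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if len(self.starts) and np.any(self.ends <= self.starts):
            raise ValueError("all fragments must satisfy end > start")

    @property
    def n(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def take(self, idx) -> "FragmentSet":
        return FragmentSet(
            self.condition, self.replicate, self.chroms[idx], self.starts[idx], self.ends[idx]
        )

    def __iter__(self):
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield Fragment(str(c), int(s), int(e))

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[Fragment], condition: str = "", replicate: str = ""
    ) -> "FragmentSet":
        frs = list(fragments)
        return cls(
            condition,
            replicate,
            np.asarray([f.chrom for f in frs], dtype=object),
            np.asarray([f.start for f in frs], dtype=np.int64),
            np.asarray([f.end for f in frs], dtype=np.int64),
        )

    @classmethod
    def empty(cls, condition: str = "", replicate: str = "") -> "FragmentSet":
        z = np.asarray([], dtype=np.int64)
        return cls(condition, replicate, np.asarray([], dtype=object), z, z.copy())


def merge_fragment_sets(sets: Sequence[FragmentSet], condition: str | None = None) -> FragmentSet:
    """Concatenate replicate fragment sets into one pooled set."""
    if not sets:
        raise ValueError("need at least one fragment set to merge")
    cond = condition if condition is not None else sets[0].condition
    return FragmentSet(
        cond,
        "merged",
        np.concatenate([s.chroms for s in sets]) if sets else np.asarray([], dtype=object),
        np.concatenate([s.starts for s in sets]),
        np.concatenate([s.ends for s in sets]),
    )


# ---------------------------------------------------------------------------
# I/O


def read_fragments(
    path,
    format: str = "bedpe",
    condition: str = "",
    replicate: str = "",
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[FragmentSet, dict[str, int]]:
    """Read fragments from BEDPE or a 3-column fragment TSV.

    BEDPE rows give both mates; the fragment is the outer span
    ``[min(start1, start2), max(end1, end2))`` and requires both mates on
    the same chromosome — inter-chromosomal pairs are skipped and counted.
    Fragments longer than ``max_length`` (QC bound against chimeric pairs)
    are dropped and counted. Returns ``(fragment_set, report)`` where the
    report holds ``kept`` / ``skipped_interchrom`` / ``dropped_long``.
    """
    if format not in ("bedpe", "fragments_tsv"):
        raise ValueError(f"unknown fragment format {format!r}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    skipped_interchrom = 0
    dropped_long = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if format == "bedpe":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
                c1, c2 = fields[0], fields[3]
                try:
                    s1, e1, s2, e2 = (int(fields[i]) for i in (1, 2, 4, 5))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
                if e1 <= s1 or e2 <= s2:
                    raise ValueError(f"{path}:{lineno}: mate end <= start")
                if c1 != c2:
                    skipped_interchrom += 1
                    continue
                chrom, start, end = c1, min(s1, s2), max(e1, e2)
            else:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: fragment TSV needs >= 3 columns")
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: end <= start")
            if end - start > max_length:
                dropped_long += 1
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    fragset = FragmentSet(
        condition,
        replicate,
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )
    report = {
        "kept": fragset.n,
        "skipped_interchrom": skipped_interchrom,
        "dropped_long": dropped_long,
    }
    return fragset, report


def write_fragments_tsv(fragset: FragmentSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for c, s, e in zip(fragset.chroms, fragset.starts, fragset.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Classification


def classify_wrapping(
    length_bp: int, boundaries: tuple[int, int] = DEFAULT_BOUNDARIES
) -> WrappingClass:
    """Map one fragment length to its wrapping class.

    ``length < low`` is UNWRAPPED, ``low <= length <= high`` PARTIAL,
    ``length > high`` FULL. Non-positive lengths are an error.
    """
    if length_bp < 1:
        raise ValueError(f"fragment length must be >= 1, got {length_bp}")
    low, high = boundaries
    if length_bp < low:
        return WrappingClass.UNWRAPPED
    if length_bp <= high:
        return WrappingClass.PARTIAL
    return WrappingClass.FULL


def classify_lengths(
    lengths: np.ndarray, boundaries: tuple[int, int] = DEFAULT_BOUNDARIES
) -> np.ndarray:
    """Vectorised wrapping classification; returns an object array of WrappingClass."""
    lengths = np.asarray(lengths)
    if len(lengths) and lengths.min() < 1:
        raise ValueError("fragment lengths must be >= 1")
    low, high = boundaries
    out = np.empty(len(lengths), dtype=object)
    out[lengths < low] = WrappingClass.UNWRAPPED
    out[(lengths >= low) & (lengths <= high)] = WrappingClass.PARTIAL
    out[lengths > high] = WrappingClass.FULL
    return out


def partition_by_class(
    fragset: FragmentSet, boundaries: tuple[int, int] = DEFAULT_BOUNDARIES
) -> dict[WrappingClass, FragmentSet]:
    """Split a fragment set into the three wrapping classes (a true partition)."""
    lengths = fragset.lengths
    low, high = boundaries
    masks = {
        WrappingClass.UNWRAPPED: lengths < low,
        WrappingClass.PARTIAL: (lengths >= low) & (lengths <= high),
        WrappingClass.FULL: lengths > high,
    }
    return {cls: fragset.take(mask) for cls, mask in masks.items()}


def filter_by_regions(fragset: FragmentSet, regions: Sequence[GenomicInterval]) -> FragmentSet:
    """Keep fragments overlapping >= 1 bp of any region, each counted once."""
    if fragset.n == 0 or not regions:
        return fragset.take(np.zeros(fragset.n, dtype=bool))
    index = RegionIndex(regions)
    keep = index.overlaps_arrays(fragset.chroms, fragset.starts, fragset.ends)
    return fragset.take(keep)


# ---------------------------------------------------------------------------
# Depth matching


def derive_subseed(master_seed: int, condition: str, replicate: str) -> int:
    """Deterministic, platform-stable sub-seed for one (condition, replicate).

    blake2b of ``"{master}|{condition}|{replicate}"`` reduced to 31 bits, so
    every stochastic stream is reproducible from the master seed alone.
    """
    digest = hashlib.blake2b(
        f"{master_seed}|{condition}|{replicate}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def subsample_to_depth(
    fragsets: Sequence[FragmentSet], seed: int, target: int | None = None
) -> list[FragmentSet]:
    """Subsample each set to exactly ``target`` fragments without replacement.

    ``target`` defaults to the smallest input depth, so every output has the
    same exact count. Sub-seeds are derived per (condition, replicate) from
    the master seed, keeping selections reproducible and independent across
    sets.
    """
    if not fragsets:
        raise ValueError("no fragment sets given")
    if target is None:
        target = min(s.n for s in fragsets)
    out = []
    for s in fragsets:
        if target > s.n:
            raise ValueError(
                f"target depth {target} exceeds set "
                f"{s.condition}/{s.replicate} with {s.n} fragments"
            )
        rng = np.random.default_rng(derive_subseed(seed, s.condition, s.replicate))
        idx = np.sort(rng.choice(s.n, size=target, replace=False))
        out.append(s.take(idx))
    return out


def count_fragments_per_region(
    fragset: FragmentSet, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Number of fragments overlapping each region by >= 1 bp.

    A fragment spanning several regions is counted in each of them.
    """
    out = np.zeros(len(regions), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(fragset.chroms.tolist()):
        mask = fragset.chroms == chrom
        by_chrom[chrom] = (
            np.sort(fragset.starts[mask]),
            np.sort(fragset.ends[mask]),
        )
    for i, iv in enumerate(regions):
        if iv.chrom not in by_chrom:
            continue
        starts_sorted, ends_sorted = by_chrom[iv.chrom]
        # overlap <=> start < region_end and end > region_start
        n_start_before_end = np.searchsorted(starts_sorted, iv.end, side="left")
        n_end_at_or_before_start = np.searchsorted(ends_sorted, iv.start, side="right")
        out[i] = n_start_before_end - n_end_at_or_before_start
    return out


def assign_unique_region(
    fragset: FragmentSet, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Index of the leftmost overlapping region per fragment (-1 if none).

    "Leftmost" means smallest region start (ties by input order). This
    deterministic single assignment is used where per-region counts must
    conserve the total fragment count. Works for overlapping regions: with
    regions sorted by start, the first position where the running maximum
    of ends exceeds the fragment start is the leftmost possible overlap,
    and every region left of it ends at or before the fragment start.
    """
    assign = np.full(fragset.n, -1, dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in regions}:
        idx = np.asarray([i for i, iv in enumerate(regions) if iv.chrom == chrom])
        starts = np.asarray([regions[i].start for i in idx], dtype=np.int64)
        ends = np.asarray([regions[i].end for i in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        by_chrom[chrom] = (
            starts[order],
            np.maximum.accumulate(ends[order]),
            idx[order],
        )
    for chrom in set(fragset.chroms.tolist()):
        if chrom not in by_chrom:
            continue
        rs, cummax_ends, orig = by_chrom[chrom]
        mask = fragset.chroms == chrom
        fs = fragset.starts[mask]
        fe = fragset.ends[mask]
        j = np.searchsorted(cummax_ends, fs, side="right")
        valid = j < len(rs)
        jj = np.clip(j, 0, len(rs) - 1)
        hit = valid & (rs[jj] < fe)
        assign[mask] = np.where(hit, orig[jj], -1)
    return assign


def length_histogram(fragset: FragmentSet, max_len: int) -> np.ndarray:
    """Per-bp length counts in ``[1, max_len]``; longer fragments pool at ``max_len``.

    Index 0 is unused (lengths are >= 1) so ``hist[L]`` is the count at L bp.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    hist = np.zeros(max_len + 1, dtype=np.int64)
    if fragset.n:
        clipped = np.minimum(fragset.lengths, max_len)
        np.add.at(hist, clipped, 1)
    return hist
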