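"""Nucleosome wrapping-state comparison between conditions.

The headline analysis: given per-condition replicate fragment sets from an
H2A.Z-style chromatin profiling experiment, quantify how the composition of
sub-nucleosomal (unwrapped), partially unwrapped, and fully wrapped
fragments changes at promoters between a test condition and a reference.

Pipeline order:

1. pool replicates per condition;
2. restrict to promoter windows;
3. depth-match conditions by exact subsampling, so later per-class
   differences are composition effects, not sequencing depth;
4. partition by wrapping class;
5. raw (unnormalised) binned coverage per class per condition;
6. per-bin log2 ratio tracks (test vs reference) per class, for browsing;
7. promoter meta-profiles per class per condition, combined into a
   per-position log2 fold-change profile;
8. per-promoter per-class fragment counts per condition.

Step 7 takes the log2 ratio of the promoter-averaged coverage profiles
(average-then-log, small pseudocount) rather than averaging the per-bin
log2 track of step 6: at depths where individual 10 bp bins hold only a
handful of fragments, log-then-average is dominated by the pseudocount and
systematically understates fold changes, while the promoter-averaged
profile estimates per-class coverage precisely before the ratio is taken.

The module also houses the one-sided Wilcoxon rank-sum machinery and the
asterisk coding (* < 0.01, ** < 0.001, *** < 0.0001) used by every boxplot
in the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .fragments import (
    DEFAULT_BOUNDARIES,
    FragmentSet,
    WRAPPING_CLASSES,
    WrappingClass,
    assign_unique_region,
    filter_by_regions,
    merge_fragment_sets,
    partition_by_class,
    subsample_to_depth,
)
from .genome import GeneRecord, Genome, GenomicInterval
from .metaprofiles import Anchor, mean_profile, reference_point_matrix
from .tracks import CoverageTrack, compare_tracks_log2, coverage_track


@dataclass
class WrapConfig:
    """Parameters of one wrapping-state run. ``seed`` is mandatory."""

    seed: int
    boundaries: tuple[int, int] = DEFAULT_BOUNDARIES
    flank: int = 1000  # promoter half-width around the TSS, bp
    bin_size: int = 10
    track_pseudocount: float = 1.0  # for the exported per-bin log2 tracks
    profile_pseudocount: float = 0.001  # for the averaged-profile log2 ratio
    count_pseudocount: float = 1.0  # for per-region count log2FC
    target_depth: int | None = None  # None = min over conditions

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("WrapConfig.seed is required")
        low, high = self.boundaries
        if not 0 < low <= high:
            raise ValueError(f"bad class boundaries {self.boundaries}")
        for name in ("flank", "bin_size", "track_pseudocount", "profile_pseudocount", "count_pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WrappingProfile:
    """Per-class log2 fold-change around the TSS for one condition pair."""

    offsets: np.ndarray  # bp relative to TSS, bin centers
    log2fc: dict[WrappingClass, np.ndarray]
    test: str
    reference: str
    bin_width: int

    def __post_init__(self):
        lengths = {len(v) for v in self.log2fc.values()}
        if len(lengths) != 1 or lengths != {len(self.offsets)}:
            raise ValueError("profile arrays must share one length")


@dataclass
class WrappingResult:
    reference: str
    depth: int  # matched fragment count per condition
    class_tracks: dict[tuple[str, WrappingClass], CoverageTrack]
    log2fc_tracks: dict[tuple[str, WrappingClass], CoverageTrack]
    profiles: dict[str, WrappingProfile]
    counts: pd.DataFrame  # index: promoter id; columns: (condition, class name)


def wrapping_pipeline(
    fragsets_by_condition: Mapping[str, Sequence[FragmentSet]],
    promoters: Sequence[GenomicInterval],
    genome: Genome,
    reference: str,
    config: WrapConfig,
) -> WrappingResult:
    """Run the full wrapping-state comparison; see the module docstring.

    ``promoters`` carry strand and (gene) name; their midpoints are the TSS
    anchors for the meta-profile, which assumes symmetric flanks. Every
    condition other than ``reference`` yields a profile and log2 tracks
    against the reference.
    """
    if reference not in fragsets_by_condition:
        raise ValueError(f"reference condition {reference!r} missing from inputs")
    if len(fragsets_by_condition) < 2:
        raise ValueError("need at least two conditions")
    if not promoters:
        raise ValueError("empty promoter set")

    # 1-2: pool replicates, restrict to promoters
    pooled: dict[str, FragmentSet] = {}
    for cond, sets in fragsets_by_condition.items():
        if not sets:
            raise ValueError(f"condition {cond!r} has no replicate fragment sets")
        merged = merge_fragment_sets(list(sets), condition=cond)
        at_prom = filter_by_regions(merged, promoters)
        if at_prom.n == 0:
            raise ValueError(f"condition {cond!r} has no fragments over promoters")
        pooled[cond] = at_prom

    # 3: exact depth matching
    conds = list(pooled)
    matched = subsample_to_depth([pooled[c] for c in conds], seed=config.seed,
                                 target=config.target_depth)
    matched_by_cond = dict(zip(conds, matched))
    depth = matched[0].n

    # 4-5: class partition and raw coverage
    class_tracks: dict[tuple[str, WrappingClass], CoverageTrack] = {}
    parts_by_cond: dict[str, dict[WrappingClass, FragmentSet]] = {}
    for cond, fs in matched_by_cond.items():
        parts = partition_by_class(fs, config.boundaries)
        parts_by_cond[cond] = parts
        for cls, part in parts.items():
            class_tracks[(cond, cls)] = coverage_track(
                part, genome, bin_size=config.bin_size, normalization="raw"
            )

    # 6: per-bin log2 ratio tracks for each test condition
    log2fc_tracks: dict[tuple[str, WrappingClass], CoverageTrack] = {}
    for cond in conds:
        if cond == reference:
            continue
        for cls in WRAPPING_CLASSES:
            log2fc_tracks[(cond, cls)] = compare_tracks_log2(
                class_tracks[(cond, cls)],
                class_tracks[(reference, cls)],
                pseudocount=config.track_pseudocount,
            )

    # 7: promoter-averaged per-class profiles, then log2 ratio
    anchors = [
        Anchor(p.name or f"promoter_{i}", p.chrom, p.midpoint, p.strand)
        for i, p in enumerate(promoters)
    ]
    mean_by_cond_class: dict[tuple[str, WrappingClass], np.ndarray] = {}
    offsets = None
    for (cond, cls), track in class_tracks.items():
        mat = reference_point_matrix(
            track, anchors, config.flank, config.flank, config.bin_size
        )
        mean_by_cond_class[(cond, cls)] = mean_profile(mat)
        offsets = mat.offsets()
    profiles: dict[str, WrappingProfile] = {}
    pc = config.profile_pseudocount
    for cond in conds:
        if cond == reference:
            continue
        log2fc = {
            cls: np.log2(
                (mean_by_cond_class[(cond, cls)] + pc)
                / (mean_by_cond_class[(reference, cls)] + pc)
            )
            for cls in WRAPPING_CLASSES
        }
        profiles[cond] = WrappingProfile(offsets, log2fc, cond, reference, config.bin_size)

    # 8: per-promoter per-class counts (unique leftmost assignment conserves depth)
    region_ids = [a.region_id for a in anchors]
    columns = pd.MultiIndex.from_product(
        [conds, [str(c) for c in WRAPPING_CLASSES]], names=["condition", "wrapping_class"]
    )
    counts = pd.DataFrame(0, index=pd.Index(region_ids, name="region"), columns=columns)
    for cond in conds:
        fs = matched_by_cond[cond]
        assign = assign_unique_region(fs, list(promoters))
        lengths = fs.lengths
        low, high = config.boundaries
        cls_code = np.where(lengths < low, 0, np.where(lengths <= high, 1, 2))
        for code, cls in enumerate(WRAPPING_CLASSES):
            sel = assign[cls_code == code]
            binc = np.bincount(sel[sel >= 0], minlength=len(region_ids))
            counts[(cond, str(cls))] = binc
    return WrappingResult(
        reference=reference,
        depth=depth,
        class_tracks=class_tracks,
        log2fc_tracks=log2fc_tracks,
        profiles=profiles,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Rank-sum machinery and boxplot statistics


def wilcoxon_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str, method: str = "auto"
) -> float:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``alternative='greater'`` tests whether x tends larger than y. With
    ``method='auto'`` the exact permutation distribution is used when
    ``len(x) + len(y) <= 16`` and there are no ties, else a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction. ``method`` may be forced to ``'exact'`` or ``'normal'``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("wilcoxon_one_sided: both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if method == "auto":
        combined = np.concatenate([x, y])
        tie_free = len(np.unique(combined)) == len(combined)
        method = "exact" if (len(combined) <= 16 and tie_free) else "normal"
    if method == "exact":
        res = _stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
    elif method == "normal":
        res = _stats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Asterisk code: *** < 1e-4, ** < 1e-3, * < 1e-2, else ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


def wrapping_boxplot_stats(
    counts: pd.DataFrame,
    test_condition: str,
    reference_condition: str,
    alternative: str = "greater",
    pseudocount: float = 1.0,
) -> dict[WrappingClass, dict | None]:
    """Per-class region-level log2FC distribution with a one-sided rank-sum test.

    ``counts`` is the WrappingCounts frame (regions x (condition, class)).
    For every class, the per-region ``log2((test + pc) / (ref + pc))``
    values feed the boxplot; the p-value compares the per-region test and
    reference count vectors as two samples. A class with zero counts
    everywhere in both conditions yields ``None`` with a warning.
    """
    for cond in (test_condition, reference_condition):
        if cond not in counts.columns.get_level_values("condition"):
            raise ValueError(f"condition {cond!r} absent from counts")
    out: dict[WrappingClass, dict | None] = {}
    for cls in WRAPPING_CLASSES:
        t = counts[(test_condition, str(cls))].to_numpy(dtype=np.float64)
        r = counts[(reference_condition, str(cls))].to_numpy(dtype=np.float64)
        if t.sum() == 0 and r.sum() == 0:
            warnings.warn(f"wrapping class {cls} has no fragments in either condition")
            out[cls] = None
            continue
        log2fc = np.log2((t + pseudocount) / (r + pseudocount))
        p = wilcoxon_one_sided(t, r, alternative=alternative)
        out[cls] = {
            "log2fc": log2fc,
            "p": p,
            "stars": significance_stars(p),
            "n": len(log2fc),
        }
    return out


def welch_t_one_sided(x: Sequence[float], y: Sequence[float], alternative: str) -> float:
    """Welch two-sample t-test p-value, one-sided; alternative as in the rank-sum."""
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    res = _stats.ttest_ind(
        np.asarray(x, dtype=np.float64),
        np.asarray(y, dtype=np.float64),
        equal_var=False,
        alternative=alternative,
    )
    return float(res.pvalue)
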