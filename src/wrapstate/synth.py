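"""Ground-truth synthetic data: fragments with class-structured lengths,
promoter-localised enrichment, and replicate intensity tables.

The generator emulates the statistical structure the downstream analyses
assume about antibody-directed tagmentation data at promoters:

* a genome of equal-length chromosomes with genes placed at a minimum
  spacing, strands Bernoulli(0.5);
* per condition, fragment lengths drawn from a three-component mixture —
  sub-nucleosomal, partially unwrapped, fully wrapped — with
  condition-specific mixing weights;
* promoter-localised positional enrichment: each fragment is promoter or
  background by an enrichment-weighted Bernoulli; promoter fragments pick
  an occupied promoter uniformly and place their midpoint Normal(TSS +
  class offset, spread) along the gene direction; background midpoints are
  uniform over the genome;
* class-conditional length distributions truncated strictly inside the
  class boundaries, so every emitted fragment classifies back to the class
  it was drawn from:
  UNWRAPPED = round Normal(70, 15) on [30, 99],
  PARTIAL   = uniform integer [100, 150],
  FULL      = round Normal(185, 20) on [151, 400];
* replicate protein-intensity tables with planted enriched interactors and
  replicate count matrices with planted fold changes, for the proteomics
  and differential-binding stages.

Every stochastic draw descends deterministically from the master seed via
a blake2b hash of (seed, condition, replicate), so the full dataset — and
each written file — is byte-reproducible from the truth manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chipms import IntensityTable
from .differential import CountMatrix
from .fragments import FragmentSet, derive_subseed
from .genome import (
    GeneRecord,
    Genome,
    GenomicInterval,
    promoters_from_genes,
    write_bed,
    write_genes,
)

CLASS_NAMES = ("unwrapped", "partial", "full")
LENGTH_MODELS = {
    "unwrapped": {"kind": "round_normal", "mean": 70.0, "sd": 15.0, "lo": 30, "hi": 99},
    "partial": {"kind": "uniform_int", "lo": 100, "hi": 150},
    "full": {"kind": "round_normal", "mean": 185.0, "sd": 20.0, "lo": 151, "hi": 400},
}
OCCUPANCY_LABELS = ("co-bound", "A-only", "B-only", "unbound")


@dataclass
class ConditionSpec:
    """Per-condition generator parameters.

    weights: (unwrapped, partial, full) mixing weights, summing to 1.
    enrichment: promoter enrichment multiplier (odds of a promoter fragment
    relative to the promoter share of the genome).
    offsets_bp: per-class midpoint offset downstream of the TSS, bp (signed,
    applied along gene direction).
    spread_bp: positional SD of promoter fragment midpoints around TSS+offset.
    """

    weights: tuple[float, float, float]
    enrichment: float = 8.0
    offsets_bp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spread_bp: float = 300.0

    def __post_init__(self):
        w = tuple(float(v) for v in self.weights)
        if len(w) != 3 or any(v < 0 for v in w):
            raise ValueError("weights must be three non-negative numbers")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixing weights must sum to 1, got {sum(w)!r}")
        self.weights = w
        self.offsets_bp = tuple(float(v) for v in self.offsets_bp)
        if self.enrichment <= 0 or self.spread_bp <= 0:
            raise ValueError("enrichment and spread_bp must be positive")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a dataset, including every seed."""

    master_seed: int
    n_chrom: int
    chrom_length: int
    n_genes: int
    min_spacing: int
    promoter_flank: int
    conditions: dict[str, ConditionSpec]
    n_replicates: int
    n_fragments_per_replicate: int
    occupancy: list[str] = field(default_factory=list)  # per-gene labels

    def genome(self) -> Genome:
        return make_genome(self.n_chrom, self.chrom_length)

    def genes(self) -> list[GeneRecord]:
        return make_genes(
            self.genome(), self.n_genes, self.min_spacing, derive_subseed(self.master_seed, "genes", "")
        )

    def promoters(self) -> list[GenomicInterval]:
        return promoters_from_genes(self.genes(), self.promoter_flank, self.genome())

    def replicate_seed(self, condition: str, replicate: str) -> int:
        return derive_subseed(self.master_seed, condition, replicate)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = {k: asdict(v) for k, v in self.conditions.items()}
        d["replicate_seeds"] = {
            f"{cond}/rep{r}": self.replicate_seed(cond, f"rep{r}")
            for cond in self.conditions
            for r in range(1, self.n_replicates + 1)
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d.pop("replicate_seeds", None)
        d["conditions"] = {
            k: ConditionSpec(
                weights=tuple(v["weights"]),
                enrichment=v["enrichment"],
                offsets_bp=tuple(v["offsets_bp"]),
                spread_bp=v["spread_bp"],
            )
            for k, v in d["conditions"].items()
        }
        return cls(**d)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Round-trippable JSON manifest with every seed and parameter."""
    with open(path, "wt") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Genome and gene placement


def make_genome(n_chrom: int, chrom_length: int, seed: int | None = None) -> Genome:
    """Deterministic genome: chr1..chrN of one fixed length each."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000 bp")
    return Genome([(f"chr{i + 1}", chrom_length) for i in range(n_chrom)])


def make_genes(
    genome: Genome, n_genes: int, min_spacing: int, seed: int
) -> list[GeneRecord]:
    """Place TSS positions >= ``min_spacing`` apart, strands Bernoulli(0.5).

    Genes are spread across chromosomes proportionally. Placement keeps a
    margin of ``min_spacing`` from chromosome ends so promoter windows and
    fragments never clip. Infeasible requests raise.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.asarray([genome[c] for c in names], dtype=np.float64)
    shares = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in range(n_genes - shares.sum()):  # distribute the remainder
        shares[i % len(shares)] += 1
    genes: list[GeneRecord] = []
    gi = 0
    for chrom, k in zip(names, shares):
        if k == 0:
            continue
        lo = min_spacing
        hi = genome[chrom] - min_spacing
        span = (hi - lo) - (k - 1) * min_spacing
        if span < 0:
            raise ValueError(
                f"cannot place {k} genes {min_spacing} bp apart on {chrom} "
                f"({genome[chrom]} bp)"
            )
        jitter = np.sort(rng.uniform(0, span, size=k))
        tss = (lo + jitter + np.arange(k) * min_spacing).astype(np.int64)
        strands = np.where(rng.random(k) < 0.5, "+", "-")
        for t, s in zip(tss, strands):
            gi += 1
            genes.append(GeneRecord(f"gene_{gi:05d}", chrom, int(t), str(s)))
    return genes


# ---------------------------------------------------------------------------
# Fragment sampling


def _draw_lengths(rng: np.random.Generator, model: dict, size: int) -> np.ndarray:
    if model["kind"] == "uniform_int":
        return rng.integers(model["lo"], model["hi"] + 1, size=size)
    vals = np.rint(rng.normal(model["mean"], model["sd"], size=size)).astype(np.int64)
    bad = (vals < model["lo"]) | (vals > model["hi"])
    while bad.any():  # strict truncation by redraw
        vals[bad] = np.rint(
            rng.normal(model["mean"], model["sd"], size=int(bad.sum()))
        ).astype(np.int64)
        bad = (vals < model["lo"]) | (vals > model["hi"])
    return vals


def sample_fragments(
    truth: SyntheticTruth,
    condition: str,
    replicate: str,
    n_fragments: int | None = None,
    seed: int | None = None,
) -> FragmentSet:
    """Draw one replicate's fragments for one condition.

    Fully reproducible from (master seed, condition, replicate); an explicit
    ``seed`` overrides the derived one. Fragments are clamped to lie wholly
    inside their chromosome, preserving the drawn length (and therefore the
    drawn class).
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    spec = truth.conditions[condition]
    n = truth.n_fragments_per_replicate if n_fragments is None else int(n_fragments)
    if n < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(
        truth.replicate_seed(condition, replicate) if seed is None else seed
    )
    genome = truth.genome()
    genes = truth.genes()
    occupancy = truth.occupancy or ["co-bound"] * len(genes)
    occupied = [g for g, lab in zip(genes, occupancy) if lab != "unbound"]
    if not occupied:
        raise ValueError("no occupied promoters to sample from")

    # promoter/background split: enrichment-weighted odds on the promoter
    # share of the genome
    f_prom = min(
        1.0, 2 * truth.promoter_flank * len(occupied) / genome.total_length()
    )
    p_prom = spec.enrichment * f_prom / (spec.enrichment * f_prom + (1 - f_prom))

    classes = rng.choice(3, size=n, p=np.asarray(spec.weights))
    is_prom = rng.random(n) < p_prom
    lengths = np.empty(n, dtype=np.int64)
    for code, name in enumerate(CLASS_NAMES):
        mask = classes == code
        lengths[mask] = _draw_lengths(rng, LENGTH_MODELS[name], int(mask.sum()))

    chroms = np.empty(n, dtype=object)
    midpoints = np.empty(n, dtype=np.float64)

    # promoter fragments
    k = int(is_prom.sum())
    if k:
        gene_idx = rng.integers(0, len(occupied), size=k)
        tss = np.asarray([g.tss for g in occupied], dtype=np.float64)[gene_idx]
        strand_sign = np.asarray(
            [1.0 if g.strand == "+" else -1.0 for g in occupied], dtype=np.float64
        )[gene_idx]
        offsets = np.asarray(spec.offsets_bp, dtype=np.float64)[classes[is_prom]]
        midpoints[is_prom] = tss + strand_sign * offsets + rng.normal(
            0.0, spec.spread_bp, size=k
        )
        chroms[is_prom] = np.asarray([g.chrom for g in occupied], dtype=object)[gene_idx]

    # background fragments: uniform over the genome
    m = n - k
    if m:
        names = genome.names
        lens = np.asarray([genome[c] for c in names], dtype=np.float64)
        ci = rng.choice(len(names), size=m, p=lens / lens.sum())
        midpoints[~is_prom] = rng.uniform(0, lens[ci])
        chroms[~is_prom] = np.asarray(names, dtype=object)[ci]

    # assemble, clamping the midpoint so the whole fragment stays on-chromosome
    chrom_len = np.asarray([genome[str(c)] for c in chroms], dtype=np.int64)
    half_lo = lengths // 2
    half_hi = lengths - half_lo
    mid = np.clip(np.rint(midpoints).astype(np.int64), half_lo, chrom_len - half_hi)
    starts = mid - half_lo
    ends = mid + half_hi
    return FragmentSet(condition, replicate, chroms, starts, ends)


def write_bedpe(fragset: FragmentSet, path, read_length: int = 50) -> None:
    """Write fragments as BEDPE mate pairs.

    Mates are the outer ``read_length`` bp of the fragment (whole fragment
    when shorter), so reading the file back reconstructs the fragment span
    losslessly.
    """
    with open(path, "wt") as fh:
        for i, (c, s, e) in enumerate(zip(fragset.chroms, fragset.starts, fragset.ends)):
            m1e = min(s + read_length, e)
            m2s = max(e - read_length, s)
            fh.write(f"{c}\t{s}\t{m1e}\t{c}\t{m2s}\t{e}\tfrag_{i}\t.\t+\t-\n")


# ---------------------------------------------------------------------------
# Proteomics and count-matrix fixtures


def sample_intensity_table(
    n_proteins: int,
    n_planted: int,
    fold: float,
    noise_sd: float,
    replicates: int,
    seed: int,
    base_log2: float = 20.0,
) -> tuple[IntensityTable, list[str]]:
    """Replicate intensity tables with planted bait-enriched proteins.

    log2 intensities are Normal(base, noise_sd); the first ``n_planted``
    proteins gain +log2(fold) in the bait group. Returns the table and the
    planted protein ids.
    """
    if n_planted > n_proteins:
        raise ValueError("n_planted cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    planted = proteins[:n_planted]
    samples = [f"bait/rep{r + 1}" for r in range(replicates)] + [
        f"control/rep{r + 1}" for r in range(replicates)
    ]
    log2i = rng.normal(base_log2, noise_sd, size=(n_proteins, 2 * replicates))
    log2i[:n_planted, :replicates] += np.log2(fold)
    design = pd.DataFrame(
        {
            "group": ["bait"] * replicates + ["control"] * replicates,
            "replicate": [f"rep{r + 1}" for r in range(replicates)] * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    table = IntensityTable(
        pd.DataFrame(2.0**log2i, index=pd.Index(proteins, name="protein"), columns=samples),
        design,
    )
    return table, planted


def sample_count_matrix(
    n_regions: int,
    planted_frac: float,
    lfc: float,
    noise_sd: float,
    replicates: int,
    seed: int,
    library_size: int = 1_000_000,
    base_log2cpm: tuple[float, float] = (4.0, 8.0),
) -> tuple[CountMatrix, list[str]]:
    """Replicate region-count matrices with planted log2 fold changes.

    Counts derive from log2 CPM values Normal(base, noise_sd) per replicate;
    planted regions (the first ``round(planted_frac * n_regions)``) gain
    ``lfc`` in the test condition. Returns the matrix and planted region ids.
    """
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_frac * n_regions))
    regions = [f"region_{i + 1:05d}" for i in range(n_regions)]
    base = rng.uniform(*base_log2cpm, size=n_regions)
    samples = [f"test/rep{r + 1}" for r in range(replicates)] + [
        f"ref/rep{r + 1}" for r in range(replicates)
    ]
    log2cpm = base[:, None] + rng.normal(0.0, noise_sd, size=(n_regions, 2 * replicates))
    log2cpm[:n_planted, :replicates] += lfc
    counts = np.rint(2.0**log2cpm * library_size / 1e6).astype(np.int64)
    design = pd.DataFrame(
        {
            "condition": ["test"] * replicates + ["ref"] * replicates,
            "replicate": [f"rep{r + 1}" for r in range(replicates)] * 2,
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(regions, name="region"), columns=samples),
        design,
        pd.Series(library_size, index=pd.Index(samples, name="sample"), name="library_size"),
    )
    return cm, regions[:n_planted]


# ---------------------------------------------------------------------------
# Presets and dataset generation

PRESETS = ("null", "wrap-shift", "asym", "cooccupancy")


def preset_truth(
    preset: str,
    seed: int,
    n_genes: int = 2000,
    n_replicates: int = 3,
    n_fragments_per_replicate: int = 66_667,
    n_chrom: int = 2,
    chrom_length: int = 5_000_000,
    min_spacing: int = 2500,
    promoter_flank: int = 1000,
) -> SyntheticTruth:
    """Build the truth manifest for a named study design.

    * ``null`` — two conditions with identical mixing weights (0.2, 0.3,
      0.5): every downstream per-class fold change should be ~0.
    * ``wrap-shift`` — reference (0.15, 0.35, 0.50) versus test
      (0.30, 0.35, 0.35): the unwrapped fraction doubles at the expense of
      fully wrapped fragments, emulating nucleosome destabilisation.
    * ``asym`` — identical weights, but the test condition's unwrapped
      fragments sit +250 bp downstream of the TSS, emulating preferential
      unwrapping over gene bodies.
    * ``cooccupancy`` — promoters carry co-bound / A-only / B-only /
      unbound labels for two factors, for peak-overlap analyses.
    """
    base = (0.2, 0.3, 0.5)
    if preset == "null":
        conditions = {"ref": ConditionSpec(base), "test": ConditionSpec(base)}
        occupancy = []
    elif preset == "wrap-shift":
        conditions = {
            "ref": ConditionSpec((0.15, 0.35, 0.50)),
            "test": ConditionSpec((0.30, 0.35, 0.35)),
        }
        occupancy = []
    elif preset == "asym":
        conditions = {
            "ref": ConditionSpec(base),
            "test": ConditionSpec(base, offsets_bp=(250.0, 0.0, 0.0)),
        }
        occupancy = []
    elif preset == "cooccupancy":
        conditions = {"ref": ConditionSpec(base), "test": ConditionSpec(base)}
        rng = np.random.default_rng(derive_subseed(seed, "occupancy", ""))
        occupancy = list(
            rng.choice(OCCUPANCY_LABELS, size=n_genes, p=[0.4, 0.2, 0.2, 0.2])
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    return SyntheticTruth(
        master_seed=seed,
        n_chrom=n_chrom,
        chrom_length=chrom_length,
        n_genes=n_genes,
        min_spacing=min_spacing,
        promoter_flank=promoter_flank,
        conditions=conditions,
        n_replicates=n_replicates,
        n_fragments_per_replicate=n_fragments_per_replicate,
        occupancy=[str(x) for x in occupancy],
    )


def weight_shift_truth(delta: float, seed: int, **kwargs) -> SyntheticTruth:
    """Truth with the unwrapped weight shifted by ``delta`` in the test
    condition (compensated on the fully wrapped class), from base
    (0.2, 0.3, 0.5)."""
    if not -0.2 < delta < 0.5:
        raise ValueError("delta must keep all weights positive")
    truth = preset_truth("null", seed, **kwargs)
    truth.conditions["test"] = ConditionSpec((0.2 + delta, 0.3, 0.5 - delta))
    return truth


def cooccupancy_peaks(
    truth: SyntheticTruth, seed: int, peak_halfwidth: int = 250
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Two factor peak sets realising the truth's promoter occupancy labels.

    Factor A peaks sit at co-bound and A-only promoters, factor B at
    co-bound and B-only promoters (small jittered centers), and each set
    gains 20% decoy peaks placed uniformly at random.
    """
    genes = truth.genes()
    occupancy = truth.occupancy or ["co-bound"] * len(genes)
    genome = truth.genome()
    rng = np.random.default_rng(derive_subseed(seed, "cooccupancy-peaks", ""))

    def peaks_for(labels: set[str], tag: str) -> list[GenomicInterval]:
        out = []
        for g, lab in zip(genes, occupancy):
            if lab not in labels:
                continue
            center = g.tss + int(rng.integers(-50, 51))
            out.append(
                GenomicInterval(
                    g.chrom,
                    max(0, center - peak_halfwidth),
                    min(genome[g.chrom], center + peak_halfwidth),
                    name=f"{tag}_{g.gene_id}",
                )
            )
        n_decoy = max(1, len(out) // 5)
        names = genome.names
        lens = np.asarray([genome[c] for c in names], dtype=np.float64)
        ci = rng.choice(len(names), size=n_decoy, p=lens / lens.sum())
        for i, c in enumerate(ci):
            start = int(rng.integers(0, genome[names[c]] - 2 * peak_halfwidth))
            out.append(
                GenomicInterval(
                    names[c], start, start + 2 * peak_halfwidth, name=f"{tag}_decoy_{i}"
                )
            )
        return out

    return peaks_for({"co-bound", "A-only"}, "A"), peaks_for({"co-bound", "B-only"}, "B")


def generate_dataset(truth: SyntheticTruth, out_dir) -> dict[str, object]:
    """Materialise a full dataset on disk: genome, genes, promoters,
    per-(condition, replicate) BEDPE files, and the truth manifest.

    Returns a manifest dict of the written paths plus the in-memory
    fragment sets keyed by condition.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = truth.genome()
    genes = truth.genes()
    promoters = truth.promoters()
    genome.to_chrom_sizes(out / "genome.chrom.sizes")
    write_genes(genes, out / "genes.tsv")
    write_bed(promoters, out / "promoters.bed")
    write_truth(truth, out / "truth.json")
    fragsets: dict[str, list[FragmentSet]] = {}
    paths: dict[str, str] = {
        "chrom_sizes": str(out / "genome.chrom.sizes"),
        "genes": str(out / "genes.tsv"),
        "promoters": str(out / "promoters.bed"),
        "truth": str(out / "truth.json"),
    }
    for cond in truth.conditions:
        fragsets[cond] = []
        for r in range(1, truth.n_replicates + 1):
            rep = f"rep{r}"
            fs = sample_fragments(truth, cond, rep)
            path = out / f"fragments_{cond}_{rep}.bedpe"
            write_bedpe(fs, path)
            fragsets[cond].append(fs)
            paths[f"bedpe:{cond}/{rep}"] = str(path)
    return {"paths": paths, "fragsets": fragsets, "genome": genome,
            "genes": genes, "promoters": promoters}
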