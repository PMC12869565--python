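"""Config-driven orchestration: synthetic data -> wrapping / co-occupancy /
differential analyses, with a deterministic run report.

A :class:`RunConfig` collects every tunable the stages need — promoter
flank (default TSS ± 1 kb), peak-anchor flank (± 3 kb), summary window
(± 200 bp), class boundaries (100/150 bp), bin size (10 bp), pseudocounts,
differential thresholds (|log2FC| > 0.5, padj < 0.05), the random-region
null (55,000 × 250 bp), and the master seed. Reruns with the same config
produce byte-identical numeric outputs: the config hash and every derived
seed go into the run report, and no timestamps enter numeric files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .differential import differential_binding, promoter_counts, volcano_table
from .fragments import derive_subseed
from .genome import fisher_overlap, intersect_classify, write_bed
from .metaprofiles import write_profile_tsv
from .synth import (
    PRESETS,
    cooccupancy_peaks,
    generate_dataset,
    preset_truth,
)
from .tracks import write_bedgraph
from .wrapping import WrapConfig, wrapping_boxplot_stats, wrapping_pipeline


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    preset: str = "null"
    n_genes: int = 2000
    n_replicates: int = 3
    n_fragments_per_replicate: int = 66_667
    promoter_flank: int = 1000
    peak_flank: int = 3000
    summary_window: int = 200
    boundaries: tuple[int, int] = (100, 150)
    bin_size: int = 10
    track_pseudocount: float = 1.0
    profile_pseudocount: float = 0.001
    count_pseudocount: float = 1.0
    lfc_thresh: float = 0.5
    alpha: float = 0.05
    n_random: int = 55_000
    random_length: int = 250

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        positives = (
            "n_genes n_replicates n_fragments_per_replicate promoter_flank "
            "peak_flank summary_window bin_size track_pseudocount "
            "profile_pseudocount count_pseudocount lfc_thresh n_random random_length"
        ).split()
        for name in positives:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must lie in (0, 1]")
        low, high = self.boundaries
        if not 0 < low <= high:
            raise ConfigError(f"bad class boundaries {self.boundaries}")
        if self.seed is None or int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "boundaries" in data:
            data["boundaries"] = tuple(data["boundaries"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _header_lines(config: RunConfig) -> list[str]:
    return [
        f"# wrapstate={__version__}",
        f"# config_hash={config.config_hash()}",
        f"# seed={config.seed}",
    ]


def _write_json(path, obj, config: RunConfig) -> None:
    out = {"wrapstate": __version__, "config_hash": config.config_hash(), "seed": config.seed}
    out.update(obj)
    with open(path, "wt") as fh:
        json.dump(out, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a run report.

    Wrapping presets run: generate -> wrapping pipeline -> profile TSVs,
    count table, boxplot stats JSON, per-class log2FC bedGraphs. The
    co-occupancy preset runs: generate -> peak classification -> Venn
    counts, shared/only BEDs, Fisher report, differential promoter binding.
    Returns the report dict (also written to ``run_report.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    truth = preset_truth(
        config.preset,
        config.seed,
        n_genes=config.n_genes,
        n_replicates=config.n_replicates,
        n_fragments_per_replicate=config.n_fragments_per_replicate,
        promoter_flank=config.promoter_flank,
    )
    data = generate_dataset(truth, out / "data")
    promoters = data["promoters"]
    genome = data["genome"]
    log.append(
        {
            "stage": "synth",
            "preset": config.preset,
            "n_genes": config.n_genes,
            "fragments_per_condition": config.n_replicates * config.n_fragments_per_replicate,
        }
    )

    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {
            f"{cond}/rep{r}": truth.replicate_seed(cond, f"rep{r}")
            for cond in truth.conditions
            for r in range(1, config.n_replicates + 1)
        },
    }

    if config.preset in ("null", "wrap-shift", "asym"):
        wrap_cfg = WrapConfig(
            seed=config.seed,
            boundaries=config.boundaries,
            flank=config.promoter_flank,
            bin_size=config.bin_size,
            track_pseudocount=config.track_pseudocount,
            profile_pseudocount=config.profile_pseudocount,
            count_pseudocount=config.count_pseudocount,
        )
        result = wrapping_pipeline(
            data["fragsets"], promoters, genome, reference="ref", config=wrap_cfg
        )
        log.append({"stage": "wrap", "matched_depth": result.depth})
        header = "\n".join(_header_lines(config)) + "\n"
        for cond, profile in result.profiles.items():
            path = out / f"wrapping_profile_{cond}_vs_{result.reference}.tsv"
            with open(path, "wt") as fh:
                fh.write(header)
                fh.write("offset\t" + "\t".join(str(c) for c in profile.log2fc) + "\n")
                for i, o in enumerate(profile.offsets):
                    row = "\t".join(repr(float(v[i])) for v in profile.log2fc.values())
                    fh.write(f"{o:g}\t{row}\n")
        counts_path = out / "wrapping_counts.tsv"
        with open(counts_path, "wt") as fh:
            fh.write(header)
            result.counts.to_csv(fh, sep="\t")
        for (cond, cls), track in result.log2fc_tracks.items():
            write_bedgraph(track, out / f"log2fc_{cond}_{cls}.bedgraph")
        stats = wrapping_boxplot_stats(
            result.counts, "test", "ref", alternative="greater",
            pseudocount=config.count_pseudocount,
        )
        stats_json = {
            str(cls): (
                None
                if entry is None
                else {
                    "p": entry["p"],
                    "stars": entry["stars"],
                    "n": entry["n"],
                    "mean_log2fc": float(np.mean(entry["log2fc"])),
                }
            )
            for cls, entry in stats.items()
        }
        _write_json(out / "wrapping_stats.json", {"classes": stats_json,
                                                  "matched_depth": result.depth}, config)
        report["wrapping"] = {
            "matched_depth": result.depth,
            "mean_log2fc": {
                cond: {str(cls): float(np.mean(vals)) for cls, vals in p.log2fc.items()}
                for cond, p in result.profiles.items()
            },
        }

    if config.preset == "cooccupancy":
        peaks_a, peaks_b = cooccupancy_peaks(truth, config.seed)
        classification = intersect_classify(peaks_a, peaks_b)
        write_bed(classification.a_only, out / "peaks_A_only.bed")
        write_bed(classification.shared, out / "peaks_shared.bed")
        write_bed(classification.b_only, out / "peaks_B_only.bed")
        venn = {
            "a_only": len(classification.a_only),
            "shared": len(classification.shared),
            "b_only": len(classification.b_only),
        }
        _write_json(out / "venn_counts.json", venn, config)
        fisher_rows = []
        for label, peaks in (
            ("A", peaks_a),
            ("B", peaks_b),
            ("shared", classification.shared),
        ):
            table, odds, log2_odds, p_two, p_greater = fisher_overlap(
                peaks,
                promoters,
                genome,
                n_random=config.n_random,
                random_length=config.random_length,
                seed=derive_subseed(config.seed, "fisher", label),
            )
            fisher_rows.append(
                (label, table.a, table.b, table.c, table.d, odds, log2_odds, p_two, p_greater)
            )
        with open(out / "fisher_report.tsv", "wt") as fh:
            fh.write("\n".join(_header_lines(config)) + "\n")
            fh.write("peak_set\ta\tb\tc\td\todds_ratio\tlog2_odds\tp_two_sided\tp_greater\n")
            for row in fisher_rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        log.append({"stage": "cooccupancy", **venn})
        report["cooccupancy"] = {
            "venn": venn,
            "fisher_log2_odds": {r[0]: r[6] for r in fisher_rows},
        }

        # differential promoter binding between the two generated conditions
        all_sets = [fs for sets in data["fragsets"].values() for fs in sets]
        cm = promoter_counts(all_sets, promoters)
        results = differential_binding(
            cm, "test", "ref", lfc_thresh=config.lfc_thresh, alpha=config.alpha
        )
        with open(out / "differential_promoters.tsv", "wt") as fh:
            fh.write("\n".join(_header_lines(config)) + "\n")
            results.to_csv(fh, sep="\t")
        with open(out / "differential_volcano.tsv", "wt") as fh:
            fh.write("\n".join(_header_lines(config)) + "\n")
            volcano_table(results).to_csv(fh, sep="\t")
        class_counts = results["class"].value_counts().to_dict()
        log.append({"stage": "differential", **class_counts})
        report["differential"] = {"classes": class_counts}

    report["log"] = log
    _write_json(out / "run_report.json", report, config)
    return report
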