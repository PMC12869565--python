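"""Differential-interactor flagging from replicate protein-intensity tables.

Chromatin immunoprecipitation followed by mass spectrometry yields, per
pulldown replicate, an intensity per detected protein. Interactors of a
bait are flagged by comparison against a negative-control pulldown (e.g. an
anti-GFP ChIP-MS): per protein, log2FC = mean log2 intensity in the bait
group minus the control group, p from a two-sample Welch t on the log2
intensities, and the enriched flag requires log2FC > 0.5 and p < 0.05.

Missing intensities are never imputed; a protein with fewer than two
observed values in either group is reported untestable (no p, never
enriched). Complex-subunit heatmap tables pull the log2FC of a configured
subunit list in its given order, without clustering — membership is
configuration, not code, and an editable example ships with the package.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats


@dataclass
class IntensityTable:
    """Protein x sample positive intensities (NaN = not detected) plus design."""

    intensities: pd.DataFrame  # index: protein ids; columns: sample names
    design: pd.DataFrame  # index: sample names; columns: group, replicate

    def __post_init__(self):
        if list(self.intensities.columns) != list(self.design.index):
            raise ValueError("intensity columns and design rows must match")
        vals = self.intensities.to_numpy(dtype=np.float64)
        observed = ~np.isnan(vals)
        if observed.any() and np.min(vals[observed]) <= 0:
            raise ValueError("intensities must be positive where observed")
        if self.design["group"].nunique() < 2:
            raise ValueError("need at least one bait and one control group")

    def samples_for(self, group: str) -> list[str]:
        return list(self.design.index[self.design["group"] == group])


def differential_interactors(
    table: IntensityTable,
    bait: str,
    control: str,
    lfc_thresh: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein bait-vs-control enrichment records.

    Returns a frame indexed by protein id with columns ``log2fc``, ``p``,
    ``testable``, ``enriched``. log2FC is computed whenever each group has
    at least one observation; p and the enriched flag require >= 2 per
    group.
    """
    bait_samples = table.samples_for(bait)
    ctrl_samples = table.samples_for(control)
    if not bait_samples:
        raise ValueError(f"bait group {bait!r} absent from design")
    if not ctrl_samples:
        raise ValueError(f"control group {control!r} absent from design")
    log2i = np.log2(table.intensities.to_numpy(dtype=np.float64))
    cols = list(table.intensities.columns)
    b_idx = [cols.index(s) for s in bait_samples]
    c_idx = [cols.index(s) for s in ctrl_samples]
    b = log2i[:, b_idx]
    c = log2i[:, c_idx]
    n_b = np.sum(~np.isnan(b), axis=1)
    n_c = np.sum(~np.isnan(c), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        log2fc = np.nanmean(b, axis=1) - np.nanmean(c, axis=1)
    testable = (n_b >= 2) & (n_c >= 2)
    p = np.full(len(log2fc), np.nan)
    if testable.any():
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            res = _stats.ttest_ind(
                b[testable], c[testable], axis=1, equal_var=False, nan_policy="omit"
            )
        p[testable] = np.asarray(res.pvalue, dtype=np.float64)
    enriched = testable & (log2fc > lfc_thresh) & (p < alpha)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "testable": testable, "enriched": enriched},
        index=table.intensities.index,
    )


def complex_heatmap_table(
    records_by_assay: Mapping[str, pd.DataFrame],
    membership: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Subunit x assay log2FC table in membership order, unclustered.

    ``records_by_assay`` maps an assay label (e.g. a bait name) to the
    frame from :func:`differential_interactors`; ``membership`` maps a
    complex name to its ordered subunit id list. Subunits absent from an
    assay's records get NaN. The output carries a ``complex`` column and
    keeps rows exactly in the order membership lists them.
    """
    if not membership:
        raise ValueError("empty complex membership")
    rows = []
    index = []
    complexes = []
    for complex_name, subunits in membership.items():
        for subunit in subunits:
            index.append(subunit)
            complexes.append(complex_name)
            row = {}
            for assay, records in records_by_assay.items():
                row[assay] = (
                    float(records.loc[subunit, "log2fc"])
                    if subunit in records.index
                    else np.nan
                )
            rows.append(row)
    out = pd.DataFrame(rows, index=pd.Index(index, name="subunit"))
    out.insert(0, "complex", complexes)
    return out


def load_complex_membership(path=None) -> dict[str, list[str]]:
    """Load a complex -> subunit-list mapping from YAML.

    Without a path, loads the packaged example list of H2A.Z-associated
    remodeler complexes (p400-TIP60, SRCAP, INO80).
    """
    if path is None:
        ref = importlib.resources.files("wrapstate").joinpath("data/complexes.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ValueError("membership YAML must map complex names to subunit lists")
    return {str(k): [str(s) for s in v] for k, v in data.items()}


def read_intensity_table(intensities_path, design_path) -> IntensityTable:
    """Read a wide protein x sample CSV/TSV plus a sample design TSV.

    The intensity file's first column is the protein id; the design file has
    columns sample, group, replicate.
    """
    sep = "," if str(intensities_path).endswith(".csv") else "\t"
    intens = pd.read_csv(intensities_path, sep=sep, index_col=0)
    design = pd.read_csv(design_path, sep="\t").set_index("sample")
    return IntensityTable(intens[list(design.index)], design)
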