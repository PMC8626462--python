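"""Pooled CRISPR domain-screen scoring.

Guides targeting catalytic/reader domains of chromatin regulators are
sequenced at an early (~day 3) and late (~day 12) timepoint in RMS and
non-RMS cell lines.  Scoring proceeds: depth normalization to reads per
million, per-guide log2 fold depletion (late vs early, replicates averaged
within timepoint), per-target aggregation, and ranking by RMS-specific
depletion (mean over RMS lines minus mean over non-RMS lines; most
negative first).  Negative-control guides provide an empirical null for
optional z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreenCounts",
    "DepletionTable",
    "read_screen_counts",
    "normalize_depth",
    "fold_depletion",
    "specificity_rank",
]


@dataclass
class ScreenCounts:
    """sgRNA count matrix plus guide and sample metadata.

    ``counts``: guide × sample integers.  ``guides``: per-guide
    ``target_domain`` and ``is_control``.  ``samples``: per-sample
    ``cell_line``, ``rms`` (bool) and ``timepoint`` ('early'/'late').
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.guides.index):
            self.guides = self.guides.reindex(self.counts.index)
            if self.guides.isna().any().any():
                raise ValueError("guide metadata missing for some guides")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for: {sorted(missing)[:5]}")
        bad_tp = set(self.samples["timepoint"]) - {"early", "late"}
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError(
                f"zero-total sample column(s): {list(totals.index[totals <= 0])}"
            )
        for line, grp in self.samples.groupby("cell_line"):
            tps = set(grp["timepoint"])
            if not {"early", "late"} <= tps:
                raise ValueError(f"cell line {line!r} lacks early+late samples")


def read_screen_counts(counts_path: str | Path, samples_path: str | Path) -> ScreenCounts:
    """Read counts TSV (guide, target_domain, is_control, one column per
    sample) and a sample sheet TSV (sample, cell_line, rms, timepoint)."""
    df = pd.read_csv(counts_path, sep="\t")
    df = df.set_index(df.columns[0])
    guides = df[["target_domain", "is_control"]].copy()
    guides["is_control"] = guides["is_control"].astype(bool)
    counts = df.drop(columns=["target_domain", "is_control"]).astype(int)
    samples = pd.read_csv(samples_path, sep="\t")
    samples = samples.set_index(samples.columns[0])
    samples["rms"] = samples["rms"].astype(bool)
    return ScreenCounts(counts, guides, samples)


def normalize_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to one million (RPM)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(
            f"cannot depth-normalize zero-total column(s): "
            f"{list(totals.index[totals <= 0])}"
        )
    return counts.astype(float) * 1e6 / totals


def fold_depletion(
    norm: pd.DataFrame, samples: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-guide, per-cell-line log2 fold depletion.

    ``LFC(g, line) = log2((mean late RPM + pc) / (mean early RPM + pc))``,
    replicates averaged within timepoint after normalization.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    out = {}
    for line, grp in samples.groupby("cell_line", sort=True):
        early = grp.index[grp["timepoint"] == "early"]
        late = grp.index[grp["timepoint"] == "late"]
        e = norm[early].mean(axis=1)
        l = norm[late].mean(axis=1)
        out[line] = np.log2((l + pseudocount) / (e + pseudocount))
    return pd.DataFrame(out)


@dataclass
class DepletionTable:
    """Ranked screen result.

    ``targets``: per-target frame with per-line aggregate LFCs,
    ``specificity`` (mean over RMS lines − mean over non-RMS lines),
    ``rank`` (1 = most RMS-specific dependency) and ``z`` against the
    control-guide null.  ``guide_lfc``: the underlying guide × line LFCs.
    ``control_null``: per-control-guide specificity values (an empirical
    null; the source screens report no p-values, so z-scores are an
    optional extra).
    """

    targets: pd.DataFrame
    guide_lfc: pd.DataFrame
    control_null: pd.Series


def specificity_rank(
    guide_lfc: pd.DataFrame,
    guides: pd.DataFrame,
    samples: pd.DataFrame,
    agg: str = "mean",
) -> DepletionTable:
    """Aggregate guide LFCs per target and rank by RMS-specific depletion.

    Most negative specificity ranks first (strongest RMS-selective
    dependency); ties break lexicographically by target name.  Targets
    with zero guides are excluded with a warning.
    """
    if agg not in ("mean", "median"):
        raise ValueError(f"agg must be 'mean' or 'median', got {agg!r}")
    line_rms = samples.drop_duplicates("cell_line").set_index("cell_line")["rms"]
    line_rms = line_rms.reindex(guide_lfc.columns)
    rms_lines = list(line_rms.index[line_rms])
    non_rms_lines = list(line_rms.index[~line_rms])
    if not rms_lines or not non_rms_lines:
        raise ValueError("need at least one RMS and one non-RMS cell line")

    is_ctrl = guides["is_control"].astype(bool)
    targeting = guide_lfc.loc[~is_ctrl]
    tgt_of = guides.loc[~is_ctrl, "target_domain"]
    per_target = targeting.groupby(tgt_of).agg(agg)
    empty = set(guides.loc[~is_ctrl, "target_domain"].unique()) - set(per_target.index)
    if empty:
        warnings.warn(f"targets with 0 guides excluded: {sorted(empty)}", stacklevel=2)
    spec = per_target[rms_lines].mean(axis=1) - per_target[non_rms_lines].mean(axis=1)

    ctrl = guide_lfc.loc[is_ctrl]
    control_null = (
        ctrl[rms_lines].mean(axis=1) - ctrl[non_rms_lines].mean(axis=1)
        if len(ctrl)
        else pd.Series(dtype=float)
    )
    targets = per_target.copy()
    targets["specificity"] = spec
    order = sorted(targets.index, key=lambda t: (targets.loc[t, "specificity"], t))
    targets = targets.loc[order]
    targets["rank"] = np.arange(1, len(targets) + 1)
    if len(control_null) >= 2 and control_null.std(ddof=1) > 0:
        targets["z"] = (
            targets["specificity"] - control_null.mean()
        ) / control_null.std(ddof=1)
    else:
        targets["z"] = np.nan
    return DepletionTable(targets, guide_lfc, control_null)
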