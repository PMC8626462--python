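"""qPCR and competition-assay quantification.

Implements the arithmetic of ChIP-qPCR percent-input recovery with
exogenous (Drosophila Pgbs) spike correction, 2^(−ΔΔCt) fold changes,
RT-qPCR relative expression by the ΔΔCT method with a technical-replicate
outlier rule, and day-2-baseline normalization of CRISPR competition
trajectories.  Amplification efficiency is fixed at 2 (perfect doubling),
as the power-of-two formulas imply.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_recovery",
    "spike_correct_ct",
    "dct_recovery",
    "ddct_fold_change",
    "remove_ct_outliers",
    "relative_expression",
    "competition_trajectory",
]


def percent_recovery(ct_input: float, x: float, ct_sample: float) -> float:
    """ChIP-qPCR percent recovery of input.

    ``%recovery = 2^(Ct(input) − log2(X) − Ct(sample)) × 100`` where X is
    the fold-dilution of the input aliquot.
    """
    if x < 1:
        raise ValueError(f"input dilution X must be >= 1, got {x}")
    return 2.0 ** (ct_input - math.log2(x) - ct_sample) * 100.0


def spike_correct_ct(
    ct_sample: float, ct_sample_pgbs: float, ct_control_pgbs: float
) -> float:
    """Correct a sample Ct for technical variation via the spike-in locus.

    ``Ct(sample)corr = Ct(sample) − (Ct(sample)Pgbs − Ct(control)Pgbs)``:
    the exogenous Drosophila chromatin is present at identical amounts in
    every reaction, so its Ct shift measures pure technical variation.
    """
    return ct_sample - (ct_sample_pgbs - ct_control_pgbs)


def dct_recovery(ct_input: float, x: float, ct_sample: float) -> float:
    """dCt for ChIP-qPCR: ``Ct(input) − log2(X) − Ct(sample)`` (log2 recovery)."""
    if x < 1:
        raise ValueError(f"input dilution X must be >= 1, got {x}")
    return ct_input - math.log2(x) - ct_sample


def ddct_fold_change(dct_control: float, dct_sample: float) -> float:
    """Fold change vs control: ``ddCt = dCt(control) − dCt(sample)``,
    ``FC = 2^(−ddCt)``."""
    return 2.0 ** (-(dct_control - dct_sample))


def remove_ct_outliers(cts: Sequence[float], sd_cutoff: float = 0.5) -> list[float]:
    """Apply the technical-replicate outlier rule.

    While the replicate SD exceeds ``sd_cutoff`` cycles and more than two
    replicates remain, the replicate farthest from the replicate median is
    dropped (ties: the larger Ct goes first, for determinism).
    """
    vals = [float(v) for v in cts]
    if len(vals) < 2:
        raise ValueError("need at least 2 technical replicates")
    while len(vals) > 2 and np.std(vals, ddof=1) > sd_cutoff:
        med = float(np.median(vals))
        worst = max(vals, key=lambda v: (abs(v - med), v))
        vals.remove(worst)
    return vals


def relative_expression(
    ct_table: pd.DataFrame,
    control_condition: str,
    reference: str = "GAPDH",
    sd_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCT method with outlier removal.

    ``ct_table`` is a long frame with columns ``target``, ``condition``,
    ``bio_rep`` and ``ct``; rows within a (target, condition, bio_rep)
    cell are technical replicates.  Per cell, outlier replicates are
    removed (SD > ``sd_cutoff`` rule), then
    ``dCt = mean Ct(target) − mean Ct(reference)``; per biological
    replicate ``ddCt = dCt(condition) − dCt(control)`` and expression is
    ``2^(−ddCt)``.  The summary reports the mean plus upper/lower limits
    (the min/max over biological replicates of the back-transformed fold
    change) and a paired two-tailed t-test on the dCt pairs.
    """
    required = {"target", "condition", "bio_rep", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    conditions = ct_table["condition"].unique().tolist()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    if reference not in set(ct_table["target"]):
        raise ValueError(f"reference assay {reference!r} absent from table")

    def cell_mean(target: str, condition: str, rep) -> float:
        sel = ct_table[
            (ct_table["target"] == target)
            & (ct_table["condition"] == condition)
            & (ct_table["bio_rep"] == rep)
        ]["ct"]
        if sel.empty:
            return np.nan
        return float(np.mean(remove_ct_outliers(sel.tolist(), sd_cutoff)))

    targets = [t for t in ct_table["target"].unique() if t != reference]
    rows = []
    for target in targets:
        # dCt per (condition, bio_rep)
        dct: dict[str, dict] = {}
        for cond in conditions:
            reps = ct_table[
                (ct_table["target"] == target) & (ct_table["condition"] == cond)
            ]["bio_rep"].unique()
            dct[cond] = {
                r: cell_mean(target, cond, r) - cell_mean(reference, cond, r)
                for r in reps
            }
        for cond in conditions:
            shared = [r for r in dct[cond] if r in dct[control_condition]]
            if not shared:
                continue
            d_cond = np.array([dct[cond][r] for r in shared])
            d_ctrl = np.array([dct[control_condition][r] for r in shared])
            expr = 2.0 ** (-(d_cond - d_ctrl))
            if len(shared) >= 2 and cond != control_condition:
                diffs = d_cond - d_ctrl
                if np.std(diffs) < 1e-9:  # degenerate paired test
                    p = 1.0 if abs(float(np.mean(diffs))) < 1e-9 else 0.0
                else:
                    p = float(stats.ttest_rel(d_cond, d_ctrl).pvalue)
            elif cond == control_condition:
                p = 1.0
            else:
                p = np.nan
            rows.append(
                (
                    target,
                    cond,
                    len(shared),
                    float(expr.mean()),
                    float(expr.min()),
                    float(expr.max()),
                    p,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "target",
            "condition",
            "n_bio_reps",
            "expression",
            "lower_limit",
            "upper_limit",
            "p_value",
        ],
    )


def competition_trajectory(records: pd.DataFrame, baseline_day: int = 2) -> pd.DataFrame:
    """Normalize competition-assay trajectories to the day-2 baseline.

    ``records`` has columns ``condition``, ``day``, ``pct_rfp`` (percent
    transduced, RFP-positive cells).  Each condition's values become
    percent-of-baseline: ``100 × pct_rfp(day) / pct_rfp(baseline_day)``.
    """
    required = {"condition", "day", "pct_rfp"}
    if not required <= set(records.columns):
        raise ValueError(f"records needs columns {sorted(required)}")
    if ((records["pct_rfp"] < 0) | (records["pct_rfp"] > 100)).any():
        raise ValueError("pct_rfp must lie in [0, 100]")
    out = []
    for cond, grp in records.groupby("condition", sort=True):
        base = grp.loc[grp["day"] == baseline_day, "pct_rfp"]
        if base.empty:
            raise ValueError(f"condition {cond!r} lacks a day-{baseline_day} baseline")
        base_val = float(base.mean())
        if base_val <= 0:
            raise ValueError(f"condition {cond!r} has nonpositive baseline")
        for _, row in grp.sort_values("day").iterrows():
            out.append(
                (cond, int(row["day"]), 100.0 * float(row["pct_rfp"]) / base_val)
            )
    return pd.DataFrame(out, columns=["condition", "day", "pct_of_baseline"])
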