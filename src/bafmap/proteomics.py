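"""Proximity-labeling (BioID) and IP-MS enrichment analysis.

A protein × sample intensity matrix (explicit missing entries) from a
label-free search is filtered (≥2 peptides, ≤4 missing values), normalized
per sample with a modified robust z-score transformation on the log2 scale,
and compared between bait and BirA-only control with a moderated two-sample
t-test (empirical-Bayes variance shrinkage).  Proteins whose control group
is entirely missing get a pseudo fold change, replacing the missing group
average by the mean of the 10% smallest observed intensities in that
condition.  Hits follow the volcano quadrant rule: log2FC > 2.5 and raw
p < 0.05 (BH-adjusted p is reported alongside but not used for the flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityMatrix",
    "read_intensity_matrix",
    "filter_matrix",
    "robust_z_normalize",
    "group_compare",
    "pseudo_fold_change",
    "bioid_enrichment",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


@dataclass
class IntensityMatrix:
    """Protein × sample intensities with peptide counts and group labels.

    ``intensities``: raw positive intensities, NaN = missing.
    ``n_peptides``: per-protein peptide count (≥1).
    ``groups``: sample → condition label (e.g. 'bait' vs 'control').
    """

    intensities: pd.DataFrame
    n_peptides: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.n_peptides = self.n_peptides.reindex(self.intensities.index)
        if self.n_peptides.isna().any():
            raise ValueError("n_peptides missing for some proteins")
        if (self.n_peptides < 1).any():
            raise ValueError("n_peptides must be >= 1")
        missing = set(self.intensities.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"group labels missing for: {sorted(missing)[:5]}")
        obs = self.intensities.to_numpy()
        obs = obs[~np.isnan(obs)]
        if obs.size and obs.min() <= 0:
            raise ValueError("intensities must be positive where observed")


def read_intensity_matrix(
    intensities_path: str | Path, groups_path: str | Path
) -> IntensityMatrix:
    """Read the intensity TSV (protein, n_peptides, one column per sample;
    empty cell = missing) and a two-column group map TSV."""
    df = pd.read_csv(intensities_path, sep="\t")
    df = df.set_index(df.columns[0])
    n_pep = df["n_peptides"].astype(int)
    inten = df.drop(columns=["n_peptides"]).astype(float)
    gm = pd.read_csv(groups_path, sep="\t")
    groups = gm.set_index(gm.columns[0]).iloc[:, 0]
    return IntensityMatrix(inten, n_pep, groups)


def filter_matrix(
    m: IntensityMatrix, min_peptides: int = 2, max_missing: int = 4
) -> IntensityMatrix:
    """Keep proteins with ≥``min_peptides`` peptides and at most
    ``max_missing`` missing entries across all samples.  Idempotent."""
    n_missing = m.intensities.isna().sum(axis=1)
    keep = (m.n_peptides >= min_peptides) & (n_missing <= max_missing)
    return IntensityMatrix(
        m.intensities.loc[keep].copy(), m.n_peptides.loc[keep].copy(), m.groups
    )


def robust_z_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Modified robust z-score normalization on the log2 scale.

    Per sample: ``z = (x − median) / (1.4826 × MAD)`` over that sample's
    observed log2 intensities, then rescaled back to a log2-intensity-like
    scale via the grand location (median of all observed values) and the
    grand scale (1.4826 × MAD of the pooled per-sample-centered values).
    The grand scale is invariant to per-sample location shifts, so a
    shift of one sample is removed up to a single global constant.  A
    sample already sitting at the grand location and scale is returned
    unchanged.  The returned matrix holds the normalized log2 values;
    missing entries stay missing.
    """
    log2 = np.log2(m.intensities)
    all_obs = log2.to_numpy()[~np.isnan(log2.to_numpy())]
    if all_obs.size < 3:
        raise ValueError("need at least 3 observed values overall")
    grand_med = float(np.median(all_obs))
    meds = {}
    mads = {}
    centered_pool = []
    for sample in log2.columns:
        obs = log2[sample].dropna()
        if len(obs) < 3:
            raise ValueError(f"sample {sample!r} has fewer than 3 observed values")
        meds[sample] = float(np.median(obs))
        mads[sample] = MAD_SCALE * float(np.median(np.abs(obs - meds[sample])))
        if mads[sample] == 0:
            raise ValueError(f"sample {sample!r} has zero MAD; cannot normalize")
        centered_pool.append(obs.to_numpy() - meds[sample])
    pooled = np.concatenate(centered_pool)
    grand_mad = MAD_SCALE * float(np.median(np.abs(pooled)))
    out = {}
    for sample in log2.columns:
        col = log2[sample]
        out[sample] = grand_med + (col - meds[sample]) / mads[sample] * grand_mad
    norm = pd.DataFrame(out, index=log2.index)[list(log2.columns)]
    return _wrap_norm(norm, m)


def _wrap_norm(norm: pd.DataFrame, m: IntensityMatrix) -> IntensityMatrix:
    # normalized values are log2-scale and may be <= 0; bypass positivity check
    obj = IntensityMatrix.__new__(IntensityMatrix)
    obj.intensities = norm
    obj.n_peptides = m.n_peptides.copy()
    obj.groups = m.groups
    return obj


# ---------------------------------------------------------------------------
# moderated two-sample test (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (df0, s0²) to observed
    per-protein sample variances, via the log-variance moments and
    trigamma inversion.  df0 = inf when the variances are underdispersed
    relative to pure chi-square sampling noise."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return math.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = math.exp(emean + float(special.digamma(df0 / 2.0)) - math.log(df0 / 2.0))
    else:
        df0 = math.inf
        s0_2 = math.exp(emean)
    return df0, s0_2


def group_compare(
    m_norm: IntensityMatrix,
    bait: str,
    control: str,
    fc_threshold: float = 2.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Bait-vs-control enrichment with moderated variance shrinkage.

    log2FC = mean(bait) − mean(control) on the normalized log2 scale.
    Per-protein pooled variances are shrunk toward a prior fitted across
    proteins; the t statistic uses the posterior variance with augmented
    degrees of freedom.  Proteins with fewer than 2 observed values in
    either group get NaN statistics (route them to
    :func:`pseudo_fold_change` when one group is entirely missing).
    Columns: log2fc, p_value, adj_p, t, df_total, pseudo_fc_flag, hit.
    """
    x = m_norm.intensities
    bait_cols = [c for c in x.columns if m_norm.groups[c] == bait]
    ctrl_cols = [c for c in x.columns if m_norm.groups[c] == control]
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >=2 samples per condition")
    xb = x[bait_cols].to_numpy()
    xc = x[ctrl_cols].to_numpy()
    n1 = np.sum(~np.isnan(xb), axis=1)
    n2 = np.sum(~np.isnan(xc), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(xb, axis=1)
        m2 = np.nanmean(xc, axis=1)
        v1 = np.nanvar(xb, axis=1, ddof=1)
        v2 = np.nanvar(xc, axis=1, ddof=1)
    testable = (n1 >= 2) & (n2 >= 2)
    log2fc = np.where((n1 >= 1) & (n2 >= 1), m1 - m2, np.nan)
    df_resid = np.where(testable, n1 + n2 - 2, np.nan)
    pooled = np.where(
        testable,
        ((n1 - 1) * np.nan_to_num(v1) + (n2 - 1) * np.nan_to_num(v2))
        / np.maximum(n1 + n2 - 2, 1),
        np.nan,
    )
    df0, s0_2 = fit_variance_prior(pooled[testable], df_resid[testable])
    if math.isinf(df0):
        post_var = np.full_like(pooled, s0_2)
        df_total = np.full_like(pooled, np.inf)
    else:
        post_var = (df0 * s0_2 + df_resid * pooled) / (df0 + df_resid)
        df_total = df0 + df_resid
    se = np.sqrt(post_var * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    tstat = np.where(testable, log2fc / se, np.nan)
    pvals = np.full(len(x), np.nan)
    finite_df = testable & np.isfinite(df_total)
    pvals[finite_df] = 2.0 * stats.t.sf(np.abs(tstat[finite_df]), df_total[finite_df])
    inf_df = testable & ~np.isfinite(df_total)
    pvals[inf_df] = 2.0 * stats.norm.sf(np.abs(tstat[inf_df]))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    adj = np.full(len(x), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "adj_p": adj,
            "t": tstat,
            "df_total": df_total,
            "pseudo_fc_flag": False,
        },
        index=x.index,
    )
    out["hit"] = (out["log2fc"] > fc_threshold) & (out["p_value"] < p_threshold)
    out.attrs["df_prior"] = df0
    out.attrs["s2_prior"] = s0_2
    return out


def pseudo_fold_change(
    m_norm: IntensityMatrix, bait: str, control: str
) -> pd.Series:
    """log2FC for proteins with exactly one condition entirely missing.

    The missing group's average is replaced by the mean of the 10%
    smallest observed (normalized log2) intensity values across that
    condition's entries over all proteins (ceil(0.1 × count), at least 1).
    Proteins missing in both groups are dropped with a warning.
    """
    x = m_norm.intensities
    bait_cols = [c for c in x.columns if m_norm.groups[c] == bait]
    ctrl_cols = [c for c in x.columns if m_norm.groups[c] == control]

    def floor_value(cols: list[str]) -> float:
        vals = np.sort(x[cols].to_numpy().ravel())
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("condition has no observed values at all")
        k = max(1, math.ceil(0.1 * vals.size))
        return float(vals[:k].mean())

    out: dict[str, float] = {}
    dropped = []
    for prot, row in x.iterrows():
        b = row[bait_cols].dropna()
        c = row[ctrl_cols].dropna()
        if len(b) == 0 and len(c) == 0:
            dropped.append(prot)
            continue
        if len(c) == 0 and len(b) >= 1:
            out[prot] = float(b.mean()) - floor_value(ctrl_cols)
        elif len(b) == 0 and len(c) >= 1:
            out[prot] = floor_value(bait_cols) - float(c.mean())
    if dropped:
        warnings.warn(
            f"{len(dropped)} protein(s) missing in both conditions dropped",
            stacklevel=2,
        )
    return pd.Series(out, dtype=float, name="pseudo_log2fc")


def bioid_enrichment(
    m: IntensityMatrix,
    bait: str,
    control: str,
    min_peptides: int = 2,
    max_missing: int = 4,
    fc_threshold: float = 2.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full enrichment pipeline: filter → normalize → moderated compare,
    with the pseudo-fold-change route for all-missing-in-one-condition
    proteins.  Returns a volcano-ready per-protein table."""
    filt = filter_matrix(m, min_peptides, max_missing)
    norm = robust_z_normalize(filt)
    res = group_compare(norm, bait, control, fc_threshold, p_threshold)
    pseudo = pseudo_fold_change(norm, bait, control)
    for prot, fc in pseudo.items():
        res.loc[prot, "log2fc"] = fc
        res.loc[prot, "pseudo_fc_flag"] = True
    res["hit"] = (res["log2fc"] > fc_threshold) & (res["p_value"] < p_threshold)
    return res
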