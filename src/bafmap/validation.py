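"""Property-based validation suite: planted-truth recovery checks.

Headline genomic quantities of the motivating study depend on aligned
reads and peak calls from controlled-access experiments, so end-to-end
validation here is property-based: each check simulates data under known
study conditions, runs the corresponding pipeline stage, and measures how
well the planted truth is recovered.  The functions return plain numbers
so both the test suite and ``scripts/acceptance.py`` can consume them.

All randomness flows from the ``seed`` argument; repeated calls with the
same seed are deterministic.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet, intersect_sets, overlaps
from .subcomplexes import CLASS_LABELS, classify_subcomplexes, cooccupancy_fractions
from .chiprx import (
    SpikeInCounts,
    invasion_analysis,
    quartile_stratify,
    rpmpr_normalize,
    rrpm_normalize,
)
from .screen import fold_depletion, normalize_depth, specificity_rank
from .qpcr import ddct_fold_change, percent_recovery, relative_expression
from .proteomics import filter_matrix, group_compare, pseudo_fold_change, robust_z_normalize
from .simulate import (
    ProteomicsConfig,
    ScreenConfig,
    SimulationConfig,
    simulate_chiprx,
    simulate_peaksets,
    simulate_proteomics,
    simulate_qpcr,
    simulate_screen,
)

__all__ = [
    "brute_force_intersect",
    "random_peakset",
    "interval_oracle_disagreements",
    "classification_check",
    "cooccupancy_check",
    "rrpm_exactness_check",
    "invasion_check",
    "quartile_monotonicity_check",
    "screen_ranking_check",
    "qpcr_formula_check",
    "proteomics_null_check",
    "proteomics_planted_check",
    "determinism_check",
]


# ---------------------------------------------------------------------------
# 1. interval algebra vs brute force
# ---------------------------------------------------------------------------

def brute_force_intersect(
    A: PeakSet, B: PeakSet, min_bp: int = 1
) -> dict[str, list[str]]:
    """All-pairs O(n·m) oracle: names of B peaks overlapping each A peak."""
    out: dict[str, list[str]] = {}
    for a in A:
        out[a.name] = [
            b.name for b in B if overlaps(a.interval, b.interval, min_bp)
        ]
    return out


def random_peakset(rng: np.random.Generator, factor: str, n: int,
                   chrom_len: int = 1_000_000, max_width: int = 5000) -> PeakSet:
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - max_width))
        width = int(rng.integers(1, max_width))
        peaks.append(Peak(GenomicInterval("chrT", start, start + width), f"{factor}_{i}"))
    return PeakSet(factor, peaks)


def interval_oracle_disagreements(
    seed: int, n_instances: int = 100, max_n: int = 300
) -> int:
    """Number of (instance, peak) pairs where the indexed intersection
    disagrees with the exhaustive all-pairs comparison."""
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_n + 1))
        m = int(rng.integers(0, max_n + 1))
        min_bp = int(rng.choice([1, 1, 10, 100]))
        A = random_peakset(rng, "A", n)
        B = random_peakset(rng, "B", m) if m else PeakSet("B", [])
        fast = intersect_sets(A, B, min_bp)
        slow = brute_force_intersect(A, B, min_bp)
        for name in slow:
            if sorted(p.name for p in fast[name]) != sorted(slow[name]):
                bad += 1
    return bad


# ---------------------------------------------------------------------------
# 2–3. classification partition + planted-rate recovery
# ---------------------------------------------------------------------------

def classification_check(seed: int, n_sites: int = 10_000) -> dict[str, float]:
    """Simulate sites, classify, and compare to the planted truth.

    Returns the partition residual (Σ class counts − n BRG1 peaks, exactly
    0 when classes partition the anchor set), the max class-proportion
    z-score vs the planted multinomial, and the site-level disagreement
    count between calls and truth labels.
    """
    cfg = SimulationConfig(seed=seed, n_sites=n_sites)
    ps, truth = simulate_peaksets(cfg)
    calls = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
    counts = calls.class_counts()
    residual = int(counts.sum() - len(ps["BRG1"]))
    probs = dict(zip(CLASS_LABELS, cfg.class_probs))
    max_z = 0.0
    for label, p in probs.items():
        se = math.sqrt(p * (1 - p) / n_sites)
        z = abs(counts[label] / n_sites - p) / se
        max_z = max(max_z, z)
    call_labels = calls.table["class_label"]
    truth_labels = truth["class_label"]
    truth_labels.index = "BRG1_" + truth_labels.index
    mismatches = int((call_labels.reindex(truth_labels.index) != truth_labels).sum())
    return {"partition_residual": residual, "max_z": max_z, "mismatches": mismatches}


def cooccupancy_check(seed: int, n_sites: int = 2000) -> float:
    """Max z-score of recovered CRTF co-binding rates at BAF_only
    (planted 0.6) and PBAF_only (planted 0.05) sites, factor P3F."""
    cfg = SimulationConfig(seed=seed, n_sites=n_sites)
    ps, truth = simulate_peaksets(cfg)
    calls = classify_subcomplexes(ps["BRG1"], ps["DPF2"], ps["PBRM1"], ps["BRD9"])
    tab = cooccupancy_fractions(calls, [ps["P3F"]])
    max_z = 0.0
    for label in ("BAF_only", "PBAF_only"):
        p = cfg.crtf_probs[label][0]
        n = int(tab.class_sizes[label])
        if n == 0:
            continue
        se = math.sqrt(p * (1 - p) / n)
        max_z = max(max_z, abs(float(tab.fractions.loc[label, "P3F"]) - p) / se)
    return max_z


# ---------------------------------------------------------------------------
# 4. normalization exactness
# ---------------------------------------------------------------------------

def rrpm_exactness_check(seed: int, n_peaks: int = 500) -> dict[str, float]:
    """RRPM halves exactly when spike totals double; RPMPR sums to 1e6."""
    rng = np.random.default_rng(seed)
    names = [f"p{i}" for i in range(n_peaks)]
    raw = pd.Series(rng.integers(0, 1000, size=n_peaks), index=names)
    raw.iloc[0] = 1  # guarantee nonzero total
    lib = SpikeInCounts("lib", "c", raw, int(raw.sum() * 2), 400_000)
    lib2 = SpikeInCounts("lib2", "c", raw, int(raw.sum() * 2), 800_000)
    s1, s2 = rrpm_normalize(lib), rrpm_normalize(lib2)
    with np.errstate(invalid="ignore"):
        rel = np.abs(s2.to_numpy() * 2 - s1.to_numpy()) / np.where(
            s1.to_numpy() > 0, s1.to_numpy(), 1.0
        )
    return {
        "halving_max_rel_err": float(np.nanmax(rel)),
        "rpmpr_sum": float(rpmpr_normalize(lib, names).sum()),
    }


# ---------------------------------------------------------------------------
# 5. invasion recovery
# ---------------------------------------------------------------------------

def invasion_check(seed: int, n_sites: int = 1000, depth: float = 100.0) -> dict[str, float]:
    """Planted +1.0 log2 shift recovery, null median, and antisymmetry."""
    cfg = SimulationConfig(seed=seed, n_sites=8, depth=depth)
    sites = [f"s{i:04d}" for i in range(n_sites)]
    libs, _ = simulate_chiprx(cfg, sites, {"control": 0.0, "treated": 1.0, "null": 0.0})
    res = invasion_analysis(sites, libs["control"], libs["treated"])
    null_res = invasion_analysis(sites, libs["control"], libs["null"])
    rev = invasion_analysis(sites, libs["treated"], libs["control"])
    anti = float(np.max(np.abs(res.deltas.to_numpy() + rev.deltas.to_numpy())))
    return {
        "median_delta": res.median_delta,
        "null_median_delta": null_res.median_delta,
        "antisymmetry_max_abs": anti,
        "fraction_increased": res.fraction_increased,
    }


# ---------------------------------------------------------------------------
# 6. quartile monotonicity under copula coupling
# ---------------------------------------------------------------------------

def quartile_monotonicity_check(
    seed: int, n_seeds: int = 100, n: int = 2000, rho: float = 0.5
) -> int:
    """Number of seeds (of ``n_seeds``) with Q4 median > Q1 median for a
    Gaussian-copula-coupled partner signal."""
    good = 0
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, 8, k])
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        names = [f"p{i}" for i in range(n)]
        anchor = pd.Series(np.exp(0.8 * z1 + 3), index=names)
        partner = pd.Series(np.exp(0.8 * z2 + 3), index=names)
        q = quartile_stratify(anchor, partner)
        if q.loc["Q4", "median_partner"] > q.loc["Q1", "median_partner"]:
            good += 1
    return good


# ---------------------------------------------------------------------------
# 7. screen ranking
# ---------------------------------------------------------------------------

def screen_ranking_check(seed: int, n_seeds: int = 100) -> int:
    """Seeds (of ``n_seeds``) where all 5 planted RMS-specific domains
    land in the top 10 specificity ranks."""
    good = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=int(np.random.default_rng([seed, 9, k]).integers(2**31)))
        sc, truth = simulate_screen(cfg)
        norm = normalize_depth(sc.counts)
        lfc = fold_depletion(norm, sc.samples)
        table = specificity_rank(lfc, sc.guides, sc.samples)
        planted = truth.index[truth["planted"]]
        if all(table.targets.loc[t, "rank"] <= 10 for t in planted):
            good += 1
    return good


# ---------------------------------------------------------------------------
# 8. qPCR formulas
# ---------------------------------------------------------------------------

def qpcr_formula_check(seed: int) -> dict[str, float]:
    """Printed-formula spot values, reciprocity, and noiseless round-trip."""
    rec = percent_recovery(25, 100, 20)
    recip = abs(ddct_fold_change(-5.0, -3.0) * ddct_fold_change(-3.0, -5.0) - 1.0)
    cfg = SimulationConfig(seed=seed)
    cfg.qpcr.noise_sd = 0.0
    fcs = {"GENE_A": {"treated": 4.0}, "GENE_B": {"treated": 0.25}}
    table, truth = simulate_qpcr(cfg, fcs, control_condition="control")
    res = relative_expression(table, control_condition="control")
    err = 0.0
    for _, row in truth[truth["condition"] == "treated"].iterrows():
        got = res[
            (res["target"] == row["target"]) & (res["condition"] == "treated")
        ]["expression"].iloc[0]
        err = max(err, abs(got - row["fold_change"]) / row["fold_change"])
    return {
        "percent_recovery_25_100_20": rec,
        "reciprocity_abs_err": recip,
        "roundtrip_max_rel_err": err,
    }


# ---------------------------------------------------------------------------
# 9. proteomics calibration and recovery
# ---------------------------------------------------------------------------

def proteomics_null_check(seed: int, n_seeds: int = 50) -> float:
    """Pooled fraction of null proteins at p < 0.05 over ``n_seeds``."""
    n_sig = 0
    n_tot = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=int(np.random.default_rng([seed, 10, k]).integers(2**31)))
        cfg.proteomics = ProteomicsConfig(n_hits=0)
        m, _ = simulate_proteomics(cfg)
        norm = robust_z_normalize(filter_matrix(m))
        res = group_compare(norm, "bait", "control")
        p = res["p_value"].dropna()
        n_sig += int((p < 0.05).sum())
        n_tot += len(p)
    return n_sig / n_tot


def proteomics_planted_check(seed: int, n_seeds: int = 100) -> dict[str, float]:
    """Recovery of 20 planted 8x-enriched proteins at the volcano
    thresholds (count of seeds with >=18/20 passing log2FC > 2.5 and
    p < 0.05), plus the pseudo-fold-change path on a simulation with
    forced all-missing-control hits (all must be finite and flagged)."""
    good = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(seed=int(np.random.default_rng([seed, 11, k]).integers(2**31)))
        cfg.proteomics = ProteomicsConfig(n_hits=20)
        m, truth = simulate_proteomics(cfg)
        norm = robust_z_normalize(filter_matrix(m))
        res = group_compare(norm, "bait", "control")
        planted = [p for p in truth.index[truth["planted"]] if p in res.index]
        passed = sum(
            1
            for p in planted
            if res.loc[p, "log2fc"] > 2.5 and res.loc[p, "p_value"] < 0.05
        )
        if passed >= 18:
            good += 1

    cfg = SimulationConfig(seed=seed)
    cfg.proteomics = ProteomicsConfig(n_hits=20, n_forced_missing_control=3)
    m, truth = simulate_proteomics(cfg)
    norm = robust_z_normalize(filter_matrix(m))
    pseudo = pseudo_fold_change(norm, "bait", "control")
    forced = truth.index[truth["forced_missing_control"]]
    pseudo_finite = all(
        p in pseudo.index and np.isfinite(pseudo[p]) for p in forced
    )
    return {
        "seeds_recovered": good,
        "pseudo_all_finite": float(pseudo_finite),
        "n_forced": int(len(forced)),
    }


# ---------------------------------------------------------------------------
# 10. pipeline determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int, workdir: str | Path, n_sites: int = 300) -> bool:
    """Run the full pipeline twice with one config; compare outputs
    byte-for-byte."""
    from .pipeline import RunConfig, run

    workdir = Path(workdir)
    outs = []
    for tag in ("run1", "run2"):
        sim = SimulationConfig(seed=seed, n_sites=n_sites)
        sim.screen = ScreenConfig(n_targets=20, n_control_guides=20)
        sim.proteomics = ProteomicsConfig(n_proteins=200, n_forced_missing_control=2)
        cfg = RunConfig(outdir=str(workdir / tag), seed=seed, sim=sim,
                        bootstrap_b=200)
        outs.append(run(cfg))
    files1 = sorted(p.relative_to(outs[0]) for p in outs[0].rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(outs[1]) for p in outs[1].rglob("*") if p.is_file())
    if files1 != files2:
        return False
    for rel in files1:
        if rel.name == "manifest.json":
            # identical up to the outdir path recorded in the config
            t1 = (outs[0] / rel).read_text().replace(str(outs[0]), "OUT")
            t2 = (outs[1] / rel).read_text().replace(str(outs[1]), "OUT")
            if t1 != t2:
                return False
        elif (outs[0] / rel).read_bytes() != (outs[1] / rel).read_bytes():
            return False
    return True
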