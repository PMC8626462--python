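"""Seeded synthetic-data generators with planted ground truth.

Every stage of the pipeline can be exercised without downloads: the
generators here produce peak sets with latent subcomplex classes and CRTF
co-binding probabilities, spike-in read counts with planted condition
effects, sgRNA counts with cell-line-specific depletion, Ct tables from
known abundances, and log-intensity proteomics matrices with
intensity-dependent missingness.  A single root seed fans out
deterministically to per-generator child streams, and every generator
emits a machine-readable truth table keyed to entity ids.

Default study conditions: a toy genome of three 10-Mb chromosomes, 600-bp
sites, subcomplex class probabilities (0.20, 0.10, 0.10, 0.05, 0.25, 0.15,
0.05, 0.10) over the eight combination classes, CRTF co-binding strongly
biased toward canonical-BAF-only sites, sequencing depth of 100 reads per
site, 5% of the library mapping to the spike genome, negative-binomial
screen counts at 500 reads per guide with dispersion 0.2, qPCR noise of
0.1 cycles, and proteomics noise of 0.5 on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, Peak, PeakSet
from .subcomplexes import CLASS_LABELS
from .chiprx import SpikeInCounts
from .screen import ScreenCounts
from .proteomics import IntensityMatrix

__all__ = [
    "SimulationConfig",
    "ScreenConfig",
    "QpcrConfig",
    "ProteomicsConfig",
    "simulate_peaksets",
    "simulate_chiprx",
    "simulate_screen",
    "simulate_qpcr",
    "simulate_proteomics",
]

DEFAULT_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
DEFAULT_CLASS_PROBS = (0.20, 0.10, 0.10, 0.05, 0.25, 0.15, 0.05, 0.10)
CRTF_FACTORS = ("P3F", "MYOD1", "MYCN")

# Class × CRTF co-binding probabilities: canonical-BAF-only sites carry the
# core regulatory factors most often, ncBAF-containing sites to a lesser
# extent, and PBAF-containing (promoter-biased) sites rarely.
DEFAULT_CRTF_PROBS = {
    "BAF+PBAF+ncBAF": (0.15, 0.15, 0.15),
    "BAF+PBAF": (0.10, 0.10, 0.10),
    "BAF+ncBAF": (0.40, 0.35, 0.30),
    "PBAF+ncBAF": (0.05, 0.05, 0.05),
    "BAF_only": (0.60, 0.50, 0.45),
    "PBAF_only": (0.05, 0.05, 0.05),
    "ncBAF_only": (0.30, 0.25, 0.20),
    "BRG1_unassigned": (0.10, 0.10, 0.10),
}

# fixed child-stream ids so each generator is independent of the others
_CHILD = {"peaks": 1, "chiprx": 2, "screen": 3, "qpcr": 4, "proteomics": 5}


@dataclass
class ScreenConfig:
    n_targets: int = 60
    guides_per_target: int = 5
    n_control_guides: int = 50
    n_rms_lines: int = 2
    n_non_rms_lines: int = 2
    planted_targets: int = 5
    effect: float = -2.0
    dispersion: float = 0.2
    depth: float = 500.0


@dataclass
class QpcrConfig:
    baseline_ct: float = 25.0
    noise_sd: float = 0.1
    n_tech_reps: int = 3
    n_bio_reps: int = 3


@dataclass
class ProteomicsConfig:
    n_proteins: int = 500
    n_samples_per_group: int = 4
    n_hits: int = 20
    effect_log2: float = 3.0
    noise_sd: float = 0.5
    baseline_log2: float = 20.0
    baseline_sd: float = 2.0
    missing_slope: float = 0.8
    missing_midpoint: float = 15.0
    n_forced_missing_control: int = 0


@dataclass
class SimulationConfig:
    """Root configuration; ``seed`` is mandatory and feeds every stream."""

    seed: int
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_sites: int = 2000
    site_width: int = 600
    jitter_bp: int = 100
    class_probs: Sequence[float] = DEFAULT_CLASS_PROBS
    crtf_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_CRTF_PROBS)
    )
    crtf_background_peaks: int = 200
    pbrm1_solo_fraction: float = 0.05
    signal_mu: float = 3.0
    signal_sigma: float = 0.8
    copula_rho: float = 0.5
    depth: float = 100.0
    weight_sigma: float = 0.5  # lognormal sigma of per-site count weights
    spike_fraction: float = 0.05
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    proteomics: ProteomicsConfig = field(default_factory=ProteomicsConfig)

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (8,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("class_probs must be 8 nonnegative values summing to 1")
        if not 0 <= self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if self.n_sites <= 0 or self.site_width <= 0:
            raise ValueError("n_sites and site_width must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-generator child stream from the root seed."""
        return np.random.default_rng([int(self.seed), _CHILD[stream]])

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("screen", ScreenConfig), ("qpcr", QpcrConfig),
                         ("proteomics", ProteomicsConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# genomic occupancy
# ---------------------------------------------------------------------------

def _place_sites(
    rng: np.random.Generator, genome: Mapping[str, int], n: int, width: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    margin: int = 200,
) -> list[GenomicInterval]:
    """Uniform non-overlapping placement with rejection sampling."""
    chroms = sorted(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    occupied = occupied if occupied is not None else {c: [] for c in chroms}
    for c in chroms:
        occupied.setdefault(c, [])
    placed: list[GenomicInterval] = []
    max_attempts = 50 * n + 1000
    attempts = 0
    import bisect

    starts_by_chrom = {c: sorted(s for s, _ in occupied[c]) for c in chroms}
    ends_by_chrom = {c: [e for _, e in sorted(occupied[c])] for c in chroms}
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "site placement failed: genome too small for requested sites; "
                "use a larger genome or fewer/narrower sites"
            )
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        start = int(rng.integers(margin, genome[chrom] - width - margin))
        end = start + width
        starts = starts_by_chrom[chrom]
        ends = ends_by_chrom[chrom]
        i = bisect.bisect_left(starts, start)
        clash = False
        if i < len(starts) and starts[i] < end + margin:
            clash = True
        if i > 0 and ends[i - 1] > start - margin:
            clash = True
        if clash:
            continue
        starts.insert(i, start)
        ends.insert(i, end)
        occupied[chrom].append((start, end))
        placed.append(GenomicInterval(chrom, start, end))
    return placed


def simulate_peaksets(cfg: SimulationConfig):
    """Generate subunit and CRTF peak sets with planted latent classes.

    Each site draws a class from ``class_probs``; BRG1 always peaks at the
    site, and DPF2/PBRM1/BRD9 peaks are placed according to the class's
    Boolean triple with jitter ≤ ``jitter_bp`` (overlap preserved).  CRTF
    peaks are planted per ``crtf_probs`` plus unbound background peaks.
    Extra PBRM1-only sites (no BRG1) exercise the PBRM1-without-BRG1 path.

    Returns ``(peaksets, truth)``: a dict of factor → PeakSet and a
    site-indexed truth table.
    """
    rng = cfg.rng("peaks")
    n_solo = int(round(cfg.pbrm1_solo_fraction * cfg.n_sites))
    occupied: dict[str, list[tuple[int, int]]] = {}
    sites = _place_sites(rng, cfg.genome, cfg.n_sites, cfg.site_width, occupied)
    solo_sites = _place_sites(rng, cfg.genome, n_solo, cfg.site_width, occupied)

    labels = np.asarray(CLASS_LABELS)
    classes = labels[rng.choice(8, size=cfg.n_sites, p=np.asarray(cfg.class_probs))]

    # Boolean triples straight from the label text
    def label_triple(lab: str) -> tuple[bool, bool, bool]:
        if lab == "BRG1_unassigned":
            return False, False, False
        parts = lab.replace("_only", "").split("+")
        return "BAF" in parts, "PBAF" in parts, "ncBAF" in parts

    factors: dict[str, list[Peak]] = {
        f: [] for f in ("BRG1", "DPF2", "PBRM1", "BRD9", *CRTF_FACTORS)
    }
    truth_rows = []
    crtf_width = max(100, cfg.site_width // 2)
    for i, (iv, lab) in enumerate(zip(sites, classes)):
        sid = f"site_{i:05d}"
        signal = float(rng.lognormal(cfg.signal_mu, cfg.signal_sigma))
        factors["BRG1"].append(Peak(iv, f"BRG1_{sid}", signal))
        has_d, has_p, has_b = label_triple(lab)
        for flag, sub in ((has_d, "DPF2"), (has_p, "PBRM1"), (has_b, "BRD9")):
            if flag:
                j = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
                sub_iv = GenomicInterval(iv.chrom, iv.start + j, iv.end + j)
                factors[sub].append(
                    Peak(sub_iv, f"{sub}_{sid}", float(rng.lognormal(cfg.signal_mu, cfg.signal_sigma)))
                )
        crtf_flags = {}
        pvec = cfg.crtf_probs[lab]
        pad = (cfg.site_width - crtf_width) // 2
        for f, p in zip(CRTF_FACTORS, pvec):
            bound = bool(rng.random() < p)
            crtf_flags[f] = bound
            if bound:
                j = int(rng.integers(-min(cfg.jitter_bp, pad), min(cfg.jitter_bp, pad) + 1))
                c_iv = GenomicInterval(iv.chrom, iv.start + pad + j, iv.end - pad + j)
                factors[f].append(
                    Peak(c_iv, f"{f}_{sid}", float(rng.lognormal(cfg.signal_mu, cfg.signal_sigma)))
                )
        truth_rows.append(
            (sid, iv.chrom, iv.start, iv.end, lab, has_d, has_p, has_b,
             *(crtf_flags[f] for f in CRTF_FACTORS))
        )
    for i, iv in enumerate(solo_sites):
        factors["PBRM1"].append(
            Peak(iv, f"PBRM1_solo_{i:04d}", float(rng.lognormal(cfg.signal_mu, cfg.signal_sigma)))
        )
    bg_sites = _place_sites(
        rng, cfg.genome, cfg.crtf_background_peaks * len(CRTF_FACTORS),
        crtf_width, occupied
    )
    for i, iv in enumerate(bg_sites):
        f = CRTF_FACTORS[i % len(CRTF_FACTORS)]
        factors[f].append(
            Peak(iv, f"{f}_bg_{i:04d}", float(rng.lognormal(cfg.signal_mu, cfg.signal_sigma)))
        )
    peaksets = {f: PeakSet(f, peaks) for f, peaks in factors.items()}
    truth = pd.DataFrame(
        truth_rows,
        columns=["site", "chrom", "start", "end", "class_label",
                 "has_dpf2", "has_pbrm1", "has_brd9", *CRTF_FACTORS],
    ).set_index("site")
    return peaksets, truth


# ---------------------------------------------------------------------------
# spike-in read counts
# ---------------------------------------------------------------------------

def simulate_chiprx(
    cfg: SimulationConfig,
    sites: PeakSet | Sequence[str],
    condition_effects: Mapping[str, Mapping[str, float] | float],
) -> tuple[dict[str, SpikeInCounts], pd.DataFrame]:
    """Per-condition spike-in libraries with planted log2 condition effects.

    Per site ``raw ~ Poisson(depth × weight × 2^effect)`` with lognormal
    site weights shared across conditions.  The spike-mapped read count is
    drawn around a condition-independent nominal library size (a constant
    amount of exogenous chromatin enters every reaction), so planted
    effects survive normalization.  ``condition_effects`` maps condition →
    either a scalar effect applied to all sites or a per-site mapping
    (missing sites default to 0).

    Returns (condition → SpikeInCounts, per-site truth table).
    """
    names = sites.names() if isinstance(sites, PeakSet) else list(sites)
    n = len(names)
    if n == 0:
        raise ValueError("sites must be nonempty")
    rng = cfg.rng("chiprx")
    weights = rng.lognormal(0.0, cfg.weight_sigma, size=n)
    nominal_total = cfg.depth * float(weights.sum())
    libs: dict[str, SpikeInCounts] = {}
    truth = pd.DataFrame(index=pd.Index(names, name="site"))
    truth["weight"] = weights
    for cond, eff in condition_effects.items():
        if isinstance(eff, Mapping):
            effect = np.array([float(eff.get(s, 0.0)) for s in names])
        else:
            effect = np.full(n, float(eff))
        lam = cfg.depth * weights * np.power(2.0, effect)
        raw = rng.poisson(lam)
        if cfg.spike_fraction <= 0:
            spike_total = 0
        else:
            spike_lambda = cfg.spike_fraction * nominal_total / (1.0 - cfg.spike_fraction)
            spike_total = int(rng.poisson(spike_lambda))
        human_total = int(raw.sum() * 1.25) + 1000  # reads outside peaks
        libs[cond] = SpikeInCounts(
            library_id=f"sim_{cond}",
            condition=cond,
            counts=pd.Series(raw, index=names),
            human_mapped_total=human_total,
            spike_mapped_total=spike_total,
        )
        truth[f"effect_{cond}"] = effect
    return libs, truth


# ---------------------------------------------------------------------------
# CRISPR screen
# ---------------------------------------------------------------------------

def simulate_screen(cfg: SimulationConfig) -> tuple[ScreenCounts, pd.DataFrame]:
    """Negative-binomial screen counts with planted RMS-specific depletion.

    Early counts ~ NB(mean=depth, dispersion); late means are the early
    means times ``2^LFC`` where LFC equals ``effect`` for planted targets
    in RMS lines and 0 otherwise (controls always 0).
    """
    sc = cfg.screen
    rng = cfg.rng("screen")
    targets = [f"DOM{i:03d}" for i in range(sc.n_targets)]
    planted = targets[: sc.planted_targets]
    guide_ids, target_of, is_ctrl = [], [], []
    for t in targets:
        for g in range(sc.guides_per_target):
            guide_ids.append(f"{t}_g{g}")
            target_of.append(t)
            is_ctrl.append(False)
    for g in range(sc.n_control_guides):
        guide_ids.append(f"CTRL_g{g:03d}")
        target_of.append("control")
        is_ctrl.append(True)
    guides = pd.DataFrame(
        {"target_domain": target_of, "is_control": is_ctrl}, index=guide_ids
    )
    lines = [(f"RMS{i + 1}", True) for i in range(sc.n_rms_lines)] + [
        (f"NONRMS{i + 1}", False) for i in range(sc.n_non_rms_lines)
    ]
    sample_rows, count_cols = [], {}
    for line, rms in lines:
        lfc = np.array(
            [
                sc.effect if (rms and t in planted and not c) else 0.0
                for t, c in zip(target_of, is_ctrl)
            ]
        )
        for tp in ("early", "late"):
            sid = f"{line}_{tp}"
            mean = sc.depth * (np.power(2.0, lfc) if tp == "late" else 1.0)
            if sc.dispersion > 0:
                r = 1.0 / sc.dispersion
                p = r / (r + mean)
                counts = rng.negative_binomial(r, p)
            else:
                counts = rng.poisson(mean)
            count_cols[sid] = counts
            sample_rows.append((sid, line, rms, tp))
    counts = pd.DataFrame(count_cols, index=pd.Index(guide_ids, name="guide"))
    guides.index.name = "guide"
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "cell_line", "rms", "timepoint"]
    ).set_index("sample")
    truth = pd.DataFrame(
        {"planted": [t in planted for t in targets],
         "effect": [sc.effect if t in planted else 0.0 for t in targets]},
        index=pd.Index(targets, name="target_domain"),
    )
    return ScreenCounts(counts, guides, samples), truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    cfg: SimulationConfig,
    true_fold_changes: Mapping[str, Mapping[str, float]],
    control_condition: str = "control",
    reference: str = "GAPDH",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct tables from known abundances: ``Ct = c0 − log2(abundance) + ε``.

    ``true_fold_changes`` maps target → {condition → fold change vs the
    control condition}; the reference assay has fold change 1 everywhere.
    Returns (long Ct table compatible with
    :func:`bafmap.qpcr.relative_expression`, truth table).
    """
    q = cfg.qpcr
    rng = cfg.rng("qpcr")
    conditions = sorted({c for m in true_fold_changes.values() for c in m} | {control_condition})
    rows = []
    truth_rows = []
    for target, fc_map in true_fold_changes.items():
        if any(fc <= 0 for fc in fc_map.values()):
            raise ValueError("fold changes must be positive")
        base_abund = 2.0 ** float(rng.normal(3.0, 1.0))
        for cond in conditions:
            fc = 1.0 if cond == control_condition else float(fc_map.get(cond, 1.0))
            abund = base_abund * fc
            truth_rows.append((target, cond, fc))
            for b in range(q.n_bio_reps):
                for _ in range(q.n_tech_reps):
                    ct = q.baseline_ct - np.log2(abund) + rng.normal(0.0, q.noise_sd)
                    rows.append((target, cond, b, float(ct)))
    ref_abund = 2.0 ** 5.0
    for cond in conditions:
        for b in range(q.n_bio_reps):
            for _ in range(q.n_tech_reps):
                ct = q.baseline_ct - np.log2(ref_abund) + rng.normal(0.0, q.noise_sd)
                rows.append((reference, cond, b, float(ct)))
    table = pd.DataFrame(rows, columns=["target", "condition", "bio_rep", "ct"])
    truth = pd.DataFrame(truth_rows, columns=["target", "condition", "fold_change"])
    return table, truth


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def simulate_proteomics(cfg: SimulationConfig) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Log-intensity matrix with planted enrichment and MNAR missingness.

    Log2 intensities are baseline + effect + Gaussian noise; an entry goes
    missing with probability ``logistic(−slope × (x − midpoint))``, so low
    intensities are missing more often (missing-not-at-random).  The first
    ``n_forced_missing_control`` planted hits are forced fully missing in
    the control group to exercise the pseudo-fold-change path.
    """
    p = cfg.proteomics
    rng = cfg.rng("proteomics")
    prots = [f"PROT{i:04d}" for i in range(p.n_proteins)]
    hits = prots[: p.n_hits]
    forced = hits[: p.n_forced_missing_control]
    samples = [f"bait_{i + 1}" for i in range(p.n_samples_per_group)] + [
        f"control_{i + 1}" for i in range(p.n_samples_per_group)
    ]
    groups = pd.Series(
        ["bait"] * p.n_samples_per_group + ["control"] * p.n_samples_per_group,
        index=samples,
    )
    base = rng.normal(p.baseline_log2, p.baseline_sd, size=p.n_proteins)
    is_hit = np.array([pr in hits for pr in prots])
    mat = np.empty((p.n_proteins, len(samples)))
    for j, s in enumerate(samples):
        eff = np.where(is_hit & (groups[s] == "bait"), p.effect_log2, 0.0)
        mat[:, j] = base + eff + rng.normal(0.0, p.noise_sd, size=p.n_proteins)
    miss_p = 1.0 / (1.0 + np.exp(p.missing_slope * (mat - p.missing_midpoint)))
    missing = rng.random(mat.shape) < miss_p
    ctrl_cols = [j for j, s in enumerate(samples) if groups[s] == "control"]
    for pr in forced:
        i = prots.index(pr)
        missing[i, ctrl_cols] = True
        missing[i, [j for j in range(len(samples)) if j not in ctrl_cols]] = False
    log2 = np.where(missing, np.nan, mat)
    prot_index = pd.Index(prots, name="protein")
    inten = pd.DataFrame(np.power(2.0, log2), index=prot_index, columns=samples)
    inten.columns.name = None
    n_pep = pd.Series(1 + rng.poisson(3.0, size=p.n_proteins), index=prot_index)
    n_pep[is_hit] = np.maximum(n_pep[is_hit], 2)  # planted hits pass the peptide filter
    truth = pd.DataFrame(
        {
            "planted": is_hit,
            "effect_log2": np.where(is_hit, p.effect_log2, 0.0),
            "forced_missing_control": [pr in forced for pr in prots],
        },
        index=pd.Index(prots, name="protein"),
    )
    return IntensityMatrix(inten, n_pep, groups), truth
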