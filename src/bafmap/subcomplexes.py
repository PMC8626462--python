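"""Classify BRG1-anchored sites into mSWI/SNF subcomplex combination classes.

The three major mSWI/SNF assemblies are distinguished by a diagnostic
subunit co-occurring with the shared BRG1 ATPase at a site:

* canonical BAF  — BRG1 and DPF2,
* PBAF           — BRG1 and PBRM1,
* ncBAF          — BRG1 and BRD9.

Every BRG1 peak thus carries a Boolean triple (DPF2, PBRM1, BRD9 overlap)
which maps deterministically onto one of eight combination classes.  On top
of the classification this module quantifies core-regulatory transcription
factor (CRTF) co-occupancy per class, ranks chromatin-state associations,
and stratifies expression changes by occupancy class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    Peak,
    PeakSet,
    StateSegmentation,
    intersect_sets,
)

__all__ = [
    "CLASS_LABELS",
    "SubcomplexCalls",
    "CooccupancyTable",
    "GeneAssignment",
    "classify_subcomplexes",
    "class_label",
    "cooccupancy_fractions",
    "state_enrichment",
    "assign_peaks_to_genes",
    "expression_by_occupancy",
    "read_tss_table",
    "read_deg_table",
]

#: The eight combination classes, in canonical order.
CLASS_LABELS = (
    "BAF+PBAF+ncBAF",
    "BAF+PBAF",
    "BAF+ncBAF",
    "PBAF+ncBAF",
    "BAF_only",
    "PBAF_only",
    "ncBAF_only",
    "BRG1_unassigned",
)


def class_label(has_dpf2: bool, has_pbrm1: bool, has_brd9: bool) -> str:
    """Deterministic 8-way label from the (DPF2, PBRM1, BRD9) triple."""
    parts = []
    if has_dpf2:
        parts.append("BAF")
    if has_pbrm1:
        parts.append("PBAF")
    if has_brd9:
        parts.append("ncBAF")
    if not parts:
        return "BRG1_unassigned"
    if len(parts) == 1:
        return parts[0] + "_only"
    return "+".join(parts)


@dataclass
class SubcomplexCalls:
    """Per-BRG1-peak subcomplex calls plus PBRM1 peaks lacking BRG1.

    ``table`` is indexed by BRG1 peak name with columns ``has_dpf2``,
    ``has_pbrm1``, ``has_brd9`` (bool) and ``class_label``.  Class counts
    always sum to the number of BRG1 peaks (the classes partition the set).
    """

    table: pd.DataFrame
    brg1: PeakSet
    pbrm1_without_brg1: PeakSet | None = None

    def class_counts(self) -> pd.Series:
        counts = self.table["class_label"].value_counts()
        return counts.reindex(CLASS_LABELS, fill_value=0)

    def class_members(self, label: str) -> list[Peak]:
        if label not in CLASS_LABELS:
            raise KeyError(f"unknown class label {label!r}")
        names = set(self.table.index[self.table["class_label"] == label])
        return [p for p in self.brg1 if p.name in names]

    def __len__(self) -> int:
        return len(self.table)


def classify_subcomplexes(
    brg1: PeakSet,
    dpf2: PeakSet,
    pbrm1: PeakSet,
    brd9: PeakSet,
    min_bp: int = 1,
) -> SubcomplexCalls:
    """Assign every BRG1 peak its subcomplex combination class.

    A site is called positive for a subunit when at least one of that
    subunit's peaks overlaps the BRG1 peak by ``min_bp`` or more.  PBRM1
    peaks with no BRG1 overlap are collected separately (promoter-biased
    PBAF-only signal is analysed on its own anchor).
    """
    if len(brg1) == 0:
        warnings.warn("empty BRG1 peak set: returning empty calls", stacklevel=2)
    hit_d = intersect_sets(brg1, dpf2, min_bp)
    hit_p = intersect_sets(brg1, pbrm1, min_bp)
    hit_b = intersect_sets(brg1, brd9, min_bp)
    rows = []
    for p in brg1:
        d, pb, b = bool(hit_d[p.name]), bool(hit_p[p.name]), bool(hit_b[p.name])
        rows.append((p.name, d, pb, b, class_label(d, pb, b)))
    table = pd.DataFrame(
        rows, columns=["peak", "has_dpf2", "has_pbrm1", "has_brd9", "class_label"]
    ).set_index("peak")
    pbrm1_hits = intersect_sets(pbrm1, brg1, min_bp)
    solo = [p for p in pbrm1 if not pbrm1_hits[p.name]]
    solo_set = PeakSet(f"{pbrm1.factor}_without_BRG1", solo) if solo else None
    return SubcomplexCalls(table, brg1, solo_set)


@dataclass
class CooccupancyTable:
    """CRTF co-occupancy fractions per subcomplex class.

    ``fractions``: class × factor (plus ``any_CRTF``) fraction of class
    sites overlapped (NaN for empty classes, never 0).  ``counts`` holds
    the corresponding site counts and ``class_sizes`` the class totals.
    ``reverse_fractions``: factor × class share of the factor's peaks that
    fall in each class.
    """

    fractions: pd.DataFrame
    counts: pd.DataFrame
    class_sizes: pd.Series
    reverse_fractions: pd.DataFrame


def cooccupancy_fractions(
    calls: SubcomplexCalls,
    crtfs: Sequence[PeakSet],
    min_bp: int = 1,
) -> CooccupancyTable:
    """Fraction of each class's sites carrying each CRTF, and the reverse.

    The forward direction answers "what share of e.g. BAF_only sites are
    MYCN-bound"; the reverse direction answers "what share of all MYCN
    peaks fall at BAF_only sites".
    """
    if len(calls) == 0:
        raise ValueError("cooccupancy_fractions requires nonempty calls")
    factors = [c.factor for c in crtfs]
    hits = {c.factor: intersect_sets(calls.brg1, c, min_bp) for c in crtfs}
    cls = calls.table["class_label"]
    sizes = calls.class_counts()
    count_tab = pd.DataFrame(0, index=list(CLASS_LABELS), columns=factors + ["any_CRTF"])
    for p in calls.brg1:
        label = cls.loc[p.name]
        any_hit = False
        for f in factors:
            if hits[f][p.name]:
                count_tab.loc[label, f] += 1
                any_hit = True
        if any_hit:
            count_tab.loc[label, "any_CRTF"] += 1
    frac = count_tab.div(sizes, axis=0)
    frac[sizes == 0] = np.nan  # undefined, not 0
    reverse = pd.DataFrame(0.0, index=factors, columns=list(CLASS_LABELS))
    for c in crtfs:
        back = intersect_sets(c, calls.brg1, min_bp)
        n = len(c)
        for p in c:
            seen = {cls.loc[b.name] for b in back[p.name]}
            for label in seen:
                reverse.loc[c.factor, label] += 1
        if n:
            reverse.loc[c.factor] /= n
    return CooccupancyTable(frac, count_tab, sizes, reverse)


def state_enrichment(
    category_peaks: PeakSet, seg: StateSegmentation, none_label: str = "none"
) -> pd.Series:
    """log2 enrichment of peak midpoints per chromatin state.

    ``enrichment(s) = log2( peak_fraction(s) / genomic_fraction(s) )`` where
    a peak contributes through its midpoint (so fractions are a partition
    even for peaks spanning state boundaries).  Midpoints in unsegmented
    gaps count toward a ``none`` state whose genomic share is the
    unsegmented remainder.  Result sorted descending; states with zero
    genomic bp are excluded with a warning.
    """
    if len(category_peaks) == 0:
        raise ValueError("state_enrichment requires nonempty peaks")
    state_bp = seg.state_bp()
    total = seg.total_genome_bp
    gap_bp = total - seg.segmented_bp
    if gap_bp > 0:
        state_bp[none_label] = gap_bp
    peak_states: dict[str, int] = {}
    for p in category_peaks:
        label = seg.state_at(p.chrom, p.interval.midpoint) or none_label
        peak_states[label] = peak_states.get(label, 0) + 1
    n = len(category_peaks)
    values = {}
    for state, bp in state_bp.items():
        if bp == 0:
            warnings.warn(f"state {state!r} covers 0 bp; excluded", stacklevel=2)
            continue
        pf = peak_states.get(state, 0) / n
        gf = bp / total
        values[state] = np.log2(pf / gf) if pf > 0 else -np.inf
    orphan = set(peak_states) - set(state_bp)
    if orphan:
        warnings.warn(f"peak midpoints in zero-bp states: {sorted(orphan)}", stacklevel=2)
    return pd.Series(values, name=category_peaks.factor).sort_values(ascending=False)


@dataclass
class GeneAssignment:
    """Peaks assigned to a gene's TSS, plus the inherited occupancy class."""

    gene: str
    tss: GenomicInterval
    assigned_peaks: list[str] = field(default_factory=list)
    occupancy_class: str | None = None


def read_tss_table(path) -> dict[str, GenomicInterval]:
    """Read a 4-column TSV (gene, chrom, tss_position 1-based, strand).

    Strand is stored in the file for provenance but unused here; the TSS
    becomes a 1-bp half-open interval at the 0-based position.
    """
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "gene\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            pos = int(fields[2]) - 1
            out[fields[0]] = GenomicInterval(fields[1], pos, pos + 1)
    return out


def read_deg_table(path) -> pd.Series:
    """Read a TSV of (gene, log2FC[, padj]) into a gene-indexed Series."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df.set_index(df.columns[0])["log2fc"].astype(float)


def assign_peaks_to_genes(
    peaks: PeakSet,
    tss_table: Mapping[str, GenomicInterval],
    window_bp: int = 50_000,
    calls: SubcomplexCalls | None = None,
) -> list[GeneAssignment]:
    """Assign peaks to genes by TSS proximity.

    A gene is "bound" iff at least one peak midpoint lies within
    ``±window_bp`` of its TSS (inclusive).  Each peak is credited to its
    nearest TSS only (ties: smaller distance, then lexicographic gene
    symbol).  When subcomplex ``calls`` on the same peaks are supplied,
    each bound gene inherits the occupancy class of its nearest assigned
    peak.
    """
    if not tss_table:
        raise ValueError("tss_table must be nonempty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene, iv in tss_table.items():
        by_chrom.setdefault(iv.chrom, []).append((iv.start, gene))
    for lst in by_chrom.values():
        lst.sort()
    assignments = {g: GeneAssignment(g, iv) for g, iv in tss_table.items()}
    nearest_peak: dict[str, tuple[int, str]] = {}
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            continue
        mid = p.interval.midpoint
        best: tuple[int, str] | None = None
        # candidate TSSs within the window, via binary search on positions
        positions = [c[0] for c in cands]
        import bisect

        lo = bisect.bisect_left(positions, mid - window_bp)
        hi = bisect.bisect_right(positions, mid + window_bp)
        for pos, gene in cands[lo:hi]:
            d = abs(mid - pos)
            key = (d, gene)
            if best is None or key < best:
                best = key
        if best is None:
            continue
        d, gene = best
        assignments[gene].assigned_peaks.append(p.name)
        cur = nearest_peak.get(gene)
        if cur is None or (d, p.name) < cur:
            nearest_peak[gene] = (d, p.name)
    if calls is not None:
        cls = calls.table["class_label"]
        for gene, (_, pname) in nearest_peak.items():
            if pname in cls.index:
                assignments[gene].occupancy_class = cls.loc[pname]
    return [a for a in assignments.values() if a.assigned_peaks]


def expression_by_occupancy(
    deg_table: Mapping[str, float] | pd.Series,
    groups: Mapping[str, Sequence[str]],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Median log2FC per occupancy group with percentile-bootstrap 95% CI.

    ``groups`` maps group names to gene lists (typically built from
    :func:`assign_peaks_to_genes` output, e.g. BRG1-only vs BRG1+MYCN).
    Genes absent from ``deg_table`` are dropped.  Empty groups are
    reported with n=0 and NaN summaries.  The raw per-group values are
    attached as ``result.attrs['values']``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deg = pd.Series(deg_table, dtype=float) if not isinstance(deg_table, pd.Series) else deg_table
    rows = []
    raw: dict[str, np.ndarray] = {}
    for name, genes in groups.items():
        vals = deg.reindex([g for g in genes if g in deg.index]).to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        raw[name] = vals
        if vals.size == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan))
            continue
        med = float(np.median(vals))
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boots = np.median(vals[idx], axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((name, int(vals.size), med, float(lo), float(hi)))
    out = pd.DataFrame(
        rows, columns=["group", "n", "median_log2fc", "ci_low", "ci_high"]
    ).set_index("group")
    out.attrs["values"] = raw
    return out
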