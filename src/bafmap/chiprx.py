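"""Spike-in (ChIP-Rx) and in-peak normalization, and differential occupancy.

Two normalizations are implemented:

* RRPM — reference exogenous reads per million mapped reads: per-peak human
  read counts scaled per million Drosophila-spike-mapped reads.  Because an
  identical amount of exogenous chromatin is carried through every ChIP
  reaction, RRPM is comparable across conditions even when global signal
  changes.
* RPMPR — reads per million peak reads: per-peak counts scaled by the total
  reads falling in the union peak set, so signals sum to 1e6 per library.

Differential occupancy ("enhancer invasion" at co-occupied sites after
ATPase loss) is quantified as a per-site pseudocounted log2 RRPM ratio with
a paired Wilcoxon signed-rank summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet

__all__ = [
    "SpikeInCounts",
    "InvasionResult",
    "read_spikein_counts",
    "write_spikein_counts",
    "rrpm_normalize",
    "rpmpr_normalize",
    "quartile_stratify",
    "invasion_analysis",
    "signal_delta_track",
]


@dataclass
class SpikeInCounts:
    """Per-peak raw read counts for one library plus mapping totals.

    ``counts`` is a peak-name-indexed Series of nonnegative integers with
    ``counts.sum() <= human_mapped_total``.  ``spike_mapped_total``
    (Drosophila-mapped reads) must be positive for RRPM normalization;
    a zero value is representable but rejected by :func:`rrpm_normalize`.
    """

    library_id: str
    condition: str
    counts: pd.Series
    human_mapped_total: int
    spike_mapped_total: int

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype="int64")
        if (self.counts < 0).any():
            bad = self.counts.index[self.counts < 0][0]
            raise ValueError(f"negative count for peak {bad!r}")
        if self.spike_mapped_total < 0:
            raise ValueError(
                f"spike_mapped_total must be nonnegative, got {self.spike_mapped_total}"
            )
        if self.human_mapped_total < 0:
            raise ValueError("human_mapped_total must be nonnegative")
        if int(self.counts.sum()) > self.human_mapped_total:
            raise ValueError(
                "per-peak counts exceed human_mapped_total "
                f"({int(self.counts.sum())} > {self.human_mapped_total})"
            )


def read_spikein_counts(path: str | Path, library_id: str | None = None,
                        condition: str = "") -> SpikeInCounts:
    """Read the TSV dialect: ``#human_mapped_total=``/``#spike_mapped_total=``
    header lines followed by ``peak_name<TAB>count`` rows."""
    path = Path(path)
    human = spike = None
    names: list[str] = []
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#human_mapped_total="):
                human = int(line.split("=", 1)[1])
            elif line.startswith("#spike_mapped_total="):
                spike = int(line.split("=", 1)[1])
            elif line.startswith("#"):
                continue
            else:
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                names.append(fields[0])
                values.append(int(fields[1]))
    if human is None or spike is None:
        raise ValueError(f"{path}: missing mapped-total header lines")
    return SpikeInCounts(
        library_id or path.stem,
        condition,
        pd.Series(values, index=names),
        human,
        spike,
    )


def write_spikein_counts(sc: SpikeInCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#human_mapped_total={sc.human_mapped_total}\n")
        fh.write(f"#spike_mapped_total={sc.spike_mapped_total}\n")
        for name, v in sc.counts.items():
            fh.write(f"{name}\t{int(v)}\n")


def rrpm_normalize(counts: SpikeInCounts) -> pd.Series:
    """RRPM: ``raw * 1e6 / spike_mapped_total`` (exactly linear in raw)."""
    if counts.spike_mapped_total <= 0:
        raise ValueError("RRPM undefined: zero spike-mapped reads")
    sig = counts.counts.astype(float) * 1e6 / counts.spike_mapped_total
    sig.attrs["units"] = "RRPM"
    return sig


def rpmpr_normalize(counts: SpikeInCounts, union_peaks: PeakSet | Sequence[str]) -> pd.Series:
    """RPMPR: per-peak counts scaled so the union peak set sums to 1e6."""
    names = union_peaks.names() if isinstance(union_peaks, PeakSet) else list(union_peaks)
    raw = counts.counts.reindex(names, fill_value=0).astype(float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("RPMPR undefined: no reads in the union peak set")
    sig = raw * 1e6 / total
    sig.attrs["units"] = "RPMPR"
    return sig


def quartile_stratify(anchor: pd.Series, partner: pd.Series) -> pd.DataFrame:
    """Partner signal distribution across quartiles of anchor signal.

    Anchor peaks are ranked ascending by signal (ties broken by peak
    name), split into four bins Q1..Q4 with any remainder going to the
    lower quartiles, and the partner signal on the same intervals (0
    where the partner has no overlapping peak) is summarized per bin.

    Returns a frame indexed Q1..Q4 with columns ``n``, ``median_partner``,
    ``anchor_min``, ``anchor_max``; the per-bin partner values are in
    ``result.attrs['values']``.
    """
    n = len(anchor)
    if n < 8:
        raise ValueError(f"need >=8 anchor peaks, got {n}")
    order = sorted(anchor.index, key=lambda name: (anchor[name], name))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]  # remainder to lower bins
    part = partner.reindex(anchor.index, fill_value=0.0).astype(float)
    rows = []
    values: dict[str, np.ndarray] = {}
    pos = 0
    for i, size in enumerate(sizes):
        names = order[pos:pos + size]
        pos += size
        q = f"Q{i + 1}"
        vals = part[names].to_numpy()
        values[q] = vals
        rows.append(
            (q, size, float(np.median(vals)),
             float(anchor[names].min()), float(anchor[names].max()))
        )
    out = pd.DataFrame(
        rows, columns=["quartile", "n", "median_partner", "anchor_min", "anchor_max"]
    ).set_index("quartile")
    out.attrs["values"] = values
    return out


@dataclass
class InvasionResult:
    """Per-site differential occupancy at co-occupied sites.

    ``deltas``: per-site log2((RRPM_treated + pc)/(RRPM_control + pc)).
    The p-value is a paired Wilcoxon signed-rank test across sites (1.0
    when every delta is zero).
    """

    deltas: pd.Series
    n_sites: int
    median_delta: float
    fraction_increased: float
    p_value: float


def _aligned_rrpm(
    sites: Sequence[str], control: SpikeInCounts, treated: SpikeInCounts
) -> tuple[pd.Series, pd.Series]:
    for lib in (control, treated):
        missing = [s for s in sites if s not in lib.counts.index]
        if missing:
            raise KeyError(
                f"library {lib.library_id!r} missing site(s): {missing[:5]}"
            )
    c = rrpm_normalize(control).reindex(sites)
    t = rrpm_normalize(treated).reindex(sites)
    return c, t


def invasion_analysis(
    sites: PeakSet | Sequence[str],
    control: SpikeInCounts,
    treated: SpikeInCounts,
    pseudocount: float = 0.5,
) -> InvasionResult:
    """Quantify occupancy change at co-occupied sites between conditions."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    names = sites.names() if isinstance(sites, PeakSet) else list(sites)
    c, t = _aligned_rrpm(names, control, treated)
    # difference of logs (not log of ratio) so a condition swap negates
    # every delta exactly in floating point
    deltas = np.log2(t + pseudocount) - np.log2(c + pseudocount)
    deltas.name = "log2_delta"
    nonzero = deltas[deltas != 0]
    if len(nonzero) == 0:
        p = 1.0
    else:
        p = float(stats.wilcoxon(deltas.to_numpy(), zero_method="wilcox").pvalue)
    return InvasionResult(
        deltas=deltas,
        n_sites=len(names),
        median_delta=float(deltas.median()),
        fraction_increased=float((deltas > 0).mean()),
        p_value=p,
    )


def signal_delta_track(
    control: SpikeInCounts,
    treated: SpikeInCounts,
    peaks: PeakSet | Sequence[str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-peak table of control RRPM, treated RRPM and log2 delta.

    Same delta formula as :func:`invasion_analysis`, for arbitrary factors
    (e.g. validating ATPase loss, or acetylation gain, after knockout).
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    names = peaks.names() if isinstance(peaks, PeakSet) else list(peaks)
    c, t = _aligned_rrpm(names, control, treated)
    return pd.DataFrame(
        {
            "control_rrpm": c,
            "treated_rrpm": t,
            "log2_delta": np.log2(t + pseudocount) - np.log2(c + pseudocount),
        }
    )
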