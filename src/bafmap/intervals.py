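"""Genomic interval types, BED/narrowPeak I/O, and exact interval algebra.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  ChIP peaks are unstranded, so strand is ignored by every
operation in this module.  "Co-occupancy" between two peak sets means an
interval overlap of at least ``min_bp`` base pairs (default 1).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "StateSegmentation",
    "PeakParseError",
    "read_peaks",
    "write_peaks",
    "read_chrom_sizes",
    "read_segmentation",
    "overlaps",
    "overlap_length",
    "intersect_sets",
    "merge_peaks",
    "subtract_intervals",
]


class PeakParseError(ValueError):
    """Raised when a BED/narrowPeak line cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """An interval plus identifier and occupancy signal.

    ``signal`` is in arbitrary units (e.g. MACS score or RPMPR).
    ``summit_offset``, when present, is the summit position relative to
    ``interval.start``.
    """

    interval: GenomicInterval
    name: str
    signal: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be nonnegative, got {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside "
                f"[0, {len(self.interval)})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """A named factor's peaks, kept sorted by (chrom, start, end).

    Duplicate identical intervals are collapsed at construction with a
    warning (keeping the first record); peak names must be unique.
    """

    def __init__(self, factor: str, peaks: Iterable[Peak]):
        if not factor:
            raise ValueError("factor name must be non-empty")
        self.factor = factor
        ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
        deduped: list[Peak] = []
        seen_iv: set[GenomicInterval] = set()
        n_dups = 0
        for p in ordered:
            if p.interval in seen_iv:
                n_dups += 1
                continue
            seen_iv.add(p.interval)
            deduped.append(p)
        if n_dups:
            warnings.warn(
                f"PeakSet({factor}): collapsed {n_dups} duplicate interval(s)",
                stacklevel=2,
            )
        names = [p.name for p in deduped]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate peak names in {factor}: {dup[:5]}")
        self.peaks: list[Peak] = deduped

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def by_name(self) -> dict[str, Peak]:
        return {p.name: p for p in self.peaks}

    def names(self) -> list[str]:
        return [p.name for p in self.peaks]

    def __repr__(self) -> str:  # pragma: no cover
        return f"PeakSet({self.factor!r}, n={len(self)})"


@dataclass
class StateSegmentation:
    """A chromatin-state segmentation (chromHMM-style) plus genome sizes.

    Segments must be non-overlapping within each chromosome and lie within
    the chromosome length recorded in ``genome_sizes``.
    """

    segments: list[tuple[GenomicInterval, str]]
    genome_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s[0].chrom, s[0].start))
        prev: dict[str, int] = {}
        for iv, label in self.segments:
            if not label:
                raise ValueError("state label must be non-empty")
            size = self.genome_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"segment chromosome {iv.chrom} not in genome_sizes")
            if iv.end > size:
                raise ValueError(
                    f"segment {iv.chrom}:{iv.start}-{iv.end} exceeds length {size}"
                )
            if iv.start < prev.get(iv.chrom, 0):
                raise ValueError(f"overlapping segments on {iv.chrom} at {iv.start}")
            prev[iv.chrom] = iv.end

    @property
    def total_genome_bp(self) -> int:
        return sum(self.genome_sizes.values())

    @property
    def segmented_bp(self) -> int:
        return sum(len(iv) for iv, _ in self.segments)

    def state_bp(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for iv, label in self.segments:
            out[label] = out.get(label, 0) + len(iv)
        return out

    def state_at(self, chrom: str, pos: int) -> str | None:
        """Return the state label covering ``pos``, or None in a gap."""
        idx = self._index().get(chrom)
        if idx is None:
            return None
        starts, ends, labels = idx
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None

    def _index(self):
        if not hasattr(self, "_idx"):
            idx: dict[str, tuple[list[int], list[int], list[str]]] = {}
            for iv, label in self.segments:
                starts, ends, labels = idx.setdefault(iv.chrom, ([], [], []))
                starts.append(iv.start)
                ends.append(iv.end)
                labels.append(label)
            self._idx = idx
        return self._idx


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_int(text: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise PeakParseError(
            f"{path}:{lineno}: non-integer {what}: {text!r}"
        ) from None


def read_peaks(path: str | Path, format: str = "bed", factor: str | None = None) -> PeakSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a sorted :class:`PeakSet`.

    Missing names are auto-generated as ``<factor>_peak_<i>``; for 3-column
    BED the signal defaults to 0.  narrowPeak takes signal from column 7 and
    the summit from column 10 (−1 means "no summit").
    """
    path = Path(path)
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    if factor is None:
        factor = path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            if format == "narrowPeak" and len(fields) < 10:
                raise PeakParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 fields, got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", str(path), lineno)
            end = _parse_int(fields[2], "end", str(path), lineno)
            if end <= start or start < 0:
                raise PeakParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else (
                f"{factor}_peak_{len(peaks)}"
            )
            signal = 0.0
            summit: int | None = None
            if format == "narrowPeak":
                try:
                    signal = float(fields[6])
                except ValueError:
                    raise PeakParseError(
                        f"{path}:{lineno}: non-numeric signalValue {fields[6]!r}"
                    ) from None
                raw_summit = _parse_int(fields[9], "summit", str(path), lineno)
                summit = None if raw_summit == -1 else raw_summit
            elif len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    signal = float(fields[4])
                except ValueError:
                    raise PeakParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), name, signal, summit)
                )
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(factor, peaks)


def write_peaks(ps: PeakSet, path: str | Path, format: str = "bed") -> None:
    """Write a PeakSet as BED6 or 10-column narrowPeak (lossless round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in ps:
            if format == "bed":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.signal:g}\t.\n"
                )
            elif format == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                    f"{p.signal:g}\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PeakParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = _parse_int(fields[1], "length", str(path), lineno)
    return sizes


def read_segmentation(path: str | Path, genome_sizes: Mapping[str, int]) -> StateSegmentation:
    """Read a 4-column BED (chrom, start, end, state_label) segmentation."""
    segments: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PeakParseError(f"{path}:{lineno}: expected 4 BED columns")
            start = _parse_int(fields[1], "start", str(path), lineno)
            end = _parse_int(fields[2], "end", str(path), lineno)
            segments.append((GenomicInterval(fields[0], start, end), fields[3]))
    return StateSegmentation(segments, dict(genome_sizes))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp between two intervals (0 if disjoint/trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` base pairs."""
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return overlap_length(a, b) >= min_bp


def _trees(ps: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in ps:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def intersect_sets(
    A: PeakSet, B: PeakSet, min_bp: int = 1
) -> dict[str, list[Peak]]:
    """Map each peak in ``A`` (by name) to its overlapping peaks in ``B``.

    Equivalent to the exhaustive all-pairs comparison with
    :func:`overlaps`; an interval-tree index supplies overlap candidates
    and the ``min_bp`` criterion is applied on top.  Hits are returned in
    (chrom, start, end, name) order.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    trees = _trees(B)
    out: dict[str, list[Peak]] = {}
    for a in A:
        tree = trees.get(a.chrom)
        hits: list[Peak] = []
        if tree is not None:
            for node in tree.overlap(a.start, a.end):
                b: Peak = node.data
                if overlap_length(a.interval, b.interval) >= min_bp:
                    hits.append(b)
        hits.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
        out[a.name] = hits
    return out


def merge_peaks(A: PeakSet, max_gap: int = 0) -> PeakSet:
    """Merge peaks separated by at most ``max_gap`` bp.

    Merged signal is the max of constituents.  Single-member groups keep
    the original peak (hence the operation is idempotent); merged groups
    are renamed ``<factor>_merged_<i>``.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[Peak] = []
    group: list[Peak] = []
    n_merged = 0

    def flush() -> None:
        nonlocal n_merged
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
        else:
            iv = GenomicInterval(
                group[0].chrom, group[0].start, max(p.end for p in group)
            )
            merged.append(
                Peak(iv, f"{A.factor}_merged_{n_merged}", max(p.signal for p in group))
            )
            n_merged += 1

    for p in A:
        if group and p.chrom == group[-1].chrom and p.start - max(
            q.end for q in group
        ) <= max_gap:
            group.append(p)
        else:
            flush()
            group = [p]
    flush()
    return PeakSet(A.factor, merged)


def subtract_intervals(A: PeakSet, blacklist: Sequence[GenomicInterval]) -> PeakSet:
    """Drop peaks overlapping any blacklisted interval (≥1 bp).

    Optional pre-filtering step for e.g. ENCODE blacklist regions; no
    blacklist is bundled.
    """
    bl = PeakSet("_blacklist", [Peak(iv, f"bl_{i}") for i, iv in enumerate(blacklist)])
    hits = intersect_sets(A, bl, min_bp=1)
    kept = [p for p in A if not hits[p.name]]
    return PeakSet(A.factor, kept)
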