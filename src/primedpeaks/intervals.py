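"""Genomic interval primitives and TSS-proximity annotation.

Coordinates are 0-based half-open throughout (BED convention). Peaks carry an
optional summit offset; the anchor point used for TSS distances is the summit
when present, otherwise the interval midpoint (floor). Signed TSS distances
are strand-oriented: negative means upstream of the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "TssRecord",
    "AnnotatedPeak",
    "merge_peak_sets",
    "remove_blacklisted",
    "annotate_closest_tss",
    "filter_tss_window",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"{self.name or self.chrom}: start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.name or ''} {self.chrom}:{self.start}-{self.end}"
                " (start >= end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """An accessibility peak: an interval plus optional summit, score, counts.

    ``summit_offset`` is measured in bp from ``interval.start``; the summit is
    the point of maximal signal within the peak.
    """

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float | None = None
    sample_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < self.interval.length:
                raise ValueError(
                    f"peak {self.name}: summit_offset {self.summit_offset} outside "
                    f"[0, {self.interval.length})"
                )
        if self.sample_counts is not None:
            for sid, c in self.sample_counts.items():
                if c < 0:
                    raise ValueError(f"peak {self.name}: negative count for sample {sid}")

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int | None:
        """Absolute genomic summit position, or None if no summit recorded."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset

    @property
    def anchor(self) -> int:
        """Point used for TSS distances: summit if present, else midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: one point per gene, strand mandatory."""

    gene_id: str
    chrom: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"{self.gene_id}: TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: TSS strand must be + or -")
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its closest-TSS gene assignment and signed distance.

    ``signed_distance`` is anchor minus TSS for + strand genes and TSS minus
    anchor for - strand genes, so that negative always means upstream of the
    gene. Peaks on chromosomes with no TSS carry ``gene_id=None`` and infinite
    distance.
    """

    peak: Peak
    gene_id: str | None
    signed_distance: float

    @property
    def name(self) -> str:
        return self.peak.name


def _validated_sorted(peaks: Iterable[Peak]) -> list[Peak]:
    out = list(peaks)
    # Peak construction already validates start < end; sorting key only.
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def merge_peak_sets(set_a: Sequence[Peak], set_b: Sequence[Peak]) -> list[Peak]:
    """Union two peak sets, fusing overlapping or book-ended intervals.

    Summits (and scores/counts) of fused peaks are dropped: a merged interval
    no longer has a single well-defined signal maximum. Output is sorted by
    (chrom, start) and guaranteed non-overlapping; merged peaks are renamed
    ``merged_<i>``.
    """
    peaks = _validated_sorted(list(set_a) + list(set_b))
    merged: list[Peak] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    idx = 0

    def emit() -> None:
        nonlocal idx
        idx += 1
        merged.append(
            Peak(GenomicInterval(cur_chrom, cur_start, cur_end, ".", f"merged_{idx}"))
        )

    for p in peaks:
        if cur_chrom is None:
            cur_chrom, cur_start, cur_end = p.chrom, p.start, p.end
        elif p.chrom == cur_chrom and p.start <= cur_end:  # overlap or book-ended
            cur_end = max(cur_end, p.end)
        else:
            emit()
            cur_chrom, cur_start, cur_end = p.chrom, p.start, p.end
    if cur_chrom is not None:
        emit()
    return merged


def remove_blacklisted(
    peaks: Sequence[Peak], blacklist: Sequence[GenomicInterval]
) -> list[Peak]:
    """Drop every peak overlapping any blacklist interval by >= 1 bp.

    Input order is preserved; an empty blacklist is the identity.
    """
    if not blacklist:
        return list(peaks)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
        # running max of ends makes the binary-search test exact for nested intervals
        ends[chrom] = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
    kept = []
    for p in peaks:
        if p.chrom not in starts:
            kept.append(p)
            continue
        s, e = starts[p.chrom], ends[p.chrom]
        # candidate blacklist intervals starting before peak end
        i = int(np.searchsorted(s, p.end, side="left"))
        if i == 0 or e[i - 1] <= p.start:
            kept.append(p)
    return kept


def annotate_closest_tss(
    peaks: Sequence[Peak], tss: Sequence[TssRecord]
) -> list[AnnotatedPeak]:
    """Assign each peak the gene whose TSS is nearest its anchor point.

    Nearest means minimal |anchor - position| among TSS on the same
    chromosome; ties are broken by lexicographically smallest gene_id.
    Peaks on chromosomes without any TSS get a null assignment with
    infinite distance.
    """
    if not tss:
        raise ValueError("TSS table must be nonempty")
    seen: set[str] = set()
    for t in tss:
        if t.gene_id in seen:
            raise ValueError(f"duplicate gene_id in TSS table: {t.gene_id}")
        seen.add(t.gene_id)

    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    pos: dict[str, np.ndarray] = {}
    recs: dict[str, list[TssRecord]] = {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: (t.position, t.gene_id))
        pos[chrom] = np.array([t.position for t in ts], dtype=np.int64)
        recs[chrom] = ts

    out: list[AnnotatedPeak] = []
    for p in peaks:
        if p.chrom not in pos:
            out.append(AnnotatedPeak(p, None, math.inf))
            continue
        a = p.anchor
        arr = pos[p.chrom]
        rs = recs[p.chrom]
        i = int(np.searchsorted(arr, a))
        best_d = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = abs(int(arr[j]) - a)
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        # all TSS at distance exactly best_d (handles duplicate positions)
        lo = int(np.searchsorted(arr, a - best_d, side="left"))
        hi = int(np.searchsorted(arr, a + best_d, side="right"))
        cands = [rs[j] for j in range(lo, hi) if abs(rs[j].position - a) == best_d]
        best = min(cands, key=lambda t: t.gene_id)
        raw = a - best.position
        signed = float(raw if best.strand == "+" else -raw)
        out.append(AnnotatedPeak(p, best.gene_id, signed))
    return out


def filter_tss_window(
    annotated: Sequence[AnnotatedPeak], window_bp: int
) -> list[AnnotatedPeak]:
    """Keep peaks with |signed_distance| <= window_bp (inclusive).

    Null assignments (no TSS on the chromosome) are dropped.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    return [
        a
        for a in annotated
        if a.gene_id is not None and abs(a.signed_distance) <= window_bp
    ]
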