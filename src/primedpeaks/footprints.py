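"""Tn5 cut-site tracks, average footprint profiles and insert-size QC.

A transcription-factor footprint is a local depletion of Tn5 insertions at
an occupied binding site inside otherwise accessible chromatin; averaging
per-bp cut counts over many motif instances makes the dip visible. The
insert-size QC looks for the ~10.4 bp DNA-helical-pitch modulation of the
fragment-length histogram expected of good ATAC libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CutSiteTrack",
    "GenomicMotifHit",
    "FootprintProfile",
    "PeriodicityResult",
    "reads_to_cuts",
    "average_profile",
    "insert_size_periodicity",
]


@dataclass(frozen=True)
class GenomicMotifHit:
    """A motif instance in genome coordinates (half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str = ""


class CutSiteTrack:
    """Per-chromosome sorted 1-bp Tn5 insertion points, split by strand."""

    def __init__(self, plus: dict[str, np.ndarray], minus: dict[str, np.ndarray]):
        self._plus = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in plus.items()}
        self._minus = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in minus.items()}

    @classmethod
    def from_cuts(cls, records: Iterable[tuple[str, int, str]]) -> "CutSiteTrack":
        plus: dict[str, list[int]] = {}
        minus: dict[str, list[int]] = {}
        for chrom, pos, strand in records:
            (plus if strand == "+" else minus).setdefault(chrom, []).append(pos)
        return cls(
            {c: np.array(v) for c, v in plus.items()},
            {c: np.array(v) for c, v in minus.items()},
        )

    def chroms(self) -> set[str]:
        return set(self._plus) | set(self._minus)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        src = self._plus if strand == "+" else self._minus
        return src.get(chrom, np.empty(0, dtype=np.int64))

    def iter_chrom(self, chrom: str):
        merged = [(int(p), "+") for p in self.positions(chrom, "+")]
        merged += [(int(p), "-") for p in self.positions(chrom, "-")]
        merged.sort()
        return merged

    def n_cuts(self) -> int:
        return sum(len(v) for v in self._plus.values()) + sum(
            len(v) for v in self._minus.values()
        )


def reads_to_cuts(
    alignments: Iterable[tuple[str, int, int, str]]
) -> CutSiteTrack:
    """Standard ATAC offsets: + strand cut at start + 4, - strand at end - 5."""
    records = []
    for chrom, start, end, strand in alignments:
        if strand == "+":
            records.append((chrom, start + 4, "+"))
        else:
            records.append((chrom, end - 5, "-"))
    return CutSiteTrack.from_cuts(records)


@dataclass
class FootprintProfile:
    """Average per-bp cut counts around motif instances, per cut strand.

    Arrays span [-F, w + F) relative to the motif start, oriented by motif
    strand; minus-strand instances are reversed and their cut-strand labels
    swapped before averaging.
    """

    motif_id: str
    flank: int
    width: int
    n_instances: int
    mean_plus: np.ndarray
    mean_minus: np.ndarray

    @property
    def length(self) -> int:
        return 2 * self.flank + self.width

    def core_slice(self) -> slice:
        return slice(self.flank, self.flank + self.width)

    def dip_depth(self) -> float:
        """1 - (mean cuts over the motif core) / (mean cuts over flanks)."""
        both = (self.mean_plus + self.mean_minus) / 2.0
        core = both[self.core_slice()].mean()
        flank_mask = np.ones(self.length, dtype=bool)
        flank_mask[self.core_slice()] = False
        fl = both[flank_mask].mean()
        if fl == 0:
            return 0.0
        return float(1.0 - core / fl)

    def to_frame(self):
        import pandas as pd

        pos = np.arange(-self.flank, self.width + self.flank)
        return pd.DataFrame(
            {"position": pos, "mean_plus": self.mean_plus, "mean_minus": self.mean_minus}
        )


def average_profile(
    track: CutSiteTrack, hits: Sequence[GenomicMotifHit], flank: int = 100
) -> FootprintProfile:
    """Strand-oriented average Tn5 cut profile over motif instances.

    Windows run [hit_start - F, hit_end + F); windows extending past the
    chromosome start are dropped. Raises if no usable hit remains.
    """
    if not hits:
        raise ValueError("no motif hits supplied")
    widths = {h.end - h.start for h in hits}
    if len(widths) != 1:
        raise ValueError(f"hits must share one motif width, got {sorted(widths)}")
    w = widths.pop()
    length = 2 * flank + w
    acc_plus = np.zeros(length)
    acc_minus = np.zeros(length)
    used = 0
    for h in hits:
        lo = h.start - flank
        hi = h.end + flank
        if lo < 0:
            continue
        used += 1
        window = {}
        for strand in ("+", "-"):
            pos = track.positions(h.chrom, strand)
            i0 = np.searchsorted(pos, lo, side="left")
            i1 = np.searchsorted(pos, hi, side="left")
            window[strand] = np.bincount(pos[i0:i1] - lo, minlength=length)
        if h.strand == "-":
            # reverse and swap cut-strand labels for minus-strand motifs
            acc_plus += window["-"][::-1]
            acc_minus += window["+"][::-1]
        else:
            acc_plus += window["+"]
            acc_minus += window["-"]
    if used == 0:
        raise ValueError("no usable hits (all windows extend past chromosome start)")
    motif_id = hits[0].motif_id
    return FootprintProfile(motif_id, flank, w, used, acc_plus / used, acc_minus / used)


@dataclass
class PeriodicityResult:
    """Dominant insert-size period (bp) or None when no peak clears noise."""

    period: float | None
    histogram: np.ndarray
    lags: np.ndarray
    autocorr: np.ndarray


def insert_size_periodicity(
    fragment_lengths: Sequence[int],
    lag_min: int = 8,
    lag_max: int = 15,
) -> PeriodicityResult:
    """Estimate the helical-pitch periodicity of an insert-size distribution.

    The 40-250 bp range of the length histogram is detrended with a 21-bp
    centered moving average; the dominant period is the argmax of the
    normalised autocorrelation of the residual over lags 8..15 bp, refined
    to 0.1 bp by parabolic interpolation. When no lag in the band exceeds
    the noise level (2 / sqrt(n) on the normalised autocorrelation) the
    period is reported as None.
    """
    lens = np.asarray(fragment_lengths, dtype=np.int64)
    if lens.size < 1000:
        raise ValueError(f"need >= 1000 fragments, got {lens.size}")
    lens = lens[(lens >= 1) & (lens <= 1000)]
    hist = np.bincount(lens, minlength=1001)[1:1001].astype(float)  # lengths 1..1000

    region = hist[39:250]  # lengths 40..250
    kernel = np.ones(21) / 21.0
    trend = np.convolve(region, kernel, mode="same")
    resid = region - trend
    # trim edges where the moving average window is truncated
    resid = resid[10:-10]

    denom = float((resid**2).sum())
    lags = np.arange(lag_min - 1, lag_max + 2)
    ac = np.array(
        [
            (resid[: resid.size - lag] * resid[lag:]).sum() / denom if denom > 0 else 0.0
            for lag in lags
        ]
    )
    band = (lags >= lag_min) & (lags <= lag_max)
    best_i = int(np.flatnonzero(band)[np.argmax(ac[band])])
    noise = 2.0 / np.sqrt(resid.size)
    if ac[best_i] < noise:
        return PeriodicityResult(None, hist, lags, ac)
    # parabolic refinement around the peak
    if 0 < best_i < len(lags) - 1:
        y0, y1, y2 = ac[best_i - 1], ac[best_i], ac[best_i + 1]
        denom2 = y0 - 2 * y1 + y2
        delta = 0.0 if denom2 == 0 else 0.5 * (y0 - y2) / denom2
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    period = round(float(lags[best_i] + delta), 1)
    return PeriodicityResult(period, hist, lags, ac)
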