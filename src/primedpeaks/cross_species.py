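"""Cross-species promoter-peak matching and paired accessibility comparison.

Promoter peaks (within +/-2 kb of a TSS) of two datasets are linked through a
1-to-1 ortholog map; a candidate pair is retained when the two peaks sit at
similar strand-oriented distances from their respective TSSs (|d_a - d_b|
within a tolerance, 500 bp by default). Accessibility per matched peak is the
read count in a summit +/- 50 bp window, normalised to reads-per-million over
all matched peaks, and matched distributions are compared with a one-sample
Wilcoxon signed-rank test (normal approximation, tie-corrected variance,
0.5 continuity correction) on per-pair differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .intervals import AnnotatedPeak

__all__ = [
    "OrthologMap",
    "MatchedPeakPair",
    "SignedRankResult",
    "match_orthologous_peaks",
    "summit_window_count",
    "rpm_over_matched",
    "signed_rank_test",
    "run_crossmatch",
    "CrossMatchResult",
]


@dataclass(frozen=True)
class OrthologMap:
    """1-to-1 gene correspondence between two species."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        pairs = tuple((str(a), str(b)) for a, b in pairs)
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in pairs:
            if a in seen_a:
                raise ValueError(f"gene_a {a!r} appears more than once (not 1-to-1)")
            if b in seen_b:
                raise ValueError(f"gene_b {b!r} appears more than once (not 1-to-1)")
            seen_a.add(a)
            seen_b.add(b)
        object.__setattr__(self, "pairs", pairs)

    def swapped(self) -> "OrthologMap":
        return OrthologMap([(b, a) for a, b in self.pairs])


@dataclass
class MatchedPeakPair:
    """One ortholog-linked promoter peak pair with TSS-relative geometry."""

    gene_a_id: str
    gene_b_id: str
    peak_a: AnnotatedPeak
    peak_b: AnnotatedPeak
    d_a: float
    d_b: float
    rel_dist: float
    rpm_a: float | None = None
    rpm_b: float | None = None
    differential_flag: bool = False


def match_orthologous_peaks(
    ann_a: Sequence[AnnotatedPeak],
    ann_b: Sequence[AnnotatedPeak],
    orth: OrthologMap,
    promoter_bp: int = 2000,
    rel_tol_bp: int = 500,
) -> list[MatchedPeakPair]:
    """Link promoter peaks across species through 1-to-1 orthologs.

    For each ortholog pair with at least one promoter peak on each side, the
    cross-combination minimising |d_a - d_b| is kept if that minimum is
    <= rel_tol_bp; at most one pair per ortholog. Ties are broken by peak
    name for determinism. Output is sorted by gene_a_id.
    """
    def by_gene(ann):
        out: dict[str, list[AnnotatedPeak]] = {}
        for a in ann:
            if a.gene_id is not None and abs(a.signed_distance) <= promoter_bp:
                out.setdefault(a.gene_id, []).append(a)
        return out

    ga = by_gene(ann_a)
    gb = by_gene(ann_b)
    matched: list[MatchedPeakPair] = []
    for gene_a, gene_b in orth.pairs:
        if gene_a not in ga or gene_b not in gb:
            continue
        best = None
        for pa in ga[gene_a]:
            for pb in gb[gene_b]:
                rel = abs(pa.signed_distance - pb.signed_distance)
                key = (rel, pa.name, pb.name)
                if best is None or key < best[0]:
                    best = (key, pa, pb)
        (rel, _, _), pa, pb = best
        if rel <= rel_tol_bp:
            matched.append(
                MatchedPeakPair(
                    gene_a, gene_b, pa, pb,
                    pa.signed_distance, pb.signed_distance, rel,
                )
            )
    matched.sort(key=lambda m: m.gene_a_id)
    return matched


def summit_window_count(
    positions: np.ndarray | Sequence[int], summit: int, flank: int = 50
) -> int:
    """Count positions p with summit - flank <= p <= summit + flank (inclusive)."""
    pos = np.asarray(positions)
    lo = np.searchsorted(pos, summit - flank, side="left")
    hi = np.searchsorted(pos, summit + flank, side="right")
    return int(hi - lo)


def rpm_over_matched(counts: Sequence[float]) -> np.ndarray:
    """Reads-per-million over the matched-peak set: c_i / sum(c) * 1e6."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("total count over matched peaks must be > 0")
    return c / total * 1e6


@dataclass(frozen=True)
class SignedRankResult:
    """Wilcoxon signed-rank outcome; degenerate means all differences zero."""

    statistic: float
    p_value: float
    n_used: int
    degenerate: bool = False


def signed_rank_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank on paired differences a_i - b_i.

    Zero differences are discarded; |d| are ranked with average ranks for
    ties; W is the sum of ranks of positive differences. The two-sided p
    uses the normal approximation with tie-corrected variance and a 0.5
    continuity correction. All-zero differences return p = 1 flagged
    degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 1.0, 0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return SignedRankResult(w_pos, 1.0, n, degenerate=True)
    diff = w_pos - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return SignedRankResult(w_pos, p, n)


@dataclass
class CrossMatchResult:
    """Matched-pair table plus the three flagged-subset rank tests."""

    pairs: list[MatchedPeakPair]
    tests: dict[str, SignedRankResult]
    rpm: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_a": [m.gene_a_id for m in self.pairs],
                "gene_b": [m.gene_b_id for m in self.pairs],
                "peak_a": [m.peak_a.name for m in self.pairs],
                "peak_b": [m.peak_b.name for m in self.pairs],
                "d_a": [m.d_a for m in self.pairs],
                "d_b": [m.d_b for m in self.pairs],
                "rel_dist": [m.rel_dist for m in self.pairs],
                "rpm_a_control": self.rpm["a_control"],
                "rpm_a_treated": self.rpm["a_treated"],
                "rpm_b_control": self.rpm["b_control"],
                "rpm_b_treated": self.rpm["b_treated"],
                "differential": [m.differential_flag for m in self.pairs],
            }
        )


def _count_track(
    pairs: Sequence[MatchedPeakPair],
    reads: Mapping[str, np.ndarray],
    side: str,
    flank: int,
) -> np.ndarray:
    out = np.zeros(len(pairs))
    for i, m in enumerate(pairs):
        peak = m.peak_a if side == "a" else m.peak_b
        chrom = peak.peak.chrom
        summit = peak.peak.anchor
        pos = reads.get(chrom)
        if pos is not None and len(pos):
            out[i] = summit_window_count(pos, summit, flank)
    return out


def run_crossmatch(
    ann_a: Sequence[AnnotatedPeak],
    ann_b: Sequence[AnnotatedPeak],
    orth: OrthologMap,
    reads_a: Mapping[str, Mapping[str, np.ndarray]],
    reads_b: Mapping[str, Mapping[str, np.ndarray]],
    differential_flags: Mapping[str, bool],
    promoter_bp: int = 2000,
    rel_tol_bp: int = 500,
    summit_flank: int = 50,
) -> CrossMatchResult:
    """Full cross-species comparison on closest-TSS annotated peak sets.

    ``reads_a``/``reads_b`` map condition ("control"/"treated") to
    {chrom: sorted read positions}. ``differential_flags`` marks dataset-A
    peaks called differential externally (consumed, not computed). The three
    signed-rank tests compare, over flagged pairs only: A-control vs
    B-control, A-treated vs B-control, and A-control vs B-treated.
    """
    pairs = match_orthologous_peaks(ann_a, ann_b, orth, promoter_bp, rel_tol_bp)
    if not pairs:
        raise ValueError("no matched ortholog peak pairs")
    for m in pairs:
        m.differential_flag = bool(differential_flags.get(m.peak_a.name, False))

    rpm = {}
    for label, reads, side in (
        ("a_control", reads_a["control"], "a"),
        ("a_treated", reads_a["treated"], "a"),
        ("b_control", reads_b["control"], "b"),
        ("b_treated", reads_b["treated"], "b"),
    ):
        counts = _count_track(pairs, reads, side, summit_flank)
        rpm[label] = rpm_over_matched(counts)
    for m, ra, rb in zip(pairs, rpm["a_control"], rpm["b_control"]):
        m.rpm_a = float(ra)
        m.rpm_b = float(rb)

    flagged = np.array([m.differential_flag for m in pairs], dtype=bool)
    if not flagged.any():
        raise ValueError("no matched pairs carry a differential flag")
    tests = {
        "a_control_vs_b_control": signed_rank_test(
            rpm["a_control"][flagged], rpm["b_control"][flagged]
        ),
        "a_treated_vs_b_control": signed_rank_test(
            rpm["a_treated"][flagged], rpm["b_control"][flagged]
        ),
        "a_control_vs_b_treated": signed_rank_test(
            rpm["a_control"][flagged], rpm["b_treated"][flagged]
        ),
    }
    return CrossMatchResult(pairs, tests, rpm)
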