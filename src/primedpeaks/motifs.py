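"""PWM scanning, binomial occupancy scores and paired-motif enrichment (PMET).

The paired-motif enrichment test ranks every peak in a universe by a
per-motif binomial occupancy score, takes the top-N peaks for each motif,
intersects the top sets of a motif pair ("peaks containing both motifs"),
and asks — by an upper-tail hypergeometric test — whether that intersection
is over-represented among the peaks annotated to a test gene set. q-values
are Benjamini-Hochberg adjusted across all unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, hypergeom

from .intervals import AnnotatedPeak

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "OccupancyScore",
    "PairEnrichment",
    "logodds_scan",
    "binomial_occupancy_score",
    "rank_and_top",
    "paired_enrichment",
    "single_motif_enrichment",
    "set_overlap_test",
    "bh_adjust",
    "run_pmet",
    "PmetResult",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A motif model: per-position base probabilities plus background.

    ``probs`` is a (width x 4) array over A,C,G,T with pseudocount already
    applied (all entries strictly positive); rows sum to 1.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "background", bg)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: probs must be (w, 4)")
        if (p <= 0).any():
            raise ValueError(f"{self.motif_id}: all probabilities must be > 0")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or (bg <= 0).any():
            raise ValueError(f"{self.motif_id}: invalid background")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(w x 4) log2(prob / background)."""
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id, self.probs[::-1, ::-1].copy(), self.background[::-1].copy()
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif match; offset is the window start on the forward strand."""

    peak_id: str
    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class OccupancyScore:
    """Per-(peak, motif) hit count and its -log10 binomial tail score."""

    peak_id: str
    motif_id: str
    k: int
    n: int
    score: float


@dataclass(frozen=True)
class PairEnrichment:
    """Hypergeometric enrichment of one motif pair's co-occurring peaks.

    N = universe size, K = peaks in both top sets within the universe,
    n = test-set size, k = test peaks in both top sets.
    """

    motif_a: str
    motif_b: str | None
    universe_size: int
    both_in_universe: int
    test_size: int
    both_in_test: int
    p_value: float
    q_value: float | None = None


def encode_sequence(seq: str) -> np.ndarray:
    """ACGTN string -> int8 codes (N and anything unknown -> -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of width w; NaN where a window has N."""
    w = lom.shape[0]
    L = codes.size
    n_win = L - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(w):
        c = codes[j : j + n_win]
        valid = c >= 0
        bad |= ~valid
        scores += np.where(valid, lom[j, np.clip(c, 0, 3)], 0.0)
    scores[bad] = np.nan
    return scores


def logodds_scan(
    pwm: PositionWeightMatrix,
    sequence: str,
    peak_id: str,
    threshold: float,
) -> list[MotifHit]:
    """Scan both strands, reporting windows scoring >= threshold in log2-odds.

    Minus-strand windows are scored against the reverse-complement matrix;
    offsets are always reported on the forward strand (window start).
    Windows containing N are skipped; sequences shorter than the motif give
    an empty result.
    """
    codes = encode_sequence(sequence)
    hits: list[MotifHit] = []
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement().log_odds)
    for strand, scores in (("+", fwd), ("-", rev)):
        if scores.size == 0:
            continue
        ok = np.flatnonzero(~np.isnan(scores) & (scores >= threshold))
        for i in ok:
            hits.append(MotifHit(peak_id, int(i), strand, float(scores[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def binomial_occupancy_score(k: int, n: int, p_bg: float) -> float:
    """-log10 of the upper binomial tail P(X >= k), X ~ Binomial(n, p_bg).

    Computed in log space via logsumexp over the tail pmf so the score stays
    finite and accurate for extreme k.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p_bg < 1:
        raise ValueError(f"p_bg must be in (0,1), got {p_bg}")
    if k == 0:
        return 0.0
    ys = np.arange(k, n + 1)
    log_tail = logsumexp(binom.logpmf(ys, n, p_bg))
    return float(max(0.0, -log_tail / np.log(10.0)))


def rank_and_top(scores: Sequence[OccupancyScore], top_n: int) -> list[str]:
    """Top-N peak ids by (score descending, peak_id ascending)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    seen = set()
    for s in scores:
        if s.peak_id in seen:
            raise ValueError(f"duplicate score for peak {s.peak_id}")
        seen.add(s.peak_id)
    ordered = sorted(scores, key=lambda s: (-s.score, s.peak_id))
    return [s.peak_id for s in ordered[: min(top_n, len(ordered))]]


def _hyper_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def paired_enrichment(
    universe: set[str],
    test_set: set[str],
    top_a: set[str],
    top_b: set[str],
    motif_a: str = "a",
    motif_b: str = "b",
) -> PairEnrichment:
    """Hypergeometric enrichment of test-set peaks among both-motif peaks."""
    if not test_set <= universe:
        raise ValueError("test_set must be a subset of the universe")
    both = top_a & top_b & universe
    k = len(test_set & both)
    p = _hyper_upper(len(universe), len(both), len(test_set), k)
    return PairEnrichment(
        motif_a, motif_b, len(universe), len(both), len(test_set), k, p
    )


def single_motif_enrichment(
    universe: set[str], test_set: set[str], top_a: set[str], motif_a: str = "a"
) -> PairEnrichment:
    """As paired_enrichment but with a single motif's top set (motif_b absent)."""
    if not test_set <= universe:
        raise ValueError("test_set must be a subset of the universe")
    K_set = top_a & universe
    k = len(test_set & K_set)
    p = _hyper_upper(len(universe), len(K_set), len(test_set), k)
    return PairEnrichment(motif_a, None, len(universe), len(K_set), len(test_set), k, p)


def set_overlap_test(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric p for the size of set_a ∩ set_b in universe."""
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    return _hyper_upper(len(universe), len(set_a), len(set_b), k)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class PmetResult:
    """All pair enrichments from one PMET run plus per-motif occupancy data."""

    pairs: list[PairEnrichment]
    top_sets: dict[str, list[str]]
    occupancy: dict[str, list[OccupancyScore]]
    p_background: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motif_a": e.motif_a,
                "motif_b": e.motif_b,
                "N": e.universe_size,
                "K": e.both_in_universe,
                "n": e.test_size,
                "k": e.both_in_test,
                "p": e.p_value,
                "q": e.q_value,
            }
            for e in self.pairs
        ]
        return pd.DataFrame(rows)

    def neglog10_q_matrix(self) -> pd.DataFrame:
        """Symmetric motif x motif matrix of -log10(q) for heat-mapping."""
        motifs = sorted(self.top_sets)
        mat = pd.DataFrame(0.0, index=motifs, columns=motifs)
        for e in self.pairs:
            v = -np.log10(max(e.q_value, 1e-300))
            mat.loc[e.motif_a, e.motif_b] = v
            mat.loc[e.motif_b, e.motif_a] = v
        return mat

    def best_pair(self) -> PairEnrichment:
        return min(self.pairs, key=lambda e: (e.q_value, e.p_value, e.motif_a, e.motif_b or ""))


def run_pmet(
    peak_sequences: Mapping[str, str],
    motifs: Sequence[PositionWeightMatrix],
    universe: Sequence[AnnotatedPeak],
    test_gene_set: Iterable[str],
    top_n: int = 5000,
    scan_threshold: float = 6.0,
    rank_by: str = "count",
    pair_mode: str = "topn",
) -> PmetResult:
    """Paired-motif enrichment over all unordered motif pairs.

    Parameters
    ----------
    peak_sequences : mapping of peak name -> DNA sequence for every universe peak.
    motifs : at least two PWMs.
    universe : TSS-window-filtered annotated peaks (the ranking universe).
    test_gene_set : gene ids; test peaks are universe peaks annotated to them.
    top_n : ranked-peak cutoff per motif (clipped to the universe size).
    scan_threshold : log2-odds threshold for counting a motif hit.
    rank_by : "count" ranks peaks by hit count, "score_sum" by summed hit scores.
    pair_mode : "topn" intersects top-N sets; "presence" uses raw hit presence.
    """
    if len(motifs) < 2:
        raise ValueError("PMET needs at least two motifs")
    if rank_by not in ("count", "score_sum"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if pair_mode not in ("topn", "presence"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")

    peak_ids = [a.name for a in universe]
    if len(set(peak_ids)) != len(peak_ids):
        raise ValueError("duplicate peak names in universe")
    missing = [pid for pid in peak_ids if pid not in peak_sequences]
    if missing:
        raise ValueError(f"no sequence for universe peaks: {missing[:5]}")
    test_genes = set(test_gene_set)
    test_peaks = {a.name for a in universe if a.gene_id in test_genes}
    universe_set = set(peak_ids)

    codes = {pid: encode_sequence(peak_sequences[pid]) for pid in peak_ids}
    top_sets: dict[str, list[str]] = {}
    occupancy: dict[str, list[OccupancyScore]] = {}
    p_bg_used: dict[str, float] = {}
    hit_presence: dict[str, set[str]] = {}

    for pwm in motifs:
        w = pwm.width
        lom_f = pwm.log_odds
        lom_r = pwm.reverse_complement().log_odds
        ks: dict[str, int] = {}
        ssum: dict[str, float] = {}
        ns: dict[str, int] = {}
        present: set[str] = set()
        total_k = 0
        total_n = 0
        for pid in peak_ids:
            c = codes[pid]
            n_pos = 2 * max(0, c.size - w + 1)
            k = 0
            s_sum = 0.0
            for lom in (lom_f, lom_r):
                sc = _window_scores(c, lom)
                if sc.size:
                    sel = ~np.isnan(sc) & (sc >= scan_threshold)
                    k += int(sel.sum())
                    if sel.any():
                        s_sum += float(sc[sel].sum())
            ks[pid] = k
            ssum[pid] = s_sum
            ns[pid] = n_pos
            if k > 0:
                present.add(pid)
            total_k += k
            total_n += n_pos
        # empirical background rate: motif hits per scanned position, floored
        p_bg = max(total_k / total_n if total_n else 0.0, 1e-9)
        p_bg = min(p_bg, 1 - 1e-9)
        p_bg_used[pwm.motif_id] = p_bg
        occ = [
            OccupancyScore(
                pid, pwm.motif_id, ks[pid], ns[pid],
                binomial_occupancy_score(ks[pid], ns[pid], p_bg) if ns[pid] else 0.0,
            )
            for pid in peak_ids
        ]
        if rank_by == "score_sum":
            occ = [
                OccupancyScore(o.peak_id, o.motif_id, o.k, o.n, ssum[o.peak_id])
                for o in occ
            ]
        occupancy[pwm.motif_id] = occ
        top_sets[pwm.motif_id] = rank_and_top(occ, min(top_n, len(peak_ids)))
        hit_presence[pwm.motif_id] = present

    source = top_sets if pair_mode == "topn" else hit_presence
    pairs: list[PairEnrichment] = []
    for ma, mb in combinations(sorted(top_sets), 2):
        pairs.append(
            paired_enrichment(
                universe_set, test_peaks, set(source[ma]), set(source[mb]), ma, mb
            )
        )
    qs = bh_adjust([e.p_value for e in pairs])
    pairs = [
        PairEnrichment(
            e.motif_a, e.motif_b, e.universe_size, e.both_in_universe,
            e.test_size, e.both_in_test, e.p_value, float(q),
        )
        for e, q in zip(pairs, qs)
    ]
    return PmetResult(pairs, top_sets, occupancy, p_bg_used)
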