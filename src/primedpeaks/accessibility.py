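"""Per-peak counting, normalisation, PCA input and differential accessibility.

The two-condition differential test is a simplified negative-binomial exact
test: replicate counts are rescaled to the geometric-mean library size,
summed per group (rounded half-to-even), and the group sums are compared
conditionally on their total. Under the null of equal means the conditional
distribution of one group's sum is proportional to f(y) * f(s - y), with f
the NB pmf at mean s/2 and a shared dispersion; the two-sided p sums all
outcomes no more likely than the observed one (minimum-likelihood rule).
At dispersion 0 the conditional law degenerates to Binomial(s, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .intervals import Peak
from .motifs import bh_adjust

__all__ = [
    "CountMatrix",
    "DiffAccessResult",
    "count_reads_in_peaks",
    "cpm_normalize",
    "top_variable_pca_input",
    "nb_exact_test",
    "estimate_dispersion",
    "run_diffacc",
    "DiffAccessSummary",
]


@dataclass
class CountMatrix:
    """Peaks x samples integer counts with condition labels and library sizes.

    ``library_sizes`` are per-sample sequencing totals and may exceed the
    column sums (reads outside peaks still count toward the library).
    """

    peak_ids: list[str]
    sample_ids: list[str]
    conditions: dict[str, str]
    counts: np.ndarray
    library_sizes: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.peak_ids)} peaks x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        for s in self.sample_ids:
            if s not in self.conditions:
                raise ValueError(f"sample {s} missing condition label")
            if self.library_sizes.get(s, 0) <= 0:
                raise ValueError(f"sample {s} needs a positive library size")

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def column_indices(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.conditions[s] == condition]
        )

    @property
    def lib_vector(self) -> np.ndarray:
        return np.array([self.library_sizes[s] for s in self.sample_ids], dtype=float)


@dataclass(frozen=True)
class DiffAccessResult:
    peak_id: str
    mean_control: float
    mean_treated: float
    direction: str  # "open" iff treated mean > control mean, else "closed"
    p_value: float
    q_value: float


def count_reads_in_peaks(
    peaks: Sequence[Peak],
    read_positions: Mapping[str, Mapping[str, np.ndarray]],
    conditions: Mapping[str, str],
) -> CountMatrix:
    """Count per-sample read positions falling in each peak's [start, end).

    ``read_positions`` maps sample_id -> {chrom: sorted positions}; reads are
    assumed already reduced to single genomic points (shifted 5' ends).
    Library sizes are the per-sample totals over all positions.
    """
    sample_ids = list(read_positions)
    counts = np.zeros((len(peaks), len(sample_ids)), dtype=np.int64)
    lib = {}
    for j, sid in enumerate(sample_ids):
        tracks = read_positions[sid]
        lib[sid] = int(sum(len(np.asarray(v)) for v in tracks.values()))
        for i, p in enumerate(peaks):
            pos = tracks.get(p.chrom)
            if pos is None:
                continue
            pos = np.asarray(pos)
            lo = np.searchsorted(pos, p.start, side="left")
            hi = np.searchsorted(pos, p.end, side="left")  # end exclusive
            counts[i, j] = hi - lo
    return CountMatrix(
        [p.name for p in peaks], sample_ids, dict(conditions), counts, lib
    )


def cpm_normalize(m: CountMatrix) -> np.ndarray:
    """Counts per million: counts_ij / library_size_j * 1e6."""
    return m.counts / m.lib_vector[None, :] * 1e6


def top_variable_pca_input(
    normalized: np.ndarray, peak_ids: Sequence[str], k: int = 500
):
    """Select the top-k most variable peaks of log2(x+1) values and project.

    Rows are ranked by across-sample variance of the log values, ties broken
    by peak_id; principal components come from the centered SVD of the
    samples x selected-peaks matrix. Each component's sign is fixed so that
    its largest-magnitude loading is positive.

    Returns (selected peak_ids, log submatrix, sample PC coordinates).
    """
    x = np.asarray(normalized, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of peaks {x.shape[0]}")
    logx = np.log2(x + 1.0)
    var = logx.var(axis=1, ddof=1)
    order = sorted(range(len(peak_ids)), key=lambda i: (-var[i], peak_ids[i]))
    sel = order[:k]
    sub = logx[sel, :]
    mat = sub.T - sub.mean(axis=1)  # samples x peaks, column-centered
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    # sign convention: largest-|loading| entry of each PC positive
    for c in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    coords = u * s
    return [peak_ids[i] for i in sel], sub, coords


def _nb_logpmf(y: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """NB log-pmf parameterised by mean and dispersion (var = m + phi m^2)."""
    r = 1.0 / phi
    logp = np.log(mean / (mean + r))
    log1mp = np.log(r / (mean + r))
    y = np.asarray(y, dtype=float)
    return gammaln(y + r) - gammaln(r) - gammaln(y + 1) + y * logp + r * log1mp


def nb_exact_test(y_a, y_b, dispersion: float = 0.05) -> float:
    """Conditional NB exact test on two group sums (or replicate vectors).

    Vectors are summed; both sums must be pre-scaled to a common effective
    library size. Two-sided p by the minimum-likelihood rule; dispersion 0
    gives the exact Binomial(s, 1/2) test.
    """
    ya = int(round(float(np.sum(y_a))))
    yb = int(round(float(np.sum(y_b))))
    if ya < 0 or yb < 0:
        raise ValueError("counts must be nonnegative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s = ya + yb
    if s == 0:
        return 1.0
    ys = np.arange(s + 1)
    if dispersion == 0:
        logp = binom.logpmf(ys, s, 0.5)
    else:
        m = s / 2.0
        lf = _nb_logpmf(ys, m, dispersion)
        logp = lf + lf[::-1]
        logp -= logp.max()
    p_obs = np.exp(logp - logp.max())
    p_obs /= p_obs.sum()
    # include outcomes with probability <= observed (small float slack, as in
    # standard exact-test practice)
    thresh = p_obs[ya] * (1 + 1e-7)
    return float(min(1.0, p_obs[p_obs <= thresh].sum()))


def estimate_dispersion(m: CountMatrix) -> float:
    """Method-of-moments common dispersion across peaks.

    Counts are rescaled to the geometric-mean library size; for every peak
    and condition with >= 2 replicates, phi_hat = (var - mean) / mean^2; the
    estimate is the median over informative peak/condition cells, floored
    at 0.
    """
    lib = m.lib_vector
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = m.counts * (target / lib)[None, :]
    phis = []
    for cond in ("control", "treated"):
        idx = m.column_indices(cond)
        if idx.size < 2:
            continue
        sub = scaled[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        phis.append((var[ok] - mu[ok]) / mu[ok] ** 2)
    if not phis:
        return 0.0
    return float(max(0.0, np.median(np.concatenate(phis))))


@dataclass
class DiffAccessSummary:
    results: list[DiffAccessResult]
    n_open: int
    n_closed: int
    fdr: float
    dispersion: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_id": [r.peak_id for r in self.results],
                "mean_control": [r.mean_control for r in self.results],
                "mean_treated": [r.mean_treated for r in self.results],
                "direction": [r.direction for r in self.results],
                "p": [r.p_value for r in self.results],
                "q": [r.q_value for r in self.results],
            }
        )

    def significant(self) -> list[DiffAccessResult]:
        return [r for r in self.results if r.q_value < self.fdr]


def run_diffacc(
    m: CountMatrix, dispersion: float | None = 0.05, fdr: float = 0.05
) -> DiffAccessSummary:
    """Per-peak NB exact test with BH correction and open/closed calls.

    Replicates are rescaled to the geometric-mean library size, summed per
    group and rounded half-to-even before testing. ``dispersion`` is the
    per-replicate value; since the sum of n i.i.d. NB(m, phi) variables is
    NB(nm, phi/n), the conditional test runs at dispersion / n_replicates.
    ``dispersion=None`` triggers the method-of-moments estimate.
    """
    if dispersion is None:
        dispersion = estimate_dispersion(m)
    lib = m.lib_vector
    target = float(np.exp(np.mean(np.log(lib))))
    scaled = m.counts * (target / lib)[None, :]
    idx_c = m.column_indices("control")
    idx_t = m.column_indices("treated")
    if idx_c.size == 0 or idx_t.size == 0:
        raise ValueError("need both control and treated samples")
    y_c = np.round(scaled[:, idx_c].sum(axis=1))  # numpy rounds half to even
    y_t = np.round(scaled[:, idx_t].sum(axis=1))
    cpm = cpm_normalize(m)
    mean_c = cpm[:, idx_c].mean(axis=1)
    mean_t = cpm[:, idx_t].mean(axis=1)

    n_rep = (idx_c.size + idx_t.size) / 2.0
    phi_sum = dispersion / n_rep
    ps = np.array(
        [nb_exact_test(int(a), int(b), phi_sum) for a, b in zip(y_c, y_t)]
    )
    qs = bh_adjust(ps)
    results = [
        DiffAccessResult(
            pid,
            float(mc),
            float(mt),
            "open" if mt > mc else "closed",
            float(p),
            float(q),
        )
        for pid, mc, mt, p, q in zip(m.peak_ids, mean_c, mean_t, ps, qs)
    ]
    sig = [r for r in results if r.q_value < fdr]
    n_open = sum(1 for r in sig if r.direction == "open")
    return DiffAccessSummary(results, n_open, len(sig) - n_open, fdr, dispersion)
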