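"""Microarray-style differential expression, profile clustering, module score.

Implements the classic array workflow: column quantile normalisation,
per-probe equal-variance t-tests with BH correction, median-ratio fold
changes reported with the negative-reciprocal convention (a ratio of 0.5 is
written -2), a strict +/-1.5 fold-change / FDR 0.05 filter with probe-to-gene
collapse, average-linkage clustering of expression profiles under a
one-minus-Pearson metric, and a per-cell gene-module score (mean module
expression minus mean of expression-matched random control genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, ttest_ind

from .motifs import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "ClusterAssignment",
    "quantile_normalize",
    "ttest_equal_var",
    "signed_fold_change",
    "run_de",
    "de_filter_and_collapse",
    "cluster_profiles",
    "module_score",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples positive intensities with control/treated labels."""

    probe_ids: list[str]
    sample_ids: list[str]
    groups: dict[str, str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("intensity matrix shape inconsistent with ids")
        if (self.intensities <= 0).any():
            raise ValueError("intensities must be strictly positive")
        for s in self.sample_ids:
            if s not in self.groups:
                raise ValueError(f"sample {s} missing group label")

    def columns(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=self.probe_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    fc_signed: float
    p_value: float
    q_value: float
    direction: str  # up / down / ns


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    linkage: np.ndarray
    excluded: list[str]

    def members(self, label: int) -> list[str]:
        return [r for r, l in self.labels.items() if l == label]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic column quantile normalisation.

    Every column is mapped onto the across-column mean of order statistics;
    tied values within a column receive the mean of the reference values
    their ranks span. All output columns share an identical sorted vector
    (up to tie averaging).
    """
    x = m.intensities
    n, p = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(p):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values over tie groups
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return ExpressionMatrix(
        list(m.probe_ids), list(m.sample_ids), dict(m.groups), out
    )


def ttest_equal_var(group_a: Sequence[float], group_b: Sequence[float]):
    """Pooled-variance two-sample t-test; two-sided p, df = n_a + n_b - 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def signed_fold_change(median_treated: float, median_control: float) -> float:
    """Median ratio with the negative-reciprocal convention for ratios < 1."""
    if median_treated <= 0 or median_control <= 0:
        raise ValueError("medians must be positive")
    r = median_treated / median_control
    return r if r >= 1 else -1.0 / r


def _raw_ratio(fc_signed: float) -> float:
    return fc_signed if fc_signed >= 1 else -1.0 / fc_signed


def run_de(
    m: ExpressionMatrix,
    control: str = "control",
    treated: str = "treated",
    normalize: bool = True,
) -> list[DEResult]:
    """Quantile-normalise, t-test each probe, BH-adjust, signed fold change.

    Direction is "up"/"down" by the sign of the fold change alone; the
    strict significance filter lives in :func:`de_filter_and_collapse`.
    """
    if normalize:
        m = quantile_normalize(m)
    ic = m.columns(control)
    it = m.columns(treated)
    x = m.intensities
    ps = np.empty(len(m.probe_ids))
    fcs = np.empty(len(m.probe_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant probes give nan p; handled below
        t, p = ttest_ind(x[:, it], x[:, ic], axis=1, equal_var=True)
    ps = np.where(np.isnan(p), 1.0, p)
    ps = np.clip(ps, np.nextafter(0, 1), 1.0)
    med_t = np.median(x[:, it], axis=1)
    med_c = np.median(x[:, ic], axis=1)
    fcs = np.array([signed_fold_change(mt, mc) for mt, mc in zip(med_t, med_c)])
    qs = bh_adjust(ps)
    return [
        DEResult(pid, float(fc), float(pv), float(qv), "up" if fc >= 1 else "down")
        for pid, fc, pv, qv in zip(m.probe_ids, fcs, ps, qs)
    ]


def de_filter_and_collapse(
    results: Sequence[DEResult],
    annot: Mapping[str, str],
    fc_thresh: float = 1.5,
    fdr: float = 0.05,
    strict_discordant: bool = False,
):
    """Strict FC/FDR filter plus unique-gene collapse.

    UP: q < fdr and raw ratio > fc_thresh (strict); DOWN: q < fdr and raw
    ratio < 1/fc_thresh (strict). Gene sets are the unique gene ids of
    qualifying probes; a gene with probes in both directions appears in both
    sets unless ``strict_discordant`` drops it from both.

    Returns (up_probes, down_probes, up_genes, down_genes).
    """
    up_probes, down_probes = [], []
    for r in results:
        if r.q_value >= fdr:
            continue
        ratio = _raw_ratio(r.fc_signed)
        if ratio > fc_thresh:
            up_probes.append(r.probe_id)
        elif ratio < 1.0 / fc_thresh:
            down_probes.append(r.probe_id)
    up_genes = {annot[p] for p in up_probes if p in annot}
    down_genes = {annot[p] for p in down_probes if p in annot}
    if strict_discordant:
        discordant = up_genes & down_genes
        up_genes -= discordant
        down_genes -= discordant
    return up_probes, down_probes, sorted(up_genes), sorted(down_genes)


def cluster_profiles(
    values: pd.DataFrame,
    k: int = 4,
    log2_transform: bool = True,
    median_center: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of expression profiles, cut to k clusters.

    Rows are log2-transformed and median-centered first; distance is
    1 - Pearson correlation with average linkage. Zero-variance rows are
    excluded with a warning. Cluster labels are canonicalised by descending
    cluster size, ties by first row id.
    """
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {values.shape[0]}")
    x = values.to_numpy(dtype=float)
    if log2_transform:
        x = np.log2(x)
    if median_center:
        x = x - np.median(x, axis=1, keepdims=True)
    var = x.var(axis=1)
    keep = var > 0
    excluded = [str(r) for r, ok in zip(values.index, keep) if not ok]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance rows from clustering")
    x = x[keep]
    ids = [str(r) for r, ok in zip(values.index, keep) if ok]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of usable rows {len(ids)}")
    d = pdist(x, metric="correlation")  # 1 - Pearson
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    z = average(d)
    raw = fcluster(z, t=k, criterion="maxclust")
    # canonical labels: descending size, tie-break by first member's position
    order = {}
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(i)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    for new, (old, _) in enumerate(ranked, start=1):
        order[old] = new
    labels = {ids[i]: order[int(lab)] for i, lab in enumerate(raw)}
    return ClusterAssignment(labels, z, excluded)


def module_score(
    expr: pd.DataFrame,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Per-cell module score: mean module expression minus matched controls.

    Genes are binned into ``n_bins`` equal-frequency bins of their
    dataset-average expression; for each module gene, ``n_ctrl`` control
    genes are drawn (with replacement) from its bin, and the score is the
    per-cell mean over module genes minus the per-cell mean over all drawn
    controls.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    genes = list(expr.index.astype(str))
    members = [g for g in gene_set if g in expr.index]
    if not members:
        raise ValueError("no module gene found in the expression matrix")
    avg = expr.mean(axis=1).to_numpy()
    n_bins = min(n_bins, len(genes))
    # equal-frequency bins of average expression (ranks, then split)
    ranks = rankdata(avg, method="ordinal") - 1
    bin_of = (ranks * n_bins // len(genes)).astype(int)
    bins: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_of == b) for b in range(n_bins)
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    ctrl_rows: list[int] = []
    for g in members:
        b = bin_of[gene_pos[g]]
        pool = bins[int(b)]
        ctrl_rows.extend(rng.choice(pool, size=n_ctrl, replace=True).tolist())
    x = expr.to_numpy(dtype=float)
    member_mean = x[[gene_pos[g] for g in members], :].mean(axis=0)
    ctrl_mean = x[ctrl_rows, :].mean(axis=0)
    return pd.Series(member_mean - ctrl_mean, index=expr.columns, name="module_score")
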