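"""Seeded generators producing fixtures with known truth for every stage.

Every generator is a pure function of (parameters, seed): one global seed
fans out to per-output child streams through a fixed counter scheme
(``_rng(seed, stream)``), so adding a new output never perturbs existing
ones and regeneration is byte-identical.

Defaults encode the study conditions each downstream stage assumes: peaks
whose summits cluster within +/-8 kb of TSSs, a motif pair co-inserted at
rate 0.6 in test-gene peaks against a 5% background, negative-binomial
counts (dispersion 0.05) with 30 two-fold-log2 differential peaks among
2000, Tn5 cut tracks with a 0.6-depth footprint dip and a 10.4 bp
insert-size modulation, a two-species promoter fixture with an optional
planted accessibility shift, and probe matrices with four planted temporal
expression programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .footprints import CutSiteTrack, GenomicMotifHit
from .intervals import GenomicInterval, Peak, TssRecord
from .motifs import PositionWeightMatrix

__all__ = [
    "GenomeFixture",
    "MotifPeakFixture",
    "CountsFixture",
    "CutSiteFixture",
    "TwoSpeciesFixture",
    "ExpressionFixture",
    "make_genome_fixture",
    "make_motif_peak_fixture",
    "make_counts_fixture",
    "make_cutsite_fixture",
    "make_two_species_fixture",
    "make_expression_fixture",
    "ARCHETYPE_PROFILES",
]

_BASES = np.array(list("ACGT"))

# per-output child streams of the global seed (documented counter scheme)
_STREAMS = {
    "genome": 0,
    "motif_peaks": 1,
    "counts": 2,
    "cutsites": 3,
    "two_species": 4,
    "expression": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.searchsorted(np.cumsum(p), rng.random(length), side="left")
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- genome

@dataclass
class GenomeFixture:
    tss: list[TssRecord]
    chrom_sizes: dict[str, int]
    sequences: dict[str, str]
    seed: int


def make_genome_fixture(
    n_chroms: int = 2,
    n_genes: int = 60,
    chrom_len: int = 1_000_000,
    gc: float = 0.42,
    seed: int = 0,
    chrom_prefix: str = "chr",
) -> GenomeFixture:
    """Uniformly placed genes with random strands on i.i.d. background sequence."""
    rng = _rng(seed, "genome")
    chroms = [f"{chrom_prefix}{i + 1}" for i in range(n_chroms)]
    sizes = {c: int(chrom_len) for c in chroms}
    seqs = {c: _random_seq(rng, int(chrom_len), gc) for c in chroms}
    tss = []
    margin = 20_000  # keep promoter windows inside the chromosome
    for g in range(n_genes):
        chrom = chroms[g % n_chroms]
        pos = int(rng.integers(margin, chrom_len - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TssRecord(f"gene_{g:04d}", chrom, pos, strand))
    return GenomeFixture(tss, sizes, seqs, seed)


# ---------------------------------------------------------------- motif/peak

def _sharp_pwm(rng: np.random.Generator, motif_id: str, width: int) -> PositionWeightMatrix:
    cons = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), 0.03)
    probs[np.arange(width), cons] = 0.91
    probs /= probs.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(motif_id, probs, np.full(4, 0.25))


@dataclass
class MotifPeakFixture:
    peaks: list[Peak]
    sequences: dict[str, str]
    motifs: list[PositionWeightMatrix]
    test_genes: set[str]
    planted_pair: tuple[str, str]
    truth_insertions: dict[str, list[str]]  # peak -> inserted motif ids
    seed: int


def make_motif_peak_fixture(
    genome: GenomeFixture,
    n_peaks: int = 600,
    n_motifs: int = 8,
    planted_pair: tuple[int, int] = (0, 1),
    co_rate: float = 0.6,
    bg_rate: float = 0.05,
    n_test_genes: int = 15,
    peak_len: int = 300,
    motif_width: int = 8,
    seed: int = 0,
) -> MotifPeakFixture:
    """Peaks near TSSs with a co-occurring motif pair planted in test-gene peaks.

    Summit-to-TSS distances are N(0, 3 kb) truncated to +/-8 kb. In peaks
    annotated to the test gene set, consensus instances of both planted
    motifs are co-inserted with probability ``co_rate``; every motif is also
    inserted independently at ``bg_rate`` everywhere. ``co_rate=0`` is the
    null setting.
    """
    rng = _rng(seed, "motif_peaks")
    motifs = [_sharp_pwm(rng, f"motif_{i:02d}", motif_width) for i in range(n_motifs)]
    pa, pb = (motifs[planted_pair[0]].motif_id, motifs[planted_pair[1]].motif_id)
    gene_ids = [t.gene_id for t in genome.tss]
    test_genes = set(rng.choice(gene_ids, size=n_test_genes, replace=False).tolist())
    tss_by_gene = {t.gene_id: t for t in genome.tss}

    peaks: list[Peak] = []
    seqs: dict[str, str] = {}
    truth: dict[str, list[str]] = {}
    half = peak_len // 2
    for i in range(n_peaks):
        gene = gene_ids[int(rng.integers(0, len(gene_ids)))]
        t = tss_by_gene[gene]
        d = int(np.clip(rng.normal(0, 3000), -8000, 8000))
        summit = t.position + d
        start = max(0, summit - half)
        end = start + peak_len
        name = f"peak_{i:04d}"
        seq = list(genome.sequences[t.chrom][start:end])
        inserted: list[str] = []
        occupied: list[tuple[int, int]] = []

        def insert(motif: PositionWeightMatrix, region: tuple[int, int]) -> None:
            # rejection-sample an offset that does not clobber an earlier
            # instance; skip (and omit from truth) if no room is found
            cons = motif.consensus
            if rng.random() < 0.5:
                cons = _revcomp(cons)
            lo, hi = region
            for _ in range(20):
                off = int(rng.integers(lo, hi - len(cons)))
                span = (off, off + len(cons))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    seq[span[0] : span[1]] = list(cons)
                    occupied.append(span)
                    inserted.append(motif.motif_id)
                    return

        is_test = gene in test_genes
        if is_test and rng.random() < co_rate:
            # co-insert the pair in disjoint halves so instances never collide
            insert(motifs[planted_pair[0]], (0, peak_len // 2))
            insert(motifs[planted_pair[1]], (peak_len // 2, peak_len))
        for j, m in enumerate(motifs):
            if rng.random() < bg_rate:
                insert(m, (0, peak_len))
        peaks.append(
            Peak(GenomicInterval(t.chrom, start, end, ".", name), summit_offset=summit - start)
        )
        seqs[name] = "".join(seq)
        truth[name] = inserted
    return MotifPeakFixture(peaks, seqs, motifs, test_genes, (pa, pb), truth, seed)


# ---------------------------------------------------------------- counts

@dataclass
class CountsFixture:
    matrix: "object"  # CountMatrix; imported lazily to avoid a cycle
    diff_peaks: set[str]
    diff_direction: dict[str, str]
    dispersion: float
    seed: int


def make_counts_fixture(
    n_peaks: int = 2000,
    n_rep: int = 3,
    mean_log: float = 4.0,
    mean_sd: float = 1.0,
    dispersion: float = 0.05,
    n_diff: int = 30,
    log2fc: float = 2.0,
    seed: int = 0,
) -> CountsFixture:
    """NB-distributed peak counts, 3v3 by default, with a differential subset.

    Peak base means are lognormal (median e^4 ~ 55 counts); library-size
    factors jitter around 1; half the differential peaks go up by
    ``log2fc`` in the treated group, half down.
    """
    from .accessibility import CountMatrix

    rng = _rng(seed, "counts")
    mu = np.exp(rng.normal(mean_log, mean_sd, size=n_peaks))
    peak_ids = [f"peak_{i:05d}" for i in range(n_peaks)]
    diff_idx = rng.choice(n_peaks, size=n_diff, replace=False)
    direction = {}
    fc = np.ones(n_peaks)
    for j, i in enumerate(sorted(diff_idx.tolist())):
        up = j % 2 == 0
        fc[i] = 2.0**log2fc if up else 2.0**-log2fc
        direction[peak_ids[i]] = "open" if up else "closed"

    samples = [f"ctrl_{r + 1}" for r in range(n_rep)] + [
        f"trt_{r + 1}" for r in range(n_rep)
    ]
    conditions = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}
    lib_factor = np.exp(rng.normal(0, 0.15, size=2 * n_rep))
    counts = np.zeros((n_peaks, 2 * n_rep), dtype=np.int64)
    r = 1.0 / dispersion if dispersion > 0 else None
    for j, s in enumerate(samples):
        m = mu * lib_factor[j]
        if conditions[s] == "treated":
            m = m * fc
        if r is None:
            counts[:, j] = rng.poisson(m)
        else:
            p = r / (r + m)
            counts[:, j] = rng.negative_binomial(r, p)
    lib_sizes = {s: int(round(lib_factor[j] * 1_000_000)) for j, s in enumerate(samples)}
    cm = CountMatrix(peak_ids, samples, conditions, counts, lib_sizes)
    return CountsFixture(cm, set(direction), direction, dispersion, seed)


# ---------------------------------------------------------------- cut sites

@dataclass
class CutSiteFixture:
    track: CutSiteTrack
    hits: list[GenomicMotifHit]
    fragment_lengths: np.ndarray
    dip: float
    rate: float
    period: float
    seed: int


def make_cutsite_fixture(
    n_instances: int = 500,
    motif_width: int = 8,
    flank: int = 100,
    dip: float = 0.6,
    rate: float = 0.5,
    period: float = 10.4,
    modulation: float = 0.25,
    n_fragments: int = 20_000,
    seed: int = 0,
) -> CutSiteFixture:
    """Cut-site track with footprint dips plus periodic fragment lengths.

    Within each motif window, per-bp cut counts are Poisson(rate) on the
    flanks and Poisson(rate * (1 - dip)) over the motif core, independently
    per strand. Fragment lengths follow a smooth decay modulated by a
    cosine of the given period; ``modulation=0`` gives the no-periodicity
    null and ``dip=0`` a flat footprint null.
    """
    rng = _rng(seed, "cutsites")
    chrom = "chrS"
    spacing = 2 * flank + motif_width + 200
    hits = []
    plus_pos: list[int] = []
    minus_pos: list[int] = []
    for i in range(n_instances):
        start = 1000 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(GenomicMotifHit(chrom, start, start + motif_width, strand, "planted"))
        lo = start - flank - 50
        hi = start + motif_width + flank + 50
        rates = np.full(hi - lo, rate)
        rates[start - lo : start - lo + motif_width] = rate * (1 - dip)
        for target, _s in ((plus_pos, "+"), (minus_pos, "-")):
            cuts = rng.poisson(rates)
            for off in np.flatnonzero(cuts):
                target.extend([lo + int(off)] * int(cuts[off]))
    track = CutSiteTrack({chrom: np.array(plus_pos)}, {chrom: np.array(minus_pos)})

    lengths = np.arange(1, 1001)
    pmf = np.where(
        lengths >= 40, np.exp(-(lengths - 40) / 120.0), 0.0
    ) * (1 + modulation * np.cos(2 * np.pi * lengths / period))
    pmf = np.clip(pmf, 0, None)
    pmf /= pmf.sum()
    frags = rng.choice(lengths, size=n_fragments, p=pmf)
    return CutSiteFixture(track, hits, frags, dip, rate, period, seed)


# ---------------------------------------------------------------- two species

@dataclass
class TwoSpeciesFixture:
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    tss_a: list[TssRecord]
    tss_b: list[TssRecord]
    orthologs: list[tuple[str, str]]
    reads_a: dict[str, dict[str, np.ndarray]]
    reads_b: dict[str, dict[str, np.ndarray]]
    flags: dict[str, bool]
    flagged_genes: set[str]
    shift_log2: float
    seed: int


def make_two_species_fixture(
    n_orthologs: int = 120,
    n_flagged: int = 40,
    shift_log2: float = 1.0,
    intensity_log: float = 5.0,
    intensity_sd: float = 0.4,
    seed: int = 0,
) -> TwoSpeciesFixture:
    """Two-species promoter fixture with an optional planted accessibility shift.

    Each ortholog gene gets one promoter peak per species at similar
    strand-oriented TSS distances (matched by construction). Read counts per
    summit window are Poisson around a shared per-gene intensity; on the
    flagged subset, species-B control reads are scaled by 2**shift_log2.
    ``shift_log2=0`` is the null.
    """
    rng = _rng(seed, "two_species")
    spacing = 10_000
    tss_a, tss_b = [], []
    peaks_a, peaks_b = [], []
    orthologs = []
    flags = {}
    flagged_idx = set(rng.choice(n_orthologs, size=n_flagged, replace=False).tolist())
    intensity = np.exp(rng.normal(intensity_log, intensity_sd, size=n_orthologs))
    reads_a = {"control": {"chrA1": []}, "treated": {"chrA1": []}}
    reads_b = {"control": {"chrB1": []}, "treated": {"chrB1": []}}
    flagged_genes = set()

    def place(tss_list, peaks_list, chrom, gene, pos, strand, d, name):
        tss_list.append(TssRecord(gene, chrom, pos, strand))
        summit = pos + d if strand == "+" else pos - d
        start = summit - 150
        peaks_list.append(
            Peak(GenomicInterval(chrom, start, start + 300, ".", name), summit_offset=150)
        )
        return summit

    for i in range(n_orthologs):
        ga, gb = f"mmu_{i:03d}", f"hsa_{i:03d}"
        orthologs.append((ga, gb))
        pos_a = 5000 + i * spacing
        pos_b = 5000 + i * spacing
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_b = "+" if rng.random() < 0.5 else "-"
        d_a = int(rng.integers(-1500, 1501))
        d_b = int(np.clip(d_a + rng.integers(-300, 301), -2000, 2000))
        name_a, name_b = f"pkA_{i:03d}", f"pkB_{i:03d}"
        sa = place(tss_a, peaks_a, "chrA1", ga, pos_a, strand_a, d_a, name_a)
        sb = place(tss_b, peaks_b, "chrB1", gb, pos_b, strand_b, d_b, name_b)

        flagged = i in flagged_idx
        flags[name_a] = flagged
        if flagged:
            flagged_genes.add(ga)
        base = intensity[i]
        for cond in ("control", "treated"):
            n_reads = rng.poisson(base)
            reads_a[cond]["chrA1"].extend(
                (sa + rng.normal(0, 20, size=n_reads)).astype(int).tolist()
            )
            mean_b = base * (2.0**shift_log2 if (flagged and cond == "control") else 1.0)
            n_reads_b = rng.poisson(mean_b)
            reads_b[cond]["chrB1"].extend(
                (sb + rng.normal(0, 20, size=n_reads_b)).astype(int).tolist()
            )
    for side in (reads_a, reads_b):
        for cond in side:
            for chrom in side[cond]:
                side[cond][chrom] = np.sort(np.array(side[cond][chrom], dtype=np.int64))
    return TwoSpeciesFixture(
        peaks_a, peaks_b, tss_a, tss_b, orthologs,
        reads_a, reads_b, flags, flagged_genes, shift_log2, seed,
    )


# ---------------------------------------------------------------- expression

# log2 condition-mean patterns over (P5-ctrl, P5-trt, P10-ctrl, P10-trt);
# C1 immune-like (developmentally down, boosted by treatment at P5),
# C2 cell-cycle-like (down by P10, persisting under treatment),
# C3 myelination-like (up by P10, blunted by treatment there, barely
# expressed and untouched at P5), C4 early-down. Up and down mass at P5 is
# kept comparable so quantile normalisation stays calibrated.
ARCHETYPE_PROFILES = {
    1: np.array([0.8, 2.8, -1.6, -0.2]),
    2: np.array([0.3, 0.3, -1.8, 1.8]),
    3: np.array([-1.5, -1.9, 1.8, 0.3]),
    4: np.array([1.0, -1.0, 0.0, 0.0]),
}

_CONDITIONS = ("P5_ctrl", "P5_trt", "P10_ctrl", "P10_trt")


@dataclass
class ExpressionFixture:
    matrix: "object"  # ExpressionMatrix over all 4 conditions x replicates
    annotation: dict[str, str]
    gene_cluster: dict[str, int]  # archetype genes only (1..4)
    up_probes_p5: set[str]
    down_probes_p5: set[str]
    up_genes_p5: set[str]
    down_genes_p5: set[str]
    condition_of: dict[str, str]
    seed: int

    def p5_matrix(self, quantile_normalized: bool = True):
        """Probes x (P5 control/treated) submatrix for the DE comparison.

        By default all 24 arrays are quantile-normalised jointly first (as a
        vendor pipeline would) and the P5 columns are then subset, so the
        caller should run the DE test with ``normalize=False``.
        """
        from .expression import ExpressionMatrix, quantile_normalize

        m = self.matrix
        if quantile_normalized:
            m = quantile_normalize(m)
        keep = [
            s for s in m.sample_ids
            if self.condition_of[s] in ("P5_ctrl", "P5_trt")
        ]
        idx = [m.sample_ids.index(s) for s in keep]
        groups = {
            s: ("control" if self.condition_of[s] == "P5_ctrl" else "treated")
            for s in keep
        }
        return ExpressionMatrix(
            list(m.probe_ids), keep, groups, m.intensities[:, idx]
        )


def make_expression_fixture(
    n_cluster_genes: int = 50,
    n_flat_genes: int = 400,
    n_reps: int = 6,
    sigma: float = 0.3,
    baseline_log2: float = 9.0,
    offset_sd: float = 2.0,
    seed: int = 0,
) -> ExpressionFixture:
    """Probe matrix with four planted temporal programs plus flat genes.

    Each archetype cluster carries ``n_cluster_genes`` genes with 1-3 probes
    each; flat genes have no condition effect. Flat genes outnumber
    programme genes roughly 2:1 so the differentially expressed fraction
    stays minor, as quantile normalisation assumes. Probe intensities are
    2**(baseline + probe offset + amplitude * pattern + N(0, sigma)). The
    planted P5 up/down truth follows each gene's amplitude-scaled P5
    treated-minus-control difference against the log2(1.5) threshold.
    """
    from .expression import ExpressionMatrix

    rng = _rng(seed, "expression")
    fc_log2 = np.log2(1.5)
    samples = [f"{c}_{r + 1}" for c in _CONDITIONS for r in range(n_reps)]
    condition_of = {s: s.rsplit("_", 1)[0] for s in samples}
    cond_idx = {c: [i for i, s in enumerate(samples) if condition_of[s] == c]
                for c in _CONDITIONS}

    probe_ids: list[str] = []
    annotation: dict[str, str] = {}
    gene_cluster: dict[str, int] = {}
    rows: list[np.ndarray] = []
    up_probes, down_probes = set(), set()
    up_genes, down_genes = set(), set()

    gi = 0
    for cluster in (1, 2, 3, 4, 0):  # 0 = flat background genes
        n_genes = n_flat_genes if cluster == 0 else n_cluster_genes
        for _ in range(n_genes):
            gene = f"g{gi:04d}"
            gi += 1
            amp = rng.uniform(0.8, 1.2)
            if cluster:
                gene_cluster[gene] = cluster
                pattern = ARCHETYPE_PROFILES[cluster] * amp
            else:
                pattern = np.zeros(4)
            delta_p5 = pattern[1] - pattern[0]
            n_probes = int(rng.integers(1, 4))
            for pi in range(n_probes):
                probe = f"{gene}_p{pi}"
                probe_ids.append(probe)
                annotation[probe] = gene
                offset = rng.normal(0, offset_sd)
                row = np.empty(len(samples))
                for ci, c in enumerate(_CONDITIONS):
                    row[cond_idx[c]] = baseline_log2 + offset + pattern[ci]
                row = row + rng.normal(0, sigma, size=len(samples))
                rows.append(2.0**row)
                if delta_p5 > fc_log2:
                    up_probes.add(probe)
                    up_genes.add(gene)
                elif delta_p5 < -fc_log2:
                    down_probes.add(probe)
                    down_genes.add(gene)
    groups = {s: condition_of[s] for s in samples}
    matrix = ExpressionMatrix(probe_ids, samples, groups, np.array(rows))
    return ExpressionFixture(
        matrix, annotation, gene_cluster,
        up_probes, down_probes, up_genes, down_genes, condition_of, seed,
    )
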