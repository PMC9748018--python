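"""Stage orchestration: validated run configuration, logging, atomic outputs.

Each run executes exactly one stage (simulate | annotate | pmet | crossmatch
| diffacc | footprint | expression) on files named in the configuration,
writes its outputs atomically (temp file + rename) under the output
directory, and emits a JSON summary recording the version, the effective
configuration, seeds and row counts at every filter step.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as ppio
from .accessibility import run_diffacc
from .cross_species import OrthologMap, run_crossmatch
from .expression import cluster_profiles, de_filter_and_collapse, run_de
from .footprints import average_profile, insert_size_periodicity
from .intervals import annotate_closest_tss, filter_tss_window, remove_blacklisted
from .motifs import run_pmet
from . import simulate as sim

__all__ = ["RunConfig", "run_stage", "STAGES"]

STAGES = (
    "simulate",
    "annotate",
    "pmet",
    "crossmatch",
    "diffacc",
    "footprint",
    "expression",
)

_DEFAULT_PARAMS: dict[str, Any] = {
    "tss_window": 8000,
    "promoter_window": 2000,
    "rel_tol": 500,
    "summit_flank": 50,
    "top_n": 5000,
    "scan_threshold": 6.0,
    "fc_thresh": 1.5,
    "fdr": 0.05,
    "k_clusters": 4,
    "dispersion": 0.05,
    "flank": 100,
    "seed": 0,
}

_KNOWN_INPUT_ROLES = {
    "peaks", "peaks_b", "blacklist", "tss", "tss_b", "sequences", "motifs",
    "orthologs", "flags", "counts", "counts_sidecar", "cuts", "fragments",
    "expression", "groups", "annotation", "test_genes", "hits", "annotated",
    "reads_a", "reads_b",
}


@dataclass
class RunConfig:
    """One stage's inputs and parameters, fully validated before any I/O."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        unknown = set(self.inputs) - _KNOWN_INPUT_ROLES
        if unknown:
            raise ValueError(f"unknown input roles: {sorted(unknown)}")
        unknown_p = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown_p:
            raise ValueError(f"unknown parameters: {sorted(unknown_p)}")
        merged = dict(_DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key in ("tss_window", "promoter_window", "rel_tol", "summit_flank",
                    "top_n", "flank"):
            if not merged[key] > 0:
                raise ValueError(f"parameter {key} must be positive, got {merged[key]}")
        if not 0 < merged["fdr"] < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if merged["fc_thresh"] <= 1:
            raise ValueError("fc_thresh must exceed 1")
        if merged["k_clusters"] < 2:
            raise ValueError("k_clusters must be >= 2")
        if merged["dispersion"] is not None and merged["dispersion"] < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(
            stage=raw.get("stage", ""),
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
            out_dir=raw.get("out_dir", "."),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {"stage": self.stage, "inputs": self.inputs, "params": self.params},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(cfg: RunConfig, *roles: str) -> None:
    for role in roles:
        path = cfg.inputs.get(role)
        if not path:
            raise ValueError(f"stage {cfg.stage} requires input {role!r}")
        if not os.path.exists(path):
            raise FileNotFoundError(f"input {role!r} not found: {path}")


def _out(cfg: RunConfig, name: str) -> str:
    os.makedirs(cfg.out_dir, exist_ok=True)
    return os.path.join(cfg.out_dir, name)


def _write_df(cfg: RunConfig, name: str, df: pd.DataFrame, log: dict) -> str:
    path = _out(cfg, name)
    with ppio.atomic_write(path) as fh:
        fh.write(f"# primedpeaks {__version__} stage={cfg.stage} "
                 f"config={cfg.config_hash()} seed={cfg.params['seed']}\n")
        df.to_csv(fh, sep="\t", index=False)
    log.setdefault("outputs", {})[name] = len(df)
    return path


def run_stage(config: RunConfig) -> dict:
    """Execute one stage; returns the JSON-serialisable run summary."""
    log: dict[str, Any] = {
        "version": __version__,
        "stage": config.stage,
        "config_hash": config.config_hash(),
        "params": dict(config.params),
        "counts": {},
    }
    handler = _HANDLERS[config.stage]
    handler(config, log)
    summary_path = _out(config, f"{config.stage}_summary.json")
    with ppio.atomic_write(summary_path) as fh:
        json.dump(log, fh, indent=2, default=str)
        fh.write("\n")
    return log


def _load_annotated(cfg: RunConfig, peaks_role: str, tss_role: str, window: int):
    peaks = ppio.read_narrowpeak(cfg.inputs[peaks_role])
    tss = ppio.read_tss_table(cfg.inputs[tss_role])
    ann = annotate_closest_tss(peaks, tss)
    return filter_tss_window(ann, window)


def _stage_simulate(cfg: RunConfig, log: dict) -> None:
    """Emit a complete fixture set, one file per downstream input role."""
    seed = int(cfg.params["seed"])
    genome = sim.make_genome_fixture(seed=seed)
    fix = sim.make_motif_peak_fixture(genome, seed=seed)
    ppio.write_tss_table(_out(cfg, "tss.tsv"), genome.tss)
    ppio.write_narrowpeak(_out(cfg, "peaks.narrowPeak"), fix.peaks)
    ppio.write_fasta(_out(cfg, "peaks.fasta"), fix.sequences)
    ppio.write_meme_motifs(_out(cfg, "motifs.meme"), fix.motifs)
    with ppio.atomic_write(_out(cfg, "test_genes.txt")) as fh:
        for g in sorted(fix.test_genes):
            fh.write(g + "\n")

    counts = sim.make_counts_fixture(seed=seed)
    ppio.write_count_matrix(
        _out(cfg, "counts.tsv"), _out(cfg, "samples.tsv"), counts.matrix
    )

    cuts = sim.make_cutsite_fixture(seed=seed)
    ppio.write_cut_sites(_out(cfg, "cut_sites.bed"), cuts.track)
    with ppio.atomic_write(_out(cfg, "fragments.tsv")) as fh:
        fh.write("length\n")
        for l in cuts.fragment_lengths:
            fh.write(f"{int(l)}\n")
    with ppio.atomic_write(_out(cfg, "motif_hits.tsv")) as fh:
        fh.write("chrom\tstart\tend\tstrand\tmotif_id\n")
        for h in cuts.hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.motif_id}\n")

    two = sim.make_two_species_fixture(seed=seed)
    ppio.write_narrowpeak(_out(cfg, "peaks_b.narrowPeak"), two.peaks_b)
    ppio.write_narrowpeak(_out(cfg, "peaks_a.narrowPeak"), two.peaks_a)
    ppio.write_tss_table(_out(cfg, "tss_a.tsv"), two.tss_a)
    ppio.write_tss_table(_out(cfg, "tss_b.tsv"), two.tss_b)
    ppio.write_ortholog_map(_out(cfg, "orthologs.tsv"), two.orthologs)
    with ppio.atomic_write(_out(cfg, "flags.tsv")) as fh:
        fh.write("peak_id\tflag\n")
        for pid, flag in sorted(two.flags.items()):
            fh.write(f"{pid}\t{flag}\n")
    for side, reads in (("a", two.reads_a), ("b", two.reads_b)):
        with ppio.atomic_write(_out(cfg, f"reads_{side}.bed")) as fh:
            for cond in ("control", "treated"):
                for chrom, pos in reads[cond].items():
                    for p in pos:
                        fh.write(f"{chrom}\t{p}\t{p + 1}\t{cond}\t0\t+\n")

    expr = sim.make_expression_fixture(seed=seed)
    p5 = expr.p5_matrix(quantile_normalized=False)
    df = p5.to_frame()
    df.index.name = "probe_id"
    with ppio.atomic_write(_out(cfg, "expression.tsv")) as fh:
        df.to_csv(fh, sep="\t")
    with ppio.atomic_write(_out(cfg, "groups.tsv")) as fh:
        fh.write("sample_id\tgroup\n")
        for s in p5.sample_ids:
            fh.write(f"{s}\t{p5.groups[s]}\n")
    with ppio.atomic_write(_out(cfg, "probe_annotation.tsv")) as fh:
        fh.write("probe_id\tgene_id\n")
        for p, g in sorted(expr.annotation.items()):
            fh.write(f"{p}\t{g}\n")

    manifest = {
        "seed": seed,
        "planted_pair": list(fix.planted_pair),
        "n_peaks": len(fix.peaks),
        "n_genes": len(genome.tss),
        "test_genes": sorted(fix.test_genes),
        "diff_peaks": sorted(counts.diff_peaks),
        "footprint_dip": cuts.dip,
        "insert_period": cuts.period,
        "flagged_genes": sorted(two.flagged_genes),
        "up_probes_p5": sorted(expr.up_probes_p5),
        "down_probes_p5": sorted(expr.down_probes_p5),
    }
    with ppio.atomic_write(_out(cfg, "manifest.json")) as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    log["counts"]["peaks"] = len(fix.peaks)
    log["counts"]["genes"] = len(genome.tss)


def _stage_annotate(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "peaks", "tss")
    peaks = ppio.read_narrowpeak(cfg.inputs["peaks"])
    log["counts"]["peaks_in"] = len(peaks)
    if cfg.inputs.get("blacklist"):
        bl = ppio.read_bed(cfg.inputs["blacklist"])
        peaks = remove_blacklisted(peaks, bl)
        log["counts"]["after_blacklist"] = len(peaks)
    tss = ppio.read_tss_table(cfg.inputs["tss"])
    ann = annotate_closest_tss(peaks, tss)
    window = int(cfg.params["tss_window"])
    kept = filter_tss_window(ann, window)
    log["counts"]["within_window"] = len(kept)
    df = pd.DataFrame(
        {
            "peak_id": [a.name for a in kept],
            "chrom": [a.peak.chrom for a in kept],
            "start": [a.peak.start for a in kept],
            "end": [a.peak.end for a in kept],
            "gene_id": [a.gene_id for a in kept],
            "signed_distance": [a.signed_distance for a in kept],
        }
    )
    _write_df(cfg, "annotated_peaks.tsv", df, log)


def _stage_pmet(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "peaks", "tss", "sequences", "motifs", "test_genes")
    ann = _load_annotated(cfg, "peaks", "tss", int(cfg.params["tss_window"]))
    log["counts"]["universe"] = len(ann)
    seqs = ppio.read_fasta(cfg.inputs["sequences"])
    motifs = ppio.read_meme_motifs(cfg.inputs["motifs"])
    with open(cfg.inputs["test_genes"]) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    res = run_pmet(
        seqs, motifs, ann, genes,
        top_n=int(cfg.params["top_n"]),
        scan_threshold=float(cfg.params["scan_threshold"]),
    )
    _write_df(cfg, "pmet_pairs.tsv", res.to_frame(), log)
    mat = res.neglog10_q_matrix()
    path = _out(cfg, "pmet_matrix.tsv")
    with ppio.atomic_write(path) as fh:
        mat.to_csv(fh, sep="\t")
    best = res.best_pair()
    log["best_pair"] = {"motif_a": best.motif_a, "motif_b": best.motif_b,
                        "q": best.q_value}


def _stage_crossmatch(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "peaks", "peaks_b", "tss", "tss_b", "orthologs", "flags",
             "reads_a", "reads_b")
    win = int(cfg.params["promoter_window"])
    ann_a = _load_annotated(cfg, "peaks", "tss", win)
    ann_b = _load_annotated(cfg, "peaks_b", "tss_b", win)
    orth = OrthologMap(ppio.read_ortholog_map(cfg.inputs["orthologs"]))
    flags_df = pd.read_csv(cfg.inputs["flags"], sep="\t", dtype={"peak_id": str})
    flags = dict(zip(flags_df["peak_id"], flags_df["flag"].astype(bool)))
    reads = {}
    for side, role in (("a", "reads_a"), ("b", "reads_b")):
        # read positions stored as BED of 1-bp points, condition in the name column
        ivs = ppio.read_bed(cfg.inputs[role])
        per_cond: dict[str, dict[str, list[int]]] = {"control": {}, "treated": {}}
        for iv in ivs:
            per_cond[iv.name].setdefault(iv.chrom, []).append(iv.start)
        reads[side] = {
            c: {ch: np.sort(np.array(v)) for ch, v in chs.items()}
            for c, chs in per_cond.items()
        }
    res = run_crossmatch(
        ann_a, ann_b, orth, reads["a"], reads["b"], flags,
        promoter_bp=win,
        rel_tol_bp=int(cfg.params["rel_tol"]),
        summit_flank=int(cfg.params["summit_flank"]),
    )
    log["counts"]["matched_pairs"] = len(res.pairs)
    _write_df(cfg, "matched_pairs.tsv", res.to_frame(), log)
    log["tests"] = {
        name: {"W": t.statistic, "p": t.p_value, "n": t.n_used,
               "degenerate": t.degenerate}
        for name, t in res.tests.items()
    }


def _stage_diffacc(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "counts", "counts_sidecar")
    cm = ppio.read_count_matrix(cfg.inputs["counts"], cfg.inputs["counts_sidecar"])
    log["counts"]["peaks"] = len(cm.peak_ids)
    summary = run_diffacc(
        cm, dispersion=cfg.params["dispersion"], fdr=float(cfg.params["fdr"])
    )
    _write_df(cfg, "diffacc_results.tsv", summary.to_frame(), log)
    log["counts"]["open"] = summary.n_open
    log["counts"]["closed"] = summary.n_closed
    log["dispersion_used"] = summary.dispersion


def _stage_footprint(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "cuts", "hits", "fragments")
    track = ppio.read_cut_sites(cfg.inputs["cuts"])
    from .footprints import GenomicMotifHit

    hits_df = pd.read_csv(cfg.inputs["hits"], sep="\t", dtype={"chrom": str})
    hits = [
        GenomicMotifHit(r.chrom, int(r.start), int(r.end), r.strand,
                        getattr(r, "motif_id", ""))
        for r in hits_df.itertuples(index=False)
    ]
    profile = average_profile(track, hits, flank=int(cfg.params["flank"]))
    _write_df(cfg, "footprint_profile.tsv", profile.to_frame(), log)
    log["dip_depth"] = profile.dip_depth()
    frags = pd.read_csv(cfg.inputs["fragments"], sep="\t")["length"].to_numpy()
    per = insert_size_periodicity(frags)
    log["insert_period"] = per.period


def _stage_expression(cfg: RunConfig, log: dict) -> None:
    _require(cfg, "expression", "groups", "annotation")
    from .expression import ExpressionMatrix

    df = pd.read_csv(cfg.inputs["expression"], sep="\t", index_col=0, comment="#")
    groups_df = pd.read_csv(cfg.inputs["groups"], sep="\t", dtype=str)
    groups = dict(zip(groups_df["sample_id"], groups_df["group"]))
    m = ExpressionMatrix(
        list(df.index.astype(str)), list(df.columns), groups, df.to_numpy()
    )
    annot_df = pd.read_csv(cfg.inputs["annotation"], sep="\t", dtype=str)
    annot = dict(zip(annot_df["probe_id"], annot_df["gene_id"]))
    results = run_de(m)
    res_df = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "fc_signed": [r.fc_signed for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
        }
    )
    _write_df(cfg, "de_results.tsv", res_df, log)
    up_p, down_p, up_g, down_g = de_filter_and_collapse(
        results, annot,
        fc_thresh=float(cfg.params["fc_thresh"]), fdr=float(cfg.params["fdr"]),
    )
    log["counts"].update(
        up_probes=len(up_p), down_probes=len(down_p),
        up_genes=len(up_g), down_genes=len(down_g),
    )
    sig = set(up_p) | set(down_p)
    if len(sig) >= int(cfg.params["k_clusters"]):
        sub = df.loc[sorted(sig)]
        clust = cluster_profiles(sub, k=int(cfg.params["k_clusters"]))
        cdf = pd.DataFrame(
            sorted(clust.labels.items()), columns=["probe_id", "cluster"]
        )
        _write_df(cfg, "clusters.tsv", cdf, log)


_HANDLERS = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "pmet": _stage_pmet,
    "crossmatch": _stage_crossmatch,
    "diffacc": _stage_diffacc,
    "footprint": _stage_footprint,
    "expression": _stage_expression,
}
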