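"""Readers and writers for the plain-text formats the pipeline consumes.

BED6 / narrowPeak are read and written without any coordinate shifting
(0-based half-open on disk and in memory). The narrowPeak summit column
(column 10) is an offset from the interval start, with -1 meaning absent.
TSS tables, ortholog maps, count matrices and expression matrices are
tab-separated with headers. Motifs use the MEME minimal text format.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, Peak, TssRecord

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tss_table",
    "write_tss_table",
    "read_fasta",
    "write_fasta",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_count_matrix",
    "write_count_matrix",
    "read_cut_sites",
    "write_cut_sites",
    "atomic_write",
]


def _open_maybe(path_or_handle, mode="r"):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


class atomic_write:
    """Context manager writing to ``<path>.tmp`` then renaming on success."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self.tmp = self.path + ".tmp"
        self._fh: TextIO | None = None

    def __enter__(self) -> TextIO:
        self._fh = open(self.tmp, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        assert self._fh is not None
        self._fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


# ---------------------------------------------------------------- BED / narrowPeak

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicIntervals (extra columns ignored)."""
    fh, close = _open_maybe(path)
    out = []
    try:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 fields")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    finally:
        if close:
            fh.close()
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], score: float = 0) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score:g}\t{iv.strand}\n")
    finally:
        if close:
            fh.close()


def read_narrowpeak(path) -> list[Peak]:
    """Read ENCODE narrowPeak (10 columns; column 10 = summit offset, -1 = absent)."""
    fh, close = _open_maybe(path)
    out = []
    try:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"narrowPeak line {ln}: expected 10 fields, got {len(f)}")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5], f[3])
            summit = int(f[9])
            out.append(
                Peak(
                    iv,
                    summit_offset=None if summit == -1 else summit,
                    score=float(f[4]) if f[4] != "." else None,
                )
            )
    finally:
        if close:
            fh.close()
    return out


def write_narrowpeak(path, peaks: Sequence[Peak]) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        for p in peaks:
            score = f"{p.score:g}" if p.score is not None else "0"
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t"
                f"{p.interval.strand}\t0\t-1\t-1\t{summit}\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------- TSS tables

def read_tss_table(path) -> list[TssRecord]:
    """TSV with header ``gene_id chrom position strand``; positions 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return [
        TssRecord(r.gene_id, r.chrom, int(r.position), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss_table(path, tss: Sequence[TssRecord]) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        fh.write("gene_id\tchrom\tposition\tstrand\n")
        for t in tss:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.position}\t{t.strand}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """FASTA to {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    fh, close = _open_maybe(path, "w")
    try:
        SeqIO.write(records, fh, "fasta")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------- MEME minimal motifs

def read_meme_motifs(path):
    """Parse MEME minimal motif format into PositionWeightMatrix objects.

    Background frequencies are taken from the ``Background letter frequencies``
    block when present, else uniform. A small pseudocount is folded into any
    zero matrix entry so log-odds are finite.
    """
    from .motifs import PositionWeightMatrix

    fh, close = _open_maybe(path)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    background = np.full(4, 0.25)
    motifs = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq[b] for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in s.split()])
                i += 1
            probs = np.asarray(rows, dtype=float)
            if probs.ndim != 2 or probs.shape[1] != 4:
                raise ValueError(f"motif {motif_id}: malformed probability matrix")
            if (probs <= 0).any():
                probs = (probs + 1e-4) / (probs + 1e-4).sum(axis=1, keepdims=True)
            motifs.append(PositionWeightMatrix(motif_id, probs, background.copy()))
            continue
        i += 1
    return motifs


def write_meme_motifs(path, motifs) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write("  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------- ortholog maps

def read_ortholog_map(path) -> list[tuple[str, str]]:
    """TSV with header ``gene_a gene_b``; 1-to-1 checked by OrthologMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("ortholog map needs columns gene_a, gene_b")
    return list(zip(df["gene_a"], df["gene_b"]))


def write_ortholog_map(path, pairs: Iterable[tuple[str, str]]) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------- count matrices

def read_count_matrix(path, sidecar):
    """Count matrix TSV (peaks x samples) plus a sidecar TSV of sample metadata.

    Sidecar columns: ``sample_id``, ``condition`` (control/treated),
    ``library_size``.
    """
    from .accessibility import CountMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(sidecar, sep="\t", dtype={"sample_id": str})
    meta = meta.set_index("sample_id").loc[list(df.columns)]
    return CountMatrix(
        peak_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns),
        conditions={s: c for s, c in meta["condition"].items()},
        counts=df.to_numpy(dtype=np.int64),
        library_sizes={s: int(v) for s, v in meta["library_size"].items()},
    )


def write_count_matrix(path, sidecar, cm) -> None:
    df = pd.DataFrame(cm.counts, index=cm.peak_ids, columns=cm.sample_ids)
    df.index.name = "peak_id"
    df.to_csv(path, sep="\t")
    with open(sidecar, "w") as fh:
        fh.write("sample_id\tcondition\tlibrary_size\n")
        for s in cm.sample_ids:
            fh.write(f"{s}\t{cm.conditions[s]}\t{cm.library_sizes[s]}\n")


# ---------------------------------------------------------------- cut sites

def read_cut_sites(path):
    """BED6 of 1-bp Tn5 insertion points -> CutSiteTrack (pre-shifted input)."""
    from .footprints import CutSiteTrack

    ivs = read_bed(path)
    recs = [(iv.chrom, iv.start, iv.strand) for iv in ivs]
    return CutSiteTrack.from_cuts(recs)


def write_cut_sites(path, track) -> None:
    fh, close = _open_maybe(path, "w")
    try:
        i = 0
        for chrom in sorted(track.chroms()):
            for pos, strand in track.iter_chrom(chrom):
                i += 1
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tcut_{i}\t0\t{strand}\n")
    finally:
        if close:
            fh.close()
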