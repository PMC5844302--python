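"""Readers and writers for the tab-delimited formats the pipeline touches.

Formats
-------
G.bed
    Six columns: chrom, start, end, ratio, total, meth. One row per CpG,
    keyed by the plus-strand C coordinate ``N`` with ``end = N + 2``.
    ``ratio`` is a fraction in [0, 1]; counts are authoritative and the
    ratio is recomputed from them on read whenever ``total > 0``. A row
    with ``total = 0`` is legal and carries ``ratio = NaN``.
BED3/BED6
    Standard 0-based half-open BED.
Gene models
    genePred-like table: gene_id, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated, trailing comma tolerated).
Strand base pileup
    chrom, pos, strand, nA, nC, nG, nT, nMeth, nUnmeth.
M-bias call table
    mate, length_class, read_pos, nMeth, nUnmeth.
Expression table
    gene_id followed by one FPKM column per replicate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, sort_intervals

GBED_COLUMNS = ["chrom", "start", "end", "ratio", "total", "meth"]
PILEUP_COLUMNS = [
    "chrom", "pos", "strand", "nA", "nC", "nG", "nT", "nMeth", "nUnmeth",
]
MBIAS_COLUMNS = ["mate", "length_class", "read_pos", "nMeth", "nUnmeth"]


class ParseError(ValueError):
    """A malformed line; the message names the file and line number."""


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# G.bed methylation dialect
# ---------------------------------------------------------------------------

def read_gbed(path) -> pd.DataFrame:
    """Read a G.bed methylation table, sorted by (chrom, start).

    Ratios are recomputed from counts where ``total > 0``; zero-depth rows
    keep ``ratio = NaN``. Rows with ``meth > total`` or a negative count
    raise :class:`ParseError`.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                _fail(path, lineno, f"expected 6 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                total, meth = int(parts[4]), int(parts[5])
            except ValueError:
                _fail(path, lineno, f"non-numeric field in {parts!r}")
            if not chrom:
                _fail(path, lineno, "empty chrom")
            if end - start != 2:
                _fail(path, lineno, f"CpG record must span 2 bp, got {end - start}")
            if meth < 0 or total < 0:
                _fail(path, lineno, "negative count")
            if meth > total:
                _fail(path, lineno, f"meth {meth} > total {total}")
            rows.append((chrom, start, end, total, meth))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "total", "meth"])
    df["ratio"] = np.where(df["total"] > 0, df["meth"] / df["total"].replace(0, 1), np.nan)
    df = df[GBED_COLUMNS]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_gbed(df: pd.DataFrame, path) -> None:
    out = df.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            ratio = "NA" if not np.isfinite(row.ratio) else f"{row.ratio:.6g}"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{ratio}\t"
                f"{int(row.total)}\t{int(row.meth)}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted :class:`GenomicInterval` records."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, "need >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates in {parts[:3]!r}")
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, strand, name))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return sort_intervals(out)


def write_bed(intervals: Iterable[GenomicInterval], path, bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene models (genePred-like)
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read a genePred-like table into :class:`GeneModel` records.

    TSS/TES follow strand: TSS = txStart for ``+``, txEnd − 1 for ``−``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                _fail(path, lineno, f"expected 7 columns, got {len(parts)}")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            try:
                tx_start, tx_end = int(parts[3]), int(parts[4])
                ex_starts = [int(x) for x in parts[5].rstrip(",").split(",") if x]
                ex_ends = [int(x) for x in parts[6].rstrip(",").split(",") if x]
            except ValueError:
                _fail(path, lineno, "non-integer coordinate field")
            if len(ex_starts) != len(ex_ends):
                _fail(
                    path, lineno,
                    f"exonStarts ({len(ex_starts)}) and exonEnds "
                    f"({len(ex_ends)}) differ in length",
                )
            if strand == "+":
                tss, tes = tx_start, tx_end - 1
            elif strand == "-":
                tss, tes = tx_end - 1, tx_start
            else:
                _fail(path, lineno, f"gene strand must be + or -, got {strand!r}")
            try:
                exons = tuple(
                    GenomicInterval(chrom, s, e, strand)
                    for s, e in zip(ex_starts, ex_ends)
                )
                out.append(GeneModel(gene_id, chrom, strand, tss, tes, exons))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return out


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.body_span()
            starts = ",".join(str(ex.start) for ex in g.exons) + ","
            ends = ",".join(str(ex.end) for ex in g.exons) + ","
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{lo}\t{hi}\t{starts}\t{ends}\n")


# ---------------------------------------------------------------------------
# Pileups, M-bias tables, expression
# ---------------------------------------------------------------------------

def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing pileup columns {sorted(missing)}")
    counts = df[["nA", "nC", "nG", "nT", "nMeth", "nUnmeth"]]
    if (counts.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative count in pileup")
    return df[PILEUP_COLUMNS]


def write_pileup(df: pd.DataFrame, path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mbias_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"length_class": str})
    missing = set(MBIAS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing M-bias columns {sorted(missing)}")
    if (df[["nMeth", "nUnmeth"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative count in M-bias table")
    return df[MBIAS_COLUMNS]


def write_mbias_table(df: pd.DataFrame, path) -> None:
    df[MBIAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression table: gene_id plus one FPKM column per replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise ParseError(f"{path}: need gene_id plus >= 1 FPKM column")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
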