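"""Readers and writers for the plain-text formats the pipeline touches.

All genomic intervals are 0-based, half-open (BED-native) everywhere inside
the package.  For a minus-strand gene the TSS is the ``end - 1`` position of
the transcript interval under this convention.  Chromosome names are passed
through verbatim — no "chr" normalization is attempted; a mismatch between
the chromosome sets of two inputs is a hard error listing the difference.

Formats
-------
* tags: BED6 (chrom, start, end, name, score, strand)
* genes: TSV with columns gene_id, chrom, strand, tss, tes, isoform_id
* expression: TSV, first column gene_id, remaining columns ``cell:time``
* coverage: bedGraph, run-length encoded, zero intervals suppressed
* ground truth / reports: JSON
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CELL_TYPES = ("Naive", "TCM", "TEM")
TIMEPOINTS = ("R", "40min", "150min", "15h")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


class ChromosomeMismatchError(ValueError):
    """Tag and annotation chromosome sets differ."""


@dataclass(frozen=True)
class Tag:
    """One uniquely aligned sequencing read as a stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid tag interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def five_prime(self) -> int:
        """0-based position of the 5' end (last base of interval on -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneRecord:
    """One transcription unit keyed by (gene_id, isoform_id).

    ``tss``/``tes`` are 0-based positions; on the minus strand tss > tes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    isoform_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.tss == self.tes:
            raise ValueError(f"tss == tes for {self.gene_id}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"+strand gene {self.gene_id} has tss > tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"-strand gene {self.gene_id} has tss < tes")


@dataclass
class ExpressionRecord:
    """FPKM values for one gene over (cell type, timepoint) conditions."""

    gene_id: str
    fpkm: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, cell: str, time: str) -> float:
        try:
            return self.fpkm[(cell, time)]
        except KeyError:
            raise KeyError(
                f"gene {self.gene_id}: no FPKM for ({cell}, {time})"
            ) from None


@dataclass
class CoverageTrack:
    """Per-base fragment coverage on one chromosome, in FPM units."""

    chrom: str
    values: np.ndarray
    total_mapped: int
    fragment_length: int


# ---------------------------------------------------------------------------
# BED6 tags
# ---------------------------------------------------------------------------

def read_tags(path: str | Path) -> dict[str, list[Tag]]:
    """Read a BED6 file into tags grouped by chromosome, sorted by start.

    Raises :class:`ParseError` naming the offending line for malformed
    records (wrong column count, start >= end, unknown strand).
    """
    by_chrom: dict[str, list[Tag]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end} "
                    "(intervals are half-open)"
                )
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            by_chrom.setdefault(chrom, []).append(Tag(chrom, start, end, strand))
    for tags in by_chrom.values():
        tags.sort(key=lambda t: t.start)
    return by_chrom


def write_tags(tags: Iterable[Tag], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tr{i}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Gene annotation TSV
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes", "isoform_id"]


def read_genes(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "isoform_id": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing gene columns {sorted(missing)}")
    return [
        GeneRecord(
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss),
            tes=int(row.tes),
            isoform_id=row.isoform_id,
        )
        for row in df.itertuples()
    ]


def write_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes, g.isoform_id) for g in genes],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def check_chromosomes(
    tag_chroms: Iterable[str], gene_chroms: Iterable[str]
) -> None:
    """Hard error if the two chromosome name sets differ."""
    a, b = set(tag_chroms), set(gene_chroms)
    if a != b:
        raise ChromosomeMismatchError(
            f"chromosome sets differ: tags-only={sorted(a - b)}, "
            f"annotation-only={sorted(b - a)}"
        )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def _parse_condition(col: str) -> tuple[str, str]:
    if ":" not in col:
        raise ParseError(f"expression column {col!r} is not 'cell:time'")
    cell, time = col.split(":", 1)
    return cell, time


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read a gene x condition FPKM table.

    Columns after ``gene_id`` are named ``cell:time``; missing cells are
    '.' or empty and simply absent from the record's map (operations that
    need them raise later).  Negative FPKM and duplicate condition columns
    or gene rows are parse errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, na_values=["."])
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: first column must be gene_id")
    conds = [c for c in df.columns if c != "gene_id"]
    if len(set(conds)) != len(conds):
        raise ParseError(f"{path}: duplicate condition columns")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene row {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        rec = ExpressionRecord(gene_id=row.gene_id)
        for col, val in zip(df.columns[1:], row[1:]):
            if pd.isna(val):
                continue
            val = float(val)
            if val < 0:
                raise ParseError(
                    f"{path}: negative FPKM {val} for gene {row.gene_id}, {col}"
                )
            rec.fpkm[_parse_condition(col)] = val
        records.append(rec)
    return records


def write_expression(
    records: Sequence[ExpressionRecord],
    path: str | Path,
    cells: Sequence[str] = CELL_TYPES,
    times: Sequence[str] = TIMEPOINTS,
) -> None:
    cols = [f"{c}:{t}" for c in cells for t in times]
    rows = []
    for rec in records:
        row: dict[str, object] = {"gene_id": rec.gene_id}
        for c in cells:
            for t in times:
                row[f"{c}:{t}"] = rec.fpkm.get((c, t), np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene_id"] + cols)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path, mode: str = "w") -> None:
    """Run-length-encode a coverage track; zero-valued runs are suppressed.

    Values are printed with 4 decimal places; the reader round-trips
    bit-exactly at that precision.
    """
    vals = np.round(np.asarray(track.values, dtype=float), 4)
    with open(path, mode) as fh:
        if vals.size == 0:
            return
        # boundaries where the value changes
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [vals.size]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v == 0:
                continue
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.4f}\n")


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_bedgraph`; unlisted positions are 0."""
    out = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom not in out:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
            out[chrom][int(s):int(e)] = float(v)
    return out


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj: object, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o: object) -> object:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
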