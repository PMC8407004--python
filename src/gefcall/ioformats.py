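"""Strict readers/writers for the plain-text formats the pipeline exchanges.

FASTA and FASTQ go through Biopython; the interval formats (BED, BEDPE,
bedGraph) are parsed here with line-numbered errors, since downstream stages
must reject malformed rows by name rather than silently coerce them.  All
interval formats are 0-based half-open.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
from Bio import SeqIO


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataError(Exception):
    """Malformed input data (CLI exit code 3)."""


class BedRecord(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


# --------------------------------------------------------------------------
# FASTA / FASTQ
# --------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; wrapping/case normalised."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class FastqRead(NamedTuple):
    name: str
    seq: str
    qual: str


def read_fastq(path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


# --------------------------------------------------------------------------
# BED / BEDPE
# --------------------------------------------------------------------------

def _parse_int(field: str, what: str, path, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise DataError(f"{path}:{lineno}: non-integer {what} {field!r}") from None


def read_bed(path, min_fields: int = 3) -> list[BedRecord]:
    """Strict BED reader; malformed rows raise :class:`DataError` naming the line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise DataError(f"{path}:{lineno}: expected >={min_fields} fields, got {len(fields)}")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            if start < 0 or start >= end:
                raise DataError(f"{path}:{lineno}: invalid interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedRecord(chrom, start, end, name, score, strand))
    return out


def write_bed(path, records: Iterable[BedRecord]) -> None:
    """Write BED6 sorted by (chrom, start, end)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_fmt_score(r.score)}\t{r.strand}\n")


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else f"{score:g}"


def read_bedpe(path) -> list[tuple[str, int, int, str, int, int]]:
    """Strict BEDPE reader (first six columns); line-numbered errors."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: BEDPE needs >=6 fields, got {len(fields)}")
            c1, c2 = fields[0], fields[3]
            s1 = _parse_int(fields[1], "start1", path, lineno)
            e1 = _parse_int(fields[2], "end1", path, lineno)
            s2 = _parse_int(fields[4], "start2", path, lineno)
            e2 = _parse_int(fields[5], "end2", path, lineno)
            for s, e, tag in ((s1, e1, "mate1"), (s2, e2, "mate2")):
                if s < 0 or s >= e:
                    raise DataError(f"{path}:{lineno}: invalid {tag} interval [{s},{e})")
            out.append((c1, s1, e1, c2, s2, e2))
    return out


# --------------------------------------------------------------------------
# bedGraph
# --------------------------------------------------------------------------

def write_bedgraph(path, values: np.ndarray, chrom: str = "genome") -> None:
    """Run-length-compressed bedGraph of a per-base vector (zero runs included)."""
    values = np.asarray(values)
    n = len(values)
    with open(path, "w") as fh:
        if n == 0:
            return
        breaks = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [n]))
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_score(float(values[s]))}\n")


def read_bedgraph(path, length: int | None = None) -> np.ndarray:
    """Re-expand a bedGraph to a per-base vector (single sequence)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(f"{path}:{lineno}: bedGraph needs 4 fields")
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            if start < 0 or start >= end:
                raise DataError(f"{path}:{lineno}: invalid interval [{start},{end})")
            rows.append((start, end, float(fields[3])))
    n = length if length is not None else (max(e for _, e, _ in rows) if rows else 0)
    out = np.zeros(n)
    for s, e, v in rows:
        out[s:e] = v
    return out


# --------------------------------------------------------------------------
# key=value config echo
# --------------------------------------------------------------------------

def write_flat_config(path, items: dict) -> None:
    with open(path, "w") as fh:
        for key, val in items.items():
            fh.write(f"{key}={val}\n")
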