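"""Readers and writers for the external formats the toolkit touches.

Supported formats: BED (3-6 columns), two-column chromosome-sizes TSV,
JASPAR-style position frequency matrices, FASTA (through pyfaidx), BAM
(through pysam) plus a plain-text alignment dialect, BED6-like gene tables,
and fixed-step wiggle export of signal tracks.

All parsers reject malformed records with an error naming the offending line
rather than silently repairing them.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .regions import Region, RegionSet

__all__ = [
    "ChromTable",
    "ReadRecord",
    "GeneSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_alignments",
    "write_alignments_text",
    "read_pfm",
    "write_pfm",
    "read_genes",
    "open_fasta",
    "write_fasta",
    "write_wiggle",
    "normalize_chrom_name",
]


class FormatError(ValueError):
    """A malformed record in an input file."""


class ChromTable(dict):
    """Ordered map chromosome name -> length in bp.

    Iteration order is insertion (input) order; lengths must be positive.
    """

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, length)

    @property
    def total_bp(self) -> int:
        return sum(self.values())

    def validate(self, regions: Iterable[Region]) -> None:
        """Raise if any region falls outside the table."""
        for r in regions:
            if r.chrom not in self:
                raise ValueError(f"unknown chromosome {r.chrom!r}")
            if r.end > self[r.chrom]:
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome "
                    f"length {self[r.chrom]}"
                )


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: chrom, [start, end), strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5' end coordinate (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


def normalize_chrom_name(name: str) -> str:
    """Opt-in helper mapping '1' -> 'chr1' etc.  Never applied automatically."""
    return name if name.startswith("chr") else f"chr{name}"


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | os.PathLike) -> ChromTable:
    table = ChromTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            name = parts[0]
            if name in table:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                table[name] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return table


def write_chrom_sizes(table: ChromTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in table.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> RegionSet:
    """Parse a 3-6 column BED file into a RegionSet (0-based half-open)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "" else "."
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "" else 0.0
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            strand = parts[5] if len(parts) > 5 and parts[5] != "" else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            regions.append(Region(parts[0], start, end, name, score, strand))
    rs = RegionSet(regions, name=os.path.basename(os.fspath(path)))
    return rs


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def write_bed(regions: RegionSet, path: str | os.PathLike, header: str | None = None) -> None:
    """Write a canonical 6-column BED file in stored order."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_fmt_score(r.score)}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# alignments: BAM via pysam, plus a first-class plain-text dialect
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | os.PathLike,
    region: Region | None = None,
) -> Iterator[ReadRecord]:
    """Stream mapped reads from a BAM file or the text alignment dialect.

    The text dialect is a TSV with columns chrom/start/end/strand ('#' lines
    are comments) and exists so that the statistical core is testable without
    binary fixtures.  BAM input skips unmapped, secondary and supplementary
    records; a region query against a BAM requires an index.
    """
    path = os.fspath(path)
    if path.endswith(".bam"):
        yield from _read_bam(path, region)
    else:
        yield from _read_text_alignments(path, region)


def _read_bam(path: str, region: Region | None) -> Iterator[ReadRecord]:
    import pysam

    with pysam.AlignmentFile(path, "rb") as bam:
        if region is not None:
            if not bam.has_index():
                raise FileNotFoundError(
                    f"{path}: region query requires a BAM index (.bai)"
                )
            it = bam.fetch(region.chrom, region.start, region.end)
        else:
            it = bam.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield ReadRecord(
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
            )


def _read_text_alignments(path: str, region: Region | None) -> Iterator[ReadRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                rec = ReadRecord(parts[0], int(parts[1]), int(parts[2]), parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if region is not None and not (
                rec.chrom == region.chrom
                and rec.start < region.end
                and region.start < rec.end
            ):
                continue
            yield rec


def write_alignments_text(
    reads: Iterable[ReadRecord], path: str | os.PathLike, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# JASPAR-style PFM
# ---------------------------------------------------------------------------

def read_pfm(path: str | os.PathLike) -> list:
    """Parse JASPAR-style PFM records into a list of Motif objects.

    Format: header line ``>ID name`` followed by four rows of non-negative
    counts (A, C, G, T order).  Rows may be bare numbers or JASPAR's
    ``A [ 1 2 3 ]`` style; both parse to the same counts.
    """
    from .motif import Motif

    motifs = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"{path}:{start_line}: motif {header[0]!r} has {len(rows)} "
                "count rows, expected 4 (A,C,G,T)"
            )
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise FormatError(
                f"{path}:{start_line}: motif {header[0]!r} has unequal row lengths"
            )
        counts = np.array(rows, dtype=float)
        if (counts < 0).any():
            raise FormatError(
                f"{path}:{start_line}: motif {header[0]!r} has negative counts"
            )
        motifs.append(Motif(id=header[0], name=header[1], counts=counts))
        header, rows = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split(None, 1)
                header = (fields[0], fields[1] if len(fields) > 1 else fields[0])
                start_line = lineno
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: counts before any header")
                cleaned = line
                for ch in "ACGTacgt[]":
                    cleaned = cleaned.replace(ch, " ")
                try:
                    row = [float(x) for x in cleaned.split()]
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric count") from None
                rows.append(row)
        flush(lineno)
    return motifs


def write_pfm(motifs: Iterable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.id} {m.name}\n")
            for row in m.counts:
                fh.write(" ".join(_fmt_score(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

class GeneSet(RegionSet):
    """Gene bodies as stranded regions; region name is the gene identifier."""

    def gene(self, gene_id: str) -> Region:
        for r in self.regions:
            if r.name == gene_id:
                return r
        raise KeyError(gene_id)

    def ids(self) -> list[str]:
        return [r.name for r in self.regions]


def read_genes(path: str | os.PathLike) -> GeneSet:
    """Read BED6-like gene records (name = gene ID, strand required).

    Duplicate gene IDs keep the longest body and emit a warning; strand is
    mandatory because promoter windows are strand-dependent.
    """
    raw = read_bed(path)
    by_id: dict[str, Region] = {}
    order: list[str] = []
    for r in raw:
        if r.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {r.name!r} lacks a strand (promoters are "
                "strand-dependent)"
            )
        if r.name in by_id:
            warnings.warn(
                f"duplicate gene id {r.name!r}: keeping the longest body",
                stacklevel=2,
            )
            if len(r) <= len(by_id[r.name]):
                continue
        else:
            order.append(r.name)
        by_id[r.name] = r
    return GeneSet([by_id[g] for g in order], name=raw.name)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def open_fasta(path: str | os.PathLike):
    """Open an indexed FASTA for random access (builds .fai on demand)."""
    from pyfaidx import Fasta

    return Fasta(os.fspath(path), sequence_always_upper=True)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# wiggle export
# ---------------------------------------------------------------------------

def write_wiggle(tracks: Sequence, path: str | os.PathLike, name: str = "rkit") -> None:
    """Export signal tracks as fixed-step wiggle (1-based per wiggle spec)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for t in tracks:
            fh.write(
                f"fixedStep chrom={t.region.chrom} start={t.region.start + 1} "
                f"step={t.step_size} span={t.bin_size}\n"
            )
            for v in t.values:
                fh.write(f"{_fmt_score(float(v))}\n")
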