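"""Synthetic data generation: random genomes, planted motifs, planted read
enrichment, and paired region sets with controlled overlap.

Every generator is deterministic given the spec's seed and writes real files
(FASTA, the text alignment dialect, BED), so the full I/O and CLI surface is
exercised end-to-end without any external download.  The simulation model is
deliberately simple: i.i.d. genome bases at a target GC, uniform Poisson
fragment sampling with per-peak rate multipliers, fixed fragment length and
a fixed 50 bp read taken from the fragment's 5' end on a random strand.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ChromTable, ReadRecord, write_alignments_text, write_fasta
from .motif import Motif
from .regions import Region, RegionSet

__all__ = [
    "FixtureSpec",
    "make_genome",
    "make_reads",
    "make_region_pair",
    "consensus_motif",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic dataset.

    planted_peaks: (region, fold) pairs — fragment rate inside the region is
    multiplied by ``fold`` (>= 1).
    planted_motifs: (motif, loci) pairs with loci as (chrom, position,
    strand); the motif consensus overwrites the genome there.
    read_depth: expected background fragments per bp (so a 1 Mb genome at
    1e-2 carries ~10k background fragments).
    """

    seed: int = 0
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 100_000)])
    gc: float = 0.5
    planted_peaks: list[tuple[Region, float]] = field(default_factory=list)
    planted_motifs: list[tuple[Motif, list[tuple[str, int, str]]]] = field(
        default_factory=list
    )
    read_depth: float = 0.01
    fragment_length: int = 200
    read_length: int = 50

    def __post_init__(self) -> None:
        sizes = dict(self.genome)
        for region, fold in self.planted_peaks:
            if fold < 1:
                raise ValueError("peak fold must be >= 1")
            if region.end > sizes.get(region.chrom, 0):
                raise ValueError(f"planted peak {region} outside the genome")
        for motif, loci in self.planted_motifs:
            for chrom, pos, strand in loci:
                if pos + len(motif) > sizes.get(chrom, 0) or pos < 0:
                    raise ValueError(f"planted motif locus {chrom}:{pos} out of bounds")

    @property
    def chrom_table(self) -> ChromTable:
        t = ChromTable()
        for name, length in self.genome:
            t[name] = length
        return t

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FixtureSpec":
        """Load a spec from JSON (peaks as [chrom,start,end,fold]; motifs as
        {consensus, loci: [[chrom,pos,strand],...]})."""
        with open(path) as fh:
            d = json.load(fh)
        peaks = [
            (Region(c, s, e), float(fold))
            for c, s, e, fold in d.get("planted_peaks", [])
        ]
        motifs = []
        for i, m in enumerate(d.get("planted_motifs", []), 1):
            motif = consensus_motif(m["consensus"], motif_id=m.get("id", f"M{i}"))
            motifs.append((motif, [tuple(l) for l in m["loci"]]))
        return cls(
            seed=int(d.get("seed", 0)),
            genome=[tuple(g) for g in d["genome"]],
            gc=float(d.get("gc", 0.5)),
            planted_peaks=peaks,
            planted_motifs=motifs,
            read_depth=float(d.get("read_depth", 0.01)),
            fragment_length=int(d.get("fragment_length", 200)),
            read_length=int(d.get("read_length", 50)),
        )


def consensus_motif(consensus: str, weight: float = 100.0, motif_id: str = "M1") -> Motif:
    """A near-deterministic motif whose PFM puts ``weight`` counts on the
    consensus base per column and 0 elsewhere."""
    from .motif import BASES

    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus.upper()):
        counts[BASES.index(base), j] = weight
    return Motif(id=motif_id, name=motif_id, counts=counts)


def make_genome(spec: FixtureSpec, path: str | os.PathLike | None = None) -> dict[str, str]:
    """Random i.i.d. genome at the spec's GC, with planted motif consensi.

    Returns {chrom: sequence}; also writes FASTA when ``path`` is given.
    Minus-strand plants insert the reverse complement so forward-strand
    scanning finds them on "-".
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )  # A C G T
    seqs: dict[str, str] = {}
    for chrom, length in spec.genome:
        codes = rng.choice(4, size=length, p=p)
        seqs[chrom] = "".join("ACGT"[c] for c in codes)
    for motif, loci in spec.planted_motifs:
        word = motif.consensus
        for chrom, pos, strand in loci:
            insert = word if strand == "+" else revcomp(word)
            s = seqs[chrom]
            seqs[chrom] = s[:pos] + insert + s[pos + len(insert):]
    if path is not None:
        write_fasta(seqs, path)
    return seqs


def make_reads(
    spec: FixtureSpec, path: str | os.PathLike | None = None
) -> list[ReadRecord]:
    """Poisson fragment sampling with planted enrichment.

    Background fragment starts are uniform at rate ``read_depth`` per bp;
    within each planted peak, additional fragments at rate (fold-1) x depth.
    Each fragment gets a random strand and contributes the 5'-most
    ``read_length`` bp as its read.
    """
    rng = np.random.default_rng(spec.seed + 1)
    reads: list[ReadRecord] = []
    flen = spec.fragment_length

    def emit(chrom: str, clen: int, start: int) -> None:
        end = min(start + flen, clen)
        if end - start < spec.read_length:
            return
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            reads.append(ReadRecord(chrom, start, start + spec.read_length, "+"))
        else:
            reads.append(ReadRecord(chrom, end - spec.read_length, end, "-"))

    for chrom, clen in spec.genome:
        n_bg = rng.poisson(spec.read_depth * clen)
        for start in rng.integers(0, max(1, clen - flen + 1), size=n_bg):
            emit(chrom, clen, int(start))
        for region, fold in spec.planted_peaks:
            if region.chrom != chrom or fold <= 1:
                continue
            n_extra = rng.poisson((fold - 1) * spec.read_depth * len(region))
            lo = max(0, region.start - flen + 1)
            hi = max(lo + 1, region.end)
            for start in rng.integers(lo, hi, size=n_extra):
                emit(chrom, clen, int(start))
    reads.sort(key=lambda r: (r.chrom, r.start, r.end))
    if path is not None:
        write_alignments_text(reads, path)
    return reads


def make_region_pair(
    chrom_table: ChromTable,
    n: int,
    length: int,
    overlap_fraction: float,
    seed: int,
    max_attempts: int = 1000,
) -> tuple[RegionSet, RegionSet]:
    """(A, B) with an expected ``overlap_fraction`` of B's regions hitting A.

    A is uniform random; each B region is either a jittered copy of a random
    A region (guaranteed >=1 bp overlap) or rejection-sampled disjoint
    from A.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from .regions import random_regions

    a = random_regions(chrom_table, [length], n, rng)
    a_merged = a.merge()
    b_regions: list[Region] = []
    for _ in range(n):
        if rng.random() < overlap_fraction:
            src = a.regions[int(rng.integers(len(a)))]
            clen = chrom_table[src.chrom]
            for _attempt in range(max_attempts):
                jitter = int(rng.integers(-(length - 1), length))  # |shift| < length
                s = src.start + jitter
                e = s + length
                if 0 <= s and e <= clen:
                    b_regions.append(Region(src.chrom, s, e))
                    break
            else:
                raise RuntimeError("could not place an overlapping B region")
        else:
            extra = random_regions(
                chrom_table, [length], 1, rng, forbid=a_merged,
                max_attempts=max_attempts,
            )
            b_regions.append(extra.regions[0])
    return a, RegionSet(b_regions)
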