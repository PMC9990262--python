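"""Genomic regions and interval algebra.

A :class:`Region` is a single genomic interval in 0-based half-open (BED)
coordinates; a :class:`RegionSet` is an ordered collection of regions and the
operand of all set algebra and association statistics in this package.

Conventions
-----------
* All coordinates are 0-based half-open everywhere inside the package;
  conversion (if any) happens only at parse/serialize boundaries.
* "Overlap" means at least one shared base pair.  Abutting half-open
  intervals ([0,10) and [10,20)) do *not* overlap, but :meth:`RegionSet.merge`
  does fuse them, since they cover a contiguous base-pair set.
* Chromosomes are ordered lexicographically (``chr10 < chr2``) for
  determinism; :func:`natural_chrom_key` is available for callers that want
  human ordering, but it is never the default.
* Strand is ignored by the algebra except where an explicit ``strand_aware``
  flag exists (:meth:`RegionSet.extend`).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Region",
    "RegionSet",
    "random_regions",
    "natural_chrom_key",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Region:
    """One genomic interval: chrom, [start, end), name, score, strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Region") -> bool:
        """>=1 shared bp on the same chromosome (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def natural_chrom_key(name: str) -> tuple:
    """Sort key giving human chromosome order (chr2 < chr10). Opt-in only."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


class RegionSet:
    """Ordered collection of :class:`Region` with a sortedness flag.

    The container preserves insertion order until :meth:`sort` is called.
    All algebra operations return new sets and never mutate their operands.
    """

    def __init__(self, regions: Iterable[Region] = (), name: str = ""):
        self.regions: list[Region] = list(regions)
        self.name = name
        self.sorted_flag = self._check_sorted()

    def _check_sorted(self) -> bool:
        keys = [r.sort_key() for r in self.regions]
        return all(a <= b for a, b in zip(keys, keys[1:]))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({self.name!r}, n={len(self)})"

    def add(self, region: Region) -> None:
        self.regions.append(region)
        self.sorted_flag = False

    def lengths(self) -> list[int]:
        return [len(r) for r in self.regions]

    # -- algebra ------------------------------------------------------------
    def sort(self) -> "RegionSet":
        """Stable sort by (chrom lexicographic, start, end)."""
        out = RegionSet(sorted(self.regions, key=Region.sort_key), self.name)
        out.sorted_flag = True
        return out

    def merge(self) -> "RegionSet":
        """Minimal disjoint cover of the same bp set; touching intervals fuse."""
        merged: list[Region] = []
        for r in sorted(self.regions, key=Region.sort_key):
            if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
                last = merged[-1]
                if r.end > last.end:
                    merged[-1] = Region(last.chrom, last.start, r.end)
            else:
                merged.append(Region(r.chrom, r.start, r.end))
        out = RegionSet(merged, self.name)
        out.sorted_flag = True
        return out

    def _merged_index(self) -> dict[str, tuple[list[int], list[int]]]:
        """chrom -> (sorted starts, matching ends) of the merged set."""
        index: dict[str, tuple[list[int], list[int]]] = {}
        for r in self.merge():
            starts, ends = index.setdefault(r.chrom, ([], []))
            starts.append(r.start)
            ends.append(r.end)
        return index

    def intersect(self, other: "RegionSet", mode: str = "overlap"):
        """Intersection with ``other``.

        mode="overlap"  -> fragment-level intersections of the two merged sets
        mode="original" -> regions of *self* (original coordinates) with >=1 bp
                           overlap with ``other``
        mode="count"    -> number of such regions
        """
        if mode == "overlap":
            out: list[Region] = []
            b_by_chrom: dict[str, list[Region]] = {}
            for r in other.merge():
                b_by_chrom.setdefault(r.chrom, []).append(r)
            for a in self.merge():
                for b in b_by_chrom.get(a.chrom, ()):
                    if b.start >= a.end:
                        break
                    s, e = max(a.start, b.start), min(a.end, b.end)
                    if s < e:
                        out.append(Region(a.chrom, s, e))
            return RegionSet(out).sort()
        if mode in ("original", "count"):
            index = other._merged_index()
            hits = [r for r in self.regions if _hits_index(r, index)]
            if mode == "count":
                return len(hits)
            return RegionSet(hits, self.name)
        raise ValueError(f"unknown intersect mode {mode!r}")

    def union(self, other: "RegionSet") -> "RegionSet":
        """bp-set union, returned merged."""
        return RegionSet(list(self.regions) + list(other.regions)).merge()

    def subtract(self, other: "RegionSet") -> "RegionSet":
        """bp-set difference self \\ other, returned merged."""
        b_index = other._merged_index()
        out: list[Region] = []
        for a in self.merge():
            cur = a.start
            starts, ends = b_index.get(a.chrom, ([], []))
            for s, e in zip(starts, ends):
                if e <= cur:
                    continue
                if s >= a.end:
                    break
                if s > cur:
                    out.append(Region(a.chrom, cur, min(s, a.end)))
                cur = max(cur, e)
                if cur >= a.end:
                    break
            if cur < a.end:
                out.append(Region(a.chrom, cur, a.end))
        res = RegionSet(out)
        res.sorted_flag = True
        return res

    def extend(
        self,
        left: int,
        right: int,
        center_mode: str = "none",
        chrom_table: Mapping[str, int] | None = None,
        strand_aware: bool = False,
    ) -> "RegionSet":
        """Extend every region by ``left``/``right`` bp.

        center_mode="midpoint" first collapses each region to a zero-width
        anchor at its midpoint (floor((start+end)/2)), so the result is
        [mid-left, mid+right) and a symmetric window has width exactly
        left+right.  Minus-strand regions swap left/right when
        ``strand_aware``.  Coordinates are clipped to [0, chrom length] when
        a chrom_table is supplied, else only at 0.  Regions that collapse to
        nothing (zero-width anchor with zero extension) are dropped.
        """
        if left < 0 or right < 0:
            raise ValueError("left/right extensions must be >= 0")
        if center_mode not in ("none", "midpoint"):
            raise ValueError(f"unknown center_mode {center_mode!r}")
        out = []
        for r in self.regions:
            lo, hi = (left, right)
            if strand_aware and r.strand == "-":
                lo, hi = right, left
            if center_mode == "midpoint":
                s = e = r.midpoint
            else:
                s, e = r.start, r.end
            s, e = s - lo, e + hi
            s = max(0, s)
            if chrom_table is not None and r.chrom in chrom_table:
                e = min(e, chrom_table[r.chrom])
            if s < e:
                out.append(replace(r, start=s, end=e))
        return RegionSet(out, self.name)

    def total_bp(self) -> int:
        """Number of distinct base pairs covered (after merging)."""
        return sum(len(r) for r in self.merge())


def _hits_index(r: Region, index: dict[str, tuple[list[int], list[int]]]) -> bool:
    entry = index.get(r.chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = bisect_right(starts, r.start)
    # candidate intervals: the one starting at/before r.start, and the next one
    if i > 0 and ends[i - 1] > r.start:
        return True
    return i < len(starts) and starts[i] < r.end


def random_regions(
    chrom_table: Mapping[str, int],
    lengths: Sequence[int],
    n: int,
    seed: int | np.random.Generator,
    forbid: RegionSet | None = None,
    max_attempts: int = 1000,
) -> RegionSet:
    """Draw ``n`` random regions, chromosome chosen proportional to length.

    Lengths are drawn with replacement from ``lengths``; the start is uniform
    in [0, chrom_len - L].  Regions overlapping ``forbid`` are rejected and
    redrawn (up to ``max_attempts`` per region).  Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(chrom_table.keys())
    sizes = np.array([chrom_table[c] for c in chroms], dtype=float)
    if n > 0 and (not chroms or not lengths):
        raise ValueError("need at least one chromosome and one length")
    if lengths and max(lengths) > max(chrom_table.values(), default=0):
        raise ValueError("a requested length exceeds every chromosome")
    probs = sizes / sizes.sum() if len(sizes) else sizes
    forbid_index = forbid._merged_index() if forbid is not None else None
    out: list[Region] = []
    lengths = list(lengths)
    for _ in range(n):
        for _attempt in range(max_attempts):
            ci = int(rng.choice(len(chroms), p=probs))
            L = int(lengths[int(rng.integers(len(lengths)))])
            clen = int(sizes[ci])
            if L > clen:
                continue
            start = int(rng.integers(0, clen - L + 1))
            cand = Region(chroms[ci], start, start + L)
            if forbid_index is not None and _hits_index(cand, forbid_index):
                continue
            out.append(cand)
            break
        else:
            raise RuntimeError(
                f"random_regions: rejection budget ({max_attempts}) exhausted"
            )
    return RegionSet(out)
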