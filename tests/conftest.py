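"""Shared fixtures and independent oracles for the test suite.

The bitmap oracle represents a region set as one boolean array per
chromosome (True = covered bp) and implements the interval algebra by
element-wise boolean logic — an implementation completely independent of the
sorted-sweep code under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from rkit.io import ChromTable
from rkit.regions import Region, RegionSet


# ---------------------------------------------------------------------------
# per-basepair bitmap oracle
# ---------------------------------------------------------------------------

def to_bitmap(rs: RegionSet, chrom_table: ChromTable) -> dict[str, np.ndarray]:
    maps = {c: np.zeros(L, dtype=bool) for c, L in chrom_table.items()}
    for r in rs:
        maps[r.chrom][r.start : r.end] = True
    return maps


def bitmap_to_regions(maps: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    """Maximal runs of True per chromosome, as (chrom, start, end)."""
    out = []
    for chrom in sorted(maps):
        m = maps[chrom]
        padded = np.concatenate([[False], m, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def regions_as_tuples(rs: RegionSet) -> list[tuple[str, int, int]]:
    return [(r.chrom, r.start, r.end) for r in rs]


def pairwise_overlap_count(a: RegionSet, b: RegionSet) -> int:
    """O(n*m) all-pairs oracle for intersect(mode='count')."""
    return sum(1 for ra in a if any(ra.overlaps(rb) for rb in b))


def random_region_set(
    rng: np.random.Generator,
    chrom_table: ChromTable,
    n_max: int = 200,
    allow_empty: bool = True,
) -> RegionSet:
    n = int(rng.integers(0 if allow_empty else 1, n_max + 1))
    regions = []
    for _ in range(n):
        chrom = list(chrom_table)[int(rng.integers(len(chrom_table)))]
        L = chrom_table[chrom]
        start = int(rng.integers(0, L))
        end = int(rng.integers(start + 1, min(L, start + max(2, L // 10)) + 1))
        regions.append(Region(chrom, start, end))
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_genome() -> ChromTable:
    t = ChromTable()
    t["chr1"] = 1000
    t["chr2"] = 600
    return t


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
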