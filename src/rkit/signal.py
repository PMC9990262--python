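"""Read-derived genomic signal: binned coverage, preprocessing, peak calling.

A :class:`SignalTrack` holds one real value per bin window
``[start + i*step, start + i*step + bin)`` over a region.  Coverage counts an
extended read in every bin it overlaps by at least one base pair — the same
>=1 bp rule the interval algebra uses.

Preprocessing utilities implement the standard constructions used in ChIP-seq
pipelines: fragment-size estimation by strand cross-correlation, centered
moving-average smoothing, counts-per-million library scaling, scaled
input-DNA subtraction floored at zero, and GC-stratum mean-ratio correction.
A deliberately minimal Poisson peak caller (single global background rate)
rounds out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ChromTable, ReadRecord
from .regions import Region, RegionSet

__all__ = [
    "SignalTrack",
    "LibraryStats",
    "estimate_fragment_size",
    "coverage",
    "smooth",
    "normalize_library",
    "normalize_input",
    "correct_gc",
    "call_peaks_demo",
]


def n_bins(width: int, bin_size: int, step_size: int) -> int:
    """Number of bin windows over a region of ``width`` bp."""
    if width < bin_size:
        return 1
    return (width - bin_size) // step_size + 1


@dataclass
class SignalTrack:
    """Binned signal over one region: values[i] covers
    [region.start + i*step, region.start + i*step + bin)."""

    region: Region
    bin_size: int
    step_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_bins(len(self.region), self.bin_size, self.step_size)
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} bins for width {len(self.region)}, "
                f"got {len(self.values)}"
            )

    def bin_window(self, i: int) -> tuple[int, int]:
        s = self.region.start + i * self.step_size
        return s, s + self.bin_size

    def copy_with(self, values: np.ndarray) -> "SignalTrack":
        return SignalTrack(self.region, self.bin_size, self.step_size, values)


@dataclass
class LibraryStats:
    """Per-library bookkeeping used by normalization."""

    total_reads: int
    estimated_fragment: int = 0

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.estimated_fragment < 0:
            raise ValueError("library statistics must be non-negative")


def _extended_interval(read: ReadRecord, extension: int) -> tuple[int, int]:
    """Replace a read by [5'end, 5'end+extension) on its strand; 0 keeps it."""
    if extension == 0:
        return read.start, read.end
    if read.strand == "+":
        return read.start, read.start + extension
    return max(0, read.end - extension), read.end


def _reads_by_chrom(
    reads: Iterable[ReadRecord], extension: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (sorted starts, sorted ends) of extended read intervals."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        buckets.setdefault(r.chrom, []).append(_extended_interval(r, extension))
    out = {}
    for chrom, ivs in buckets.items():
        arr = np.array(ivs, dtype=np.int64)
        out[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    return out


def coverage(
    reads: Iterable[ReadRecord],
    regions: RegionSet | Sequence[Region],
    bin_size: int,
    step_size: int,
    extension: int = 0,
) -> list[SignalTrack]:
    """Count extended reads overlapping each bin window of each region.

    An interval [s, e) overlaps window [ws, we) iff s < we and e > ws, so the
    bin value is #(starts < we) - #(ends <= ws) on the sorted endpoint arrays.
    """
    if bin_size < 1 or not (1 <= step_size <= bin_size):
        raise ValueError("need bin_size >= 1 and 1 <= step_size <= bin_size")
    if extension < 0:
        raise ValueError("extension must be >= 0")
    index = _reads_by_chrom(reads, extension)
    tracks = []
    for region in regions:
        k = n_bins(len(region), bin_size, step_size)
        ws = region.start + step_size * np.arange(k, dtype=np.int64)
        we = ws + bin_size
        entry = index.get(region.chrom)
        if entry is None:
            vals = np.zeros(k)
        else:
            starts, ends = entry
            vals = (
                np.searchsorted(starts, we, side="left")
                - np.searchsorted(ends, ws, side="right")
            ).astype(float)
        tracks.append(SignalTrack(region, bin_size, step_size, vals))
    return tracks


def estimate_fragment_size(
    reads: Iterable[ReadRecord],
    chrom_table: ChromTable,
    max_shift: int = 400,
    bin_size: int = 10,
) -> int:
    """Estimate the sequenced fragment length by strand cross-correlation.

    Builds 10 bp-binned 5'-end profiles per strand and returns the shift d
    (in bp, multiples of the bin size) maximizing the Pearson correlation
    between the plus profile and the minus profile shifted left by d.
    Ties break toward the smallest shift.
    """
    plus: dict[str, np.ndarray] = {}
    minus: dict[str, np.ndarray] = {}
    for c, L in chrom_table.items():
        nb = L // bin_size + 1
        plus[c] = np.zeros(nb)
        minus[c] = np.zeros(nb)
    n_plus = n_minus = 0
    for r in reads:
        if r.chrom not in plus:
            continue
        b = min(r.five_prime // bin_size, len(plus[r.chrom]) - 1)
        if r.strand == "+":
            plus[r.chrom][b] += 1
            n_plus += 1
        else:
            minus[r.chrom][b] += 1
            n_minus += 1
    if n_plus == 0 or n_minus == 0:
        raise ValueError("fragment-size estimation needs reads on both strands")
    best_shift, best_corr = 0, -np.inf
    for s in range(0, max_shift // bin_size + 1):
        xs, ys = [], []
        for c in plus:
            p, m = plus[c], minus[c]
            if s >= len(p):
                continue
            xs.append(p[: len(p) - s] if s else p)
            ys.append(m[s:])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.std() == 0 or y.std() == 0:
            continue
        corr = float(np.corrcoef(x, y)[0, 1])
        if corr > best_corr:
            best_shift, best_corr = s, corr
    return best_shift * bin_size


def smooth(track: SignalTrack, window_bins: int) -> SignalTrack:
    """Centered moving average; edges use truncated windows; window 1 = identity."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 1")
    if window_bins == 1:
        return track.copy_with(track.values.copy())
    h = window_bins // 2
    v = track.values
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return track.copy_with(out)


def normalize_library(
    tracks: Sequence[SignalTrack], stats_: LibraryStats, target: float = 1e6
) -> list[SignalTrack]:
    """Scale values by target/total_reads (CPM at the default target)."""
    if stats_.total_reads <= 0:
        raise ValueError("cannot normalize an empty library")
    factor = target / stats_.total_reads
    return [t.copy_with(t.values * factor) for t in tracks]


def normalize_input(
    treat: SignalTrack,
    control: SignalTrack,
    treat_total: int,
    control_total: int,
) -> SignalTrack:
    """Input-DNA correction: max(0, treat - control * treat_total/control_total)."""
    if control_total <= 0:
        raise ValueError("control library is empty")
    scaled = control.values * (treat_total / control_total)
    return treat.copy_with(np.maximum(0.0, treat.values - scaled))


def _gc_fraction(seq: str) -> float:
    """GC over non-N bases; NaN when the window is all N."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def correct_gc(track: SignalTrack, genome_fasta, n_strata: int = 10) -> SignalTrack:
    """Rescale bins so GC-content strata share the global mean signal.

    Bins are grouped into GC-fraction deciles (quantile strata over the
    track's own bins); each value is multiplied by global_mean/stratum_mean.
    Strata with zero mean, and all-N bins, are left unscaled.
    """
    v = track.values
    gc = np.empty(len(v))
    chrom = track.region.chrom
    for i in range(len(v)):
        s, e = track.bin_window(i)
        gc[i] = _gc_fraction(str(genome_fasta[chrom][s:e]))
    out = v.astype(float).copy()
    ok = ~np.isnan(gc)
    if not ok.any():
        return track.copy_with(out)
    edges = np.quantile(gc[ok], np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    strata = np.digitize(gc[ok], edges[1:-1], right=True)
    global_mean = v[ok].mean()
    for s_id in np.unique(strata):
        mask = np.where(ok)[0][strata == s_id]
        m = v[mask].mean()
        if m > 0:
            out[mask] = v[mask] * (global_mean / m)
    return track.copy_with(out)


def call_peaks_demo(
    reads: Sequence[ReadRecord],
    chrom_table: ChromTable,
    bin_size: int = 100,
    extension: int = 200,
    alpha: float = 1e-5,
) -> RegionSet:
    """Minimal Poisson peak caller over genome-wide non-overlapping bins.

    One global background rate lambda = mean bin count; a bin is significant
    when the upper-tail Poisson p-value P(X >= k) is below ``alpha``;
    adjacent significant bins merge into one peak scored -log10(min p).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("peak calling needs at least one read")
    chrom_regions = [Region(c, 0, L) for c, L in chrom_table.items()]
    tracks = coverage(reads, chrom_regions, bin_size, bin_size, extension)
    lam = float(np.mean(np.concatenate([t.values for t in tracks])))
    peaks: list[Region] = []
    for t in tracks:
        counts = t.values
        pvals = stats.poisson.sf(counts - 1, lam)  # P(X >= k)
        sig = pvals < alpha
        i = 0
        while i < len(sig):
            if sig[i]:
                j = i
                while j + 1 < len(sig) and sig[j + 1]:
                    j += 1
                s, _ = t.bin_window(i)
                _, e = t.bin_window(j)
                e = min(e, t.region.end)
                minp = float(pvals[i : j + 1].min())
                score = 350.0 if minp == 0 else -np.log10(minp)
                peaks.append(
                    Region(t.region.chrom, s, e, f"peak_{len(peaks) + 1}", score)
                )
                i = j + 1
            else:
                i += 1
    out = RegionSet(peaks, name="peaks")
    out.sorted_flag = True
    return out
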