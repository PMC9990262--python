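"""Signal aggregation over region sets: the data behind boxplots, line plots
and heatmaps.

``region_counts`` tallies reads per region per library (boxplot input);
``profile_matrix`` stacks binned coverage over windows centered on region
midpoints (lineplot/heatmap input).  Bin offsets are reported relative to the
region center so matrices from different window sizes align.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ReadRecord
from .regions import Region, RegionSet
from .signal import SignalTrack, coverage, n_bins

__all__ = [
    "ProfileMatrix",
    "region_counts",
    "profile_matrix",
    "mean_profile",
    "export_matrix",
    "read_matrix",
    "plot_lineplot",
    "plot_heatmap",
    "plot_boxplot",
]


@dataclass
class ProfileMatrix:
    """n_regions x n_bins signal matrix over midpoint-centered windows."""

    matrix: np.ndarray
    window: int
    bin_size: int
    step_size: int
    region_ids: list[str]
    library_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        expected = n_bins(2 * self.window, self.bin_size, self.step_size)
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"expected {expected} bins for window {self.window}, "
                f"got {self.matrix.shape[1]}"
            )
        if self.matrix.shape[0] != len(self.region_ids):
            raise ValueError("region_ids length must match the number of rows")

    @property
    def offsets(self) -> np.ndarray:
        """Bin-midpoint offsets relative to the region center (center = 0)."""
        starts = -self.window + self.step_size * np.arange(self.matrix.shape[1])
        return starts + self.bin_size / 2.0


def region_counts(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    regions: RegionSet,
    extension: int = 0,
    normalize: bool = False,
) -> pd.DataFrame:
    """Reads overlapping each region, per library (>=1 bp rule).

    Rows are libraries, columns are regions.  With ``normalize``, counts are
    scaled to counts-per-million by each library's total read count.
    """
    if not reads_by_library:
        raise ValueError("need at least one library")
    cols = [r.name if r.name != "." else f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    rows = {}
    for lib, reads in reads_by_library.items():
        reads = list(reads)
        counts = np.array(
            [
                _count_overlapping(reads, region, extension)
                for region in regions
            ],
            dtype=float,
        )
        if normalize:
            if not reads:
                raise ValueError(f"library {lib!r} is empty, cannot normalize")
            counts = counts * 1e6 / len(reads)
        rows[lib] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _count_overlapping(
    reads: Sequence[ReadRecord], region: Region, extension: int
) -> int:
    track = coverage(reads, [Region(region.chrom, region.start, region.end)],
                     bin_size=len(region), step_size=len(region),
                     extension=extension)[0]
    return int(track.values[0])


def profile_matrix(
    reads: Sequence[ReadRecord],
    regions: RegionSet,
    window: int,
    bin_size: int,
    step_size: int,
    extension: int = 0,
    strand_aware: bool = False,
    library_id: str = "",
) -> ProfileMatrix:
    """Stack binned coverage over +/-window around each region's midpoint.

    Row i is the coverage of region i's window; with ``strand_aware``, rows
    of minus-strand regions are reversed so that 5'->3' reads left to right.
    """
    if window < bin_size:
        raise ValueError("window must be >= bin_size")
    windows = regions.extend(window, window, center_mode="midpoint")
    tracks = coverage(list(reads), windows, bin_size, step_size, extension)
    mat = np.vstack([t.values for t in tracks]) if len(tracks) else np.zeros((0, n_bins(2 * window, bin_size, step_size)))
    ids = []
    for i, r in enumerate(regions):
        ids.append(r.name if r.name != "." else f"{r.chrom}:{r.start}-{r.end}")
        if strand_aware and r.strand == "-":
            mat[i] = mat[i][::-1]
    return ProfileMatrix(mat, window, bin_size, step_size, ids, library_id)


def mean_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column means: the average signal profile across regions."""
    return matrix.matrix.mean(axis=0)


def export_matrix(matrix: ProfileMatrix, path: str | os.PathLike) -> None:
    """Write the matrix as TSV; header = bin-midpoint offsets from center."""
    df = pd.DataFrame(
        matrix.matrix,
        index=matrix.region_ids,
        columns=[f"{o:g}" for o in matrix.offsets],
    )
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def read_matrix(
    path: str | os.PathLike, window: int, bin_size: int, step_size: int
) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileMatrix(
        df.to_numpy(dtype=float), window, bin_size, step_size, list(df.index)
    )


def _use_agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_lineplot(matrix: ProfileMatrix, path: str | os.PathLike) -> None:
    """Mean profile with a +/-1 SE band."""
    plt = _use_agg()
    mean = mean_profile(matrix)
    n = max(1, matrix.matrix.shape[0])
    se = matrix.matrix.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(matrix.offsets, mean, lw=1.5)
    ax.fill_between(matrix.offsets, mean - se, mean + se, alpha=0.3)
    ax.set_xlabel("distance from region center (bp)")
    ax.set_ylabel("mean signal")
    if matrix.library_id:
        ax.set_title(matrix.library_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(matrix: ProfileMatrix, path: str | os.PathLike) -> None:
    """Per-region heatmap, rows ordered by total signal descending."""
    plt = _use_agg()
    order = np.argsort(-matrix.matrix.sum(axis=1), kind="stable")
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(
        matrix.matrix[order],
        aspect="auto",
        interpolation="nearest",
        extent=[matrix.offsets[0], matrix.offsets[-1], matrix.matrix.shape[0], 0],
    )
    fig.colorbar(im, ax=ax, label="signal")
    ax.set_xlabel("distance from region center (bp)")
    ax.set_ylabel("regions (by total signal)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_boxplot(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Boxplot of per-region counts, one box per library."""
    plt = _use_agg()
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(counts.index), 3.5))
    ax.boxplot([counts.loc[lib].to_numpy() for lib in counts.index],
               tick_labels=list(counts.index))
    ax.set_ylabel("reads per region")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
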