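"""Morphology analysis of dried-in patterns.

The 3D final state is projected onto a 2D height map (particle cells per
column), mirroring what an AFM scan of the dried deposit measures.  Grains
are connected components of the occupied projection, holes of the
unoccupied one; the two use complementary connectivities (grains
8-connected => holes 4-connected) so that grain and hole boundaries are
consistent under digital topology.  Hole-size histograms over log-spaced
bins expose dual-scale (cellular-network) patterns as two occupied size
ranges separated by a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .lattice import CellKind, LatticeState

__all__ = [
    "HeightMap",
    "GrainTable",
    "HoleHistogram",
    "project_height",
    "label_components",
    "label_grains",
    "hole_histogram",
    "detect_dual_scale",
    "log_bins",
]


@dataclass
class HeightMap:
    """2D map of particle cells per lattice column.

    ``cell_size`` is the physical edge length of one lattice cell in nm,
    used only to report physical areas; the simulation itself is
    dimensionless.
    """

    grid: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("height map must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("heights must be non-negative")

    @property
    def occupied(self) -> np.ndarray:
        return self.grid > 0

    # --- plain-text / image round trips -------------------------------
    def to_text(self, path) -> None:
        np.savetxt(path, self.grid, fmt="%d")

    @classmethod
    def from_text(cls, path, cell_size: float = 1.0) -> "HeightMap":
        return cls(np.loadtxt(path, dtype=np.int64, ndmin=2), cell_size)

    def to_pgm(self, path) -> None:
        """Write a binary (P5) 8-bit grayscale PGM; heights must be <= 255."""
        from PIL import Image

        if self.grid.max(initial=0) > 255:
            raise ValueError("PGM export supports heights <= 255 only")
        Image.fromarray(self.grid.astype(np.uint8), mode="L").save(
            path, format="PPM"
        )

    @classmethod
    def from_pgm(cls, path, cell_size: float = 1.0) -> "HeightMap":
        """Read an 8- or 16-bit grayscale PGM; values are heights."""
        from PIL import Image

        arr = np.asarray(Image.open(path)).astype(np.int64)
        return cls(arr, cell_size)

    @classmethod
    def from_snapshot(cls, path, cell_size: float = 1.0) -> "HeightMap":
        from .lattice import load_snapshot

        return project_height(load_snapshot(path), cell_size)


def project_height(state: LatticeState, cell_size: float = 1.0) -> HeightMap:
    """Column-wise particle counts; the sum equals the particle count."""
    counts = np.count_nonzero(
        state.grid[:, :, 1:] == CellKind.PARTICLE, axis=2
    ).astype(np.int64)
    return HeightMap(counts, cell_size)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(
    mask: np.ndarray,
    connectivity: int = 8,
    periodic: bool = False,
) -> tuple[np.ndarray, int]:
    """Connected-component labels of a boolean mask.

    ``periodic=True`` identifies components across the lateral seams
    (toroidal wrap), matching the simulation's boundary conditions;
    ``periodic=False`` treats the map as a plain image (AFM frame).
    Returns (labels, n) with labels in 1..n like ``scipy.ndimage.label``.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if not periodic or n <= 1:
        return labels, int(n)

    # Union labels joined across the seams.  Checking every positive-direction
    # offset whose unwrapped target leaves the grid covers both edges and the
    # 8-connectivity corner wrap.
    if connectivity == 4:
        offsets = [(0, 1), (1, 0)]
    else:
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    n0, n1 = mask.shape
    parent = np.arange(n + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    boundary = set()
    for i in range(n0):
        boundary.add((i, 0))
        boundary.add((i, n1 - 1))
    for j in range(n1):
        boundary.add((0, j))
        boundary.add((n0 - 1, j))
    for (i, j) in boundary:
        if not mask[i, j]:
            continue
        for di, dj in offsets:
            ii, jj = i + di, j + dj
            if 0 <= ii < n0 and 0 <= jj < n1:
                continue  # in-grid adjacency already handled by label()
            ii %= n0
            jj %= n1
            if mask[ii, jj]:
                a, b = find(labels[i, j]), find(labels[ii, jj])
                if a != b:
                    parent[max(a, b)] = min(a, b)

    roots = np.array([find(i) for i in range(n + 1)])
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], int(len(uniq))


@dataclass
class GrainTable:
    """Per-grain rows plus population summary statistics.

    ``table`` columns: grain_id, area_cells, area_nm2, centroid_x,
    centroid_y, max_height.  The summary's mean/std use the population
    (divide-by-n) convention.
    """

    table: pd.DataFrame
    cell_size: float = 1.0

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def summary(self) -> dict:
        areas = self.table["area_cells"].to_numpy(dtype=float)
        if len(areas) == 0:
            s = {"count": 0, "min_area": 0.0, "max_area": 0.0,
                 "mean_area": 0.0, "std_area": 0.0}
        else:
            s = {
                "count": int(len(areas)),
                "min_area": float(areas.min()),
                "max_area": float(areas.max()),
                "mean_area": float(areas.mean()),
                "std_area": float(areas.std(ddof=0)),
            }
        scale = self.cell_size**2
        s.update(
            {
                "min_area_nm2": s["min_area"] * scale,
                "max_area_nm2": s["max_area"] * scale,
                "mean_area_nm2": s["mean_area"] * scale,
                "std_area_nm2": s["std_area"] * scale,
            }
        )
        return s

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary_to_tsv(self, path) -> None:
        pd.DataFrame([self.summary]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def label_grains(
    hmap: HeightMap,
    min_area_cells: int = 0,
    connectivity: int = 8,
    periodic: bool = True,
    min_max_height: int = 0,
) -> GrainTable:
    """Label the occupied projection and tabulate grain statistics.

    Components smaller than ``min_area_cells`` are dropped before the
    statistics, emulating the minimum-size filtering applied to measured
    grain tables; ``min_max_height`` additionally drops grains whose tallest
    column is below the threshold.
    """
    if min_area_cells < 0:
        raise ValueError("min_area_cells must be >= 0")
    labels, n = label_components(hmap.occupied, connectivity, periodic)
    rows = []
    if n:
        areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        idx = np.arange(1, n + 1)
        max_h = ndimage.labeled_comprehension(
            hmap.grid, labels, idx, np.max, np.int64, 0
        )
        # Seam-spanning grains get the arithmetic mean of their raw
        # coordinates; a circular mean is not attempted.
        cyx = ndimage.center_of_mass(hmap.occupied, labels, idx)
        for gid, area, mh, (cx, cy) in zip(idx, areas, max_h, cyx):
            if area < min_area_cells or mh < min_max_height:
                continue
            rows.append(
                {
                    "grain_id": int(gid),
                    "area_cells": int(area),
                    "area_nm2": float(area) * hmap.cell_size**2,
                    "centroid_x": float(cx),
                    "centroid_y": float(cy),
                    "max_height": int(mh),
                }
            )
    cols = ["grain_id", "area_cells", "area_nm2",
            "centroid_x", "centroid_y", "max_height"]
    return GrainTable(pd.DataFrame(rows, columns=cols), hmap.cell_size)


@dataclass
class HoleHistogram:
    """Total hole area per size bin, plus the empty-bin gaps between
    occupied bins (the signature of a dual-scale pattern)."""

    bin_edges: np.ndarray  # len B+1, strictly increasing
    total_area: np.ndarray  # len B
    hole_areas: np.ndarray = field(default_factory=lambda: np.array([]))
    cell_size: float = 1.0

    @property
    def gap_ranges(self) -> list[tuple[float, float]]:
        """Maximal runs of empty bins strictly between occupied bins,
        as (low_edge, high_edge) intervals."""
        occ = np.nonzero(self.total_area > 0)[0]
        if len(occ) < 2:
            return []
        gaps = []
        for a, b in zip(occ[:-1], occ[1:]):
            if b - a > 1:
                gaps.append(
                    (float(self.bin_edges[a + 1]), float(self.bin_edges[b]))
                )
        return gaps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "total_area": self.total_area,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def log_bins(max_area: float, n_bins: int = 12) -> np.ndarray:
    """Log-spaced bin edges [1, max_area]; hole areas span orders of
    magnitude in cellular patterns."""
    return np.geomspace(1.0, float(max_area) + 1.0, n_bins + 1)


def hole_histogram(
    hmap: HeightMap,
    bin_edges: Optional[Sequence[float]] = None,
    connectivity: int = 8,
    periodic: bool = True,
) -> HoleHistogram:
    """Histogram of total hole area by hole size.

    ``connectivity`` is the grain convention; holes are labeled with the
    complementary one (8 -> 4 and 4 -> 8).  Each hole contributes its full
    area to the bin its size falls in (bins are [low, high)); holes outside
    the binned range are ignored.
    """
    hole_conn = 4 if connectivity == 8 else 8
    labels, n = label_components(~hmap.occupied, hole_conn, periodic)
    areas = (
        np.bincount(labels.ravel(), minlength=n + 1)[1:]
        if n
        else np.array([], dtype=np.int64)
    )
    if bin_edges is None:
        top = areas.max() if len(areas) else hmap.grid.size
        bin_edges = log_bins(top)
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    totals = np.zeros(len(edges) - 1)
    which = np.searchsorted(edges, areas, side="right") - 1
    for a, b in zip(areas, which):
        if 0 <= b < len(totals) and a < edges[b + 1]:
            totals[b] += a
    return HoleHistogram(edges, totals, np.sort(areas), hmap.cell_size)


def detect_dual_scale(hist: HoleHistogram, min_fraction: float = 0.05) -> bool:
    """True iff some empty-bin gap separates two occupied groups that each
    carry at least ``min_fraction`` of the total hole area."""
    total = hist.total_area.sum()
    if total <= 0:
        return False
    edges = hist.bin_edges
    for low, high in hist.gap_ranges:
        below = hist.total_area[edges[1:] <= low].sum()
        above = hist.total_area[edges[:-1] >= high].sum()
        if below >= min_fraction * total and above >= min_fraction * total:
            return True
    return False
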