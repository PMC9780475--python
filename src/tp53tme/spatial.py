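"""Spatial tumor-microenvironment analysis of imaging-mass-cytometry ROIs.

Each 1 mm^2 region of interest (ROI) is partitioned into a 20 x 20 grid of
400 numbered blocks (N1..N400, row-major from the origin corner); blocks
carry tumor / tumor-stromal boundary / stroma labels supplied by the mask
table.  Cell phenotype abundance is compared per region between patient
groups, and neighborhood composition is tallied for cells whose membranes
lie within a fixed margin (default 4 um) of a center cell: cells i and j
are neighbors iff

    dist(centroid_i, centroid_j) <= r_i + r_j + margin

which with zero radii degrades to a plain centroid-distance rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

REGIONS = ("tumor", "boundary", "stroma")


class SpatialError(ValueError):
    pass


@dataclass(frozen=True)
class GridPartition:
    """Equal-square tiling of one ROI; block indices are 1-based, row-major."""

    roi_side: float
    n_blocks: int

    def __post_init__(self) -> None:
        if self.roi_side <= 0:
            raise SpatialError(f"roi_side must be positive, got {self.roi_side}")
        k = math.isqrt(self.n_blocks)
        if k * k != self.n_blocks:
            raise SpatialError(f"n_blocks must be a perfect square, got {self.n_blocks}")

    @property
    def k(self) -> int:
        return math.isqrt(self.n_blocks)

    @property
    def block_side(self) -> float:
        return self.roi_side / self.k

    def block_rect(self, index: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of block ``index`` (1..n_blocks)."""
        if not 1 <= index <= self.n_blocks:
            raise SpatialError(f"block index {index} outside 1..{self.n_blocks}")
        row, col = divmod(index - 1, self.k)
        s = self.block_side
        return (col * s, row * s, (col + 1) * s, (row + 1) * s)

    def block_of(self, x, y) -> np.ndarray:
        """Block index for each (x, y); half-open tiles, outer edge closed."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        bad = (x < 0) | (x > self.roi_side) | (y < 0) | (y > self.roi_side)
        if bad.any():
            i = int(np.argwhere(np.atleast_1d(bad))[0][0])
            raise SpatialError(
                f"cell at ({np.atleast_1d(x)[i]}, {np.atleast_1d(y)[i]}) outside ROI bounds"
            )
        col = np.minimum((x / self.block_side).astype(int), self.k - 1)
        row = np.minimum((y / self.block_side).astype(int), self.k - 1)
        return row * self.k + col + 1


def grid_partition(roi_side: float = 1000.0, n_blocks: int = 400) -> GridPartition:
    """Partition one ROI into ``n_blocks`` equal square blocks (default 400)."""
    return GridPartition(roi_side=roi_side, n_blocks=n_blocks)


def assign_regions(
    cells: pd.DataFrame, mask: pd.DataFrame, grid: GridPartition | None = None
) -> pd.DataFrame:
    """Annotate each cell with the region label of its block.

    ``cells`` needs columns roi_id, x, y; ``mask`` needs roi_id,
    block_index, region.  Returns a copy with ``block`` and ``region``
    columns.
    """
    grid = grid or grid_partition()
    out = cells.copy()
    out["block"] = 0
    out["region"] = ""
    for roi, sub in out.groupby("roi_id"):
        blocks = grid.block_of(sub["x"].to_numpy(), sub["y"].to_numpy())
        roi_mask = mask[mask["roi_id"] == roi]
        if len(roi_mask) != grid.n_blocks:
            raise SpatialError(
                f"mask for ROI {roi!r} has {len(roi_mask)} blocks, expected {grid.n_blocks}"
            )
        lut = roi_mask.set_index("block_index")["region"]
        out.loc[sub.index, "block"] = blocks
        out.loc[sub.index, "region"] = lut.reindex(blocks).to_numpy()
    if out["region"].isna().any() or (out["region"] == "").any():
        raise SpatialError("some cells fall in blocks missing from the region mask")
    return out


def region_abundance(
    cells: pd.DataFrame, phenotype: str, region: str
) -> tuple[pd.DataFrame, float, float]:
    """Per-ROI phenotype proportion in one region, compared between groups.

    Returns ``(per_roi_table, statistic, p_value)`` where the table has one
    row per ROI (roi_id, patient_group, proportion) and the comparison is a
    two-sided Wilcoxon rank-sum on the per-ROI proportions between the high
    and low patient groups.  ROIs whose region contains no cells are
    excluded and logged.
    """
    if phenotype not in set(cells["phenotype"]):
        raise SpatialError(f"phenotype {phenotype!r} absent from the cell palette")
    rows = []
    for (roi, grp), sub in cells.groupby(["roi_id", "patient_group"]):
        reg = sub[sub["region"] == region]
        if len(reg) == 0:
            logger.info("ROI %s: region %s empty, excluded", roi, region)
            continue
        rows.append(
            {
                "roi_id": roi,
                "patient_group": grp,
                "proportion": (reg["phenotype"] == phenotype).mean(),
            }
        )
    table = pd.DataFrame(rows)
    groups = table.groupby("patient_group")["proportion"]
    if table.empty or table["patient_group"].nunique() != 2:
        raise SpatialError("need ROIs from exactly two patient groups for comparison")
    a, b = (groups.get_group(g).to_numpy() for g in sorted(groups.groups))
    stat, p = stats.ranksums(a, b)
    return table, float(stat), float(p)


def find_neighbors(
    cells: pd.DataFrame, margin: float = 4.0, default_radius: float = 0.0
) -> dict[int, list[int]]:
    """Membrane-gap adjacency among cells of a single ROI.

    ``cells`` needs x, y and optionally a ``radius`` column (missing radii
    default to ``default_radius``).  Returns a symmetric, irreflexive
    mapping from cell index (the DataFrame index) to neighbor indices.
    Uses a k-d tree capped at the largest possible interaction distance,
    then filters pairs against the exact rule.
    """
    if margin < 0:
        raise SpatialError(f"margin must be non-negative, got {margin}")
    if "roi_id" in cells and cells["roi_id"].nunique() > 1:
        raise SpatialError("find_neighbors operates on a single ROI")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if "radius" in cells:
        radii = cells["radius"].fillna(default_radius).to_numpy(dtype=float)
    else:
        radii = np.full(len(cells), default_radius)
    if (radii < 0).any():
        raise SpatialError("cell radii must be non-negative")
    adjacency: dict[int, list[int]] = {idx: [] for idx in cells.index}
    if len(cells) < 2:
        return adjacency
    tree = cKDTree(xy)
    cap = 2 * radii.max() + margin
    for i, j in tree.query_pairs(r=cap):
        if np.hypot(*(xy[i] - xy[j])) <= radii[i] + radii[j] + margin:
            a, b = cells.index[i], cells.index[j]
            adjacency[a].append(b)
            adjacency[b].append(a)
    return {k: sorted(v) for k, v in adjacency.items()}


def neighbors_brute_force(
    cells: pd.DataFrame, margin: float = 4.0, default_radius: float = 0.0
) -> dict[int, list[int]]:
    """All-pairs reference implementation of the membrane-gap rule."""
    if margin < 0:
        raise SpatialError(f"margin must be non-negative, got {margin}")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if "radius" in cells:
        radii = cells["radius"].fillna(default_radius).to_numpy(dtype=float)
    else:
        radii = np.full(len(cells), default_radius)
    n = len(cells)
    adjacency: dict[int, list[int]] = {idx: [] for idx in cells.index}
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= radii[i] + radii[j] + margin:
                adjacency[cells.index[i]].append(cells.index[j])
                adjacency[cells.index[j]].append(cells.index[i])
    return {k: sorted(v) for k, v in adjacency.items()}


def neighborhood_composition(
    cells: pd.DataFrame, center_phenotype: str, margin: float = 4.0
) -> pd.DataFrame:
    """Neighbor phenotype composition around one center phenotype, per group.

    Adjacency is computed independently within each ROI (no cross-ROI
    neighbors).  Returns one row per (patient_group, neighbor phenotype)
    with columns ``count``, ``proportion`` and ``n_centers``; a group with
    no centers yields a single flagged row of zero centers.
    """
    frames = []
    for grp, gsub in cells.groupby("patient_group"):
        counts: dict[str, int] = {}
        n_centers = 0
        for _, roi_cells in gsub.groupby("roi_id"):
            adj = find_neighbors(roi_cells, margin=margin)
            centers = roi_cells.index[roi_cells["phenotype"] == center_phenotype]
            n_centers += len(centers)
            for c in centers:
                for nb in adj[c]:
                    ph = roi_cells.at[nb, "phenotype"]
                    counts[ph] = counts.get(ph, 0) + 1
        total = sum(counts.values())
        if n_centers == 0:
            logger.warning("patient group %s has no %s centers", grp, center_phenotype)
            frames.append(
                pd.DataFrame(
                    [{"patient_group": grp, "neighbor_phenotype": None, "count": 0,
                      "proportion": np.nan, "n_centers": 0}]
                )
            )
            continue
        if total == 0:
            frames.append(
                pd.DataFrame(
                    [{"patient_group": grp, "neighbor_phenotype": None, "count": 0,
                      "proportion": np.nan, "n_centers": n_centers}]
                )
            )
            continue
        frames.append(
            pd.DataFrame(
                [
                    {
                        "patient_group": grp,
                        "neighbor_phenotype": ph,
                        "count": c,
                        "proportion": c / total,
                        "n_centers": n_centers,
                    }
                    for ph, c in sorted(counts.items())
                ]
            )
        )
    return pd.concat(frames, ignore_index=True)
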