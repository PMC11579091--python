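"""Link detected brain centroids to metadata-table cells.

Both point grids — detection centroids in pixels, table cells in (col, row)
units — are standardized per axis to z-scores so they live in one unit of
measurement, then matched one-to-one by solving the minimum-total-cost
assignment (Hungarian method) with squared Euclidean distance as the cost.
Slides may carry fewer brains than the table has cells; leftover cells are
reported as missing, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import PointSet
from .slide_io import MetadataTable

__all__ = ["Assignment", "grid_from_metadata", "standardize", "assign", "label_brains"]


@dataclass
class Assignment:
    """Optimal pairing of detections to layout cells.

    ``pairs`` lists (detection_index, cell_index); ``total_cost`` is the sum
    of squared Euclidean distances over the pairs in standardized units.
    """

    pairs: list[tuple[int, int]]
    total_cost: float
    unmatched_cells: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def grid_from_metadata(table: MetadataTable) -> tuple[PointSet, list[tuple[int, int]]]:
    """One point per non-empty cell at (col, row), in row-major order.

    Returns the point set and the parallel list of (row, col) cell keys.
    """
    keys = sorted(table.cells.keys())  # row-major
    if not keys:
        raise ValueError("metadata table has no filled cells")
    pts = np.array([(c, r) for r, c in keys], dtype=float)
    return PointSet(pts), keys


def standardize(ps: PointSet) -> PointSet:
    """Per-axis z-score; an axis with zero variance is centered only."""
    if ps.n <= 1:
        raise ValueError("need at least 2 points to standardize")
    xy = ps.xy - ps.xy.mean(axis=0)
    sd = ps.xy.std(axis=0)
    out = np.where(sd > 1e-12, xy / np.where(sd > 1e-12, sd, 1.0), xy)
    return PointSet(out)


def assign(detections: PointSet, cells: PointSet) -> Assignment:
    """Minimum-total-cost one-to-one pairing of size min(n, m).

    Cost is squared Euclidean distance between standardized points. Exact
    global optimum (Hungarian method); ties resolved deterministically by
    the solver's row order (lowest detection index first).
    """
    if detections.n == 0 or cells.n == 0:
        raise ValueError("assignment needs at least one point on each side")
    diff = detections.xy[:, None, :] - cells.xy[None, :, :]
    cost = np.sum(diff * diff, axis=2)
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(cost[rows, cols].sum())
    unmatched_cells = sorted(set(range(cells.n)) - {c for _, c in pairs})
    unmatched_dets = sorted(set(range(detections.n)) - {d for d, _ in pairs})
    return Assignment(
        pairs=pairs,
        total_cost=total,
        unmatched_cells=unmatched_cells,
        unmatched_detections=unmatched_dets,
    )


def label_brains(
    assignment: Assignment,
    table: MetadataTable,
    objects: list,
    cell_keys: list[tuple[int, int]] | None = None,
    brain_indices: list[int] | None = None,
) -> tuple[list[dict], list[tuple[int, int]]]:
    """Attach sample/group labels to matched brains.

    ``cell_keys`` is the row-major (row, col) list matching the cell point
    order (from :func:`grid_from_metadata`); ``brain_indices`` maps
    detection-point order back to indices in ``objects`` (from
    :func:`~brainslide.detect.centroid_grid`). Returns labeled records and
    the (row, col) keys of unmatched cells (missing brains).
    """
    if cell_keys is None:
        cell_keys = sorted(table.cells.keys())
    labeled = []
    for det_idx, cell_idx in assignment.pairs:
        key = cell_keys[cell_idx]
        sample, group = table.cells[key]
        obj_idx = brain_indices[det_idx] if brain_indices is not None else det_idx
        labeled.append(
            {
                "object_index": obj_idx,
                "cell": key,
                "sample": sample,
                "group": group,
                "centroid": tuple(objects[obj_idx].centroid) if objects else None,
            }
        )
    missing = [cell_keys[i] for i in assignment.unmatched_cells]
    return labeled, missing
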