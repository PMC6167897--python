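"""Radius-based spatial interaction metrics between two marker-positive
cell populations.

The headline metric counts the source-marker cells (e.g. PD-1+) having at
least one target-marker cell (e.g. PD-L1+) within a fixed radius, 20 um by
default, and normalizes by the total TME (IT+PT) area.  A source cell is
counted once no matter how many targets are near.  The radius comparison is
strict ``<`` by default; an ``inclusive`` flag switches to ``<=``.

Distances are centroid-to-centroid by default (``edge_mode='centroid'``);
with ``edge_mode='surface'`` the cell radii are subtracted so the distance
approximates the gap between cell membranes (floored at zero for
overlapping cells).  Queries use a k-d tree; the brute-force pairwise scan
is kept in the test suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_RADIUS_UM = 20.0


@dataclass
class ProximityResult:
    """Count/density of source cells with >= 1 target within ``radius_um``."""

    specimen_id: str
    source_marker: str
    target_marker: str
    radius_um: float
    count: int
    n_source: int
    area_mm2: float | None = None
    pairs: pd.DataFrame | None = None

    @property
    def density(self) -> float:
        """Counted source cells per mm^2 of total TME area."""
        if self.area_mm2 is None or self.area_mm2 <= 0:
            raise ValueError("no TME area supplied; density undefined")
        return self.count / self.area_mm2


def _self_positions(source, target, exclude_self) -> np.ndarray | None:
    """Target row index of each source cell's own record, or None when the
    populations come from different physical sections.

    Source and target are "the same physical cells" when they share the
    specimen/section frame; a dual-positive cell then appears in both
    populations under one cell id and must not count as its own neighbor.
    """
    same_frame = source is target or (
        source.specimen_id == target.specimen_id
        and source.section_id == target.section_id
    )
    if exclude_self is not None:
        same_frame = exclude_self
    if not same_frame:
        return None
    pos = pd.Index(target.data["cell_id"]).get_indexer(source.data["cell_id"])
    return pos  # -1 where the source cell is absent from the target set


def _nn_surface(src_xy, src_r, tgt_xy, tgt_r, tree, self_pos):
    """Nearest surface-to-surface distance per source cell.

    With heterogeneous radii the centroid-nearest target need not be the
    surface-nearest, so candidates are gathered within an upper bound on the
    centroid distance of the surface-nearest target and scanned exactly.
    """
    n_src = len(src_xy)
    out = np.empty(n_src, float)
    max_tr = float(tgt_r.max()) if len(tgt_r) else 0.0
    d_cen = tree.query(src_xy, k=min(2, len(tgt_xy)))[0]
    d_cen = np.atleast_2d(np.asarray(d_cen, float).T).T
    # surface distance of the farthest of the two centroid-nearest targets
    # bounds the optimum even when the nearest is the excluded self record
    bound = np.maximum(d_cen[:, -1] - src_r, 0.0)
    search = bound + src_r + max_tr + 1e-9
    for i in range(n_src):
        cand = tree.query_ball_point(src_xy[i], search[i])
        if self_pos is not None:
            cand = [j for j in cand if j != self_pos[i]]
        if not cand:
            out[i] = np.inf
            continue
        cd = np.linalg.norm(tgt_xy[cand] - src_xy[i], axis=1)
        out[i] = np.maximum(cd - src_r[i] - np.asarray(tgt_r)[cand], 0.0).min()
    return out


def _nearest_distances(source, target, edge_mode, exclude_self):
    src_xy, tgt_xy = source.xy, target.xy
    if len(tgt_xy) == 0:
        raise ValueError("target population is empty; distances undefined")
    self_pos = _self_positions(source, target, exclude_self)
    tree = cKDTree(tgt_xy)
    if edge_mode == "centroid":
        k = min(2 if self_pos is not None else 1, len(tgt_xy))
        d, idx = tree.query(src_xy, k=k)
        d = np.atleast_2d(np.asarray(d, float).T).T
        idx = np.atleast_2d(np.asarray(idx, int).T).T
        out_d, out_i = d[:, 0].copy(), idx[:, 0].copy()
        if self_pos is not None:
            hit_self = idx[:, 0] == self_pos
            if k >= 2:
                out_d[hit_self] = d[hit_self, 1]
                out_i[hit_self] = idx[hit_self, 1]
            else:  # the only target is the cell itself
                out_d[hit_self] = np.inf
                out_i[hit_self] = -1
        return out_d, out_i
    if edge_mode == "surface":
        d = _nn_surface(src_xy, source.radii, tgt_xy, target.radii, tree, self_pos)
        return d, None
    raise ValueError("edge_mode must be 'centroid' or 'surface'")


def nearest_neighbor_distances(
    source,
    target,
    edge_mode: str = "centroid",
    exclude_self: bool | None = None,
) -> np.ndarray:
    """Distance from each source cell to its nearest target cell (um).

    Self-pairs are excluded automatically when source and target are the
    same physical cells (same table or same section/ids); override with
    ``exclude_self``.
    """
    d, _ = _nearest_distances(source, target, edge_mode, exclude_self)
    return d


def count_within_radius(
    source,
    target,
    radius_um: float = DEFAULT_RADIUS_UM,
    area_mm2: float | None = None,
    edge_mode: str = "centroid",
    inclusive: bool = False,
    exclude_self: bool | None = None,
    with_pairs: bool = False,
    source_marker: str = "",
    target_marker: str = "",
) -> ProximityResult:
    """Count source cells with at least one target within ``radius_um``.

    Both tables must be in one coordinate frame (register serial sections
    first).  ``area_mm2`` is the total TME area used for the density.  When
    ``with_pairs`` the result carries one row per counted source cell with
    its nearest target and distance, for drawing interaction lines.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if len(source) == 0 or len(target) == 0:
        return ProximityResult(
            source.specimen_id, source_marker, target_marker,
            radius_um, 0, len(source), area_mm2,
        )
    if source.attrs.get("registration_rmse_um", 0.0) > radius_um or target.attrs.get(
        "registration_rmse_um", 0.0
    ) > radius_um:
        import warnings

        warnings.warn(
            "registration residual exceeds the proximity radius; counts are "
            "unreliable",
            stacklevel=2,
        )
    d, idx = _nearest_distances(source, target, edge_mode, exclude_self)
    hit = d <= radius_um if inclusive else d < radius_um
    pairs = None
    if with_pairs and idx is not None:
        pairs = pd.DataFrame(
            {
                "source_id": source.data["cell_id"].to_numpy()[hit],
                "target_id": target.data["cell_id"].to_numpy()[idx[hit]],
                "distance_um": d[hit],
            }
        )
    return ProximityResult(
        source.specimen_id,
        source_marker,
        target_marker,
        radius_um,
        int(hit.sum()),
        len(source),
        area_mm2,
        pairs,
    )


def transpose_metric(
    source,
    target,
    radius_um: float = DEFAULT_RADIUS_UM,
    **kwargs,
) -> ProximityResult:
    """The transposed metric: target cells with >= 1 source within radius
    (identical contract to :func:`count_within_radius` with roles swapped)."""
    kwargs["source_marker"], kwargs["target_marker"] = (
        kwargs.pop("target_marker", ""),
        kwargs.pop("source_marker", ""),
    )
    return count_within_radius(target, source, radius_um, **kwargs)
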