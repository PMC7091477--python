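"""Cluster analysis of single-molecule localization tables.

The stage mirrors standard STORM post-processing: repeated detections of
one emitter in consecutive frames are merged (blink correction), clusters
are identified with DBSCAN at a density threshold of 20 detections within
a 20 nm radius, per-cluster and field-level metrics are computed, and a
super-resolution image is rendered by placing a unit-mass Gaussian kernel
of sd 10 nm at every localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .datatypes import LocalizationTable

__all__ = [
    "ClusterSet",
    "RenderedImage",
    "merge_consecutive_detections",
    "dbscan_cluster",
    "cluster_metrics",
    "render_storm",
]


@dataclass
class ClusterSet:
    """DBSCAN partition of a localization table.

    ``labels[i]`` is the cluster id of localization ``i`` in the input
    table's row order, or -1 for noise.  Cluster ids are contiguous from 0
    and canonically ordered by the (frame, x, y) rank of each cluster's
    first core point, so the partition is invariant to input row
    permutations.
    """

    labels: np.ndarray
    x_nm: np.ndarray = field(repr=False, default=None)
    y_nm: np.ndarray = field(repr=False, default=None)
    field_area_um2: float = 0.0
    eps_nm: float = 20.0
    min_pts: int = 20

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) and self.labels.max() >= 0 else 0

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == -1))

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass
class RenderedImage:
    """Super-resolution rendering: sum of unit-mass Gaussian kernels."""

    image: np.ndarray
    pixel_size_nm: float = 10.0
    kernel_sigma_nm: float = 10.0
    edge_truncated: bool = False


def merge_consecutive_detections(
    locs: LocalizationTable,
    merge_radius_nm: float = 20.0,
    max_frame_gap: int = 1,
) -> LocalizationTable:
    """Merge repeated detections of one emitter in consecutive frames.

    Detections are chained greedily in frame order: a detection extends an
    open chain when its frame is within ``max_frame_gap`` frames of the
    chain's last detection and it lies within ``merge_radius_nm`` of the
    chain's running centroid.  Each chain collapses to one localization at
    the chain centroid, stamped with the chain's first frame.  The pass is
    repeated until a fixed point so the operation is idempotent.
    """
    if merge_radius_nm < 0 or max_frame_gap < 0:
        raise ValueError("merge radius and frame gap must be non-negative")
    out = locs
    for _ in range(64):  # fixed point is reached after 1-2 passes in practice
        merged = _merge_pass(out, merge_radius_nm, max_frame_gap)
        if len(merged) == len(out):
            return merged
        out = merged
    return out


def _merge_pass(
    locs: LocalizationTable, radius: float, gap: int
) -> LocalizationTable:
    order = locs.sort_order()
    frame = locs.frame[order]
    x = locs.x_nm[order]
    y = locs.y_nm[order]
    n = len(frame)
    if n == 0:
        return locs.take(order)

    # open chains: running centroid sums, count, first/last frame
    sum_x: list[float] = []
    sum_y: list[float] = []
    count: list[int] = []
    first: list[int] = []
    last: list[int] = []

    frames_unique = np.unique(frame)
    start_of_frame = np.searchsorted(frame, frames_unique)
    end_of_frame = np.append(start_of_frame[1:], n)

    for f, s, e in zip(frames_unique, start_of_frame, end_of_frame):
        # candidate chains: last frame within gap of f (and strictly before f)
        cand = [
            j
            for j in range(len(count))
            if last[j] < f and f - last[j] <= gap
        ]
        claimed: set[int] = set()
        for i in range(s, e):
            best_j, best_d = -1, np.inf
            for j in cand:
                if j in claimed:
                    continue
                cxj = sum_x[j] / count[j]
                cyj = sum_y[j] / count[j]
                d = np.hypot(x[i] - cxj, y[i] - cyj)
                if d <= radius and d < best_d:
                    best_j, best_d = j, d
            if best_j >= 0:
                sum_x[best_j] += x[i]
                sum_y[best_j] += y[i]
                count[best_j] += 1
                claimed.add(best_j)
            else:
                sum_x.append(x[i])
                sum_y.append(y[i])
                count.append(1)
                first.append(int(f))
                last.append(int(f))
                claimed.add(len(count) - 1)
        for j in claimed:
            last[j] = int(f)

    cnt = np.array(count, dtype=np.float64)
    return LocalizationTable(
        frame=np.array(first, dtype=np.int64),
        x_nm=np.array(sum_x) / cnt,
        y_nm=np.array(sum_y) / cnt,
        field_width_nm=locs.field_width_nm,
        field_height_nm=locs.field_height_nm,
    )


def dbscan_cluster(
    locs: LocalizationTable, eps_nm: float = 20.0, min_pts: int = 20
) -> ClusterSet:
    """DBSCAN on localization coordinates (density threshold: ``min_pts``
    detections within a radial distance of ``eps_nm``).

    Standard semantics: a core point has at least ``min_pts`` neighbours
    within ``eps_nm`` (counting itself); clusters are density-connected
    components of core points plus border points.  Deterministic tie-break:
    points are ranked in (frame, x, y) order, cluster ids follow the rank of
    each cluster's first core point, and a border point reachable from
    several clusters joins the lowest cluster id.
    """
    if eps_nm <= 0:
        raise ValueError("eps_nm must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")

    n = len(locs)
    labels_sorted = np.full(n, -1, dtype=np.int64)
    order = locs.sort_order()
    if n:
        x = locs.x_nm[order]
        y = locs.y_nm[order]
        pts = np.column_stack([x, y])
        tree = cKDTree(pts)
        neighbors = tree.query_ball_point(pts, r=eps_nm)
        counts = np.array([len(nb) for nb in neighbors])
        core = counts >= min_pts

        # connected components of core points (BFS in canonical order)
        cluster_id = 0
        for i in np.flatnonzero(core):
            if labels_sorted[i] != -1:
                continue
            stack = [i]
            labels_sorted[i] = cluster_id
            while stack:
                j = stack.pop()
                for k in neighbors[j]:
                    if core[k] and labels_sorted[k] == -1:
                        labels_sorted[k] = cluster_id
                        stack.append(k)
            cluster_id += 1

        # border points: lowest reachable cluster id
        for i in np.flatnonzero(~core):
            reach = [labels_sorted[k] for k in neighbors[i] if core[k]]
            if reach:
                labels_sorted[i] = min(reach)

    labels = np.full(n, -1, dtype=np.int64)
    labels[order] = labels_sorted
    return ClusterSet(
        labels=labels,
        x_nm=locs.x_nm,
        y_nm=locs.y_nm,
        field_area_um2=locs.field_area_um2,
        eps_nm=eps_nm,
        min_pts=min_pts,
    )


def cluster_metrics(cs: ClusterSet) -> dict:
    """Per-cluster and field-level cluster statistics.

    Per cluster: number of detections, convex-hull area in nm^2 (collinear
    or too-small clusters get area 0 and ``degenerate=True``), centroid.
    Field level: detections per square micrometre and the fraction of
    detections inside clusters.
    """
    if cs.field_area_um2 <= 0:
        raise ValueError("field area must be positive")
    records = []
    for cid in range(cs.n_clusters):
        idx = cs.members(cid)
        pts = np.column_stack([cs.x_nm[idx], cs.y_nm[idx]])
        degenerate = False
        if len(pts) < 3:
            area = 0.0
            degenerate = True
        else:
            try:
                area = float(ConvexHull(pts).volume)  # 2-D: volume == area
            except QhullError:
                area = 0.0
                degenerate = True
        records.append(
            {
                "cluster_id": cid,
                "n_detections": int(len(idx)),
                "area_nm2": area,
                "centroid_x_nm": float(pts[:, 0].mean()),
                "centroid_y_nm": float(pts[:, 1].mean()),
                "degenerate": degenerate,
            }
        )
    per_cluster = pd.DataFrame(
        records,
        columns=[
            "cluster_id",
            "n_detections",
            "area_nm2",
            "centroid_x_nm",
            "centroid_y_nm",
            "degenerate",
        ],
    )
    n_total = len(cs.labels)
    n_clustered = int(np.sum(cs.labels >= 0))
    return {
        "per_cluster": per_cluster,
        "n_clusters": cs.n_clusters,
        "detections_per_um2": n_total / cs.field_area_um2,
        "fraction_in_clusters": (n_clustered / n_total) if n_total else 0.0,
    }


def render_storm(
    locs: LocalizationTable,
    pixel_size_nm: float = 10.0,
    kernel_sigma_nm: float = 10.0,
) -> RenderedImage:
    """Render localizations as a sum of unit-mass Gaussians (sd 10 nm).

    The image covers the full field at ``pixel_size_nm`` sampling; each
    localization is binned and the histogram convolved with a normalized
    Gaussian kernel, so total image mass equals the number of localizations
    up to edge truncation (flagged when any localization lies within six
    kernel sigmas of the field border).
    """
    if pixel_size_nm <= 0 or kernel_sigma_nm <= 0:
        raise ValueError("pixel size and kernel sigma must be positive")
    w = int(np.ceil(locs.field_width_nm / pixel_size_nm))
    h = int(np.ceil(locs.field_height_nm / pixel_size_nm))
    hist = np.zeros((h, w), dtype=np.float64)
    if len(locs):
        col = np.clip((locs.x_nm / pixel_size_nm).astype(np.int64), 0, w - 1)
        row = np.clip((locs.y_nm / pixel_size_nm).astype(np.int64), 0, h - 1)
        np.add.at(hist, (row, col), 1.0)
    sigma_px = kernel_sigma_nm / pixel_size_nm
    img = gaussian_filter(hist, sigma=sigma_px, mode="constant", truncate=6.0)
    margin = 6.0 * kernel_sigma_nm
    edge = bool(
        len(locs)
        and (
            locs.x_nm.min() < margin
            or locs.y_nm.min() < margin
            or locs.x_nm.max() > locs.field_width_nm - margin
            or locs.y_nm.max() > locs.field_height_nm - margin
        )
    )
    return RenderedImage(
        image=img,
        pixel_size_nm=pixel_size_nm,
        kernel_sigma_nm=kernel_sigma_nm,
        edge_truncated=edge,
    )
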