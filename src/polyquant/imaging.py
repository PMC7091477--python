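"""Wavelet-based puncta segmentation and colocalization metrics.

Fluorescent structures (aggregates, receptor clusters, synaptic puncta)
are segmented with the undecimated a-trous wavelet transform using the
B3-spline kernel: the detail plane at the chosen scale is thresholded at
``k`` times a robust (median-absolute-deviation) estimate of its noise sd,
producing background-free masks.  Structure intensities are always summed
from the original image under the mask.  Colocalization between two
channels is mask overlap (>= 1 shared pixel); the endocytosis readout
classifies "green" structures without any "red" (surface-marker) overlap
as internalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "StructureMask",
    "ColocalizationResult",
    "EndocytosisResult",
    "atrous_planes",
    "wavelet_segment",
    "structure_metrics",
    "colocalize",
    "classify_endocytosed",
]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class StructureMask:
    """Labeled segmentation of an image into puncta.

    ``label_image`` holds integer labels (0 = background, structures 1..N,
    8-connected).  ``table`` lists per-structure pixel count, area in um^2,
    total intensity summed from the original image, and centroid in
    (row, col) pixel coordinates (0-based, origin top-left).
    """

    label_image: np.ndarray
    table: pd.DataFrame
    pixel_size_nm: float
    n_scales: int = 2
    threshold_k: float = 4.0
    min_size_px: int = 4

    @property
    def n_structures(self) -> int:
        return len(self.table)

    @property
    def field_area_um2(self) -> float:
        return self.label_image.size * (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class ColocalizationResult:
    """Overlap-based colocalization of channel-A structures with channel B."""

    fraction_a_coloc: float
    n_a: int
    n_b: int
    n_coloc: int
    pairing: pd.DataFrame  # columns a_id, b_id (one row per overlapping pair)
    mode: str = "overlap"


@dataclass
class EndocytosisResult:
    """Surface vs internalized classification of green structures."""

    n_total_green: int
    n_surface: int
    n_internal: int
    fraction_internal: float
    undefined: bool = False


def atrous_planes(image: np.ndarray, n_scales: int) -> list:
    """Undecimated a-trous wavelet detail planes (B3-spline kernel).

    Plane j is the difference between successive smoothings with the
    B3-spline kernel dilated by 2**(j-1); reflective boundaries.
    """
    c = np.asarray(image, dtype=np.float64)
    planes = []
    for j in range(1, n_scales + 1):
        dilation = 2 ** (j - 1)
        kernel = np.zeros((len(_B3) - 1) * dilation + 1)
        kernel[::dilation] = _B3
        smooth = ndimage.convolve1d(c, kernel, axis=0, mode="reflect")
        smooth = ndimage.convolve1d(smooth, kernel, axis=1, mode="reflect")
        planes.append(c - smooth)
        c = smooth
    return planes


def wavelet_segment(
    image: np.ndarray,
    n_scales: int = 2,
    threshold_k: float = 4.0,
    min_size_px: int = 4,
    pixel_size_nm: float = 100.0,
) -> StructureMask:
    """Segment spot-like structures above background.

    The detection plane is the a-trous detail plane at scale ``n_scales``;
    the binary mask keeps pixels above ``threshold_k`` times the plane's
    robust noise sd (median absolute deviation / 0.6745).  8-connected
    components smaller than ``min_size_px`` pixels are discarded; labels
    are contiguous from 1.  A constant image yields an empty mask.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")

    plane = atrous_planes(image, n_scales)[-1]
    mad = np.median(np.abs(plane - np.median(plane)))
    sigma = mad / 0.6745
    # sigma == 0 (noise-free image) degrades to "any positive detail"
    mask = plane > threshold_k * sigma

    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_size_px)
        keep = keep[keep > 0]
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        n = len(keep)

    rows = []
    if n:
        ids = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(labels), labels, ids)
        intensities = ndimage.sum_labels(image.astype(np.float64), labels, ids)
        centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
        px_area_um2 = (pixel_size_nm / 1000.0) ** 2
        for i, sid in enumerate(ids):
            rows.append(
                {
                    "structure_id": int(sid),
                    "n_pixels": int(counts[i]),
                    "area_um2": float(counts[i] * px_area_um2),
                    "total_intensity": float(intensities[i]),
                    "centroid_row": float(centroids[i][0]),
                    "centroid_col": float(centroids[i][1]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "n_pixels",
            "area_um2",
            "total_intensity",
            "centroid_row",
            "centroid_col",
        ],
    )
    return StructureMask(
        label_image=labels.astype(np.int32),
        table=table,
        pixel_size_nm=pixel_size_nm,
        n_scales=n_scales,
        threshold_k=threshold_k,
        min_size_px=min_size_px,
    )


def structure_metrics(mask: StructureMask) -> dict:
    """Per-image structure statistics.

    ``mean_intensity_per_cluster`` averages each structure's total
    fluorescence over the field; ``summed_intensity`` is the sum over all
    structures; ``clusters_per_um2`` is the structure density; and
    ``percent_area`` the percentage of field pixels inside structures.
    """
    n = mask.n_structures
    area = mask.field_area_um2
    if n == 0:
        return {
            "n_structures": 0,
            "mean_intensity_per_cluster": 0.0,
            "clusters_per_um2": 0.0,
            "summed_intensity": 0.0,
            "percent_area": 0.0,
        }
    total = float(mask.table["total_intensity"].sum())
    covered = int(mask.table["n_pixels"].sum())
    return {
        "n_structures": n,
        "mean_intensity_per_cluster": total / n,
        "clusters_per_um2": n / area,
        "summed_intensity": total,
        "percent_area": 100.0 * covered / mask.label_image.size,
    }


def colocalize(
    mask_a: StructureMask, mask_b: StructureMask, mode: str = "overlap"
) -> ColocalizationResult:
    """Fraction of channel-A structures colocalized with channel B.

    ``overlap``: an A structure is colocalized iff it shares at least one
    pixel with any B structure.  ``apposition`` additionally counts A
    structures whose centroid lies within 2 px of a B centroid.
    """
    if mask_a.label_image.shape != mask_b.label_image.shape:
        raise ValueError("masks must have the same shape")
    if mode not in ("overlap", "apposition"):
        raise ValueError(f"unknown mode {mode!r}")

    la, lb = mask_a.label_image, mask_b.label_image
    both = (la > 0) & (lb > 0)
    pairs = (
        np.unique(np.column_stack([la[both], lb[both]]), axis=0)
        if both.any()
        else np.empty((0, 2), dtype=np.int64)
    )
    coloc_ids = set(int(a) for a in pairs[:, 0]) if len(pairs) else set()

    pair_rows = [{"a_id": int(a), "b_id": int(b)} for a, b in pairs]
    if mode == "apposition" and mask_a.n_structures and mask_b.n_structures:
        ca = mask_a.table[["centroid_row", "centroid_col"]].to_numpy()
        cb = mask_b.table[["centroid_row", "centroid_col"]].to_numpy()
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        for i, sid in enumerate(mask_a.table["structure_id"]):
            j = int(np.argmin(d[i]))
            if d[i, j] <= 2.0 and int(sid) not in coloc_ids:
                coloc_ids.add(int(sid))
                pair_rows.append(
                    {"a_id": int(sid), "b_id": int(mask_b.table["structure_id"].iloc[j])}
                )

    n_a = mask_a.n_structures
    n_coloc = len(coloc_ids)
    return ColocalizationResult(
        fraction_a_coloc=(n_coloc / n_a) if n_a else 0.0,
        n_a=n_a,
        n_b=mask_b.n_structures,
        n_coloc=n_coloc,
        pairing=pd.DataFrame(pair_rows, columns=["a_id", "b_id"]),
        mode=mode,
    )


def classify_endocytosed(
    mask_green: StructureMask, mask_red: StructureMask
) -> EndocytosisResult:
    """Classify green structures as surface (red overlap) or internalized.

    Green structures overlapping the red surface marker sit at the cell
    surface; green-only structures are endocytosed.  With zero green
    structures the fraction is undefined and flagged.
    """
    res = colocalize(mask_green, mask_red, mode="overlap")
    n_total = res.n_a
    n_surface = res.n_coloc
    n_internal = n_total - n_surface
    if n_total == 0:
        return EndocytosisResult(0, 0, 0, float("nan"), undefined=True)
    return EndocytosisResult(
        n_total_green=n_total,
        n_surface=n_surface,
        n_internal=n_internal,
        fraction_internal=n_internal / n_total,
    )
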