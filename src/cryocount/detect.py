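"""Cluster detection: hysteresis segmentation, 3D labelling, feature
extraction, and knowledge-based false-positive rejection.

The grayscale volume I_Gray is segmented with two thresholds.  The high
threshold T_H = 0.6 * min over culture-cluster maxima guarantees every cell
cluster keeps at least one seed voxel; the low threshold
T_L = mu_img + c * sigma_img (c >= 1.4) excludes the dim autofluorescent
floor.  Low-threshold voxels survive only when 26-connected to a
high-threshold voxel.  Connected components are labelled in 3D so a cell
sectioned across two slices stays one cluster, and per-cluster features
feed the false-positive rules: reject when the volume exceeds T_V or the
integrated-intensity-to-volume ratio falls outside [T_RL, T_RH].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "DetectConfig",
    "Cluster",
    "compute_high_threshold",
    "compute_low_threshold",
    "hysteresis_threshold",
    "connected_components",
    "culture_cluster_maxima",
    "reject_false_positives",
    "clusters_to_frame",
]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class DetectConfig:
    """Segmentation thresholds and false-positive rules.

    ``t_high``/``t_low`` may be given directly or derived at run time
    (``t_high`` from a culture image, ``t_low`` from the stack statistics
    with constant ``c``).  ``t_volume`` is the maximum plausible cluster
    volume in voxels; ``ratio_low``/``ratio_high`` bound the integrated
    intensity / volume ratio of genuine label clusters.
    """

    c: float = 1.4
    t_high: float | None = None
    t_low: float | None = None
    t_volume: float = 500.0
    ratio_low: float = 0.0
    ratio_high: float = np.inf

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.t_volume < 1:
            raise ValueError("t_volume must be >= 1")
        if self.ratio_high < self.ratio_low:
            raise ValueError("ratio_high must be >= ratio_low")
        if (self.t_high is not None and self.t_low is not None
                and self.t_high <= self.t_low):
            raise ValueError("t_high must exceed t_low")


@dataclass
class Cluster:
    """One connected fluorescent component with its features."""

    id: int
    voxels: np.ndarray            # (n, 3) int array of (slice, row, col)
    volume: int                   # C_V, voxel count
    integrated_intensity: float   # integral of I_Gray over the voxels
    bbox: tuple[int, int, int, int, int, int]  # z0, z1, y0, y1, x0, x1 (incl.)
    center: tuple[float, float, float]         # intensity-weighted (z, y, x)
    slice_span: int

    @property
    def intensity_volume_ratio(self) -> float:
        return self.integrated_intensity / self.volume

    @property
    def max_intensity(self) -> float:
        return float(self._max_intensity)

    _max_intensity: float = 0.0


def compute_high_threshold(culture_cluster_maxima: np.ndarray | list[float]
                           ) -> float:
    """High hysteresis threshold from culture-image cluster maxima:
    ``T_H = 0.6 * min_n Cmax(n)`` so even the dimmest cultured cell would
    retain a seed voxel."""
    maxima = np.asarray(culture_cluster_maxima, dtype=float)
    if maxima.size == 0:
        raise ValueError("need at least one culture cluster maximum")
    return 0.6 * float(maxima.min())


def compute_low_threshold(igray: np.ndarray, c: float = 1.4) -> float:
    """Low hysteresis threshold ``T_L = mu_img + c * sigma_img`` over all
    voxels of I_Gray (zeros included)."""
    if c < 0:
        raise ValueError("c must be non-negative")
    igray = np.asarray(igray, dtype=float)
    return float(igray.mean() + c * igray.std())


def hysteresis_threshold(igray: np.ndarray, t_high: float,
                         t_low: float) -> np.ndarray:
    """Dual-threshold segmentation of I_Gray.

    A voxel is kept iff it exceeds ``t_low`` (strictly) and its
    26-connected component of above-``t_low`` voxels contains at least one
    voxel exceeding ``t_high``.
    """
    if t_high < t_low:
        raise ValueError("t_high must be >= t_low")
    igray = np.asarray(igray, dtype=float)
    squeeze = False
    if igray.ndim == 2:
        igray = igray[None]
        squeeze = True
    low_mask = igray > t_low
    labels, n = ndi.label(low_mask, structure=_STRUCT_3D)
    if n == 0:
        mask = low_mask
    else:
        maxima = ndi.maximum(igray, labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = np.asarray(maxima) > t_high
        mask = keep[labels]
    return mask[0] if squeeze else mask


def connected_components(mask: np.ndarray, igray: np.ndarray,
                         connectivity_3d: bool = True) -> list[Cluster]:
    """Label the binary mask and compute features from I_Gray.

    Uses 26-connectivity in 3D (8 in-plane) by default so fragments of one
    sectioned cell in adjacent slices merge into a single cluster.
    """
    mask = np.asarray(mask, dtype=bool)
    igray = np.asarray(igray, dtype=float)
    squeeze = mask.ndim == 2
    if squeeze:
        mask, igray = mask[None], igray[None]
    structure = _STRUCT_3D if connectivity_3d else None
    labels, n = ndi.label(mask, structure=structure)
    clusters: list[Cluster] = []
    if n == 0:
        return clusters
    objects = ndi.find_objects(labels)
    for i, slc in enumerate(objects, start=1):
        sub_lab = labels[slc] == i
        sub_int = igray[slc]
        coords = np.argwhere(sub_lab)
        offset = np.array([s.start for s in slc])
        voxels = coords + offset
        vals = sub_int[sub_lab]
        total = float(vals.sum())
        if total > 0:
            w = (sub_int * sub_lab)
            com = ndi.center_of_mass(w)
            center = tuple(float(c + o) for c, o in zip(com, offset))
        else:  # pragma: no cover - empty-intensity cluster
            center = tuple(voxels.mean(axis=0))
        z0, y0, x0 = voxels.min(axis=0)
        z1, y1, x1 = voxels.max(axis=0)
        cl = Cluster(
            id=i, voxels=voxels, volume=int(len(voxels)),
            integrated_intensity=total,
            bbox=(int(z0), int(z1), int(y0), int(y1), int(x0), int(x1)),
            center=center, slice_span=int(z1 - z0 + 1))
        cl._max_intensity = float(vals.max())
        clusters.append(cl)
    return clusters


def culture_cluster_maxima(igray: np.ndarray, c: float = 1.4,
                           min_volume: int = 4,
                           rel_floor: float = 0.5) -> np.ndarray:
    """Per-cluster maximum intensities from a culture image.

    Segments the (preprocessed) culture image at its own
    ``mu + c * sigma`` floor — cultured cells are bright and well
    separated, so a single low threshold suffices — and returns each
    labelled cluster's maximum, the Cmax(n) inputs of the T_H rule.
    Residual noise specks are excluded on two grounds so they cannot drag
    the minimum down: components smaller than ``min_volume`` voxels (a
    point-scale cell exceeds several pixels at the low threshold), and
    components whose maximum falls below ``rel_floor`` times the median
    component maximum — cultured cells are comparably bright, while a
    noise clump peaks at a small fraction of any cell.
    """
    igray = np.asarray(igray, dtype=float)
    t_low = compute_low_threshold(igray, c)
    mask = igray > t_low
    if igray.ndim == 2:
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    else:
        labels, n = ndi.label(mask, structure=_STRUCT_3D)
    if n == 0:
        return np.array([])
    idx = np.arange(1, n + 1)
    maxima = np.asarray(ndi.maximum(igray, labels, idx), dtype=float)
    volumes = np.asarray(ndi.sum_labels(mask, labels, idx))
    keep = volumes >= min_volume
    if keep.any():
        maxima = maxima[keep]
    if len(maxima) > 1:
        maxima = maxima[maxima >= rel_floor * np.median(maxima)]
    return maxima


def reject_false_positives(clusters: list[Cluster], t_volume: float,
                           ratio_low: float, ratio_high: float
                           ) -> tuple[list[Cluster], list[tuple[Cluster, str]]]:
    """Apply the knowledge-based rules.

    Keeps clusters with ``C_V <= t_volume`` and
    ``ratio_low <= integral(C_i)/C_V <= ratio_high``; every rejection
    records which rule fired (``volume``, ``ratio_low`` or ``ratio_high``).
    """
    kept: list[Cluster] = []
    rejected: list[tuple[Cluster, str]] = []
    for cl in clusters:
        if cl.volume > t_volume:
            rejected.append((cl, "volume"))
        elif cl.intensity_volume_ratio < ratio_low:
            rejected.append((cl, "ratio_low"))
        elif cl.intensity_volume_ratio > ratio_high:
            rejected.append((cl, "ratio_high"))
        else:
            kept.append(cl)
    return kept, rejected


def clusters_to_frame(clusters: list[Cluster],
                      rejected: list[tuple[Cluster, str]] | None = None
                      ) -> pd.DataFrame:
    """Cluster table (one row per cluster) for CSV interchange."""
    rows = []
    for cl in clusters:
        rows.append(dict(
            id=cl.id, volume=cl.volume,
            integrated_intensity=cl.integrated_intensity,
            z0=cl.bbox[0], z1=cl.bbox[1], y0=cl.bbox[2], y1=cl.bbox[3],
            x0=cl.bbox[4], x1=cl.bbox[5],
            ratio=cl.intensity_volume_ratio,
            center_z=cl.center[0], center_y=cl.center[1],
            center_x=cl.center[2], slice_span=cl.slice_span,
            max_intensity=cl.max_intensity, kept=True, reject_reason=""))
    if rejected:
        for cl, reason in rejected:
            rows.append(dict(
                id=cl.id, volume=cl.volume,
                integrated_intensity=cl.integrated_intensity,
                z0=cl.bbox[0], z1=cl.bbox[1], y0=cl.bbox[2], y1=cl.bbox[3],
                x0=cl.bbox[4], x1=cl.bbox[5],
                ratio=cl.intensity_volume_ratio,
                center_z=cl.center[0], center_y=cl.center[1],
                center_x=cl.center[2], slice_span=cl.slice_span,
                max_intensity=cl.max_intensity, kept=False,
                reject_reason=reason))
    cols = ["id", "volume", "integrated_intensity", "z0", "z1", "y0", "y1",
            "x0", "x1", "ratio", "center_z", "center_y", "center_x",
            "slice_span", "max_intensity", "kept", "reject_reason"]
    return pd.DataFrame(rows, columns=cols)
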