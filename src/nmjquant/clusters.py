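"""Acetylcholine-receptor (AChR) cluster quantification.

Clusters of nicotinic receptors on myotube membranes, labeled with
fluorescent α-bungarotoxin, are segmented by intensity thresholding; per
cluster, area and mean intensity are measured, and the cluster count is
normalized to the myotube area (clusters per mm² of myotube) obtained by
contrast-stretching and thresholding a myotube-visualizing channel. A
secondary channel (rapsyn co-staining, or a binarized neurite mask for
colocalization) can be scored per cluster with an explicit rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DenominatorError, DimensionError, ParameterError
from .io_core import CalibratedImage
from .nuclei import LabelMask, label_binary, region_features


@dataclass
class ClusterTable:
    """Per-cluster records plus field-level summary quantities."""

    records: list[dict] = field(default_factory=list)
    pixel_size_um: float = 1.0
    myotube_area_mm2: Optional[float] = None
    clusters_per_mm2: Optional[float] = None

    @property
    def n_clusters(self) -> int:
        return len(self.records)

    @property
    def mean_area_um2(self) -> float:
        if not self.records:
            return 0.0
        return float(np.mean([r["area_um2"] for r in self.records]))

    @property
    def mean_intensity_au(self) -> float:
        if not self.records:
            return 0.0
        return float(np.mean([r["mean_intensity_au"] for r in self.records]))

    @property
    def fraction_rapsyn_positive(self) -> Optional[float]:
        flags = [r.get("rapsyn_positive") for r in self.records]
        if not flags or any(f is None for f in flags):
            return None
        return float(np.mean([bool(f) for f in flags]))


def segment_clusters(
    btx: CalibratedImage,
    threshold: float,
    min_area_px2: float = 4.0,
) -> LabelMask:
    """4-connected components of (btx > threshold) at least ``min_area_px2``.

    The minimum-area filter (default 4 px², excluding sub-diffraction
    specks) is the automated surrogate for interactive cluster curation.
    """
    if min_area_px2 < 0:
        raise ParameterError("min_area_px2 must be >= 0")
    labels = label_binary(btx.as_float() > threshold)
    feats = region_features(LabelMask(labels)).features
    keep = [f.label for f in feats if f.area_px2 >= min_area_px2]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        lut[old] = new
    return region_features(LabelMask(lut[labels]), intensity=btx)


def cluster_table(
    clusters: LabelMask,
    pixel_size_um: float,
    myotube_area_mm2: Optional[float] = None,
) -> ClusterTable:
    """Tabulate per-cluster area (px² and µm²), intensity and centroid."""
    records = [
        {
            "label": f.label,
            "area_px2": f.area_px2,
            "area_um2": f.area_px2 * pixel_size_um**2,
            "mean_intensity_au": f.mean_intensity,
            "centroid": f.centroid,
        }
        for f in clusters.features
    ]
    table = ClusterTable(records=records, pixel_size_um=pixel_size_um)
    if myotube_area_mm2 is not None:
        table = normalize_cluster_count(table, myotube_area_mm2)
    return table


def segment_myotubes_for_normalization(
    myotube_channel: CalibratedImage,
    contrast_percentiles: tuple[float, float] = (1.0, 99.0),
    threshold: float = 0.5,
) -> tuple[LabelMask, float]:
    """Contrast-stretch, threshold and label the myotube channel.

    The low/high intensity percentiles are mapped linearly to [0, 1]
    (mimicking "increasing image contrast" before segmentation), the result
    is thresholded, and the total foreground area is returned in mm²
    (pixel count × pixel_size_um² / 10⁶). A constant image yields an empty
    mask and area 0.
    """
    low, high = contrast_percentiles
    if not (0 <= low < high <= 100):
        raise ParameterError("need 0 <= low < high <= 100 percentiles")
    img = myotube_channel.as_float()
    lo, hi = np.percentile(img, [low, high])
    if hi <= lo:
        empty = LabelMask(np.zeros(myotube_channel.shape, dtype=np.int32))
        return empty, 0.0
    stretched = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    labels = label_binary(stretched > threshold)
    mask = region_features(LabelMask(labels))
    area_mm2 = float(
        (labels > 0).sum() * myotube_channel.pixel_size_um**2 / 1e6
    )
    return mask, area_mm2


def normalize_cluster_count(table: ClusterTable, myotube_area_mm2: float) -> ClusterTable:
    """Attach clusters_per_mm2 = n_clusters / myotube area in mm²."""
    if not (myotube_area_mm2 > 0):
        raise DenominatorError(
            f"myotube area must be > 0 mm², got {myotube_area_mm2}"
        )
    return ClusterTable(
        records=table.records,
        pixel_size_um=table.pixel_size_um,
        myotube_area_mm2=float(myotube_area_mm2),
        clusters_per_mm2=table.n_clusters / float(myotube_area_mm2),
    )


def score_secondary_channel(
    clusters: LabelMask,
    secondary: CalibratedImage,
    rule: str,
    threshold: float,
    binarize_threshold: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Score each cluster against a second channel; returns (calls, fraction).

    rule="mean_gt": positive when the mean secondary intensity inside the
    cluster mask is strictly greater than ``threshold``.

    rule="overlap_frac": positive when the fraction of cluster pixels lying
    on the binarized secondary mask is at least ``threshold``; the
    binarization cut is ``binarize_threshold`` (Otsu when None). This is an
    automated analogue of interactive colocalization counting, not a
    reproduction of it.
    """
    if secondary.shape != clusters.labels.shape:
        raise DimensionError("secondary channel does not match cluster mask shape")
    n = clusters.n_labels
    if n == 0:
        return np.zeros(0, dtype=bool), 0.0
    sec = secondary.as_float()
    if rule == "mean_gt":
        feats = region_features(LabelMask(clusters.labels), intensity=secondary).features
        calls = np.array([f.mean_intensity > threshold for f in feats])
    elif rule == "overlap_frac":
        if binarize_threshold is None:
            binarize_threshold = float(threshold_otsu(sec))
        secmask = sec > binarize_threshold
        calls = np.empty(n, dtype=bool)
        for i in range(1, n + 1):
            inside = clusters.labels == i
            calls[i - 1] = secmask[inside].mean() >= threshold
    else:
        raise ParameterError(f"unknown rule {rule!r}; use 'mean_gt' or 'overlap_frac'")
    return calls, float(calls.mean())
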