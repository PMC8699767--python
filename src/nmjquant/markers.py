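"""Per-nucleus marker-positivity classification.

Two rules, both strict (> threshold):

* ``point_max`` — smooth the marker channel with a small Gaussian
  (sigma 0.5 px by default), take the maximum inside a 3×3 px window
  centered on each detected nucleus, and call the cell positive when that
  maximum exceeds a user-defined threshold. Windows are clipped at the
  image border rather than discarded.
* ``nuclear_mean`` — mean marker intensity over each segmented nuclear
  mask, compared to a user-defined threshold.

Thresholds are in the marker channel's native intensity units and have no
default; they are the analysis' main free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError
from .io_core import CalibratedImage
from .nuclei import LabelMask, PointSet, region_features


@dataclass
class ClassificationResult:
    marker: str
    rule: str
    threshold_used: float
    calls: np.ndarray  # boolean per nucleus
    scores: np.ndarray  # the statistic compared to the threshold

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_total(self) -> int:
        return len(self.calls)

    @property
    def n_positive(self) -> int:
        return int(self.calls.sum())

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_total if self.n_total else 0.0


def classify_point_max(
    marker_img: CalibratedImage,
    centers: PointSet,
    threshold: float,
    smooth_sigma_px: float = 0.5,
    window_px: int = 3,
) -> ClassificationResult:
    """Point-based rule: window maximum of the smoothed marker channel."""
    if window_px < 1 or window_px % 2 == 0:
        raise ParameterError(f"window_px must be odd and >= 1, got {window_px}")
    if centers.source_shape != marker_img.shape:
        raise DimensionError("point set does not match marker image shape")
    smoothed = marker_img.as_float()
    if smooth_sigma_px > 0:
        smoothed = ndimage.gaussian_filter(smoothed, smooth_sigma_px, mode="reflect")
    half = window_px // 2
    nrows, ncols = marker_img.shape
    scores = np.empty(len(centers), dtype=float)
    for i, (r, c) in enumerate(centers.rounded()):
        rlo, rhi = max(0, r - half), min(nrows, r + half + 1)
        clo, chi = max(0, c - half), min(ncols, c + half + 1)
        scores[i] = smoothed[rlo:rhi, clo:chi].max()
    calls = scores > threshold
    return ClassificationResult(
        marker=marker_img.channel or "marker",
        rule="point_max",
        threshold_used=float(threshold),
        calls=calls,
        scores=scores,
    )


def classify_nuclear_mean(
    marker_img: CalibratedImage,
    nuclei: LabelMask,
    threshold: float,
) -> ClassificationResult:
    """Mask-based rule: mean marker intensity within each segmented nucleus."""
    if nuclei.labels.shape != marker_img.shape:
        raise DimensionError("label mask does not match marker image shape")
    # always score against this marker channel (cached features may carry
    # intensities from a different channel, e.g. DAPI)
    feats = region_features(LabelMask(nuclei.labels), intensity=marker_img).features
    scores = np.array([f.mean_intensity for f in feats], dtype=float)
    calls = scores > threshold
    return ClassificationResult(
        marker=marker_img.channel or "marker",
        rule="nuclear_mean",
        threshold_used=float(threshold),
        calls=calls,
        scores=scores,
    )
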