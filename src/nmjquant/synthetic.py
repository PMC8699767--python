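"""Synthetic multi-channel micrograph generator with exact ground truth.

The generator emulates the phenotypes the analysis pipeline was designed
for, so every stage can be validated against planted truth:

* DAPI-like nuclear blobs (isotropic Gaussians) with a controllable
  marker-positive fraction in a second channel;
* bipolar spindle-shaped cell bodies (capsules: a rectangle with
  semicircular caps) versus flat rounded cells (discs of comparable area);
* myotube-like large smooth regions covering a target fraction of the
  frame, with punctate receptor clusters (uniform-intensity discs) placed
  on them, optionally co-positive in a second (rapsyn-like) channel.

Noise model: additive Gaussian with standard deviation ``peak / snr``
on top of a constant background offset of three noise sigma, clipped at
zero. The offset keeps clipping negligible so the noise sigma is directly
measurable on blank regions; Poisson shot noise is deliberately omitted.

Determinism: each generator call consumes a single NumPy ``default_rng``
stream seeded from ``SynthSpec.seed``; identical specs give bit-identical
images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import CapacityError, ParameterError
from .io_core import CalibratedImage


@dataclass
class SynthSpec:
    """Parameters of one synthetic field.

    Defaults describe the standard validation field: a 512×512 px frame at
    0.5 µm/px, 200 nuclei of radius 6 px with 60% marker-positive, spindle
    bodies of 150×8 px, 25 receptor clusters of radius 6 px on a myotube
    mask covering 40% of the frame, peak signal 1000 au at SNR 10.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    n_nuclei: int = 200
    positive_fraction: float = 0.6
    nucleus_radius_px: float = 6.0
    cell_morphology: str = "spindle"
    spindle_length_px: float = 150.0
    spindle_width_px: float = 8.0
    n_clusters: int = 25
    cluster_radius_px: float = 6.0
    myotube_fraction: float = 0.4
    rapsyn_fraction: float = 0.6
    snr: float = 10.0
    amplitude: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ParameterError("positive_fraction must lie in [0, 1]")
        if not (0.0 <= self.rapsyn_fraction <= 1.0):
            raise ParameterError("rapsyn_fraction must lie in [0, 1]")
        if not (self.snr > 0):
            raise ParameterError("snr must be > 0")
        if self.cell_morphology not in {"spindle", "round"}:
            raise ParameterError(
                f"cell_morphology must be 'spindle' or 'round', got {self.cell_morphology!r}"
            )
        for name in (
            "nucleus_radius_px",
            "spindle_length_px",
            "spindle_width_px",
            "cluster_radius_px",
            "amplitude",
            "pixel_size_um",
        ):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0")
        if self.n_nuclei < 0 or self.n_clusters < 0:
            raise ParameterError("counts must be >= 0")

    @property
    def noise_sigma(self) -> float:
        return self.amplitude / self.snr

    @property
    def background(self) -> float:
        # 3 sigma above zero: < 0.14% of noise samples clip, so the
        # blank-region standard deviation stays within 5% of noise_sigma.
        return 3.0 * self.noise_sigma


@dataclass
class ClusterRecord:
    center: tuple[float, float]
    radius_px: float
    true_area_px2: int
    true_mean_intensity: float
    rapsyn_positive: bool = False


@dataclass
class GroundTruth:
    """Planted truth accompanying each generated field."""

    nucleus_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    nucleus_positive_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    nucleus_label_mask: Optional[np.ndarray] = None
    cell_body_mask: Optional[np.ndarray] = None
    cluster_records: list[ClusterRecord] = field(default_factory=list)
    myotube_mask: Optional[np.ndarray] = None
    myotube_areas_um2: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rendering primitives


def _add_gaussian_blob(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    """Add an isotropic Gaussian of given peak amplitude, in place."""
    r0, c0 = center
    half = int(np.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - half), min(img.shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(img.shape[1], int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)
    )


def disc_mask(shape, center, radius: float) -> np.ndarray:
    """Boolean disc over pixel centers: distance from center <= radius."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def capsule_mask(shape, center, length: float, width: float, angle_rad: float) -> np.ndarray:
    """Boolean capsule: pixels within width/2 of the central segment.

    The segment has total extent ``length`` (including the semicircular
    caps), so the rendered body is ``length`` long and ``width`` wide.
    """
    half_seg = max(length / 2.0 - width / 2.0, 0.0)
    dr, dc = np.sin(angle_rad) * half_seg, np.cos(angle_rad) * half_seg
    p0 = np.array([center[0] - dr, center[1] - dc])
    p1 = np.array([center[0] + dr, center[1] + dc])
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pr, pc = rr - p0[0], cc - p0[1]
    vr, vc = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = vr**2 + vc**2
    if seg_len2 == 0:
        t = np.zeros_like(pr)
    else:
        t = np.clip((pr * vr + pc * vc) / seg_len2, 0.0, 1.0)
    dist2 = (pr - t * vr) ** 2 + (pc - t * vc) ** 2
    return dist2 <= (width / 2.0) ** 2


def _finalize(signal: np.ndarray, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    noisy = signal + spec.background + rng.normal(0.0, spec.noise_sigma, signal.shape)
    return np.clip(noisy, 0.0, None)


def _sample_centers(
    rng: np.random.Generator,
    shape,
    n: int,
    min_separation: float,
    margin: float,
    what: str,
    max_tries_per_point: int = 200,
) -> np.ndarray:
    """Rejection-sample n centers with a minimum pairwise separation."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise CapacityError(n, 0, what)
    centers: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(centers) < n:
        if tries >= budget:
            raise CapacityError(n, len(centers), what)
        tries += 1
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(
            (cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_separation**2
            for r, c in centers
        ):
            centers.append(cand)
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _choose_positive(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    n_pos = int(np.floor(fraction * n + 0.5))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:n_pos]] = True
    return flags


# ---------------------------------------------------------------------------
# generators


def generate_nuclei_image(
    spec: SynthSpec,
) -> tuple[CalibratedImage, CalibratedImage, GroundTruth]:
    """Render a DAPI channel plus a marker channel positive at a known fraction.

    Nuclei are isotropic Gaussian blobs (sigma = nucleus radius / 2) whose
    centers are at least two nucleus radii apart; the marker channel carries
    a blob only at the ``round(positive_fraction * n_nuclei)`` nuclei flagged
    positive by the seeded RNG.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    r = spec.nucleus_radius_px
    centers = _sample_centers(rng, shape, spec.n_nuclei, 2 * r + 2, 2 * r, "nuclei")
    flags = _choose_positive(rng, spec.n_nuclei, spec.positive_fraction)

    dapi = np.zeros(shape, dtype=float)
    marker = np.zeros(shape, dtype=float)
    label_mask = np.zeros(shape, dtype=np.int32)
    for i, (cr, cc) in enumerate(centers):
        _add_gaussian_blob(dapi, (cr, cc), r / 2.0, spec.amplitude)
        if flags[i]:
            _add_gaussian_blob(marker, (cr, cc), r / 2.0, spec.amplitude)
        label_mask[disc_mask(shape, (cr, cc), r)] = i + 1

    truth = GroundTruth(
        nucleus_centers=centers,
        nucleus_positive_flags=flags,
        nucleus_label_mask=label_mask,
    )
    dapi_img = CalibratedImage(_finalize(dapi, spec, rng), spec.pixel_size_um, "DAPI")
    marker_img = CalibratedImage(
        _finalize(marker, spec, rng), spec.pixel_size_um, "marker"
    )
    return dapi_img, marker_img, truth


def generate_cell_body_image(spec: SynthSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Render spindle-shaped (capsule) or round (disc) cell bodies.

    Spindles have the spec's length × width at random orientations; round
    cells are discs matched in area. One nucleus center is recorded per
    body. Bodies are kept ≥ 20 px from the frame border and well separated
    so that heavy smoothing downstream cannot merge neighbours.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    n = spec.n_nuclei
    length, width = spec.spindle_length_px, spec.spindle_width_px
    capsule_area = (length - width) * width + np.pi * (width / 2.0) ** 2
    disc_radius = float(np.sqrt(capsule_area / np.pi))
    border, sep = 20.0, 20.0  # px from frame edge; minimum body-to-body gap

    body = np.zeros(shape, dtype=bool)
    # bodies dilated by `sep`: candidates may not touch this zone, so any
    # two bodies end up >= sep apart and sigma-8 smoothing cannot merge them
    forbidden = np.zeros(shape, dtype=bool)
    centers_list: list[tuple[float, float]] = []
    tries, budget = 0, 400 * max(n, 1)
    while len(centers_list) < n:
        if tries >= budget:
            raise CapacityError(n, len(centers_list), "cell bodies")
        tries += 1
        if spec.cell_morphology == "spindle":
            angle = rng.uniform(0.0, np.pi)
            ext_r = abs(np.sin(angle)) * length / 2.0 + width / 2.0
            ext_c = abs(np.cos(angle)) * length / 2.0 + width / 2.0
        else:
            ext_r = ext_c = disc_radius
        lo_r, hi_r = border + ext_r, shape[0] - border - ext_r
        lo_c, hi_c = border + ext_c, shape[1] - border - ext_c
        if hi_r <= lo_r or hi_c <= lo_c:
            continue
        center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if spec.cell_morphology == "spindle":
            cand = capsule_mask(shape, center, length + sep, width + sep, angle)
        else:
            cand = disc_mask(shape, center, disc_radius + sep / 2.0)
        if (cand & forbidden).any():
            continue
        if spec.cell_morphology == "spindle":
            mask = capsule_mask(shape, center, length, width, angle)
        else:
            mask = disc_mask(shape, center, disc_radius)
        body |= mask
        forbidden |= cand
        centers_list.append(center)
    centers = np.asarray(centers_list, dtype=float).reshape(n, 2)

    signal = body.astype(float) * spec.amplitude
    truth = GroundTruth(
        nucleus_centers=centers,
        nucleus_positive_flags=np.ones(n, dtype=bool),
        cell_body_mask=body,
    )
    stain = CalibratedImage(_finalize(signal, spec, rng), spec.pixel_size_um, "S100b")
    return stain, truth


def generate_coculture_image(
    spec: SynthSpec,
) -> tuple[list[CalibratedImage], GroundTruth]:
    """Render a myotube channel, a receptor-cluster channel and a rapsyn channel.

    The myotube mask is a thresholded low-frequency Gaussian random field
    covering ``myotube_fraction`` of the frame (exact to pixel-count
    rounding). Receptor clusters are non-overlapping uniform-intensity discs
    placed entirely on the myotube mask; a seeded ``rapsyn_fraction`` of
    them is co-positive in the rapsyn channel.

    Returns channels in the order [myotube, btx, rapsyn].
    """
    if not (0.0 < spec.myotube_fraction < 1.0):
        raise ParameterError("myotube_fraction must lie in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape

    field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 12.0)
    cut = np.quantile(field_, 1.0 - spec.myotube_fraction)
    myotube_mask = field_ > cut

    labels, n_tubes = ndimage.label(myotube_mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    areas_px = ndimage.sum_labels(myotube_mask, labels, index=np.arange(1, n_tubes + 1))
    myotube_areas_um2 = [float(a) * spec.pixel_size_um**2 for a in areas_px]

    # cluster centers: disc must lie entirely on the myotube mask
    radius = spec.cluster_radius_px
    interior = ndimage.binary_erosion(
        myotube_mask, structure=np.ones((3, 3), bool), iterations=int(np.ceil(radius)) + 1
    )
    valid = np.argwhere(interior)
    centers: list[tuple[float, float]] = []
    tries, budget = 0, 200 * max(spec.n_clusters, 1)
    min_sep = 2 * radius + 3
    while len(centers) < spec.n_clusters:
        if tries >= budget or len(valid) == 0:
            raise CapacityError(spec.n_clusters, len(centers), "clusters")
        tries += 1
        cr, cc = valid[rng.integers(len(valid))]
        if all((cr - r) ** 2 + (cc - c) ** 2 >= min_sep**2 for r, c in centers):
            centers.append((float(cr), float(cc)))

    rapsyn_flags = _choose_positive(rng, spec.n_clusters, spec.rapsyn_fraction)

    btx = np.zeros(shape, dtype=float)
    rapsyn = np.zeros(shape, dtype=float)
    records: list[ClusterRecord] = []
    for i, center in enumerate(centers):
        mask = disc_mask(shape, center, radius)
        intensity = float(spec.amplitude * rng.uniform(0.8, 1.2))
        btx[mask] = intensity
        if rapsyn_flags[i]:
            rapsyn[mask] = spec.amplitude
        records.append(
            ClusterRecord(
                center=center,
                radius_px=radius,
                true_area_px2=int(mask.sum()),
                true_mean_intensity=intensity,
                rapsyn_positive=bool(rapsyn_flags[i]),
            )
        )

    myo_signal = myotube_mask.astype(float) * spec.amplitude
    truth = GroundTruth(
        cluster_records=records,
        myotube_mask=myotube_mask,
        myotube_areas_um2=myotube_areas_um2,
    )
    channels = [
        CalibratedImage(_finalize(myo_signal, spec, rng), spec.pixel_size_um, "myotube"),
        CalibratedImage(_finalize(btx, spec, rng), spec.pixel_size_um, "aBTX"),
        CalibratedImage(_finalize(rapsyn, spec, rng), spec.pixel_size_um, "rapsyn"),
    ]
    return channels, truth
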