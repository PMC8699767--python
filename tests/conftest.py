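"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
moments are summed per pixel, and morphology is an explicit
neighborhood sweep via array shifts.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmjquant.io_core import CalibratedImage


# ---------------------------------------------------------------------------
# independent oracles


def moment_oracle(coords: np.ndarray) -> tuple[float, float, float]:
    """(area, eccentricity, major_axis) from raw pixel-center coordinates.

    Second central moments over pixel centers, no per-pixel variance
    correction; major axis = 4 * sqrt(largest covariance eigenvalue).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = coords - coords.mean(axis=0)
    cov = d.T @ d / n
    lmin, lmax = np.linalg.eigvalsh(cov)
    lmin = max(lmin, 0.0)
    major = 4.0 * np.sqrt(lmax)
    ecc = float(np.sqrt(1.0 - lmin / lmax)) if lmax > 0 else 0.0
    return float(n), ecc, float(major)


def erode_diamond_oracle(x: np.ndarray) -> np.ndarray:
    """One erosion by the 4-connected cross; outside the frame is background."""
    p = np.pad(np.asarray(x, bool), 1, constant_values=False)
    return (
        p[1:-1, 1:-1]
        & p[:-2, 1:-1]
        & p[2:, 1:-1]
        & p[1:-1, :-2]
        & p[1:-1, 2:]
    )


def dilate_diamond_oracle(x: np.ndarray) -> np.ndarray:
    """One dilation by the 4-connected cross; nothing enters from outside."""
    p = np.pad(np.asarray(x, bool), 1, constant_values=False)
    return (
        p[1:-1, 1:-1]
        | p[:-2, 1:-1]
        | p[2:, 1:-1]
        | p[1:-1, :-2]
        | p[1:-1, 2:]
    )


def open_diamond_oracle(x: np.ndarray, n_erosions: int, n_dilations: int) -> np.ndarray:
    out = np.asarray(x, bool)
    for _ in range(n_erosions):
        out = erode_diamond_oracle(out)
    for _ in range(n_dilations):
        out = dilate_diamond_oracle(out)
    return out


def diamond_shape(radius: int) -> np.ndarray:
    """A filled L1 ball of the given radius, rendered by oracle dilations."""
    size = 2 * radius + 21
    x = np.zeros((size, size), bool)
    x[size // 2, size // 2] = True
    for _ in range(radius):
        x = dilate_diamond_oracle(x)
    return x


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def make_image(pixels, pixel_size_um: float = 0.5, channel: str = "") -> CalibratedImage:
    return CalibratedImage(np.asarray(pixels, dtype=float), pixel_size_um, channel)
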