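"""Puncta detection: measured connected components of a binary mask.

A punctum is one 8-connected component of the thresholded channel mask that
passes the per-channel size limits and whose centroid lies inside the region
of interest.  Each punctum is measured: centroid, area, equivalent circular
radius, and circularity (4*pi*area / perimeter**2).

Circularity values depend on the perimeter estimator, so one estimator is
used everywhere: boundary crack length with corner correction (see
:func:`component_perimeter`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .thresholding import BinaryMask


@dataclass
class ROISpec:
    """Region of interest: the whole image or a circle (e.g. around a soma).

    ``contains`` tests membership of a point (by the centroid rule); ``area``
    is pi*r**2 for a circle and width*height for the whole image.  A circular
    ROI is not required to lie fully inside the image bounds.
    """

    kind: str = "whole_image"
    cx: float = 0.0
    cy: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("whole_image", "circle"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle" and self.radius <= 0:
            raise ValueError("circle ROI needs a positive radius")

    def contains(self, x: float, y: float) -> bool:
        if self.kind == "whole_image":
            return True
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2

    def area(self, image_shape: tuple[int, int] | None = None) -> float:
        if self.kind == "circle":
            return math.pi * self.radius**2
        if image_shape is None:
            raise ValueError("whole-image ROI area needs the image shape")
        return float(image_shape[0] * image_shape[1])


@dataclass
class Punctum:
    """One detected connected component with its measurements.

    Centroid coordinates are 0-based ``(x = column, y = row)``.  ``pixels``
    holds the component's pixel coordinates as an ``(n, 2)`` array of
    (row, col) pairs.
    """

    id: int
    channel: str
    centroid_x: float
    centroid_y: float
    area: int
    equiv_radius: float
    circularity: float
    pixels: np.ndarray = field(repr=False)


def component_perimeter(submask: np.ndarray) -> float:
    """Perimeter of a component: crack length with corner correction.

    The crack length counts every pixel edge exposed to the background (or
    the image border).  Each 90-degree corner of that boundary — a 2x2
    neighbourhood holding exactly one (convex) or three (concave) foreground
    pixels — is shortened by replacing its two half-edges with a diagonal:

        perimeter = n_exposed_edges - (2 - sqrt(2)) / 2 * n_corners

    On test shapes this equals the corner-cut boundary polygon length: a
    rasterised disc of radius ~10 px measures within ~4% of 2*pi*r, while a
    1-px-wide line is properly penalised.
    """
    m = np.pad(np.asarray(submask, dtype=np.int8), 1)
    edges = 0
    for axis in (0, 1):
        for shift in (1, -1):
            edges += int(((m - np.roll(m, shift, axis=axis)) == 1).sum())
    window = m[:-1, :-1] + m[1:, :-1] + m[:-1, 1:] + m[1:, 1:]
    corners = int(((window == 1) | (window == 3)).sum())
    return edges - (2.0 - math.sqrt(2.0)) / 2.0 * corners


def _circularity(area: int, perimeter: float) -> float:
    if area == 1 or perimeter <= 0:
        return 1.0  # single pixels are defined as perfectly compact
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def measure_circularity(pixels: np.ndarray) -> float:
    """Circularity 4*pi*area / perimeter**2 of one component's pixel set.

    Values above 1 caused by discretisation are clamped to 1; a single-pixel
    component is defined as perfectly compact (1.0).
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("component must be nonempty")
    if pixels.ndim != 2 or pixels.shape[1] != 2:
        raise ValueError("pixels must be an (n, 2) array of (row, col) pairs")
    area = pixels.shape[0]
    if area == 1:
        return 1.0
    r0, c0 = pixels.min(axis=0)
    sub = np.zeros((pixels[:, 0].max() - r0 + 1, pixels[:, 1].max() - c0 + 1), dtype=bool)
    sub[pixels[:, 0] - r0, pixels[:, 1] - c0] = True
    return _circularity(area, component_perimeter(sub))


def detect_puncta(
    mask: BinaryMask,
    channel: str,
    min_size: int = 4,
    max_size: float = math.inf,
    roi: ROISpec | None = None,
) -> list[Punctum]:
    """Extract measured puncta from a binary mask.

    Connected components are computed with 8-connectivity.  Components with
    area outside [min_size, max_size] are discarded, as are components whose
    centroid lies outside the ROI (membership is decided by the centroid so
    each punctum is counted exactly once, unambiguously at ROI edges).  The
    result is sorted by (centroid_y, centroid_x) with ids assigned in that
    order, for determinism.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    roi = roi or ROISpec()
    labels = measure.label(mask.mask, connectivity=2)
    found = []
    for region in measure.regionprops(labels):
        area = int(region.area)
        if area < min_size or area > max_size:
            continue
        cy, cx = region.centroid
        if not roi.contains(cx, cy):
            continue
        circularity = _circularity(area, component_perimeter(region.image))
        found.append(
            (
                cy,
                cx,
                Punctum(
                    id=0,
                    channel=channel,
                    centroid_x=cx,
                    centroid_y=cy,
                    area=area,
                    equiv_radius=math.sqrt(area / math.pi),
                    circularity=circularity,
                    pixels=region.coords.copy(),
                ),
            )
        )
    found.sort(key=lambda t: (t[0], t[1]))
    puncta = []
    for i, (_, _, p) in enumerate(found, start=1):
        p.id = i
        puncta.append(p)
    return puncta
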