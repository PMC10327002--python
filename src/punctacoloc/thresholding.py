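"""Converting channel planes into binary foreground masks.

Four routes are provided:

* ``fixed_threshold`` — one intensity cutoff applied to the whole plane
  (foreground is intensity >= value, the ImageJ-style inclusive pass).
* ``thresholds_from_file`` — per-image, per-channel cutoffs read from a CSV
  table; this replaces interactive manual thresholding and lets a previous
  run's emitted threshold log reproduce an analysis bit-exactly.
* ``synquant_threshold`` — a statistical spot detector in the SynQuant
  spirit, re-implemented here in simplified form: candidate objects are
  connected components collected over a descending intensity-level sweep and
  accepted by a local-contrast z-score against a surrounding ring plus
  size, fill and aspect-ratio filters.  It is NOT a port of the original
  component-tree algorithm; behaviour is defined by this module's contract.
* ``external_mask`` — ingest a probability map or binary mask produced by an
  external pixel classifier (e.g. a trained ilastik model).

Every mask-producing call can append a :class:`ThresholdRecord` to a log so
that all thresholding decisions of a run are auditable and replayable.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class BinaryMask:
    """A boolean foreground mask with the same shape as its source plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        self.mask = self.mask.astype(bool)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class ThresholdRecord:
    """Audit record of one thresholding decision.

    ``value`` is present exactly for the fixed-value methods (``fixed`` and
    ``from_file``); the statistical and external methods have no single
    cutoff value.
    """

    image_name: str
    channel: str
    method: str
    value: int | None = None

    def __post_init__(self) -> None:
        has_value = self.value is not None
        needs_value = self.method in ("fixed", "from_file")
        if has_value != needs_value:
            raise ValueError(
                f"method {self.method!r} "
                + ("requires" if needs_value else "must not carry")
                + " a threshold value"
            )


@dataclass
class SynQuantParams:
    """Tunable parameters of the statistical spot detector.

    Defaults follow the settings used for simulated two-channel synapse
    data: z-score threshold 10, object size 10–100 px², minimum fill 0.5,
    maximum width-to-height ratio 4, estimated noise standard deviation 12
    intensity units.  ``z_axis_multiplier`` is accepted for configuration
    parity but has no effect in this 2D pipeline.
    """

    z_threshold: float = 10.0
    min_size: int = 10
    max_size: int = 100
    min_fill: float = 0.5
    max_wh_ratio: float = 4.0
    noise_sd: float = 12.0
    z_axis_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if not 0 < self.min_fill <= 1:
            raise ValueError("min_fill must be in (0, 1]")
        if self.max_wh_ratio < 1:
            raise ValueError("max_wh_ratio must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.z_axis_multiplier != 1.0:
            logger.warning(
                "z_axis_multiplier has no effect in the 2D pipeline; value %g ignored",
                self.z_axis_multiplier,
            )


def _check_plane(plane: np.ndarray) -> None:
    if plane.ndim != 2 or plane.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) 2D plane")


def fixed_threshold(
    plane: np.ndarray,
    value: int,
    *,
    image_name: str = "",
    channel: str = "",
    method: str = "fixed",
    log: list[ThresholdRecord] | None = None,
) -> BinaryMask:
    """Threshold a plane at a fixed intensity cutoff (foreground >= value)."""
    _check_plane(plane)
    if not 0 <= value <= 255:
        raise ValueError("threshold value must be in [0, 255]")
    if log is not None:
        log.append(ThresholdRecord(image_name, channel, method, int(value)))
    return BinaryMask(plane >= value)


def thresholds_from_file(csv_path: str | os.PathLike) -> dict[tuple[str, str], int]:
    """Read a per-image, per-channel threshold table.

    The CSV must have columns ``image``, ``channel`` and ``value`` (extra
    columns, e.g. the ``method`` column of an emitted audit log, are
    ignored).  Duplicate (image, channel) pairs are an error.
    """
    table = pd.read_csv(csv_path, comment="#")
    missing_cols = {"image", "channel", "value"} - set(table.columns)
    if missing_cols:
        raise ValueError(f"threshold file {csv_path!r} lacks columns: {sorted(missing_cols)}")
    table = table.dropna(subset=["value"])
    keys = list(zip(table["image"].astype(str), table["channel"].astype(str)))
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ValueError(f"duplicate (image, channel) pairs in threshold file: {sorted(dupes)}")
    return {k: int(v) for k, v in zip(keys, table["value"])}


def require_thresholds(
    table: dict[tuple[str, str], int], pairs: list[tuple[str, str]]
) -> None:
    """Fail loudly if any analysed (image, channel) pair lacks a threshold."""
    missing = [p for p in pairs if p not in table]
    if missing:
        raise KeyError(
            "threshold file is missing values for image/channel pairs: "
            + ", ".join(f"{img}/{ch}" for img, ch in missing)
        )


def _ring_zscore(
    plane: np.ndarray, comp: np.ndarray, noise_sd: float, ring_width: int = 2
) -> float | None:
    """Contrast z-score of a component against its 2-px surrounding ring."""
    ring = ndimage.binary_dilation(comp, structure=_STRUCT8, iterations=ring_width) & ~comp
    n_in = int(comp.sum())
    n_ring = int(ring.sum())
    if n_ring == 0:
        return None
    mean_in = float(plane[comp].mean())
    mean_ring = float(plane[ring].mean())
    return (mean_in - mean_ring) / (noise_sd * math.sqrt(1.0 / n_in + 1.0 / n_ring))


def synquant_threshold(
    plane: np.ndarray,
    params: SynQuantParams | None = None,
    *,
    image_name: str = "",
    channel: str = "",
    log: list[ThresholdRecord] | None = None,
) -> BinaryMask:
    """Statistical spot detection by a descending intensity-level sweep.

    For each intensity level present in the plane (highest first), connected
    components (8-connectivity) of ``plane >= level`` are candidate objects.
    A candidate is accepted iff

    * ``min_size <= area <= max_size``,
    * bounding-box fill ``area / (w*h) >= min_fill``,
    * bounding-box aspect ``max(w, h) / min(w, h) <= max_wh_ratio``, and
    * the contrast z-score against a 2-px surrounding ring,
      ``(mean_in - mean_ring) / (noise_sd * sqrt(1/n_in + 1/n_ring))``,
      is at least ``z_threshold``.

    Overlapping accepted candidates (the same physical object grows across
    levels) are resolved greedily by descending z-score: a candidate is kept
    only if none of its pixels is already claimed.  The sweep stops once the
    level covers more than half of the plane, where no compact small object
    can still emerge; a degenerate constant plane yields an empty mask.
    Intensity offsets cancel in the z statistic, so the output is invariant
    to adding a constant to the whole plane (up to saturation).
    """
    _check_plane(plane)
    if params is None:
        params = SynQuantParams()
    if log is not None:
        log.append(ThresholdRecord(image_name, channel, "synquant"))
    out = np.zeros(plane.shape, dtype=bool)
    if plane.max() == plane.min():
        return BinaryMask(out)

    candidates: list[tuple[float, int, tuple[np.ndarray, np.ndarray]]] = []
    seen: set[tuple[int, int, int, int, int]] = set()
    h_img, w_img = plane.shape
    for level in np.unique(plane)[::-1]:
        if level == 0:
            continue
        fg = plane >= level
        if fg.mean() > 0.5:
            break
        labels, n = ndimage.label(fg, structure=_STRUCT8)
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())
        slices = ndimage.find_objects(labels)
        for i, sl in enumerate(slices, start=1):
            area = int(areas[i])
            if not params.min_size <= area <= params.max_size:
                continue
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            if max(w, h) / min(w, h) > params.max_wh_ratio:
                continue
            if area / (w * h) < params.min_fill:
                continue
            key = (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop, area)
            if key in seen:  # unchanged since a higher level; already scored
                continue
            seen.add(key)
            r0 = max(sl[0].start - 3, 0)
            r1 = min(sl[0].stop + 3, h_img)
            c0 = max(sl[1].start - 3, 0)
            c1 = min(sl[1].stop + 3, w_img)
            comp = labels[r0:r1, c0:c1] == i
            z = _ring_zscore(plane[r0:r1, c0:c1], comp, params.noise_sd)
            if z is None or z < params.z_threshold:
                continue
            rows, cols = np.nonzero(comp)
            candidates.append((z, int(level), (rows + r0, cols + c0)))

    # Greedy non-overlapping selection by z-score (ties: higher level first),
    # so each pixel belongs to the strongest object that claims it.
    for z, level, (rows, cols) in sorted(candidates, key=lambda t: (-t[0], -t[1])):
        if out[rows, cols].any():
            continue
        out[rows, cols] = True
    return BinaryMask(out)


def external_mask(
    plane: np.ndarray,
    mask_path: str | os.PathLike,
    *,
    image_name: str = "",
    channel: str = "",
    log: list[ThresholdRecord] | None = None,
) -> BinaryMask:
    """Load an externally produced probability map or binary mask.

    Float-valued maps are binarised at probability 0.5.  Integer images are
    passed through as binary when their values are 0/1, otherwise treated as
    8-bit probability maps and binarised at 128.  ``.npy`` arrays and any
    raster format readable by the image loaders are accepted; the mask must
    match the plane's shape.
    """
    _check_plane(plane)
    path = os.fspath(mask_path)
    if path.lower().endswith(".npy"):
        arr = np.load(path)
    elif path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.shape != plane.shape:
        raise ValueError(
            f"external mask shape {arr.shape} does not match plane shape {plane.shape}"
        )
    if np.issubdtype(arr.dtype, np.floating):
        mask = arr >= 0.5
    elif arr.max(initial=0) <= 1:
        mask = arr.astype(bool)
    else:
        mask = arr >= 128
    if log is not None:
        log.append(ThresholdRecord(image_name, channel, "external_mask"))
    return BinaryMask(mask)


def records_to_frame(records: list[ThresholdRecord]) -> pd.DataFrame:
    """Tabulate threshold records with the audit-log CSV schema."""
    return pd.DataFrame(
        [
            {
                "image": r.image_name,
                "channel": r.channel,
                "method": r.method,
                "value": r.value,
            }
            for r in records
        ],
        columns=["image", "channel", "method", "value"],
    )
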