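"""Reading microscopy images and normalising them into 8-bit RGB working copies.

The analysis pipeline operates on a canonical representation: a 2D image with
three 8-bit planes playing the roles *red*, *green* and *blue* (pre-synaptic,
post-synaptic, optional third marker).  Confocal z-stacks are first collapsed
into grouped maximum-intensity projections, each of which is then analysed as
an independent image.

Coordinate convention used throughout the package: pixel coordinates are
0-based, ``(x = column, y = row)``, origin at the top-left corner.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Channel roles recognised by the pipeline, in canonical order.
ROLES = ("red", "green", "blue")

#: Image file extensions discovered by the batch driver.
IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".bmp")


class ImageNameError(ValueError):
    """Raised for file names that violate the single-extension naming rule."""


def parse_image_name(filename: str) -> str:
    """Return the image name (stem) for *filename*, enforcing the naming rule.

    Image names may contain only one ``.`` character, the one preceding the
    file extension.  Names such as ``image1.lif.tif`` (left behind by format
    converters) are rejected because downstream bookkeeping uses the ``.`` to
    split name from extension.
    """
    base = os.path.basename(filename)
    parts = base.split(".")
    if len(parts) > 2:
        raise ImageNameError(
            f"image file name {base!r} contains more than one '.' character; "
            "image names must contain only one '.' (the file-extension "
            "separator). Rename the file, e.g. 'image1.lif.tif' -> 'image1.tif'."
        )
    return parts[0]


@dataclass
class RawImage:
    """A single multi-channel 2D image at its original bit depth.

    ``data`` is a ``(height, width, n_channels)`` unsigned-integer array.
    """

    name: str
    data: np.ndarray
    pixel_size: float | None = None
    source_projection_index: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim == 2:
            self.data = self.data[:, :, np.newaxis]
        if self.data.ndim != 3:
            raise ValueError("RawImage data must be (height, width, channels)")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass
class ZStack:
    """An ordered stack of multi-channel optical sections.

    ``planes`` is a list of ``(height, width, n_channels)`` arrays in
    acquisition order.
    """

    name: str
    planes: list[np.ndarray]
    z_step: float | None = None

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("a ZStack needs at least one plane")
        shape = self.planes[0].shape
        for p in self.planes:
            if p.shape != shape:
                raise ValueError("all z-stack planes must share shape and channel count")

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class ChannelMapping:
    """Assignment of input channel indices to the red/green/blue roles.

    ``channels`` maps a role name to the index of the input channel that
    fills it.  Red and green must always be assigned; blue is optional.
    """

    channels: dict[str, int]
    mode: str = "two-channel"

    def __post_init__(self) -> None:
        for role in self.channels:
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if "red" not in self.channels or "green" not in self.channels:
            raise ValueError("red and green roles must both be assigned")

    @classmethod
    def two_channel(cls, red: int = 0, green: int = 1) -> "ChannelMapping":
        return cls({"red": red, "green": green}, mode="two-channel")

    @classmethod
    def three_channel(cls, red: int = 0, green: int = 1, blue: int = 2) -> "ChannelMapping":
        return cls({"red": red, "green": green, "blue": blue}, mode="three-channel")

    @classmethod
    def pick(cls, **channels: int) -> "ChannelMapping":
        return cls(dict(channels), mode="pick-channels")


@dataclass
class RGBImage:
    """The canonical analysis unit: three 8-bit planes keyed by role.

    All three planes share the same shape; unassigned roles are all-zero.
    """

    name: str
    planes: dict[str, np.ndarray] = field(repr=False)
    pixel_size: float | None = None
    source_projection_index: int | None = None

    def __post_init__(self) -> None:
        if "." in self.name:
            raise ImageNameError(f"image name {self.name!r} may not contain '.'")
        shapes = {role: p.shape for role, p in self.planes.items()}
        if set(self.planes) != set(ROLES):
            raise ValueError("an RGBImage needs exactly the red, green and blue planes")
        if len(set(shapes.values())) != 1:
            raise ValueError(f"planes disagree in shape: {shapes}")
        for role, p in self.planes.items():
            if p.dtype != np.uint8:
                raise ValueError(f"{role} plane must be 8-bit (uint8), got {p.dtype}")

    @property
    def height(self) -> int:
        return self.planes["red"].shape[0]

    @property
    def width(self) -> int:
        return self.planes["red"].shape[1]

    def to_array(self) -> np.ndarray:
        """Stack the planes into an ``(height, width, 3)`` uint8 array."""
        return np.stack([self.planes[r] for r in ROLES], axis=-1)


def _split_channel_axis(arr: np.ndarray) -> np.ndarray:
    """Normalise a 2D/3D page to ``(height, width, channels)``.

    A 3D page is treated as channel-first or channel-last depending on which
    axis has length <= 4 (microscopy images have few channels and many
    pixels); ties are resolved in favour of channel-last, the TIFF default.
    """
    if arr.ndim == 2:
        return arr[:, :, np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret page of shape {arr.shape}")
    if arr.shape[2] <= 4:
        return arr
    if arr.shape[0] <= 4:
        return np.moveaxis(arr, 0, -1)
    raise ValueError(
        f"page of shape {arr.shape} has no axis that looks like channels (length <= 4)"
    )


def load_image(path: str | os.PathLike) -> RawImage | ZStack:
    """Load a raster image file, preserving its original bit depth.

    Multi-page TIFFs become a :class:`ZStack`; single-page files become a
    :class:`RawImage`.  TIFF is the preferred input; PNG and BMP are accepted
    for 8-bit images.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    name = parse_image_name(path)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - report the offending file
        raise IOError(f"could not read image file {path!r}: {exc}") from exc

    if arr.ndim == 2:
        return RawImage(name, arr[:, :, np.newaxis])
    if arr.ndim == 3:
        # Either a single multi-channel page or a stack of single-channel pages.
        if arr.shape[0] <= 4 or arr.shape[2] <= 4:
            return RawImage(name, _split_channel_axis(arr))
        return ZStack(name, [p[:, :, np.newaxis] for p in arr])
    if arr.ndim == 4:
        return ZStack(name, [_split_channel_axis(p) for p in arr])
    raise IOError(f"unsupported image dimensionality {arr.shape} in {path!r}")


def _rescale_to_8bit(plane: np.ndarray) -> np.ndarray:
    """Rescale one unsigned-integer plane to 8-bit over its nominal range.

    The full nominal range of the dtype is used (``/ (2**bits - 1) * 255``
    with round-half-up), not a per-image min-max stretch, so the conversion
    is data independent and reproducible.  Per-image stretching is available
    only through the explicit brightness-normalisation preprocessing step.
    """
    if plane.dtype == np.uint8:
        return plane.copy()
    if not np.issubdtype(plane.dtype, np.unsignedinteger):
        raise ValueError(f"unsupported plane dtype {plane.dtype}; expected unsigned integer")
    maxval = np.iinfo(plane.dtype).max
    scaled = np.floor(plane.astype(np.float64) * (255.0 / maxval) + 0.5)
    return scaled.astype(np.uint8)


def to_rgb(image: RawImage | np.ndarray, mapping: ChannelMapping) -> RGBImage:
    """Convert a raw multi-channel image to the canonical 8-bit RGB form.

    Each assigned channel is rescaled to 8-bit over the nominal range of its
    bit depth; roles without an assigned channel become all-zero planes.
    """
    if isinstance(image, np.ndarray):
        image = RawImage("image", image)
    planes: dict[str, np.ndarray] = {}
    for role in ROLES:
        if role in mapping.channels:
            idx = mapping.channels[role]
            if idx < 0 or idx >= image.n_channels:
                raise ValueError(
                    f"mapping assigns role {role!r} to channel {idx}, but the "
                    f"image has only {image.n_channels} channel(s)"
                )
            planes[role] = _rescale_to_8bit(image.data[:, :, idx])
        else:
            planes[role] = np.zeros((image.height, image.width), dtype=np.uint8)
    return RGBImage(
        name=image.name,
        planes=planes,
        pixel_size=image.pixel_size,
        source_projection_index=image.source_projection_index,
    )


def grouped_max_projection(stack: ZStack, group_size: int) -> list[RawImage]:
    """Collapse a z-stack into grouped maximum-intensity projections.

    Planes are partitioned in acquisition order into consecutive groups of
    ``group_size``; each group yields one per-pixel, per-channel maximum.
    A trailing remainder group that does not fill ``group_size`` planes is
    dropped (a partial projection would have a different effective depth)
    and a warning is logged.  ``group_size=1`` returns each plane unchanged.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n_groups, remainder = divmod(stack.n_planes, group_size)
    if remainder:
        logger.warning(
            "z-stack %r: dropping %d trailing plane(s) that do not fill a "
            "complete group of %d",
            stack.name,
            remainder,
            group_size,
        )
    projections = []
    for k in range(n_groups):
        group = stack.planes[k * group_size : (k + 1) * group_size]
        proj = np.max(np.stack(group, axis=0), axis=0)
        projections.append(RawImage(stack.name, proj, source_projection_index=k))
    return projections


def projection_count(n_planes: int, group_size: int) -> int:
    """Number of projections produced for a stack of ``n_planes`` planes."""
    return n_planes // group_size


def save_rgb(image: RGBImage, path: str | os.PathLike) -> None:
    """Save an :class:`RGBImage` losslessly (TIFF or PNG by extension)."""
    path = os.fspath(path)
    arr = image.to_array()
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
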