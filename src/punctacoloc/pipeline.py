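"""Batch driver: run the full analysis over an experiment directory.

The experiment directory contains one or more subfolders of images (groups
of an experiment are commonly split between subfolders, but this does not
affect the analysis).  Every image — or every grouped max-projection of a
z-stack — is preprocessed, thresholded, measured and colocalized, and the
results are written as CSV tables plus per-image feedback images:

* ``Summary.csv`` — one row per analysed image/projection with puncta
  counts, colocalization counts, thresholds, size settings and ROI area.
* ``thresholds.csv`` — the audit log of every thresholding decision; under
  the ``from_file`` method this same file reproduces the run bit-exactly.
* ``red_puncta.csv`` / ``green_puncta.csv`` / ``blue_puncta.csv`` and
  ``coloc_puncta.csv`` — per-punctum and per-colocalization tables.
* ``<name>_colocs`` overlay images and ``<name>_<channel>_thresholded``
  binary masks for visual validation.

All CSVs use 0-based pixel coordinates, (x = column, y = row), origin
top-left, as stated in their header comment.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk

from .colocalization import (
    ColocalizationRecord,
    circular_colocalize_image,
    dedup_count,
    pixel_colocalize_image,
)
from .image_io import (
    IMAGE_EXTENSIONS,
    ChannelMapping,
    ImageNameError,
    RGBImage,
    ZStack,
    grouped_max_projection,
    load_image,
    to_rgb,
)
from .preprocessing import PreprocessConfig, preprocess_plane
from .puncta import Punctum, ROISpec, detect_puncta
from .thresholding import (
    BinaryMask,
    SynQuantParams,
    ThresholdRecord,
    fixed_threshold,
    records_to_frame,
    require_thresholds,
    synquant_threshold,
    thresholds_from_file,
)

logger = logging.getLogger(__name__)

COORD_COMMENT = "# pixel coordinates are 0-based, (x=column, y=row), origin top-left\n"


@dataclass
class RunConfig:
    """Everything needed to (re)run one batch analysis."""

    experiment_dir: str
    output_dir: str
    mode: str = "two-channel"  # two-channel | three-channel
    channel_map: dict = field(default_factory=dict)  # role -> input channel index
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    threshold_method: str = "fixed"  # fixed | from_file | synquant
    threshold_values: dict = field(default_factory=dict)  # role -> intensity
    threshold_file: str | None = None
    synquant: SynQuantParams = field(default_factory=SynQuantParams)
    roi: ROISpec = field(default_factory=ROISpec)
    analysis_mode: str = "circular"  # circular | pixel
    group_size: int = 3
    min_size: dict = field(default_factory=dict)  # role -> px^2 (default 4)
    max_size: dict = field(default_factory=dict)  # role -> px^2 (default inf)
    coloc_min_size: int = 1
    seed: int = 0

    @property
    def channels(self) -> tuple[str, ...]:
        return ("red", "green", "blue") if self.mode == "three-channel" else ("red", "green")

    def mapping(self) -> ChannelMapping:
        if self.channel_map:
            return ChannelMapping.pick(**self.channel_map)
        if self.mode == "three-channel":
            return ChannelMapping.three_channel()
        return ChannelMapping.two_channel()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "synquant" in raw:
            raw["synquant"] = SynQuantParams(**raw["synquant"])
        if "roi" in raw:
            raw["roi"] = ROISpec(**raw["roi"])
        return cls(**raw)

    def echo(self) -> dict:
        out = asdict(self)
        out["roi"] = asdict(self.roi)
        return out


def _threshold_channel(
    plane: np.ndarray,
    role: str,
    image_name: str,
    config: RunConfig,
    table: dict | None,
    log: list[ThresholdRecord],
) -> BinaryMask:
    if config.threshold_method == "fixed":
        value = int(config.threshold_values.get(role, 50))
        return fixed_threshold(plane, value, image_name=image_name, channel=role, log=log)
    if config.threshold_method == "from_file":
        value = table[(image_name, role)]
        return fixed_threshold(
            plane, value, image_name=image_name, channel=role, method="from_file", log=log
        )
    if config.threshold_method == "synquant":
        return synquant_threshold(
            plane, config.synquant, image_name=image_name, channel=role, log=log
        )
    raise ValueError(f"unknown threshold method {config.threshold_method!r}")


def analyze_image(
    rgb: RGBImage,
    config: RunConfig,
    image_name: str,
    threshold_table: dict | None = None,
    log: list[ThresholdRecord] | None = None,
) -> tuple[dict, dict[str, list[Punctum]], list[ColocalizationRecord], dict[str, BinaryMask]]:
    """Analyse one RGB image: preprocess, threshold, detect, colocalize.

    Returns the Summary row, the per-channel puncta, the colocalization
    records and the per-channel masks.
    """
    log = [] if log is None else log
    masks: dict[str, BinaryMask] = {}
    puncta: dict[str, list[Punctum]] = {}
    for role in config.channels:
        plane = preprocess_plane(rgb.planes[role], config.preprocess)
        masks[role] = _threshold_channel(
            plane, role, image_name, config, threshold_table, log
        )
        puncta[role] = detect_puncta(
            masks[role],
            role,
            min_size=int(config.min_size.get(role, 4)),
            max_size=float(config.max_size.get(role, math.inf)),
            roi=config.roi,
        )

    if config.analysis_mode == "circular":
        if config.mode == "three-channel":
            raise ValueError("circular analysis supports two channels; use pixel mode")
        records = circular_colocalize_image(
            puncta["red"], puncta["green"], image_name=image_name
        )
    elif config.analysis_mode == "pixel":
        records = pixel_colocalize_image(
            [masks[r] for r in config.channels],
            min_size=config.coloc_min_size,
            roi=config.roi,
            image_name=image_name,
        )
    else:
        raise ValueError(f"unknown analysis mode {config.analysis_mode!r}")

    thr_by_role = {
        (r.channel): (r.value if r.value is not None else r.method)
        for r in log
        if r.image_name == image_name
    }
    shape = (rgb.height, rgb.width)
    row = {
        "image_name": image_name,
        "n_red": len(puncta["red"]),
        "n_green": len(puncta["green"]),
        "n_blue": len(puncta.get("blue", [])),
        "n_coloc_records": len(records),
        "n_coloc_dedup": dedup_count(records),
        "red_threshold": thr_by_role.get("red", ""),
        "green_threshold": thr_by_role.get("green", ""),
        "blue_threshold": thr_by_role.get("blue", ""),
        "min_size_red": int(config.min_size.get("red", 4)),
        "min_size_green": int(config.min_size.get("green", 4)),
        "min_size_blue": int(config.min_size.get("blue", 4)),
        "roi_area": config.roi.area(shape),
    }
    return row, puncta, records, masks


def render_overlay(
    image: RGBImage,
    records: list[ColocalizationRecord],
    radius: int = 3,
    path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Feedback image: the input with a white disc at each record center."""
    canvas = image.to_array().copy()
    for r in records:
        rr, cc = disk((r.center_y, r.center_x), radius, shape=canvas.shape[:2])
        canvas[rr, cc] = 255
    if path is not None:
        iio.imwrite(os.fspath(path), canvas)
    return canvas


def write_thresholded_channels(
    masks: dict[str, BinaryMask], name: str, out_dir: str | os.PathLike, ext: str = ".png"
) -> list[str]:
    """Save each channel's binary mask as a 0/255 image for inspection."""
    paths = []
    for role, m in masks.items():
        path = os.path.join(os.fspath(out_dir), f"{name}_{role}_thresholded{ext}")
        iio.imwrite(path, (m.mask.astype(np.uint8)) * 255)
        paths.append(path)
    return paths


def _puncta_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["image", "channel", "id", "x", "y", "area", "equiv_radius", "circularity"]
    )


def _write_csv(frame: pd.DataFrame, path: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(COORD_COMMENT)
        frame.to_csv(fh, index=False, float_format="%.6g")


def _discover_images(experiment_dir: str) -> list[str]:
    subfolders = sorted(
        e.path for e in os.scandir(experiment_dir) if e.is_dir()
    )
    if not subfolders:
        raise ValueError(
            f"experiment directory {experiment_dir!r} has no subfolders; the "
            "directory must include at least one subfolder of images"
        )
    files = []
    for sub in subfolders:
        files.extend(
            sorted(
                e.path
                for e in os.scandir(sub)
                if e.is_file() and e.name.lower().endswith(IMAGE_EXTENSIONS)
            )
        )
    return files


def run_experiment(config: RunConfig) -> str:
    """Run the batch analysis described by *config*; returns the output dir.

    Processing is all-or-nothing per image: a failing image is skipped and
    reported at the end, without aborting the batch.
    """
    files = _discover_images(config.experiment_dir)
    os.makedirs(config.output_dir, exist_ok=True)
    table = None
    log: list[ThresholdRecord] = []
    summary_rows: list[dict] = []
    puncta_rows: dict[str, list[dict]] = {r: [] for r in ("red", "green", "blue")}
    coloc_rows: list[dict] = []
    failures: list[tuple[str, str]] = []
    mapping = config.mapping()

    analysis_units: list[tuple[str, RGBImage]] = []
    for path in files:
        try:
            loaded = load_image(path)
        except (ImageNameError, IOError) as exc:
            logger.error("skipping %s: %s", path, exc)
            failures.append((path, str(exc)))
            continue
        if isinstance(loaded, ZStack):
            for proj in grouped_max_projection(loaded, config.group_size):
                rgb = to_rgb(proj, mapping)
                analysis_units.append(
                    (f"{rgb.name}_proj{proj.source_projection_index}", rgb)
                )
        else:
            analysis_units.append((loaded.name, to_rgb(loaded, mapping)))

    if config.threshold_method == "from_file":
        if not config.threshold_file:
            raise ValueError("threshold_method 'from_file' needs threshold_file")
        table = thresholds_from_file(config.threshold_file)
        require_thresholds(
            table, [(name, role) for name, _ in analysis_units for role in config.channels]
        )

    for image_name, rgb in analysis_units:
        try:
            row, puncta, records, masks = analyze_image(
                rgb, config, image_name, threshold_table=table, log=log
            )
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            logger.error("analysis failed for %s: %s", image_name, exc)
            failures.append((image_name, str(exc)))
            continue
        summary_rows.append(row)
        for role, plist in puncta.items():
            for p in plist:
                puncta_rows[role].append(
                    {
                        "image": image_name,
                        "channel": role,
                        "id": p.id,
                        "x": p.centroid_x,
                        "y": p.centroid_y,
                        "area": p.area,
                        "equiv_radius": p.equiv_radius,
                        "circularity": p.circularity,
                    }
                )
        for r in records:
            coloc_rows.append(
                {
                    "image": image_name,
                    "method": r.method,
                    "center_x": r.center_x,
                    "center_y": r.center_y,
                    "overlap_area": r.overlap_area,
                    "red_id": r.red_id,
                    "green_id": r.green_id,
                    "blue_id": r.blue_id,
                }
            )
        render_overlay(
            rgb, records, path=os.path.join(config.output_dir, f"{image_name}_colocs.png")
        )
        write_thresholded_channels(masks, image_name, config.output_dir)

    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "image_name",
            "n_red",
            "n_green",
            "n_blue",
            "n_coloc_records",
            "n_coloc_dedup",
            "red_threshold",
            "green_threshold",
            "blue_threshold",
            "min_size_red",
            "min_size_green",
            "min_size_blue",
            "roi_area",
        ],
    )
    _write_csv(summary, os.path.join(config.output_dir, "Summary.csv"))
    _write_csv(records_to_frame(log), os.path.join(config.output_dir, "thresholds.csv"))
    for role in config.channels:
        _write_csv(
            _puncta_frame(puncta_rows[role]),
            os.path.join(config.output_dir, f"{role}_puncta.csv"),
        )
    _write_csv(
        pd.DataFrame(
            coloc_rows,
            columns=[
                "image",
                "method",
                "center_x",
                "center_y",
                "overlap_area",
                "red_id",
                "green_id",
                "blue_id",
            ],
        ),
        os.path.join(config.output_dir, "coloc_puncta.csv"),
    )
    with open(os.path.join(config.output_dir, "run_log.json"), "w") as fh:
        json.dump(
            {
                "config": config.echo(),
                "n_images_analyzed": len(summary_rows),
                "failures": failures,
            },
            fh,
            indent=2,
            default=str,
        )
    if failures:
        logger.warning("%d image(s) failed: %s", len(failures), [f[0] for f in failures])
    return config.output_dir
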