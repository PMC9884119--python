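"""TIFF and configuration I/O.

Stacks are written as ImageJ-style multi-channel TIFFs with axes ZCYX, the
xy pixel size in the resolution tags and the z step in the ImageJ
``spacing`` field, so calibration round-trips. Acquisitions are expected at
8-bit depth (the contract of the published protocol); deeper data is
rejected unless explicitly allowed. Label volumes are 16-bit single-channel
TIFFs. Pipeline configuration is a YAML file with strict (unknown keys
rejected) parsing into the dataclass parameter blocks.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Calibration, ImageStack, LabelVolume
from .quantify import QCThresholds
from .segmentation import SegmentationParams


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as an ImageJ-compatible ZCYX TIFF."""
    res = 1.0 / stack.calibration.pixel_size_um
    tifffile.imwrite(
        path,
        stack.data,
        imagej=True,
        resolution=(res, res),
        metadata={
            "axes": "ZCYX",
            "spacing": stack.calibration.z_step_um,
            "unit": "um",
            "Labels": list(stack.channel_names) * stack.n_z,
            "channel_names": ",".join(stack.channel_names),
        },
    )


def read_stack(
    path,
    channel_names: tuple[str, ...] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    allow_any_depth: bool = False,
) -> ImageStack:
    """Read a calibrated multi-channel z-stack.

    Calibration and channel names come from the file's ImageJ metadata when
    present; explicit arguments override. Missing z spacing or pixel size
    without an override is an error naming the missing field, as is non-
     8-bit data without ``allow_any_depth``.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ij = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags.get("XResolution")

    if data.dtype != np.uint8 and not allow_any_depth:
        raise ValueError(
            f"{path}: expected 8-bit data, got {data.dtype}; "
            "pass allow_any_depth=True to accept"
        )

    # reduce to ZCYX
    if axes in ("ZCYX", "CZYX"):
        if axes == "CZYX":
            data = np.moveaxis(data, 0, 1)
    elif axes == "ZYX":
        data = data[:, None]
    elif axes == "YX":
        data = data[None, None]
    else:
        raise ValueError(f"{path}: cannot interpret TIFF axes {axes!r}")

    if z_step_um is None:
        z_step_um = ij.get("spacing")
        if z_step_um is None:
            raise ValueError(f"{path}: missing z spacing metadata; pass z_step_um")
    if pixel_size_um is None:
        if xres is not None and xres.value[0]:
            num, den = xres.value
            pixel_size_um = den / num
        else:
            raise ValueError(f"{path}: missing pixel size metadata; pass pixel_size_um")

    if channel_names is None:
        meta_names = ij.get("channel_names")
        if meta_names:
            channel_names = tuple(meta_names.split(","))
        else:
            channel_names = tuple(f"ch{i}" for i in range(data.shape[1]))
    if len(channel_names) != data.shape[1]:
        raise ValueError(
            f"{path}: {data.shape[1]} channels but {len(channel_names)} names"
        )
    return ImageStack(data, channel_names, Calibration(float(pixel_size_um), float(z_step_um)))


def write_labels(labels: LabelVolume, path) -> None:
    if labels.data.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    res = 1.0 / labels.calibration.pixel_size_um
    tifffile.imwrite(
        path,
        labels.data.astype(np.uint16),
        imagej=True,
        resolution=(res, res),
        metadata={"axes": "ZYX", "spacing": labels.calibration.z_step_um, "unit": "um"},
    )


def read_labels(path, pixel_size_um=None, z_step_um=None) -> LabelVolume:
    stack = read_stack(path, channel_names=("labels",),
                       pixel_size_um=pixel_size_um, z_step_um=z_step_um,
                       allow_any_depth=True)
    return LabelVolume(stack.data[:, 0].astype(np.int32), stack.calibration)


def write_roi(mask: np.ndarray, calibration: Calibration, path) -> None:
    res = 1.0 / calibration.pixel_size_um
    tifffile.imwrite(
        path,
        (np.asarray(mask, dtype=bool)).astype(np.uint8) * 255,
        imagej=True,
        resolution=(res, res),
        metadata={"axes": "ZYX", "spacing": calibration.z_step_um, "unit": "um"},
    )


def read_roi(path) -> np.ndarray:
    stack = read_stack(path, channel_names=("roi",), allow_any_depth=True)
    return stack.data[:, 0] > 0


@dataclass
class StatsOptions:
    channels: tuple[str, ...] = ("pY705", "TFCP2L1", "NANOG")
    adjust: str | None = None
    per_embryo: bool = False


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to YAML.

    Defaults are the published acquisition/processing parameters wherever
    the protocol states them (percentile window, detection and overlap
    thresholds, unsharp radius/weight, area and duration filters, DAPI-mean
    and volume QC windows); the rest are this package's documented
    defaults.
    """

    version: int = 1
    dna_channel: str = "DAPI"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    stats: StatsOptions = field(default_factory=StatsOptions)
    gates: list[dict] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["channels"] = list(d["stats"]["channels"])
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in (("segmentation", SegmentationParams),
                             ("qc", QCThresholds), ("stats", StatsOptions)):
            if key in raw and isinstance(raw[key], dict):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(raw[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in config section {key!r}: {sorted(sub_unknown)}"
                    )
                raw[key] = sub_cls(**raw[key])
        if "stats" in raw and isinstance(raw["stats"], StatsOptions):
            raw["stats"].channels = tuple(raw["stats"].channels)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


MANIFEST_COLUMNS = ["embryo_id", "stage", "genotype", "stack_path", "roi_path", "seed"]


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    if manifest["embryo_id"].duplicated().any():
        raise ValueError("manifest embryo_ids must be unique")
    return manifest
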