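"""Core in-memory containers shared across the pipeline.

An :class:`ImageStack` holds a multi-channel confocal z-stack together with
its physical calibration (xy pixel size and z step, both in micrometres).
A :class:`LabelVolume` is the integer-valued 3D segmentation derived from
the DNA channel of such a stack; label 0 is background, labels 1..K are
nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STAGES = ("E3.5", "E4.5", "diapause")
LINEAGES = ("EPI", "PRE", "TE")


@dataclass
class Calibration:
    """Physical voxel calibration in micrometres."""

    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration lengths must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um


@dataclass
class ImageStack:
    """A calibrated multi-channel z-stack, axis order (z, channel, y, x)."""

    data: np.ndarray  # (z, c, y, x), typically uint8
    channel_names: tuple[str, ...]
    calibration: Calibration

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (z, channel, y, x)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        idx = self.channel_index(name_or_index)
        return self.data[:, idx]

    def channel_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            idx = int(name_or_index)
            if not 0 <= idx < len(self.channel_names):
                raise KeyError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_names.index(name_or_index)
        except ValueError:
            raise KeyError(
                f"unknown channel {name_or_index!r}; have {self.channel_names}"
            ) from None


@dataclass
class LabelVolume:
    """Integer 3D segmentation, axis order (z, y, x); 0 = background."""

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D (z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer typed")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        present = np.unique(self.data)
        return present[present > 0]
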