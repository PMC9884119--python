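"""Per-nucleus measurement, QC filtering, region restriction and export.

The segmentation label volume is used as a mask over every channel of the
raw stack to measure, for each 3D nucleus: the unweighted voxel centroid
(µm), the voxel count and physical volume, and per channel the mean voxel
value and the integrated density (the sum of all voxel values in the
object). Two published QC windows remove mis-segmented objects: the mean
DNA-stain signal must fall strictly inside (2, 10) on a 0–10 scale (the
8-bit mean divided by 25.5) and the volume strictly inside (150, 700) µm³.
Both windows are open intervals and configurable. Region restriction marks
each nucleus as inside or outside the embryonic-region mask by centroid
membership, mirroring the manual crop that removes mural trophectoderm.

The 0-10 DNA QC scale is the per-slice percentile-normalised DNA image
(the same 1.0-99.9 percentile contrast stretch the detector uses, values
in [0, 1]) multiplied by 10; a window of (2, 10) on that scale removes
objects whose DNA signal is implausibly dim for a nucleus. The raw 8-bit
mean is also reported (``mean_<dna>``) so the filter can be re-pointed at
raw units via ``qc_filter(..., dapi_col=...)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import ImageStack, LabelVolume
from .segmentation import normalize_percentiles

logger = logging.getLogger(__name__)

#: Percentile window of the contrast stretch behind the 0-10 DNA QC scale.
QC_NORM_PERCENTILES = (1.0, 99.9)


@dataclass
class QCThresholds:
    dapi_mean_low: float = 2.0
    dapi_mean_high: float = 10.0
    volume_low: float = 150.0
    volume_high: float = 700.0

    def __post_init__(self) -> None:
        if self.dapi_mean_low >= self.dapi_mean_high:
            raise ValueError("dapi_mean_low must be < dapi_mean_high")
        if self.volume_low >= self.volume_high:
            raise ValueError("volume_low must be < volume_high")


def measure_nuclei(
    labels: LabelVolume,
    stack: ImageStack,
    embryo_id: str = "embryo",
    stage: str = "",
    genotype: str = "WT",
    dna_channel: str | int = "DAPI",
) -> pd.DataFrame:
    """Measure every labelled nucleus; one row per 3D object.

    Columns: embryo_id, nucleus_id, x_um, y_um, z_um, voxel_count,
    volume_um3, per channel mean_<name> and intden_<name>, dapi_mean_qc
    (the DNA mean on the 0-10 QC scale), in_region, stage, genotype.
    """
    if labels.data.shape != stack.data[:, 0].shape:
        raise ValueError(
            f"label shape {labels.data.shape} does not match "
            f"stack slice shape {stack.data[:, 0].shape}"
        )
    cal = stack.calibration
    ids = labels.labels
    if ids.size == 0:
        return _empty_table(stack.channel_names)

    lab = labels.data
    counts = ndi.sum_labels(np.ones(lab.shape), lab, index=ids)
    # unweighted voxel centroid in physical units
    com = np.array(ndi.center_of_mass(np.ones(lab.shape), lab, ids))
    table = pd.DataFrame(
        {
            "embryo_id": embryo_id,
            "nucleus_id": ids.astype(int),
            "x_um": com[:, 2] * cal.pixel_size_um,
            "y_um": com[:, 1] * cal.pixel_size_um,
            "z_um": com[:, 0] * cal.z_step_um,
            "voxel_count": counts.astype(int),
            "volume_um3": counts * cal.voxel_volume_um3,
        }
    )
    for name in stack.channel_names:
        ch = stack.channel(name).astype(np.float64)
        sums = ndi.sum_labels(ch, lab, index=ids)
        means = sums / counts
        table[f"mean_{name}"] = means
        # stored as mean x voxel_count so the tabulated identity
        # intden == mean * voxel_count is bit-exact; equals the raw voxel
        # sum to within one unit in the last place
        table[f"intden_{name}"] = means * counts
    dna_name = stack.channel_names[stack.channel_index(dna_channel)]
    dna = stack.channel(dna_name).astype(np.float64)
    norm_dna = np.empty_like(dna)
    for z in range(dna.shape[0]):
        norm_dna[z] = normalize_percentiles(dna[z], *QC_NORM_PERCENTILES)
    norm_sums = ndi.sum_labels(norm_dna, lab, index=ids)
    table["dapi_mean_qc"] = norm_sums / counts * 10.0
    table["in_region"] = True
    table["stage"] = stage
    table["genotype"] = genotype
    return table


def _empty_table(channel_names) -> pd.DataFrame:
    cols = table_columns(channel_names)
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def table_columns(channel_names) -> list[str]:
    """The fixed CSV column order for the per-object table."""
    cols = ["embryo_id", "nucleus_id", "x_um", "y_um", "z_um",
            "voxel_count", "volume_um3"]
    for name in channel_names:
        cols += [f"mean_{name}", f"intden_{name}"]
    return cols + ["dapi_mean_qc", "in_region", "stage", "genotype"]


def qc_filter(
    table: pd.DataFrame,
    thr: QCThresholds | None = None,
    dapi_col: str = "dapi_mean_qc",
    volume_col: str = "volume_um3",
) -> pd.DataFrame:
    """Drop mis-segmented nuclei outside the open QC windows.

    Keeps rows with ``dapi_col`` strictly inside (dapi_mean_low,
    dapi_mean_high) and ``volume_col`` strictly inside (volume_low,
    volume_high); boundary-equal values are removed. Idempotent; returns a
    subset of the input.
    """
    thr = thr or QCThresholds()
    for col in (dapi_col, volume_col):
        if col not in table.columns:
            raise KeyError(f"table lacks required column {col!r}")
    keep = (
        (table[dapi_col] > thr.dapi_mean_low)
        & (table[dapi_col] < thr.dapi_mean_high)
        & (table[volume_col] > thr.volume_low)
        & (table[volume_col] < thr.volume_high)
    )
    removed = int((~keep).sum())
    if removed:
        logger.info("qc_filter: removed %d of %d nuclei", removed, len(table))
    return table.loc[keep].copy()


def apply_region(table: pd.DataFrame, roi_mask: np.ndarray,
                 calibration) -> pd.DataFrame:
    """Set ``in_region`` by centroid membership in a boolean (z, y, x) mask."""
    roi = np.asarray(roi_mask, dtype=bool)
    out = table.copy()
    if len(out) == 0:
        return out
    zi = np.clip(np.rint(out["z_um"] / calibration.z_step_um).astype(int),
                 0, roi.shape[0] - 1)
    yi = np.clip(np.rint(out["y_um"] / calibration.pixel_size_um).astype(int),
                 0, roi.shape[1] - 1)
    xi = np.clip(np.rint(out["x_um"] / calibration.pixel_size_um).astype(int),
                 0, roi.shape[2] - 1)
    out["in_region"] = roi[zi, yi, xi]
    return out


def export_table(table: pd.DataFrame, path, channel_names=None) -> None:
    """Write the per-object table as CSV in the fixed column order."""
    if channel_names is None:
        channel_names = [c[len("intden_"):] for c in table.columns
                         if c.startswith("intden_")]
    cols = [c for c in table_columns(channel_names) if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`export_table` (lossless floats)."""
    return pd.read_csv(path, float_precision="round_trip")
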