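"""In-silico embryos: co-expression gating and spatial reconstruction.

Per-nucleus feature tables can be treated like flow-cytometry events: each
nucleus is a point in a gene-expression space spanned by per-channel
integrated densities. A :class:`ThresholdGate` keeps nuclei whose
integrated density exceeds a cutoff (strictly above, as in "raw integrated
density above 5x10^5"); a :class:`PolygonGate` keeps nuclei whose
(x_channel, y_channel) point falls inside a polygon drawn in a 2D
co-expression plane, with boundary points counting as inside. Selected
nuclei can then be mapped back into their embryo of origin as a 3D point
cloud built from the measured centroids — an "in silico" embryo — and
summarised per embryo (cell counts, mean marker level, spatial enrichment
of the selection in the embryonic region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import Polygon

RecordId = tuple[str, int]  # (embryo_id, nucleus_id)


@dataclass(frozen=True)
class ThresholdGate:
    channel: str
    min_intden: float

    def __post_init__(self) -> None:
        if self.min_intden < 0:
            raise ValueError("threshold must be non-negative")


@dataclass(frozen=True)
class PolygonGate:
    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(map(tuple, self.vertices)))
        if len(self.vertices) < 3:
            raise ValueError("polygon gate needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon gate is self-intersecting or degenerate")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


Gate = ThresholdGate | PolygonGate


def _intden_col(table: pd.DataFrame, channel: str) -> str:
    col = channel if channel in table.columns else f"intden_{channel}"
    if col not in table.columns:
        raise KeyError(f"unknown channel {channel!r} in table")
    return col


def gate_select(table: pd.DataFrame, gate: Gate) -> list[RecordId]:
    """Apply a gate; returns the selected (embryo_id, nucleus_id) ids.

    Selections are id-based and therefore stable under row reordering. A
    threshold gate keeps records strictly above its cutoff; a polygon gate
    keeps records whose co-expression point lies inside or on the boundary
    of the polygon.
    """
    if isinstance(gate, ThresholdGate):
        col = _intden_col(table, gate.channel)
        mask = table[col].to_numpy() > gate.min_intden
    elif isinstance(gate, PolygonGate):
        xcol = _intden_col(table, gate.x_channel)
        ycol = _intden_col(table, gate.y_channel)
        points = shapely.points(table[xcol].to_numpy(), table[ycol].to_numpy())
        mask = shapely.covers(gate.polygon(), points)
    else:
        raise TypeError(f"unknown gate type {type(gate).__name__}")
    sel = table.loc[mask, ["embryo_id", "nucleus_id"]]
    return [(str(e), int(n)) for e, n in sel.itertuples(index=False)]


@dataclass
class InSilicoEmbryo:
    """3D point-cloud reconstruction of one embryo from nucleus centroids."""

    embryo_id: str
    points: pd.DataFrame  # x_um, y_um, z_um, colour, selected

    def to_csv(self, path) -> None:
        out = self.points.copy()
        out.insert(0, "embryo_id", self.embryo_id)
        out.to_csv(path, index=False)


def reconstruct(
    table: pd.DataFrame,
    colour_channel: str,
    selection: list[RecordId] | None = None,
    embryo_id: str | None = None,
) -> InSilicoEmbryo:
    """Build the in-silico embryo point cloud for one embryo.

    One point per record of that embryo, coloured by ``colour_channel``'s
    integrated density, with ``selected`` flagged from the gate selection.
    """
    if embryo_id is None:
        ids = table["embryo_id"].unique()
        if len(ids) != 1:
            raise ValueError("table spans several embryos; pass embryo_id")
        embryo_id = str(ids[0])
    sub = table[table["embryo_id"] == embryo_id]
    col = _intden_col(sub, colour_channel)
    selected_ids = set(selection or [])
    points = pd.DataFrame(
        {
            "nucleus_id": sub["nucleus_id"].astype(int).to_numpy(),
            "x_um": sub["x_um"].to_numpy(),
            "y_um": sub["y_um"].to_numpy(),
            "z_um": sub["z_um"].to_numpy(),
            "colour": sub[col].to_numpy(),
            "selected": [
                (str(e), int(n)) in selected_ids
                for e, n in zip(sub["embryo_id"], sub["nucleus_id"])
            ],
        }
    )
    return InSilicoEmbryo(embryo_id, points)


@dataclass
class EnrichmentReport:
    n_selected: int
    n_total: int
    frac_selected_in_region: float | None
    frac_all_in_region: float
    ratio: float | None  # None when no cells are selected
    p_hypergeometric: float | None  # one-sided over-representation p


def region_enrichment(
    table: pd.DataFrame,
    selection: list[RecordId],
    region_col: str = "in_region",
) -> EnrichmentReport:
    """Is the gated selection over-represented in the embryonic region?

    Reports the in-region fraction among selected cells, among all cells,
    their ratio, and a one-sided hypergeometric p-value for
    over-representation. The hypergeometric p is an added quantification of
    what is otherwise a visual claim; it assumes exchangeable cells.
    """
    ids = list(zip(table["embryo_id"].astype(str), table["nucleus_id"].astype(int)))
    in_region = table[region_col].astype(bool).to_numpy()
    selected_mask = np.array([i in set(selection) for i in ids])
    n_total = len(table)
    n_sel = int(selected_mask.sum())
    k_pop = int(in_region.sum())
    frac_all = k_pop / n_total if n_total else float("nan")
    if n_sel == 0:
        return EnrichmentReport(0, n_total, None, frac_all, None, None)
    k_sel = int((selected_mask & in_region).sum())
    frac_sel = k_sel / n_sel
    ratio = frac_sel / frac_all if frac_all > 0 else float("inf")
    p = float(sps.hypergeom.sf(k_sel - 1, n_total, k_pop, n_sel))
    return EnrichmentReport(n_sel, n_total, frac_sel, frac_all, ratio, p)


def per_embryo_summary(tables) -> pd.DataFrame:
    """One row per embryo: cell count and mean integrated density per channel."""
    if isinstance(tables, (list, tuple)):
        table = pd.concat(tables, ignore_index=True)
    else:
        table = tables
    intden_cols = [c for c in table.columns if c.startswith("intden_")]
    grouped = table.groupby("embryo_id", sort=True)
    out = grouped.size().rename("n_cells").to_frame()
    for c in intden_cols:
        out[f"mean_{c}"] = grouped[c].mean()
    return out.reset_index()


def size_intensity_correlation(
    summary: pd.DataFrame,
    channel: str,
    method: str = "spearman",
):
    """Correlate per-embryo mean marker level with embryonic-region size.

    Size is the number of segmented cells. Spearman by default, consistent
    with the rank-based statistics elsewhere; Pearson by flag. Returns
    (coefficient, p_value).
    """
    col = f"mean_intden_{channel}" if f"mean_intden_{channel}" in summary.columns \
        else channel
    if col not in summary.columns:
        raise KeyError(f"no column for channel {channel!r} in summary")
    x = summary["n_cells"].to_numpy(dtype=float)
    y = summary[col].to_numpy(dtype=float)
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)
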