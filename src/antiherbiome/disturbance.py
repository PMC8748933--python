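"""Wildfire filtering/aggregation rules and the hurricane-activity metric.

Fire hotspots (satellite active-fire detections) carry a position, a
detection date, a detection confidence (percent) and a fire radiative
power (FRP, MW).  Only confident detections inside a fixed observation
window are kept, and a land-cover buffer test removes fires in
human-dominated or water-adjacent settings so that retained hotspots can
be read as wildfires: a hotspot is dropped when more than 10 % of the
land-cover cells within 1000 m of its centroid are agricultural, urban
or water.

Per-ecoregion metrics are then a vegetation-corrected fire rate
(count / area x vegetated proportion), a mean FRP ("fire intensity") and
a hurricane-occurrence rate (six-hourly track points / area).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# land-cover class codes
NATURAL_VEGETATED = 0
AGRICULTURE = 1
URBAN = 2
WATER = 3
OTHER = 4

ANTHROPOGENIC_OR_WATER = (AGRICULTURE, URBAN, WATER)

FIRE_WINDOW = ("2000-11-01", "2019-12-31")


@dataclass
class LandCoverGrid:
    """Per-cell land-cover classes on the study lattice (cell size in metres)."""

    classes: np.ndarray  # 2D int array of class codes
    cell_size_m: float

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell size must be positive")
        self.classes = np.asarray(self.classes)

    @property
    def shape(self):
        return self.classes.shape

    def cell_centres(self):
        """(ys, xs) metre coordinates of cell centres, row/col order."""
        h, w = self.classes.shape
        ys = (np.arange(h) + 0.5) * self.cell_size_m
        xs = (np.arange(w) + 0.5) * self.cell_size_m
        return ys, xs


def filter_wildfires(
    hotspots: pd.DataFrame,
    landcover: LandCoverGrid,
    buffer_m: float = 1000.0,
    confidence_min: float = 95.0,
    window=FIRE_WINDOW,
    max_anthro_fraction: float = 0.10,
) -> pd.DataFrame:
    """Retain wildfire hotspots per confidence, date-window and buffer rules.

    A hotspot is kept when its confidence is >= ``confidence_min``, its
    date falls inside ``window`` (both ends included) and at most
    ``max_anthro_fraction`` of the land-cover cells whose centres lie
    within ``buffer_m`` (Euclidean) of the hotspot are agriculture, urban
    or water.  Hotspots outside the land-cover extent are dropped with a
    warning.  The three filters commute; order is immaterial.
    """
    hs = hotspots.copy()
    dates = pd.to_datetime(hs["date"])
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    keep = (hs["confidence"] >= confidence_min) & (dates >= start) & (dates <= end)

    ys, xs = landcover.cell_centres()
    h, w = landcover.shape
    extent_y = h * landcover.cell_size_m
    extent_x = w * landcover.cell_size_m
    anthro = np.isin(landcover.classes, ANTHROPOGENIC_OR_WATER)

    in_extent = (
        (hs["x"] >= 0) & (hs["x"] <= extent_x) & (hs["y"] >= 0) & (hs["y"] <= extent_y)
    ).to_numpy()
    n_outside = int((~in_extent & keep.to_numpy()).sum())
    if n_outside:
        logger.warning("%d hotspots outside the land-cover extent dropped", n_outside)
    keep &= in_extent

    buffer_ok = np.zeros(len(hs), dtype=bool)
    idx = np.flatnonzero(keep.to_numpy())
    for i in idx:
        dy2 = (ys - float(hs["y"].iloc[i])) ** 2
        dx2 = (xs - float(hs["x"].iloc[i])) ** 2
        mask = dy2[:, None] + dx2[None, :] <= buffer_m**2
        n_cells = int(mask.sum())
        if n_cells == 0:
            continue
        frac = anthro[mask].sum() / n_cells
        buffer_ok[i] = frac <= max_anthro_fraction
    keep &= buffer_ok
    return hs.loc[keep.to_numpy()]


def _assign_ecoregion(hotspots: pd.DataFrame, raster: np.ndarray, cell_size_m: float) -> np.ndarray:
    """Ecoregion id under each hotspot (-1 outside the raster/study area)."""
    rows = np.floor(hotspots["y"].to_numpy() / cell_size_m).astype(int)
    cols = np.floor(hotspots["x"].to_numpy() / cell_size_m).astype(int)
    h, w = raster.shape
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    out = np.full(len(hotspots), -1, dtype=int)
    out[ok] = raster[rows[ok], cols[ok]]
    return out


def fire_metrics(
    retained: pd.DataFrame,
    raster: np.ndarray,
    landcover: LandCoverGrid,
    cell_area_km2: float,
    vegetated_min: float = 0.5,
    vegetated_classes=(NATURAL_VEGETATED,),
) -> pd.DataFrame:
    """Per-ecoregion fire rate and intensity from retained hotspots.

    ``fire_count_per_area`` is count / ecoregion area multiplied by the
    ecoregion's vegetated land-cover proportion; ``FI`` is the mean FRP of
    the ecoregion's hotspots (missing when there are none).  Ecoregions
    whose vegetated proportion is below ``vegetated_min`` are flagged
    ``excluded`` (lacking large preserved vegetated areas).
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell area must be positive")
    if landcover.shape != raster.shape:
        raise ValueError(f"land cover {landcover.shape} does not match raster {raster.shape}")
    ids = np.unique(raster[raster >= 0])
    n = int(raster.max()) + 1
    n_cells = np.bincount(raster[raster >= 0], minlength=n)
    area = n_cells * cell_area_km2
    if np.any(area[ids] <= 0):
        raise ValueError("zero-area ecoregion in raster")
    veg = np.isin(landcover.classes, vegetated_classes)
    veg_cells = np.bincount(raster[(raster >= 0) & veg], minlength=n)
    veg_prop = veg_cells / np.maximum(n_cells, 1)

    eco = _assign_ecoregion(retained, raster, landcover.cell_size_m)
    inside = eco >= 0
    counts = np.bincount(eco[inside], minlength=n)
    frp_sum = np.bincount(eco[inside], weights=retained["frp"].to_numpy()[inside], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.where(counts > 0, frp_sum / np.maximum(counts, 1), np.nan)

    out = pd.DataFrame(
        {
            "fire_count": counts[ids],
            "fire_count_per_area": counts[ids] / area[ids] * veg_prop[ids],
            "FI": fi[ids],
            "vegetated_prop": veg_prop[ids],
            "excluded": veg_prop[ids] < vegetated_min,
        },
        index=pd.Index(ids, name="ecoregion_id"),
    )
    return out


def hurricane_rate(
    tracks: pd.DataFrame,
    raster: np.ndarray,
    cell_size_m: float,
    cell_area_km2: float,
) -> pd.Series:
    """Six-hourly track-point occurrences per ecoregion area (points/km^2)."""
    ids = np.unique(raster[raster >= 0])
    n = int(raster.max()) + 1
    area = np.bincount(raster[raster >= 0], minlength=n) * cell_area_km2
    if len(tracks):
        eco = _assign_ecoregion(tracks, raster, cell_size_m)
        counts = np.bincount(eco[eco >= 0], minlength=n)
    else:
        counts = np.zeros(n)
    out = pd.Series(
        counts[ids] / area[ids], index=pd.Index(ids, name="ecoregion_id"), name="HUR"
    )
    return out
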