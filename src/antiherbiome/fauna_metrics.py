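"""Ecoregion-level metrics for extinct megafauna and extant mammal herbivores.

Species pools come with body mass (kg), a diet guild (browser / grazer /
mixed, or unknown), the fraction of the diet made of plants, an
extinction status and a per-grid-cell presence map.  The megafauna subset
keeps prehistorically extinct species ("EP", extinct before 1500 CE) with
body mass strictly above 50 kg and at least 90 % plant diet; the extant
subset keeps extant strict herbivores that feed mainly on above-ground
vegetative tissue, with no size threshold.

All metrics follow the same cell-then-ecoregion recipe: a quantity is
evaluated per grid cell (species count, mean body mass of the species
present, allometric density) and the ecoregion value is the mean over the
ecoregion's cells.  With one cell per ecoregion the two levels coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIET_GUILDS = ("browser", "grazer", "mixed")

STATUS_EXTINCT = "EP_extinct"
STATUS_EXTANT = "extant"

MEGAFAUNA_MASS_KG = 50.0  # strict: mass must exceed this
HERBIVORY_MIN = 0.9


@dataclass
class FaunaAssemblage:
    """Mammal species table plus presence grids on a shared lattice.

    Attributes
    ----------
    table : DataFrame indexed by species id with columns ``body_mass``,
        ``diet``, ``herbivory_fraction``, ``status``,
        ``feeds_mainly_on_vegetative``.
    presence : bool array, shape (n_species, H, W), aligned with
        ``table.index``; True where the species occurs.
    raster : int array (H, W) of ecoregion ids, -1 outside the study area.
    cell_area_km2 : area of one grid cell.
    """

    table: pd.DataFrame
    presence: np.ndarray
    raster: np.ndarray
    cell_area_km2: float = 9312.25  # 96.5 km resolution
    ecoregion_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.presence.shape[0] != len(self.table):
            raise ValueError("presence stack and species table sizes differ")
        if self.presence.shape[1:] != self.raster.shape:
            raise ValueError(
                f"presence grids {self.presence.shape[1:]} do not match "
                f"ecoregion raster {self.raster.shape}"
            )
        bad = self.table["body_mass"] <= 0
        if bad.any():
            raise ValueError(f"non-positive body masses for {list(self.table.index[bad])}")
        self.ecoregion_ids = np.unique(self.raster[self.raster >= 0])

    def subset(self, species_ids) -> "FaunaAssemblage":
        idx = self.table.index.get_indexer(pd.Index(species_ids))
        if (idx < 0).any():
            raise KeyError("unknown species ids in subset request")
        return FaunaAssemblage(
            table=self.table.loc[species_ids],
            presence=self.presence[idx],
            raster=self.raster,
            cell_area_km2=self.cell_area_km2,
        )


def filter_megafauna(table: pd.DataFrame) -> pd.DataFrame:
    """Extinct strict-herbivore megafauna: EP status, > 50 kg, >= 90 % plants."""
    keep = (
        (table["status"] == STATUS_EXTINCT)
        & (table["body_mass"] > MEGAFAUNA_MASS_KG)
        & (table["herbivory_fraction"] >= HERBIVORY_MIN)
    )
    return table.loc[keep]


def filter_extant(table: pd.DataFrame) -> pd.DataFrame:
    """Extant strict herbivores feeding mainly on vegetative tissue (no mass cut)."""
    keep = (
        (table["status"] == STATUS_EXTANT)
        & (table["herbivory_fraction"] >= HERBIVORY_MIN)
        & table["feeds_mainly_on_vegetative"].astype(bool)
    )
    return table.loc[keep]


def _check_raster(assemblage: FaunaAssemblage, raster: np.ndarray | None) -> np.ndarray:
    if raster is None:
        return assemblage.raster
    if raster.shape != assemblage.presence.shape[1:]:
        raise ValueError(
            f"raster {raster.shape} does not match presence grids "
            f"{assemblage.presence.shape[1:]}"
        )
    return raster


def _ecoregion_cell_mean(values: np.ndarray, raster: np.ndarray, valid: np.ndarray | None = None) -> pd.Series:
    """Mean of a per-cell field within each ecoregion (optionally over a cell mask)."""
    inside = raster >= 0
    if valid is not None:
        inside = inside & valid
    ids = raster[inside]
    vals = values[inside]
    n = int(raster.max()) + 1
    sums = np.bincount(ids, weights=vals, minlength=n)
    counts = np.bincount(ids, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    all_ids = np.unique(raster[raster >= 0])
    return pd.Series(means[all_ids], index=pd.Index(all_ids, name="ecoregion_id"))


def _select(assemblage: FaunaAssemblage, species_ids=None, diet: str | None = None):
    table = assemblage.table if species_ids is None else assemblage.table.loc[species_ids]
    if diet is not None:
        if diet not in DIET_GUILDS:
            raise ValueError(f"unknown diet guild {diet!r}; expected one of {DIET_GUILDS}")
        table = table.loc[table["diet"] == diet]
    idx = assemblage.table.index.get_indexer(table.index)
    return table, assemblage.presence[idx]


def ecoregion_richness(
    assemblage: FaunaAssemblage,
    species_ids=None,
    diet: str | None = None,
    raster: np.ndarray | None = None,
) -> pd.Series:
    """Mean per-cell species richness per ecoregion.

    Richness is counted per grid cell (optionally within one diet guild;
    species with unknown diet never count toward a guild) and averaged
    over all cells of the ecoregion, including empty ones.
    """
    raster = _check_raster(assemblage, raster)
    _, pres = _select(assemblage, species_ids, diet)
    richness = pres.sum(axis=0).astype(float) if len(pres) else np.zeros(raster.shape)
    return _ecoregion_cell_mean(richness, raster)


def ecoregion_body_mass(
    assemblage: FaunaAssemblage,
    species_ids=None,
    raster: np.ndarray | None = None,
) -> pd.Series:
    """Mean body mass (kg) of the species present, cell-wise then ecoregion-wise.

    Cells holding no species are excluded from the ecoregion mean (the
    mean mass of an empty assemblage is undefined); ecoregions with no
    occupied cell are missing.
    """
    raster = _check_raster(assemblage, raster)
    table, pres = _select(assemblage, species_ids)
    masses = table["body_mass"].to_numpy(dtype=float)
    if len(pres) == 0:
        return _ecoregion_cell_mean(np.full(raster.shape, np.nan), raster, valid=np.zeros(raster.shape, bool))
    count = pres.sum(axis=0)
    total = np.tensordot(masses, pres.astype(float), axes=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return _ecoregion_cell_mean(cell_mean, raster, valid=count > 0)


def diet_difference(summary: pd.DataFrame, grazer_col: str, browser_col: str) -> pd.Series:
    """Grazer minus browser richness (mixed feeders excluded)."""
    return summary[grazer_col] - summary[browser_col]


def allometric_density(
    assemblage: FaunaAssemblage,
    species_ids=None,
    c: float = 1.0,
    b: float = -0.75,
    raster: np.ndarray | None = None,
) -> tuple[pd.Series, float]:
    """Allometric density index per ecoregion and its correlation with richness.

    Per-species density is ``c * mass ** b`` (Damuth-type scaling by
    default), summed over the species present in each cell and averaged
    per ecoregion.  The Pearson correlation with plain richness is
    returned alongside, as the diagnostic the index exists for.
    """
    if b >= 0:
        logger.warning("allometric exponent b=%.3g >= 0; densities normally decline with mass", b)
    raster = _check_raster(assemblage, raster)
    table, pres = _select(assemblage, species_ids)
    if len(pres) == 0:
        dens = _ecoregion_cell_mean(np.zeros(raster.shape), raster)
        return dens, np.nan
    per_species = c * table["body_mass"].to_numpy(dtype=float) ** b
    cell = np.tensordot(per_species, pres.astype(float), axes=1)
    dens = _ecoregion_cell_mean(cell, raster)
    rich = ecoregion_richness(assemblage, species_ids, raster=raster)
    both = pd.concat([dens, rich], axis=1).dropna()
    corr = float(both.corr().iloc[0, 1]) if len(both) > 2 else np.nan
    return dens, corr


def compute_fauna_summary(assemblage: FaunaAssemblage) -> pd.DataFrame:
    """All standard fauna indicators per ecoregion.

    Columns: M_rich, M_bm, MG_rich, MB_rich, MMf_rich, MGB_dif (extinct
    megafauna) and H_rich, H_bm, HG_rich, HB_rich, HGB_dif (extant
    herbivores).  Species with unknown diet contribute to overall
    richness but to no guild.
    """
    mega = filter_megafauna(assemblage.table).index
    extant = filter_extant(assemblage.table).index
    out = pd.DataFrame(
        {
            "M_rich": ecoregion_richness(assemblage, mega),
            "M_bm": ecoregion_body_mass(assemblage, mega),
            "MG_rich": ecoregion_richness(assemblage, mega, diet="grazer"),
            "MB_rich": ecoregion_richness(assemblage, mega, diet="browser"),
            "MMf_rich": ecoregion_richness(assemblage, mega, diet="mixed"),
            "H_rich": ecoregion_richness(assemblage, extant),
            "H_bm": ecoregion_body_mass(assemblage, extant),
            "HG_rich": ecoregion_richness(assemblage, extant, diet="grazer"),
            "HB_rich": ecoregion_richness(assemblage, extant, diet="browser"),
        }
    )
    out["MGB_dif"] = diet_difference(out, "MG_rich", "MB_rich")
    out["HGB_dif"] = diet_difference(out, "HG_rich", "HB_rich")
    out.index.name = "ecoregion_id"
    return out
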