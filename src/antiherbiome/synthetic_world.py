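"""Self-consistent synthetic study system with known planted effects.

The generator emulates, at desk scale, the data a continental
trait-biogeography analysis consumes: an ecoregion lattice, climate /
soil / disturbance covariates, a mammal herbivore assemblage with
per-cell presence maps, a plant occurrence matrix with species trait
values, fire hotspots and land cover, hurricane track points, and
fossil sites with known ground truth.  Every planted structure is
recorded in a truth record so downstream stages can be tested for
recovery.

Geometry is a rectangular lattice of grid cells tiled into contiguous
rectangular ecoregions (no attempt at realistic coastlines).  Ecoregion
adjacency is tile adjacency.

Key planted structures
----------------------
* ``target_corr_map_ph`` — the sample correlation between mean annual
  rainfall and soil pH is induced *exactly* (residualized Gaussian
  construction), matching the strong anticorrelation of real Neotropical
  covariates (r = -0.78 by default).
* ``effect_sizes`` — standardized slopes of ecoregion-level expected
  trait values on fauna/environment predictors.  Each plant species has
  a "home" ecoregion where its negative-binomial abundance dominates;
  its trait values are drawn around the home ecoregion's expectation,
  so community-weighted means inherit the planted slopes.
* diet-structured fauna richness gradients (grazers pulled toward open,
  high-pH, low-rainfall ecoregions), an island richness penalty, and an
  extinct megafauna pool with configurable diet-guild counts.
* a planted savanna-to-forest shift set: ecoregions whose planted
  antiherbiome and fauna richness satisfy the shift rule's fauna
  criteria are split between present-day forest (true shifts) and
  savanna (stable savannas); fossil sites are placed inside, adjacent
  to, and away from the true shifts.

One RNG stream per component (covariates, fauna, occurrences, biomes,
hotspots, sites, tracks): regenerating one component leaves the others
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import biome_shift, disturbance, fauna_metrics
from .disturbance import LandCoverGrid
from .fauna_metrics import STATUS_EXTANT, STATUS_EXTINCT, FaunaAssemblage

logger = logging.getLogger(__name__)

_STREAMS = {
    "covariates": 1, "fauna": 2, "occurrences": 3, "biomes": 4,
    "hotspots": 5, "sites": 6, "tracks": 7, "landcover": 8,
}

COVARIATE_NAMES = ("MAT", "MAR", "RS", "CEC", "pH", "SND", "FI", "fire_count", "HUR")

# standardized-trait offsets of the three antiherbiome archetypes
ARCHETYPE_Z = {
    "WD": {"SLT": -0.3, "ILW": 1.0, "BCL": -0.7},
    "LeafSize": {"SLT": -1.0, "ILW": 0.1, "BCL": 1.0},
    "StemSpines": {"SLT": 1.1, "ILW": -0.2, "BCL": -0.9},
    "LeafSpines": {"SLT": 0.8, "ILW": 0.0, "BCL": -0.8},
    "Latex": {"SLT": -0.8, "ILW": -0.1, "BCL": 1.0},
}


def default_effect_sizes() -> dict:
    """Planted standardized slopes per trait (defence increases with
    megafauna history, latex with small extant herbivores and acid
    fertile soils)."""
    return {
        "WD": {"M_rich": 0.5, "MGB_dif": 0.25, "HUR": 0.2},
        "LeafSize": {"M_rich": -0.4, "MAT": -0.2},
        "StemSpines": {"pH": 0.5, "MGB_dif": 0.3, "H_rich": 0.25},
        "Latex": {"H_bm": -0.3, "pH": -0.3, "CEC": 0.25},
        "LeafSpines": {"M_rich": 0.4},
    }


def default_richness_effects() -> dict:
    return {"CEC": -0.4, "MAR": -0.35, "RS": -0.15, "fire_count": 0.35}


def default_extant_richness_effects() -> dict:
    # a different gradient set from the extinct pool: extinct and extant
    # richness indicators are only weakly correlated in the study system
    return {"MAT": 0.3, "SND": -0.3}


@dataclass
class WorldConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    n_ecoregions: int = 179
    n_cells_per_ecoregion: int = 16
    n_plant_species: int = 1000
    n_fauna_species: int = 186
    n_extinct_megafauna: int = 66
    megafauna_diet_counts: tuple = (22, 16, 15)  # browsers, grazers, mixed; rest unknown
    island_fraction: float = 0.16
    effect_sizes: dict = field(default_factory=default_effect_sizes)
    target_corr_map_ph: float = -0.78
    quantile_rule: float = 0.75
    cluster_separation: float = 2.0  # scales the archetype offsets
    palm_fraction: float = 0.2
    nb_dispersion: float = 1.5
    home_abundance: float = 60.0
    background_abundance: float = 0.05
    trait_noise_sd: float = 0.5
    occupancy_base: float = -1.6
    occupancy_sd: float = 0.5
    richness_effects: dict = field(default_factory=default_richness_effects)
    extant_richness_effects: dict = field(default_factory=default_extant_richness_effects)
    grazer_openness_effect: float = 0.5
    island_penalty: float = -2.0
    shift_fraction: float = 0.5
    n_hotspots: int = 400
    n_track_points: int = 300
    fossil_inside: int = 13
    fossil_adjacent: int = 3
    fossil_stable: int = 6
    fossil_cap_per_ecoregion: int = 6
    cell_area_km2: float = 9312.25  # 96.5 km cells
    cell_size_m: float = 96_500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ecoregions", "n_cells_per_ecoregion", "n_plant_species", "n_fauna_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not abs(self.target_corr_map_ph) < 1:
            raise ValueError("|target_corr_map_ph| must be < 1")
        if not 0 <= self.island_fraction <= 1:
            raise ValueError("island_fraction must be in [0, 1]")
        if self.n_extinct_megafauna > self.n_fauna_species:
            raise ValueError("n_extinct_megafauna exceeds n_fauna_species")
        if sum(self.megafauna_diet_counts) > self.n_extinct_megafauna:
            raise ValueError("diet-guild counts exceed the extinct species pool")


def _rng(config: WorldConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# geometry

def ecoregion_lattice(config: WorldConfig) -> tuple[np.ndarray, dict]:
    """Ecoregion-id raster (-1 outside) and the tile adjacency map."""
    n = config.n_ecoregions
    tiles_x = int(np.ceil(np.sqrt(n)))
    tiles_y = int(np.ceil(n / tiles_x))
    c = config.n_cells_per_ecoregion
    a = int(np.floor(np.sqrt(c)))
    while c % a:
        a -= 1
    b = c // a
    raster = np.full((tiles_y * a, tiles_x * b), -1, dtype=int)
    for t in range(n):
        ty, tx = divmod(t, tiles_x)
        raster[ty * a : (ty + 1) * a, tx * b : (tx + 1) * b] = t
    adjacency: dict = {t: set() for t in range(n)}
    for t in range(n):
        ty, tx = divmod(t, tiles_x)
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            ny, nx = ty + dy, tx + dx
            if 0 <= ny < tiles_y and 0 <= nx < tiles_x:
                u = ny * tiles_x + nx
                if u < n:
                    adjacency[t].add(u)
    return raster, adjacency


# ---------------------------------------------------------------------------
# covariates

def generate_covariates(config: WorldConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-ecoregion climate/soil/disturbance covariates.

    MAR and pH carry the target sample correlation exactly; remaining
    covariates are independent draws on realistic scales, except CEC
    which tracks pH weakly (soil fertility coherence).
    """
    if config.n_ecoregions < 10:
        raise ValueError("n_ecoregions < 10: correlation target unenforceable")
    rng = _rng(config, "covariates") if rng is None else rng
    n = config.n_ecoregions
    r = config.target_corr_map_ph

    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z_res = z - (z @ x) / (x @ x) * x
    z_res = (z_res - z_res.mean()) / z_res.std()
    y = r * x + np.sqrt(1 - r**2) * z_res  # corr(x, y) == r exactly

    df = pd.DataFrame(index=pd.RangeIndex(n, name="ecoregion_id"))
    df["MAR"] = 1500.0 + 420.0 * x  # mm/yr
    df["pH"] = 5.8 + 0.9 * y
    df["MAT"] = 22.0 + 4.0 * rng.standard_normal(n)  # deg C
    df["RS"] = np.clip(45.0 + 15.0 * rng.standard_normal(n), 2.0, None)  # CV %
    df["CEC"] = np.clip(15.0 + 2.5 * y + 5.0 * rng.standard_normal(n), 0.5, None)  # cmol/kg
    df["SND"] = np.clip(45.0 + 15.0 * rng.standard_normal(n), 1.0, 99.0)  # sand %
    df["FI"] = 30.0 * np.exp(0.5 * rng.standard_normal(n))  # MW
    df["fire_count"] = rng.gamma(2.0, 0.01, size=n)  # events/km^2
    df["HUR"] = rng.gamma(0.3, 0.02, size=n)  # points/km^2
    n_isl = int(round(config.island_fraction * n))
    insular = np.zeros(n, dtype=bool)
    insular[rng.choice(n, size=n_isl, replace=False)] = True
    df["insular"] = insular
    # provisional biome from the rainfall gradient; the world orchestrator
    # reassigns eligible ecoregions when planting the shift set
    terciles = df["MAR"].rank(pct=True)
    df["biome"] = np.where(terciles < 1 / 3, "savanna",
                           np.where(terciles < 2 / 3, "dry_forest", "moist_forest"))
    return df


def true_antiherbiome_labels(covariates: pd.DataFrame) -> pd.Series:
    """Deterministic planted antiherbiome label from the covariates.

    Dry ecoregions are SLT; the rest split into BCL (fertile, high-CEC)
    and ILW (nutrient-poor) — the planted trait archetypes follow.
    """
    mar_rank = covariates["MAR"].rank(pct=True)
    cec_med = covariates.loc[mar_rank >= 0.25, "CEC"].median()
    labels = np.where(
        mar_rank < 0.25, "SLT", np.where(covariates["CEC"] > cec_med, "BCL", "ILW")
    )
    return pd.Series(labels, index=covariates.index, name="true_antiherbiome")


# ---------------------------------------------------------------------------
# fauna

def _standardized(df: pd.DataFrame, cols) -> pd.DataFrame:
    z = df[list(cols)].astype(float)
    return (z - z.mean()) / z.std(ddof=0).replace(0, 1.0)


def generate_fauna(
    config: WorldConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> FaunaAssemblage:
    """Mammal species pool and presence grids with planted gradients.

    Extinct species ("EP", > 50 kg, strict herbivores) carry the
    configured diet-guild counts; extant species span sizes and diets
    and include non-qualifying species (frugivores, partial herbivores)
    so the filters have work to do.  Occupancy follows a logistic model
    of the covariates; grazers are pulled toward open (dry, alkaline)
    ecoregions and islands are penalized.
    """
    rng = _rng(config, "fauna") if rng is None else rng
    n_ext = config.n_extinct_megafauna
    n_liv = config.n_fauna_species - n_ext
    nb, ng, nm = config.megafauna_diet_counts
    diets_ext = (["browser"] * nb + ["grazer"] * ng + ["mixed"] * nm
                 + ["unknown"] * (n_ext - nb - ng - nm))
    rng.shuffle(diets_ext)
    species = [f"A{i:04d}" for i in range(config.n_fauna_species)]
    mass_ext = 50.0 * np.exp(rng.uniform(0.05, 2.3, size=n_ext))
    mass_liv = np.exp(rng.normal(np.log(8.0), 1.2, size=n_liv))
    herb_ext = rng.uniform(0.9, 1.0, size=n_ext)
    herb_liv = np.where(rng.random(n_liv) < 0.7,
                        rng.uniform(0.9, 1.0, size=n_liv),
                        rng.uniform(0.3, 0.9, size=n_liv))
    diets_liv = list(rng.choice(["browser", "grazer", "mixed", "unknown"],
                                size=n_liv, p=(0.35, 0.25, 0.15, 0.25)))
    table = pd.DataFrame(
        {
            "body_mass": np.concatenate([mass_ext, mass_liv]),
            "diet": diets_ext + diets_liv,
            "herbivory_fraction": np.concatenate([herb_ext, herb_liv]),
            "status": [STATUS_EXTINCT] * n_ext + [STATUS_EXTANT] * n_liv,
            "feeds_mainly_on_vegetative": [True] * n_ext
            + list(rng.random(n_liv) < 0.75),
        },
        index=pd.Index(species, name="species_id"),
    )

    all_effects = {**config.richness_effects, **config.extant_richness_effects}
    Z = _standardized(covariates, [c for c in all_effects if c in covariates])
    island = config.island_penalty * covariates["insular"].to_numpy(dtype=float)
    eta_by_status = {}
    for status, effects in ((STATUS_EXTINCT, config.richness_effects),
                            (STATUS_EXTANT, config.extant_richness_effects)):
        eta = np.full(len(covariates), config.occupancy_base)
        for cov_name, g in effects.items():
            if cov_name in Z:
                eta = eta + g * Z[cov_name].to_numpy()
        eta_by_status[status] = eta + island
    openness = np.zeros(len(covariates))
    if "MAR" in covariates and "pH" in covariates:
        zmar = _standardized(covariates, ["MAR"])["MAR"].to_numpy()
        zph = _standardized(covariates, ["pH"])["pH"].to_numpy()
        openness = (-zmar + zph) / np.sqrt(2)

    raster, _ = ecoregion_lattice(config)
    flat = raster.ravel()
    inside = flat >= 0
    intercepts = rng.normal(0.0, config.occupancy_sd, size=len(table))
    presence = np.zeros((len(table), raster.size), dtype=bool)
    for i, (sp, row) in enumerate(table.iterrows()):
        eta_i = eta_by_status[row["status"]] + intercepts[i]
        if row["diet"] == "grazer":
            eta_i = eta_i + config.grazer_openness_effect * openness
        p = 1.0 / (1.0 + np.exp(-eta_i))
        p_cell = np.zeros(raster.size)
        p_cell[inside] = p[flat[inside]]
        presence[i] = rng.random(raster.size) < p_cell
    presence = presence.reshape((len(table),) + raster.shape)
    return FaunaAssemblage(table=table, presence=presence, raster=raster,
                           cell_area_km2=config.cell_area_km2)


# ---------------------------------------------------------------------------
# plants

def generate_occurrences_and_traits(
    config: WorldConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence matrix (ecoregions x species) and species trait table.

    ``covariates`` must already hold every predictor named in
    ``config.effect_sizes`` (fauna metrics included, when planted).
    Each species has a home ecoregion where its abundance dominates;
    species trait values are drawn around the home ecoregion's planted
    expectation trait = X beta (+ archetype offsets), so aggregated
    community means recover the planted slopes.
    """
    rng = _rng(config, "occurrences") if rng is None else rng
    n_eco = len(covariates)
    n_sp = config.n_plant_species

    needed = sorted({p for slopes in config.effect_sizes.values() for p in slopes})
    unknown = [p for p in needed if p not in covariates.columns]
    if unknown:
        raise ValueError(f"effect_sizes name unknown predictors: {unknown}")
    Z = _standardized(covariates, needed) if needed else pd.DataFrame(index=covariates.index)

    labels = true_antiherbiome_labels(covariates)
    lp = {}
    for trait in ("WD", "LeafSize", "StemSpines", "LeafSpines", "Latex"):
        v = np.zeros(n_eco)
        if config.cluster_separation > 0:
            v = v + config.cluster_separation * labels.map(ARCHETYPE_Z[trait]).to_numpy(float)
        for pred, beta in config.effect_sizes.get(trait, {}).items():
            v = v + beta * Z[pred].to_numpy()
        lp[trait] = v

    # homes are i.i.d. uniform across ecoregions: each abundance column is
    # then exchangeable, so matrix-randomization nulls are exactly calibrated
    homes = rng.integers(0, n_eco, size=n_sp)
    is_palm = rng.random(n_sp) < config.palm_fraction
    if n_sp >= 7 and not is_palm.any():
        is_palm[rng.integers(0, n_sp)] = True
    noise = config.trait_noise_sd

    def eco_lp(trait):
        return lp[trait][homes]

    wd = np.clip(0.62 + 0.10 * (eco_lp("WD") + noise * rng.standard_normal(n_sp)), 0.05, 1.5)
    leaf = np.exp(3.3 + 0.7 * (eco_lp("LeafSize") + noise * rng.standard_normal(n_sp)))

    def bern(trait, p0):
        eta = np.log(p0 / (1 - p0)) + 1.6 * eco_lp(trait)
        return (rng.random(n_sp) < 1.0 / (1.0 + np.exp(-eta))).astype(float)

    spines = bern("StemSpines", 0.25)
    latex = bern("Latex", 0.25)
    leaf_spines = np.where(is_palm, bern("LeafSpines", 0.35), np.nan)

    mu = np.full((n_eco, n_sp), config.background_abundance)
    mu[homes, np.arange(n_sp)] = config.home_abundance
    k = config.nb_dispersion
    occ_counts = rng.negative_binomial(k, k / (k + mu))
    species_ids = [f"P{i:04d}" for i in range(n_sp)]
    occ = pd.DataFrame(occ_counts, index=covariates.index.copy(), columns=species_ids)

    rows = []
    values = {"WD": wd, "LeafSize": leaf, "StemSpines": spines,
              "LeafSpines": leaf_spines, "Latex": latex}
    for trait, vals in values.items():
        for sp, v in zip(species_ids, vals):
            if np.isnan(v):
                continue
            rows.append((sp, trait, float(v), 1))
    traits = pd.DataFrame(rows, columns=["species_id", "trait", "value", "n_records"])
    return occ, traits


def palm_species_of(traits: pd.DataFrame) -> set:
    """Species carrying a leaf-spine value (the palm set by construction)."""
    return set(traits.loc[traits["trait"] == "LeafSpines", "species_id"])


# ---------------------------------------------------------------------------
# fire / hurricanes

def generate_landcover(config: WorldConfig, raster: np.ndarray,
                       rng: np.random.Generator | None = None) -> LandCoverGrid:
    rng = _rng(config, "landcover") if rng is None else rng
    classes = rng.choice(
        [disturbance.NATURAL_VEGETATED, disturbance.AGRICULTURE,
         disturbance.URBAN, disturbance.WATER, disturbance.OTHER],
        size=raster.shape, p=(0.8, 0.08, 0.04, 0.04, 0.04),
    )
    return LandCoverGrid(classes=classes, cell_size_m=config.cell_size_m)


def generate_hotspots(config: WorldConfig, raster: np.ndarray,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    rng = _rng(config, "hotspots") if rng is None else rng
    h, w = raster.shape
    n = config.n_hotspots
    days = rng.integers(0, 365 * 22, size=n)  # 1999-2021: spills beyond the window
    dates = pd.Timestamp("1999-01-01") + pd.to_timedelta(days, unit="D")
    return pd.DataFrame(
        {
            "x": rng.uniform(0, w * config.cell_size_m, size=n),
            "y": rng.uniform(0, h * config.cell_size_m, size=n),
            "date": dates.strftime("%Y-%m-%d"),
            "confidence": rng.uniform(50, 100, size=n),
            "frp": 25.0 * np.exp(0.8 * rng.standard_normal(n)),
        }
    )


def generate_tracks(config: WorldConfig, raster: np.ndarray,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    rng = _rng(config, "tracks") if rng is None else rng
    h, w = raster.shape
    n = config.n_track_points
    return pd.DataFrame(
        {
            "x": rng.uniform(0, w * config.cell_size_m, size=n),
            "y": rng.uniform(0, h * config.cell_size_m, size=n),
        }
    )


# ---------------------------------------------------------------------------
# truth + fossils + orchestration

@dataclass
class TruthRecord:
    planted_effects: dict
    cluster_labels: pd.Series
    shift_set: frozenset
    stable_set: frozenset
    thresholds: biome_shift.Thresholds
    biome: pd.Series


def generate_fossil_sites(
    config: WorldConfig,
    truth: TruthRecord,
    adjacency: dict,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fossil-site fixture: sites inside true shifts (forest locally),
    adjacent to them (forest locally), and in stable savannas (savanna
    locally)."""
    rng = _rng(config, "sites") if rng is None else rng
    cap = config.fossil_cap_per_ecoregion

    shift = sorted(truth.shift_set)
    stable = sorted(truth.stable_set)
    adjacent = sorted(
        {nb for e in shift for nb in adjacency.get(e, ()) if nb not in truth.shift_set}
    )

    def pick(pool, count, kind):
        if count == 0:
            return []
        if not pool or count > len(pool) * cap:
            raise ValueError(
                f"cannot place {count} {kind} fossil sites in {len(pool)} ecoregions "
                f"(cap {cap}/ecoregion)"
            )
        reps = np.resize(np.array(pool, dtype=object), count)
        return list(reps)

    rows = []
    placements = (
        (pick(shift, config.fossil_inside, "inside"), "inside", "forest"),
        (pick(adjacent, config.fossil_adjacent, "adjacent"), "adjacent", "forest"),
        (pick(stable, config.fossil_stable, "stable"), "stable", "savanna"),
    )
    i = 0
    for ecoregions, placement, local in placements:
        for eco in ecoregions:
            rows.append(
                {
                    "site_id": f"F{i:03d}",
                    "ecoregion_id": eco,
                    "epoch": rng.choice(["LGM", "mid-Holocene", "both"]),
                    "past_vegetation": "savanna",
                    "current_local_vegetation": local,
                    "placement": placement,
                }
            )
            i += 1
    return pd.DataFrame(rows, columns=["site_id", "ecoregion_id", "epoch",
                                       "past_vegetation", "current_local_vegetation",
                                       "placement"])


@dataclass
class SyntheticWorld:
    config: WorldConfig
    covariates: pd.DataFrame  # covariates + fauna summary + final biome
    occurrences: pd.DataFrame
    traits: pd.DataFrame
    fauna: FaunaAssemblage
    hotspots: pd.DataFrame
    landcover: LandCoverGrid
    tracks: pd.DataFrame
    fossil_sites: pd.DataFrame
    truth: TruthRecord
    raster: np.ndarray
    adjacency: dict
    palm_species: set

    def save(self, outdir) -> None:
        """Write the world as plain-text artefacts plus a JSON manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "ecoregions.csv")
        self.occurrences.to_csv(out / "occurrences.csv")
        self.traits.to_csv(out / "traits.csv", index=False)
        self.fauna.table.to_csv(out / "fauna_species.csv")
        self.hotspots.to_csv(out / "hotspots.csv", index=False)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.fossil_sites.to_csv(out / "fossil_sites.csv", index=False)
        np.savetxt(out / "ecoregion_raster.txt", self.raster, fmt="%d")
        np.savetxt(out / "landcover.txt", self.landcover.classes, fmt="%d")
        flat = self.fauna.presence.reshape(len(self.fauna.table), -1).astype(np.int8)
        np.savetxt(out / "fauna_presence.txt", flat, fmt="%d")
        sidecar = {
            "cell_size_m": self.config.cell_size_m,
            "cell_area_km2": self.config.cell_area_km2,
            "raster_shape": list(self.raster.shape),
            "adjacency": {str(k): sorted(v) for k, v in self.adjacency.items()},
            "palm_species": sorted(self.palm_species),
            "truth": {
                "shift_set": sorted(self.truth.shift_set),
                "stable_set": sorted(self.truth.stable_set),
                "thresholds": [self.truth.thresholds.m_rich, self.truth.thresholds.mg_rich],
            },
        }
        (out / "grids.json").write_text(json.dumps(sidecar, indent=1))
        checksums = {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.txt"))
        }
        manifest = {"config": _config_dict(self.config), "checksums": checksums}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_dict(config: WorldConfig) -> dict:
    d = asdict(config)
    d["megafauna_diet_counts"] = list(d["megafauna_diet_counts"])
    return d


def generate_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate the full world: covariates, fauna, plants, disturbance
    layers, planted shift set and fossil sites."""
    config = config or WorldConfig()
    cov = generate_covariates(config)
    raster, adjacency = ecoregion_lattice(config)
    fauna = generate_fauna(config, cov)
    fsum = fauna_metrics.compute_fauna_summary(fauna)
    table = cov.join(fsum)

    occ, traits = generate_occurrences_and_traits(config, table)
    labels = true_antiherbiome_labels(cov)

    continental = ~table["insular"].astype(bool)
    thresholds = biome_shift.derive_thresholds(
        table.loc[continental], biome_shift.ShiftRule(quantile=config.quantile_rule)
    )
    eligible = (
        continental
        & labels.isin(("SLT", "ILW"))
        & (table["M_rich"] >= thresholds.m_rich)
        & (table["MG_rich"] >= thresholds.mg_rich)
    )
    rng_b = _rng(config, "biomes")
    biome = table["biome"].copy()
    elig_ids = table.index[eligible]
    to_forest = rng_b.random(len(elig_ids)) < config.shift_fraction
    mar_med = table["MAR"].median()
    for eco, forested in zip(elig_ids, to_forest):
        if forested:
            biome.loc[eco] = "moist_forest" if table.loc[eco, "MAR"] >= mar_med else "dry_forest"
        else:
            biome.loc[eco] = "savanna"
    table["biome"] = biome
    shift_set = frozenset(e for e, f in zip(elig_ids, to_forest) if f)
    stable_set = frozenset(e for e, f in zip(elig_ids, to_forest) if not f)

    truth = TruthRecord(
        planted_effects=config.effect_sizes,
        cluster_labels=labels,
        shift_set=shift_set,
        stable_set=stable_set,
        thresholds=thresholds,
        biome=table["biome"].copy(),
    )
    landcover = generate_landcover(config, raster)
    hotspots = generate_hotspots(config, raster)
    tracks = generate_tracks(config, raster)
    fossils = generate_fossil_sites(config, truth, adjacency)
    table["true_antiherbiome"] = labels
    return SyntheticWorld(
        config=config, covariates=table, occurrences=occ, traits=traits,
        fauna=fauna, hotspots=hotspots, landcover=landcover, tracks=tracks,
        fossil_sites=fossils, truth=truth, raster=raster, adjacency=adjacency,
        palm_species=palm_species_of(traits),
    )


def planted_defence_blobs(
    n_per_cluster: int = 30,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Three trait-profile clusters in 5-trait space for recovery tests.

    ``separation`` is the minimum pairwise centroid distance in pooled-SD
    units (pooled SD = sqrt of the trace of the unit within-cluster
    covariance, i.e. sqrt(5) per-dimension SDs).  Labels follow the three
    antiherbiome archetypes.
    """
    rng = np.random.default_rng(seed)
    names = ("SLT", "ILW", "BCL")
    traits = ("WD", "LeafSize", "StemSpines_prop", "LeafSpines_prop", "Latex_prop")
    trait_keys = ("WD", "LeafSize", "StemSpines", "LeafSpines", "Latex")
    centroids = np.array([[ARCHETYPE_Z[t][n] for t in trait_keys] for n in names])
    d_min = min(
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(3) for j in range(i + 1, 3)
    )
    pooled_sd = np.sqrt(len(traits))
    centroids = centroids * (separation * pooled_sd / d_min)
    rows, labels = [], []
    for name, c in zip(names, centroids):
        rows.append(c + rng.standard_normal((n_per_cluster, len(traits))))
        labels += [name] * n_per_cluster
    values = pd.DataFrame(np.vstack(rows), columns=list(traits))
    values.index.name = "ecoregion_id"
    return values, pd.Series(labels, index=values.index, name="true_antiherbiome")
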