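"""Shared fixtures: random occurrence/trait fixtures with exact (dyadic)
arithmetic, record-level brute-force oracles, and small fauna worlds."""

import numpy as np
import pandas as pd
import pytest

from antiherbiome.fauna_metrics import FaunaAssemblage


def make_occurrence_fixture(rng, n_eco=6, n_sp=12, n_cells=1, max_abund=50):
    """Random abundance matrix + trait table with dyadic trait values.

    Dyadic rationals (multiples of 1/8) and small integer abundances keep
    every sum exact in binary floating point, so a vectorized path and a
    record-level loop must agree bit for bit.
    """
    species = [f"P{j}" for j in range(n_sp)]
    if n_cells == 1:
        index = pd.Index(range(n_eco), name="ecoregion_id")
    else:
        index = pd.MultiIndex.from_product(
            [range(n_eco), range(n_cells)], names=["ecoregion_id", "cell"]
        )
    occ = pd.DataFrame(
        rng.integers(0, max_abund + 1, size=(len(index), n_sp)), index=index, columns=species
    )
    rows = []
    for j, sp in enumerate(species):
        if rng.random() < 0.9:  # some species lack some traits
            rows.append((sp, "WD", rng.integers(1, 17) / 8.0, 1))
        if rng.random() < 0.9:
            rows.append((sp, "LeafSize", rng.integers(1, 33) / 8.0, 1))
        if rng.random() < 0.9:
            rows.append((sp, "StemSpines", float(rng.integers(0, 2)), 1))
        if rng.random() < 0.9:
            rows.append((sp, "Latex", float(rng.integers(0, 2)), 1))
        if rng.random() < 0.5:  # palms
            rows.append((sp, "LeafSpines", float(rng.integers(0, 2)), 1))
    traits = pd.DataFrame(rows, columns=["species_id", "trait", "value", "n_records"])
    return occ, traits


# ---------------------------------------------------------------------------
# record-level brute-force oracles (independent of the package's vector path)

def brute_weighted_mean(occ, traits, trait):
    vals = {
        r.species_id: r.value
        for r in traits.itertuples()
        if r.trait == trait and not pd.isna(r.value)
    }
    eco_level = occ.index.get_level_values(0) if isinstance(occ.index, pd.MultiIndex) else occ.index
    cells_by_eco = {}
    for i in range(len(occ)):
        eco = eco_level[i]
        num = den = 0.0
        for sp in occ.columns:
            if sp in vals:
                a = occ.iloc[i][sp]
                num += a * vals[sp]
                den += a
        cells_by_eco.setdefault(eco, []).append(num / den if den > 0 else np.nan)
    out = {}
    for eco, cells in cells_by_eco.items():
        good = [c for c in cells if not np.isnan(c)]
        out[eco] = sum(good) / len(good) if good else np.nan
    return pd.Series(out)


def brute_binary_counts(occ, traits, trait):
    vals = {
        r.species_id: r.value
        for r in traits.itertuples()
        if r.trait == trait and not pd.isna(r.value)
    }
    eco_level = occ.index.get_level_values(0) if isinstance(occ.index, pd.MultiIndex) else occ.index
    pres, tot = {}, {}
    for i in range(len(occ)):
        eco = eco_level[i]
        for sp in occ.columns:
            if sp in vals:
                a = int(occ.iloc[i][sp])
                tot[eco] = tot.get(eco, 0) + a
                if vals[sp] == 1:
                    pres[eco] = pres.get(eco, 0) + a
    return pd.DataFrame(
        {
            "presences": pd.Series({e: pres.get(e, 0) for e in tot}),
            "absences": pd.Series({e: tot[e] - pres.get(e, 0) for e in tot}),
        }
    )


def brute_presence_counts(occ, traits, trait="LeafSpines", palm_species=None):
    vals = {
        r.species_id: r.value
        for r in traits.itertuples()
        if r.trait == trait and not pd.isna(r.value)
    }
    if palm_species is not None:
        vals = {s: v for s, v in vals.items() if s in palm_species}
    eco_level = occ.index.get_level_values(0) if isinstance(occ.index, pd.MultiIndex) else occ.index
    out = {}
    for eco in eco_level.unique():
        sub = occ.loc[eco_level == eco]
        present = absent = 0
        for sp in occ.columns:
            if sp in vals and (sub[sp] > 0).any():
                if vals[sp] == 1:
                    present += 1
                else:
                    absent += 1
        out[eco] = (present, absent)
    return pd.DataFrame(out, index=["present", "absent"]).T


@pytest.fixture
def occurrence_fixture():
    return make_occurrence_fixture


@pytest.fixture
def oracles():
    return {
        "weighted_mean": brute_weighted_mean,
        "binary_counts": brute_binary_counts,
        "presence_counts": brute_presence_counts,
    }


# ---------------------------------------------------------------------------
# fauna fixtures

def make_assemblage(rng, n_species=10, shape=(4, 6), n_eco=4):
    raster = np.full(shape, -1, dtype=int)
    cols = shape[1] // 2
    for e in range(n_eco):
        r0 = (e // 2) * (shape[0] // 2)
        c0 = (e % 2) * cols
        raster[r0 : r0 + shape[0] // 2, c0 : c0 + cols] = e
    table = pd.DataFrame(
        {
            "body_mass": rng.uniform(1, 500, n_species),
            "diet": rng.choice(["browser", "grazer", "mixed", "unknown"], n_species),
            "herbivory_fraction": rng.uniform(0.8, 1.0, n_species),
            "status": rng.choice(["EP_extinct", "extant"], n_species),
            "feeds_mainly_on_vegetative": rng.random(n_species) < 0.8,
        },
        index=pd.Index([f"A{i}" for i in range(n_species)], name="species_id"),
    )
    presence = rng.random((n_species,) + shape) < 0.5
    return FaunaAssemblage(table=table, presence=presence, raster=raster, cell_area_km2=1.0)


@pytest.fixture
def assemblage_factory():
    return make_assemblage
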