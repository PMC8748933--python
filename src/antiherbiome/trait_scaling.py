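"""Species-level trait summarisation and scaling to ecoregion values.

Five woody-plant antiherbivory traits are handled:

* ``WD`` — wood density (g/cm^3), continuous;
* ``LeafSize`` — leaf area (unit carried by the caller), continuous;
* ``StemSpines`` — presence of spines/thorns/prickles on stems, binary;
* ``LeafSpines`` — presence of leaf spines (palms only), binary;
* ``Latex`` — latex production, binary.

Species records are first collapsed to one value per species and trait
(arithmetic mean for continuous traits, maximum for binary traits — a
reported presence is trusted over an omission).  Species values are then
scaled to ecoregions through an occurrence-record abundance matrix:

* continuous traits become abundance-weighted means per grid cell,
  averaged (unweighted) over the cells of the ecoregion;
* stem spines and latex become counts of spiny/latex-bearing occurrence
  records ("presences") and their complement ("absences") out of the
  total covered abundance;
* leaf spines, whose abundance signal is unreliable at the species-pool
  size available for palms, are collapsed to species presence/absence
  before counting.

Occurrence matrices are :class:`pandas.DataFrame` objects with species as
columns and either a plain ecoregion index or a ``(ecoregion, cell)``
MultiIndex as rows; the single-index form behaves exactly like a world
with one grid cell per ecoregion.  Species lacking a value for a trait are
excluded from both the numerator and the denominator of that trait's
aggregation, never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS_TRAITS = ("WD", "LeafSize")
BINARY_TRAITS = ("StemSpines", "LeafSpines", "Latex")
ALL_TRAITS = CONTINUOUS_TRAITS + BINARY_TRAITS

TRAIT_COLUMNS = ("species_id", "trait", "value")


def summarize_species(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw trait records to one value per species and trait.

    Parameters
    ----------
    records : DataFrame with columns ``species_id``, ``trait``, ``value``.

    Returns
    -------
    DataFrame with columns ``species_id``, ``trait``, ``value``,
    ``n_records`` (records retained for the species/trait pair).

    Continuous traits are averaged; binary traits take the maximum of the
    recorded 0/1 values.  Negative continuous values are rejected record
    by record with a logged warning; binary values outside {0, 1} raise.
    """
    missing = [c for c in TRAIT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"trait records lack columns: {missing}")
    unknown = set(records["trait"]) - set(ALL_TRAITS)
    if unknown:
        raise ValueError(f"unknown trait names: {sorted(unknown)}")

    rec = records.loc[:, list(TRAIT_COLUMNS)].copy()
    cont = rec["trait"].isin(CONTINUOUS_TRAITS)
    bad = cont & (rec["value"] < 0)
    if bad.any():
        logger.warning("rejecting %d negative continuous trait records", int(bad.sum()))
        rec = rec.loc[~bad]
    binary = rec["trait"].isin(BINARY_TRAITS)
    if not rec.loc[binary, "value"].isin([0, 1]).all():
        offending = rec.loc[binary & ~rec["value"].isin([0, 1])]
        raise ValueError(
            "binary trait values outside {0, 1}: "
            f"{offending[['species_id', 'trait', 'value']].head().to_dict('records')}"
        )

    grouped = rec.groupby(["species_id", "trait"], sort=True)["value"]
    agg = grouped.agg(["mean", "max", "size"]).reset_index()
    is_binary = agg["trait"].isin(BINARY_TRAITS)
    agg["value"] = np.where(is_binary, agg["max"], agg["mean"])
    out = agg[["species_id", "trait", "value"]].copy()
    out["n_records"] = agg["size"].astype(int)
    return out


def trait_values(traits: pd.DataFrame, trait: str) -> pd.Series:
    """Return the per-species value Series for one trait of a trait table."""
    if trait not in ALL_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {ALL_TRAITS}")
    sub = traits.loc[traits["trait"] == trait]
    if sub["species_id"].duplicated().any():
        raise ValueError(f"trait table has duplicate rows for trait {trait!r}")
    return pd.Series(sub["value"].to_numpy(), index=sub["species_id"].to_numpy(), name=trait)


def _ecoregion_index(occ: pd.DataFrame) -> pd.Index:
    """Ecoregion label per row, for plain or (ecoregion, cell) indices."""
    if isinstance(occ.index, pd.MultiIndex):
        return occ.index.get_level_values(0)
    return occ.index


def ecoregion_weighted_mean(occ: pd.DataFrame, traits: pd.DataFrame, trait: str) -> pd.Series:
    """Abundance-weighted ecoregion mean of a continuous trait.

    Per grid cell the community-weighted mean is
    ``sum(abundance * species value) / sum(abundance)`` over species with
    a value; the ecoregion value is the unweighted mean over its cells.
    Cells (and hence ecoregions) with zero covered abundance are missing.
    """
    if trait in BINARY_TRAITS:
        raise ValueError(
            f"{trait} is binary; use ecoregion_binary_counts or ecoregion_presence_fraction"
        )
    vals = trait_values(traits, trait).dropna()
    cols = occ.columns.intersection(vals.index)
    A = occ[cols].to_numpy(dtype=float)
    v = vals.loc[cols].to_numpy(dtype=float)
    den = A.sum(axis=1)
    num = A @ v
    with np.errstate(invalid="ignore", divide="ignore"):
        cell = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    eco = _ecoregion_index(occ)
    # plain sequential accumulation in row order: the mean over cells is
    # then bit-reproducible against a record-level loop
    codes, uniques = pd.factorize(eco)
    valid = np.isfinite(cell)
    sums = np.bincount(codes[valid], weights=cell[valid], minlength=len(uniques))
    counts = np.bincount(codes[valid], minlength=len(uniques))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.Series(means, index=uniques, name=f"{trait}_mean")
    out.index.name = "ecoregion_id"
    return out.reindex(eco.unique())


def ecoregion_binary_counts(occ: pd.DataFrame, traits: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Presence/absence record counts for stem spines or latex.

    presences = sum(abundance * indicator); absences = covered total
    abundance - presences.  Both are integers and sum to the covered
    abundance of the ecoregion (cells pooled).
    """
    if trait not in ("StemSpines", "Latex"):
        raise ValueError(f"{trait!r} is not an abundance-counted binary trait")
    vals = trait_values(traits, trait).dropna()
    cols = occ.columns.intersection(vals.index)
    A = occ[cols].to_numpy(dtype=float)
    ind = vals.loc[cols].to_numpy(dtype=float)
    pres = A @ ind
    total = A.sum(axis=1)
    eco = _ecoregion_index(occ)
    df = pd.DataFrame({"presences": pres, "total": total}, index=eco).groupby(level=0).sum()
    out = pd.DataFrame(
        {
            f"{trait}_presences": df["presences"].round().astype(int),
            f"{trait}_absences": (df["total"] - df["presences"]).round().astype(int),
        }
    )
    out.index.name = "ecoregion_id"
    return out.reindex(eco.unique())


def ecoregion_presence_fraction(
    occ: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str = "LeafSpines",
    palm_species=None,
) -> pd.DataFrame:
    """Species-level presence counts for the palm-only leaf-spine trait.

    Ecoregion abundance is collapsed to species presence/absence before
    applying the trait indicator, so a species recorded a hundred times
    counts once.  When ``palm_species`` is given, non-palm species in the
    trait table are excluded with a logged count (the trait is scored for
    palms only).  Ecoregions with no covered species have both counts 0
    and are flagged ``has_palms = False``.
    """
    vals = trait_values(traits, trait).dropna()
    if palm_species is not None:
        palm_species = set(palm_species)
        dropped = [s for s in vals.index if s not in palm_species]
        if dropped:
            logger.warning("excluding %d non-palm species from %s", len(dropped), trait)
            vals = vals.loc[[s for s in vals.index if s in palm_species]]
    cols = occ.columns.intersection(vals.index)
    eco = _ecoregion_index(occ)
    present = (occ[cols] > 0).groupby(eco).any()  # species present anywhere in ecoregion
    P = present.to_numpy(dtype=float)
    ind = vals.loc[cols].to_numpy(dtype=float)
    n_present = P @ ind
    n_total = P.sum(axis=1)
    out = pd.DataFrame(
        {
            f"{trait}_present_species": n_present.round().astype(int),
            f"{trait}_absent_species": (n_total - n_present).round().astype(int),
            "has_palms": n_total > 0,
        },
        index=present.index,
    )
    out.index.name = "ecoregion_id"
    n_missing = int((~out["has_palms"]).sum())
    if n_missing:
        logger.info("%d ecoregions lack covered species for %s", n_missing, trait)
    return out.reindex(eco.unique())


def species_coverage(occ: pd.DataFrame, traits: pd.DataFrame) -> pd.Series:
    """Number of distinct trait-covered species present per ecoregion."""
    covered = occ.columns.intersection(pd.unique(traits["species_id"]))
    eco = _ecoregion_index(occ)
    present = (occ[covered] > 0).groupby(eco).any()
    out = present.sum(axis=1).astype(int)
    out.name = "species_coverage"
    return out


def summarize_ecoregions(
    occ: pd.DataFrame, traits: pd.DataFrame, palm_species=None
) -> pd.DataFrame:
    """Full per-ecoregion trait summary (means, counts, coverage)."""
    parts = [
        ecoregion_weighted_mean(occ, traits, "WD"),
        ecoregion_weighted_mean(occ, traits, "LeafSize"),
        ecoregion_binary_counts(occ, traits, "StemSpines"),
        ecoregion_binary_counts(occ, traits, "Latex"),
        ecoregion_presence_fraction(occ, traits, "LeafSpines", palm_species=palm_species),
        species_coverage(occ, traits),
    ]
    out = pd.concat(parts, axis=1)
    out.index.name = "ecoregion_id"
    return out
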