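"""Savanna-to-forest biome-shift classification and fossil validation.

An ecoregion is inferred to have shifted from a Pleistocene grassy
ecosystem to present-day forest when it (1) is currently
forest-dominated, (2) belongs to an antiherbiome analogous to an
African savanna type (SLT or ILW) and (3) was rich in megafauna and,
especially, mega-grazers — richness at or above the 0.75 quantile of
the respective ecoregion distributions.  Currently savanna-dominated
ecoregions meeting the same fauna criteria are classed as stable
savannas.  Manual overrides (e.g. a savanna one species short of the
megafauna threshold) are applied last and logged verbatim.

Classifications are validated against fossil sites with evidence of
past savanna dominance: a site supports a shift when its local
vegetation is currently forest and it lies inside, or adjacent to, a
shift-classified ecoregion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOIST_FOREST_BIOMES = frozenset({"moist_forest"})
DRY_FOREST_BIOMES = frozenset({"dry_forest"})
FOREST_BIOMES = MOIST_FOREST_BIOMES | DRY_FOREST_BIOMES
SAVANNA_BIOMES = frozenset({"savanna", "grassland"})

CLASS_STABLE = "StableSavanna"
CLASS_SHIFT_MOIST = "ShiftToMoistForest"
CLASS_SHIFT_DRY = "ShiftToDryForest"
CLASS_NA = "NotApplicable"
SHIFT_CLASSES = (CLASS_SHIFT_MOIST, CLASS_SHIFT_DRY)


@dataclass
class Override:
    ecoregion_id: object
    action: str  # "stable" | "shift" | "exclude"
    reason: str


@dataclass
class ShiftRule:
    quantile: float = 0.75
    antiherbiomes_eligible: tuple = ("SLT", "ILW")
    manual_overrides: list = field(default_factory=list)


@dataclass
class Thresholds:
    m_rich: float
    mg_rich: float
    quantile: float
    method: str = "nearest_rank"


def nearest_rank_quantile(values, q: float) -> float:
    """Type-1 (nearest-rank) empirical quantile: the ceil(qn)-th order stat."""
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values to take a quantile of")
    idx = max(int(np.ceil(q * len(v))) - 1, 0)
    return float(v[idx])


def derive_thresholds(fauna_summary: pd.DataFrame, rule: ShiftRule | None = None) -> Thresholds:
    """Empirical richness thresholds at the rule's quantile (nearest-rank)."""
    rule = rule or ShiftRule()
    usable = fauna_summary[["M_rich", "MG_rich"]].dropna()
    if len(usable) < 4:
        raise ValueError(f"need at least 4 ecoregions to derive thresholds, got {len(usable)}")
    return Thresholds(
        m_rich=nearest_rank_quantile(usable["M_rich"], rule.quantile),
        mg_rich=nearest_rank_quantile(usable["MG_rich"], rule.quantile),
        quantile=rule.quantile,
    )


def classify_shift(
    table: pd.DataFrame,
    rule: ShiftRule | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Classify every ecoregion with a full rule trace.

    ``table`` needs columns ``biome``, ``antiherbiome``, ``M_rich``,
    ``MG_rich`` (and optionally ``insular``; insular ecoregions are not
    classified).  Thresholds are derived from the table itself
    (non-insular rows) when not supplied.  Overrides are applied last and
    appear verbatim in the trace.
    """
    rule = rule or ShiftRule()
    work = table.copy()
    insular = work["insular"].astype(bool) if "insular" in work else pd.Series(False, index=work.index)
    if thresholds is None:
        thresholds = derive_thresholds(work.loc[~insular], rule)

    classes, traces = {}, {}
    for eco, row in work.iterrows():
        if insular.loc[eco]:
            classes[eco], traces[eco] = CLASS_NA, "insular"
            continue
        label = row.get("antiherbiome")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            classes[eco], traces[eco] = CLASS_NA, "missing antiherbiome label"
            continue
        eligible = label in rule.antiherbiomes_eligible
        m_ok = np.isfinite(row["M_rich"]) and row["M_rich"] >= thresholds.m_rich
        mg_ok = np.isfinite(row["MG_rich"]) and row["MG_rich"] >= thresholds.mg_rich
        biome = row["biome"]
        forest = biome in FOREST_BIOMES
        savanna = biome in SAVANNA_BIOMES
        trace = (
            f"biome={biome};antiherbiome={label}"
            f"({'eligible' if eligible else 'ineligible'});"
            f"M_rich={row['M_rich']:.3g}{'>=' if m_ok else '<'}{thresholds.m_rich:.3g};"
            f"MG_rich={row['MG_rich']:.3g}{'>=' if mg_ok else '<'}{thresholds.mg_rich:.3g}"
        )
        if eligible and m_ok and mg_ok and forest:
            cls = CLASS_SHIFT_MOIST if biome in MOIST_FOREST_BIOMES else CLASS_SHIFT_DRY
        elif eligible and m_ok and mg_ok and savanna:
            cls = CLASS_STABLE
        else:
            cls = CLASS_NA
        classes[eco], traces[eco] = cls, trace

    for ov in rule.manual_overrides:
        if ov.ecoregion_id not in work.index:
            logger.warning("override for unknown ecoregion %r ignored", ov.ecoregion_id)
            continue
        eco = ov.ecoregion_id
        if ov.action == "stable":
            classes[eco] = CLASS_STABLE
        elif ov.action == "shift":
            biome = work.loc[eco, "biome"]
            classes[eco] = CLASS_SHIFT_MOIST if biome in MOIST_FOREST_BIOMES else CLASS_SHIFT_DRY
        elif ov.action == "exclude":
            classes[eco] = CLASS_NA
        else:
            raise ValueError(f"unknown override action {ov.action!r}")
        traces[eco] = f"{traces[eco]};override[{ov.action}]: {ov.reason}"
        logger.info("override applied to %r: %s (%s)", eco, ov.action, ov.reason)

    out = pd.DataFrame(
        {"class": pd.Series(classes), "trace": pd.Series(traces)}
    ).reindex(work.index)
    out.index.name = "ecoregion_id"
    return out


@dataclass
class ValidationSummary:
    sites: pd.DataFrame  # per-site verdict and reason
    n_sites: int
    n_inside: int
    n_nearby: int
    n_supporting: int
    n_excluded_unknown: int

    @property
    def support_fraction(self) -> float | None:
        if self.n_sites == 0:
            return None
        return self.n_supporting / self.n_sites

    def __str__(self) -> str:
        if self.n_sites == 0:
            return "0 fossil sites; support fraction undefined"
        return (
            f"{self.n_supporting}/{self.n_sites} fossil sites support a savanna-to-forest "
            f"shift ({self.n_inside} inside, {self.n_nearby} nearby shift ecoregions)"
        )


def validate_fossils(
    sites: pd.DataFrame,
    classification: pd.DataFrame,
    adjacency: dict,
) -> ValidationSummary:
    """Score fossil sites against the shift classification.

    A site supports the shift hypothesis when its current local
    vegetation is forest and its ecoregion is classified as a shift, or
    is adjacent to a shift-classified ecoregion.  Sites in unknown
    ecoregions are excluded (and counted).
    """
    cls = classification["class"]
    shift_set = set(cls.index[cls.isin(SHIFT_CLASSES)])
    rows = []
    n_excluded = 0
    for _, site in sites.iterrows():
        eco = site["ecoregion_id"]
        if eco not in cls.index:
            n_excluded += 1
            logger.warning("fossil site %r in unknown ecoregion %r excluded", site.get("site_id"), eco)
            continue
        forest_local = site["current_local_vegetation"] == "forest"
        inside = eco in shift_set
        nearby = (not inside) and any(nb in shift_set for nb in adjacency.get(eco, ()))
        supports = forest_local and (inside or nearby)
        if not forest_local:
            reason = "local vegetation still savanna"
        elif inside:
            reason = "forest site inside a shift ecoregion"
        elif nearby:
            reason = "forest site adjacent to a shift ecoregion"
        else:
            reason = "forest site away from any shift ecoregion"
        rows.append(
            {
                "site_id": site.get("site_id"),
                "ecoregion_id": eco,
                "supports_shift": supports,
                "position": "inside" if inside else ("nearby" if nearby else "outside"),
                "reason": reason,
            }
        )
    df = pd.DataFrame(rows, columns=["site_id", "ecoregion_id", "supports_shift", "position", "reason"])
    supp = df.loc[df["supports_shift"]] if len(df) else df
    return ValidationSummary(
        sites=df,
        n_sites=len(df),
        n_inside=int((supp["position"] == "inside").sum()) if len(df) else 0,
        n_nearby=int((supp["position"] == "nearby").sum()) if len(df) else 0,
        n_supporting=int(df["supports_shift"].sum()) if len(df) else 0,
        n_excluded_unknown=n_excluded,
    )
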