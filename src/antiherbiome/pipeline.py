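"""End-to-end orchestration: world -> trait scaling -> fauna metrics ->
disturbance -> regression models -> randomization test -> antiherbiome
clustering -> biome-shift classification -> reports.

Defaults match the protocol's printed settings: correlation screen at
r = 0.60, significance at p <= 0.05, VIF bound 3.33, shift-rule quantile
0.75, fire-detection confidence 95 %, 1000 m land-cover buffer, 10 %
anthropogenic fraction, 1000 randomization replicates.  Every run can
emit a resolved-config snapshot alongside its outputs, and a fixed seed
reproduces all outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    assoc_models,
    biome_shift,
    defence_space,
    disturbance,
    fauna_metrics,
    permutation_null,
    synthetic_world,
    trait_scaling,
)
from .synthetic_world import WorldConfig, _config_dict

logger = logging.getLogger(__name__)

BASE_PREDICTORS = (
    "M_rich", "M_bm", "MGB_dif", "H_rich", "H_bm", "HGB_dif",
    "MAT", "MAR", "pH", "RS", "CEC", "SND", "FI",
)

RESPONSES = ("WD", "LeafSize", "StemSpines", "Latex", "LeafSpines")

# herbivory predictors and the coefficient sign indicating a defence
# response (traits where "more" means more defended)
DEFENCE_SIGNS = {
    "WD": {"M_rich": 1, "M_bm": 1, "MGB_dif": 1, "H_rich": 1, "H_bm": 1, "HGB_dif": 1},
    "StemSpines": {"M_rich": 1, "MGB_dif": 1, "H_rich": 1, "HGB_dif": 1},
    "Latex": {"M_rich": 1, "MGB_dif": 1, "H_rich": 1, "HGB_dif": 1},
    "LeafSpines": {"M_rich": 1, "MGB_dif": 1, "H_rich": 1, "HGB_dif": 1},
    # smaller leaves are the defended state: a negative richness slope is defensive
    "LeafSize": {"M_rich": -1, "MGB_dif": -1, "H_rich": -1, "HGB_dif": -1},
}


def model_candidates(response: str) -> tuple[list, tuple]:
    cands = list(BASE_PREDICTORS)
    if response == "WD":
        cands.append("HUR")
    forced = ("M_bm", "H_bm") if response == "StemSpines" else ()
    return cands, forced


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    r_threshold: float = 0.60
    p_threshold: float = 0.05
    vif_max: float = 3.33
    quantile: float = 0.75
    confidence_min: float = 95.0
    buffer_m: float = 1000.0
    max_anthro_fraction: float = 0.10
    n_reps: int = 1000
    permutation_scheme: str = "shuffle_species_columns"
    k_max: int = 6
    n_axes: int | None = None
    run_disturbance: bool = True
    run_models: bool = True
    run_permutation: bool = True
    run_clustering: bool = True
    run_shift: bool = True
    overrides: list = field(default_factory=list)

    @property
    def seed(self) -> int:
        return self.world.seed

    def resolved(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k not in ("world", "overrides")}
        d["world"] = _config_dict(self.world)
        d["overrides"] = [o.__dict__ for o in self.overrides]
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: synthetic_world.SyntheticWorld
    trait_summary: pd.DataFrame
    fauna_summary: pd.DataFrame
    disturbance_obs: pd.DataFrame | None
    predictors: pd.DataFrame
    models: dict
    null_tests: dict
    defence: defence_space.DefenceMatrix | None
    pca: defence_space.PCAResult | None
    clusters: defence_space.ClusterResult | None
    contrasts: defence_space.ContrastResult | None
    thresholds: biome_shift.Thresholds | None
    classification: pd.DataFrame | None
    fossil_validation: biome_shift.ValidationSummary | None
    reports: dict

    def save(self, outdir) -> None:
        write_reports(self, outdir)


def _standardize_predictors(table: pd.DataFrame, cols) -> pd.DataFrame:
    X = table[list(cols)].astype(float)
    sd = X.std(ddof=0).replace(0, np.nan)
    return (X - X.mean()) / sd


def _response_of(summary: pd.DataFrame, response: str):
    if response in ("WD", "LeafSize"):
        return summary[f"{response}_mean"]
    if response == "LeafSpines":
        return summary["LeafSpines_present_species"], summary["LeafSpines_absent_species"]
    return summary[f"{response}_presences"], summary[f"{response}_absences"]


def run_pipeline(config: PipelineConfig | None = None, outdir=None,
                 world: synthetic_world.SyntheticWorld | None = None) -> PipelineResult:
    """Run every enabled stage in order and (optionally) write reports.

    Stage dependencies are enforced with clear refusals: permutation
    needs the models, shift classification needs the clustering labels.
    """
    config = config or PipelineConfig()
    if world is None:
        world = synthetic_world.generate_world(config.world)
    table = world.covariates  # covariates + fauna summary + biome

    trait_summary = trait_scaling.summarize_ecoregions(
        world.occurrences, world.traits, palm_species=world.palm_species
    )
    fauna_summary = fauna_metrics.compute_fauna_summary(world.fauna)

    disturbance_obs = None
    if config.run_disturbance:
        kept = disturbance.filter_wildfires(
            world.hotspots, world.landcover,
            buffer_m=config.buffer_m, confidence_min=config.confidence_min,
            max_anthro_fraction=config.max_anthro_fraction,
        )
        fires = disturbance.fire_metrics(
            kept, world.raster, world.landcover, world.config.cell_area_km2
        )
        hur = disturbance.hurricane_rate(
            world.tracks, world.raster, world.config.cell_size_m, world.config.cell_area_km2
        )
        disturbance_obs = fires.add_suffix("_obs").join(hur.rename("HUR_obs"))

    continental = ~table["insular"].astype(bool)
    all_preds = sorted(set(BASE_PREDICTORS) | {"HUR"})
    pred_rows = table.index[continental & table[all_preds].notna().all(axis=1)]
    X_all = _standardize_predictors(table.loc[pred_rows], all_preds)
    X_all = assoc_models.add_quadratic_terms(X_all, ["M_bm", "H_bm"])

    models: dict = {}
    null_tests: dict = {}
    if config.run_models:
        for response in RESPONSES:
            resp = _response_of(trait_summary, response)
            if isinstance(resp, tuple):
                ok = resp[0].reindex(pred_rows).notna() & resp[1].reindex(pred_rows).notna()
                ok &= (resp[0].reindex(pred_rows) + resp[1].reindex(pred_rows)) > 0
                family = "binomial_counts"
            else:
                ok = resp.reindex(pred_rows).notna()
                family = "gaussian"
            rows = pred_rows[ok.reindex(pred_rows).fillna(False)]
            cands, forced = model_candidates(response)
            X = X_all.loc[rows]
            y = (
                resp.loc[rows]
                if family == "gaussian"
                else (resp[0].loc[rows], resp[1].loc[rows])
            )
            cols = cands + [assoc_models.quad_name(q) for q in forced]
            # multicollinearity guard: when a selected model violates the
            # VIF bound, the worst-inflated predictor leaves the candidate
            # set and selection is re-run (no multicollinearity may remain)
            for _ in range(len(cands)):
                fit = assoc_models.stepwise_select(
                    y, X[cols],
                    family=family, response_name=response,
                    forced_quadratics=tuple(q for q in forced if q in cols),
                    branch_pair=("MAR", "pH"),
                    r_threshold=config.r_threshold, p_threshold=config.p_threshold,
                    expected_signs=DEFENCE_SIGNS.get(response),
                )
                if fit.empty:
                    break
                try:
                    fit, _ = assoc_models.diagnostics(
                        fit, X, y, adjacency=world.adjacency, index=rows,
                        p_threshold=config.p_threshold, vif_max=config.vif_max,
                    )
                    break
                except assoc_models.CollinearityError:
                    vif = assoc_models.variance_inflation(X.loc[rows], fit.predictors)
                    worst = assoc_models.base_of(str(vif.idxmax()))
                    logger.info("%s: dropping %s (VIF %.2f) and re-selecting",
                                response, worst, vif.max())
                    cols = [c for c in cols
                            if assoc_models.base_of(c) != worst]
            if not fit.empty:
                assoc_models.effect_sizes(fit)
                fit.contributions = assoc_models.dominance_contributions(
                    y, X, fit.predictors, family=family
                )
            models[response] = fit
            logger.info("%s: selected %s (branch %s)", response, fit.predictors, fit.branch)

        if config.run_permutation:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
            for response, fit in models.items():
                if fit.empty:
                    continue
                null_tests[response] = permutation_null.coefficient_null_test(
                    fit, world.occurrences, world.traits,
                    X_all.loc[fit_rows_of(fit, trait_summary, pred_rows)],
                    n_reps=config.n_reps, rng=rng,
                    scheme=config.permutation_scheme,
                    palm_species=world.palm_species,
                )
    elif config.run_permutation:
        raise RuntimeError("permutation stage needs the models stage; enable run_models")

    defence = pca = clusters = contrasts = None
    thresholds = classification = validation = None
    if config.run_clustering:
        spine_model = models.get("LeafSpines")
        if spine_model is not None and spine_model.empty:
            spine_model = None
        defence = defence_space.build_defence_matrix(
            trait_summary.loc[pred_rows], spine_model=spine_model, predictors=X_all
        )
        pca = defence_space.pca_axes(defence)
        clusters = defence_space.cluster_antiherbiomes(
            pca, defence.z, k_max=config.k_max, n_axes=config.n_axes
        )
        contrast_vars = pd.concat(
            [pca.scores.iloc[:, :3],
             table.loc[pca.scores.index,
                       ["M_rich", "M_bm", "MG_rich", "MB_rich", "MMf_rich", "MGB_dif",
                        "H_rich", "H_bm", "HGB_dif", "MAT", "MAR", "RS", "CEC", "pH",
                        "SND", "FI", "fire_count", "HUR"]]],
            axis=1,
        )
        contrasts = defence_space.contrast_groups(contrast_vars, clusters.labels)

    if config.run_shift:
        if clusters is None:
            raise RuntimeError(
                "biome-shift stage needs antiherbiome labels; enable run_clustering"
            )
        rule = biome_shift.ShiftRule(
            quantile=config.quantile, manual_overrides=list(config.overrides)
        )
        thresholds = biome_shift.derive_thresholds(
            fauna_summary.loc[continental.index[continental]], rule
        )
        shift_table = pd.DataFrame(
            {
                "biome": table["biome"],
                "antiherbiome": clusters.labels.reindex(table.index),
                "M_rich": fauna_summary["M_rich"],
                "MG_rich": fauna_summary["MG_rich"],
                "insular": table["insular"],
            }
        )
        classification = biome_shift.classify_shift(shift_table, rule, thresholds)
        validation = biome_shift.validate_fossils(
            world.fossil_sites, classification, world.adjacency
        )

    result = PipelineResult(
        config=config, world=world, trait_summary=trait_summary,
        fauna_summary=fauna_summary, disturbance_obs=disturbance_obs,
        predictors=X_all, models=models, null_tests=null_tests,
        defence=defence, pca=pca, clusters=clusters, contrasts=contrasts,
        thresholds=thresholds, classification=classification,
        fossil_validation=validation, reports={},
    )
    result.reports = build_reports(result)
    if outdir is not None:
        write_reports(result, outdir)
    return result


def fit_rows_of(fit, trait_summary, pred_rows):
    """Rows a fitted model actually used (response present among predictors rows)."""
    resp = _response_of(trait_summary, fit.response)
    if isinstance(resp, tuple):
        ok = resp[0].reindex(pred_rows).notna() & resp[1].reindex(pred_rows).notna()
        ok &= (resp[0].reindex(pred_rows) + resp[1].reindex(pred_rows)) > 0
    else:
        ok = resp.reindex(pred_rows).notna()
    return pred_rows[ok.reindex(pred_rows).fillna(False)]


# ---------------------------------------------------------------------------
# reports

def model_table(fit) -> pd.DataFrame:
    """Per-predictor effect-size/contribution table for one selected model."""
    if fit.empty:
        return pd.DataFrame(columns=["r", "ci_low", "ci_high", "avg_contribution", "p"])
    eff = fit.effect_table if fit.effect_table is not None else assoc_models.effect_sizes(fit)
    out = eff.copy()
    if fit.contributions is not None:
        out["avg_contribution"] = fit.contributions
    out["p"] = fit.pvalues.reindex(out.index)
    return out


def build_reports(result: PipelineResult) -> dict:
    reports: dict = {}
    per_trait = {}
    for response, fit in result.models.items():
        per_trait[response] = {
            "predictors": fit.predictors,
            "fit_stat": fit.fit_stat,
            "branch": fit.branch,
            "delta_aic": fit.delta_aic,
            "table": model_table(fit),
        }
    reports["models"] = per_trait

    if result.clusters is not None:
        table = result.world.covariates
        cell_area = result.world.config.cell_area_km2
        n_cells = pd.Series(
            np.bincount(result.world.raster[result.world.raster >= 0]),
            index=pd.RangeIndex(result.world.config.n_ecoregions),
        )
        area = n_cells * cell_area
        total = float(area.sum())
        labels = result.clusters.labels.reindex(table.index)
        rows = []
        for name in sorted(labels.dropna().unique()):
            for biome_name in sorted(table["biome"].unique()):
                mask = (labels == name) & (table["biome"] == biome_name)
                rows.append((name, biome_name, float(area[mask].sum()) / total))
        area_tab = pd.DataFrame(rows, columns=["antiherbiome", "biome", "area_proportion"])
        reports["antiherbiome_area"] = area_tab
        reports["unclassified_area_proportion"] = float(area[labels.isna()].sum()) / total

    if result.classification is not None:
        cls = result.classification["class"]
        shift = cls[cls.isin(biome_shift.SHIFT_CLASSES)]
        reports["shift"] = {
            "n_shift": int(len(shift)),
            "n_stable": int((cls == biome_shift.CLASS_STABLE).sum()),
            "summary": "none detected" if len(shift) == 0 else
                       f"{len(shift)} shift ecoregions "
                       f"({int((cls == biome_shift.CLASS_SHIFT_MOIST).sum())} moist, "
                       f"{int((cls == biome_shift.CLASS_SHIFT_DRY).sum())} dry)",
        }
        if result.fossil_validation is not None:
            reports["fossil_validation"] = str(result.fossil_validation)
    return reports


def write_reports(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(json.dumps(result.config.resolved(), indent=1))
    result.trait_summary.to_csv(out / "trait_summary.csv")
    result.fauna_summary.to_csv(out / "fauna_summary.csv")
    if result.disturbance_obs is not None:
        result.disturbance_obs.to_csv(out / "disturbance_observed.csv")
    for response, fit in result.models.items():
        model_table(fit).to_csv(out / f"model_{response}.csv")
    if result.null_tests:
        pd.concat(
            {name: t.table for name, t in result.null_tests.items()}, names=["response"]
        ).to_csv(out / "null_tests.csv")
    if result.pca is not None:
        result.pca.scores.to_csv(out / "pca_scores.csv")
        result.pca.loadings.to_csv(out / "pca_loadings.csv")
        result.clusters.labels.to_csv(out / "antiherbiome_labels.csv")
        result.contrasts.global_tests.to_csv(out / "contrasts_global.csv", index=False)
        result.contrasts.pairwise.to_csv(out / "contrasts_pairwise.csv", index=False)
        result.reports["antiherbiome_area"].to_csv(out / "antiherbiome_area.csv", index=False)
    if result.classification is not None:
        result.classification.to_csv(out / "shift_classification.csv")
        result.fossil_validation.sites.to_csv(out / "fossil_validation.csv", index=False)
    summary = {
        "seed": result.config.seed,
        "fossil_validation": result.reports.get("fossil_validation"),
        "shift": result.reports.get("shift"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
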