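"""Antiherbiome detection: the 5-trait defence matrix, its principal
components, hierarchical clustering, and group contrasts.

Each ecoregion is described by five defence coordinates — mean wood
density, mean leaf size, and the proportions of spiny-stemmed plants,
spiny-leaved palm species and latex-bearing plants — standardized to
zero mean and unit variance.  Principal components of this matrix span
the defence-strategy space; Ward hierarchical clustering on the
component scores groups ecoregions into "antiherbiomes", named after
their trait profile:

* ``SLT`` — Small Leaves Thorny (physical defence, arid nutrient-rich
  savanna analogue);
* ``ILW`` — Intermediate Leaves Woody (high wood density, mesic
  nutrient-poor savanna analogue);
* ``BCL`` — Broad Chemically-defended Leaves (large leaves and latex,
  the forest strategy).

The cluster count is chosen by the relative loss of within-group
inertia as the partition is refined, and differences among the groups
are tested with Kruskal–Wallis plus pairwise Dunn tests under
Benjamini–Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .assoc_models import FitResult

logger = logging.getLogger(__name__)

DEFENCE_COLUMNS = ("WD", "LeafSize", "StemSpines_prop", "LeafSpines_prop", "Latex_prop")
ANTIHERBIOME_NAMES = ("SLT", "ILW", "BCL")

# trait-profile archetypes in standardized defence space, used to name
# clusters (indices are permutation-arbitrary, profiles are not)
_ARCHETYPE_SCORES = {
    "SLT": {"LeafSize": -1.0, "StemSpines_prop": 1.0},
    "ILW": {"WD": 1.0},
    "BCL": {"LeafSize": 1.0, "Latex_prop": 1.0},
}


@dataclass
class DefenceMatrix:
    values: pd.DataFrame  # raw means/proportions, complete rows only
    z: pd.DataFrame  # standardized copy
    filled: list = field(default_factory=list)  # ecoregions filled from the spine model
    excluded: list = field(default_factory=list)  # ecoregions dropped as incomplete


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean unit-variance columns; constant columns raise."""
    sd = df.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant defence columns cannot be standardized: {const}")
    return (df - df.mean()) / sd


def build_defence_matrix(
    summary: pd.DataFrame,
    spine_model: FitResult | None = None,
    predictors: pd.DataFrame | None = None,
) -> DefenceMatrix:
    """Assemble and standardize the ecoregion-by-trait defence matrix.

    ``summary`` is the per-ecoregion trait summary (means plus
    presence/absence counts).  Binary traits become proportions.
    Ecoregions without palms get their leaf-spine proportion from the
    fitted leaf-spine model's predicted probability (``spine_model`` +
    ``predictors``); these fills are logged and recorded.  Ecoregions
    still missing any value are excluded, also recorded.
    """
    vals = pd.DataFrame(index=summary.index)
    vals["WD"] = summary["WD_mean"]
    vals["LeafSize"] = summary["LeafSize_mean"]
    for trait in ("StemSpines", "Latex"):
        pres = summary[f"{trait}_presences"]
        tot = pres + summary[f"{trait}_absences"]
        vals[f"{trait}_prop"] = pres / tot.where(tot > 0)
    pres = summary["LeafSpines_present_species"]
    tot = pres + summary["LeafSpines_absent_species"]
    vals["LeafSpines_prop"] = pres / tot.where(tot > 0)

    filled = []
    missing_ls = vals["LeafSpines_prop"].isna()
    if missing_ls.any() and spine_model is not None:
        if predictors is None:
            raise ValueError("predictors needed to fill leaf-spine values from the model")
        fill_idx = vals.index[missing_ls & vals.index.isin(predictors.index)]
        if len(fill_idx):
            probs = spine_model.predict(predictors.loc[fill_idx])
            vals.loc[fill_idx, "LeafSpines_prop"] = probs
            filled = list(fill_idx)
            logger.info("filled leaf-spine proportion for %d palm-free ecoregions", len(filled))

    complete = vals.dropna()
    excluded = [e for e in vals.index if e not in complete.index]
    if excluded:
        logger.warning("excluding %d ecoregions with incomplete defence data", len(excluded))
    vals = complete[list(DEFENCE_COLUMNS)]
    return DefenceMatrix(values=vals, z=standardize(vals), filled=filled, excluded=excluded)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # ecoregions x Dim1..Dim5
    loadings: pd.DataFrame  # traits x Dim1..Dim5
    var_frac: np.ndarray  # variance fraction per axis


def pca_axes(dm: DefenceMatrix) -> PCAResult:
    """Principal axes of the standardized defence matrix.

    Eigendecomposition of the trait correlation structure.  Signs are
    fixed deterministically: Dim1 loads positively on the stem-spine
    proportion (the physical-defence pole); every other axis has its
    largest-magnitude loading positive.
    """
    Z = dm.z.to_numpy(float)
    n, p = Z.shape
    if n <= p:
        raise ValueError(f"need more ecoregions ({n}) than traits ({p})")
    C = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.linalg.matrix_rank(C) < 3:
        raise ValueError("defence matrix has rank < 3; cannot extract three axes")
    cols = list(dm.z.columns)
    spine_row = cols.index("StemSpines_prop")
    for j in range(len(eigval)):
        if j == 0:
            flip = eigvec[spine_row, 0] < 0
        else:
            flip = eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0
        if flip:
            eigvec[:, j] = -eigvec[:, j]
    dims = [f"Dim{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=cols, columns=dims)
    scores = pd.DataFrame(Z @ eigvec, index=dm.z.index, columns=dims)
    var_frac = eigval / eigval.sum()
    return PCAResult(scores=scores, loadings=loadings, var_frac=var_frac)


@dataclass
class ClusterResult:
    labels: pd.Series  # antiherbiome name per ecoregion
    k: int
    inertia_gain_ratio: pd.Series  # indexed by k = 2..k_max
    within_inertia: pd.Series  # indexed by k = 1..k_max + 1
    name_map: dict  # raw cluster id -> antiherbiome name


def _within_inertia(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        sub = points[labels == g]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def _name_clusters(z: pd.DataFrame, labels: np.ndarray) -> dict:
    """Map raw cluster ids to antiherbiome names by trait-profile match."""
    ids = np.unique(labels)
    profile = np.zeros((len(ids), len(ANTIHERBIOME_NAMES)))
    means = {g: z.loc[labels == g].mean() for g in ids}
    for i, g in enumerate(ids):
        for j, name in enumerate(ANTIHERBIOME_NAMES):
            profile[i, j] = sum(w * means[g].get(tr, 0.0) for tr, w in _ARCHETYPE_SCORES[name].items())
    if len(ids) == len(ANTIHERBIOME_NAMES):
        rows, cols = linear_sum_assignment(-profile)
        return {ids[r]: ANTIHERBIOME_NAMES[c] for r, c in zip(rows, cols)}
    # degenerate cluster counts: nearest archetype, deduplicated by suffix
    out, used = {}, {}
    for i, g in enumerate(ids):
        name = ANTIHERBIOME_NAMES[int(np.argmax(profile[i]))]
        used[name] = used.get(name, 0) + 1
        out[g] = name if used[name] == 1 else f"{name}-{used[name]}"
    return out


def cluster_antiherbiomes(
    pca: PCAResult,
    z: pd.DataFrame,
    k_max: int = 6,
    n_axes: int | None = None,
) -> ClusterResult:
    """Ward clustering on PC scores with inertia-loss choice of k.

    Refining a partition from k-1 to k groups lowers the within-group
    inertia by the gain D(k) = W(k-1) - W(k); the selected k is the one
    whose gain stands out most against the next refinement, i.e. the
    argmax of D(k)/D(k+1) over k = 2..k_max (the partition after which
    further splits stop paying — the elbow the hierarchical-clustering-
    on-principal-components procedure uses).  Ties go to the lower k; a
    maximal ratio below 2 triggers a weak-structure warning.  Clusters
    are then named by matching their mean standardized trait profile to
    the three antiherbiome archetypes.
    """
    scores = pca.scores if n_axes is None else pca.scores.iloc[:, :n_axes]
    pts = scores.to_numpy(float)
    n = len(pts)
    if not 2 <= k_max < n - 1:
        raise ValueError(f"k_max must be in [2, n_ecoregions - 1); got {k_max} for n={n}")
    link = sch.linkage(pts, method="ward")
    within = {1: _within_inertia(pts, np.zeros(n, dtype=int))}
    labels_by_k = {}
    for k in range(2, k_max + 2):
        lab = sch.fcluster(link, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        within[k] = _within_inertia(pts, lab)
    gain = {k: within[k - 1] - within[k] for k in range(2, k_max + 2)}
    ratio = {}
    for k in range(2, k_max + 1):
        nxt = gain[k + 1]
        ratio[k] = gain[k] / nxt if nxt > 0 else np.inf
    ratios = pd.Series(ratio)
    best = ratios.max()
    k_sel = int(ratios.index[np.argmax(ratios.to_numpy() >= best - 1e-12)])
    if (ratios >= best - 1e-12).sum() > 1:
        logger.info("inertia-gain tie; choosing the lower k = %d", k_sel)
    if best < 2.0:
        logger.warning("weak cluster structure (max inertia-gain ratio %.2f)", best)
    raw = labels_by_k[k_sel]
    name_map = _name_clusters(z.loc[scores.index], raw)
    labels = pd.Series([name_map[g] for g in raw], index=scores.index, name="antiherbiome")
    return ClusterResult(
        labels=labels,
        k=k_sel,
        inertia_gain_ratio=ratios,
        within_inertia=pd.Series(within).sort_index(),
        name_map=name_map,
    )


# ---------------------------------------------------------------------------
# group contrasts

def dunn_test(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise Dunn z tests on ranks (tie-corrected), unadjusted p."""
    df = pd.DataFrame({"v": values, "g": labels}).dropna()
    N = len(df)
    ranks = st.rankdata(df["v"])
    _, tie_counts = np.unique(df["v"], return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    groups = sorted(df["g"].unique())
    mean_rank = {g: ranks[(df["g"] == g).to_numpy()].mean() for g in groups}
    sizes = {g: int((df["g"] == g).sum()) for g in groups}
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else np.nan
            p = 2 * st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append((a, b, float(z), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])


@dataclass
class ContrastResult:
    global_tests: pd.DataFrame  # variable, kw_stat, kw_p, n_groups
    pairwise: pd.DataFrame  # variable, group_a, group_b, z, p_raw, p_bh


def contrast_groups(values, labels: pd.Series) -> ContrastResult:
    """Kruskal–Wallis + Dunn/BH contrasts for one or many variables.

    Groups with fewer than 2 members are excluded (flagged in the log).
    BH correction is applied across the pairwise tests of each variable.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "value")
    glob_rows, pair_frames = [], []
    for col in values.columns:
        df = pd.DataFrame({"v": values[col], "g": labels}).dropna()
        sizes = df["g"].value_counts()
        small = sizes[sizes < 2].index.tolist()
        if small:
            logger.warning("%s: excluding groups with < 2 members: %s", col, small)
            df = df[~df["g"].isin(small)]
        groups = [df.loc[df["g"] == g, "v"].to_numpy() for g in sorted(df["g"].unique())]
        if len(groups) < 2:
            logger.warning("%s: fewer than two usable groups; skipped", col)
            continue
        stat, p = st.kruskal(*groups)
        glob_rows.append((col, float(stat), float(p), len(groups)))
        pw = dunn_test(df["v"], df["g"])
        pw.insert(0, "variable", col)
        pw["p_bh"] = multipletests(pw["p_raw"].to_numpy(), method="fdr_bh")[1]
        pair_frames.append(pw)
    global_tests = pd.DataFrame(glob_rows, columns=["variable", "kw_stat", "kw_p", "n_groups"])
    pairwise = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["variable", "group_a", "group_b", "z", "p_raw", "p_bh"])
    )
    return ContrastResult(global_tests=global_tests, pairwise=pairwise)
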