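"""Regression protocol: screening, stepwise AIC selection, overdispersed
binomial fits, effect sizes, dominance analysis and diagnostics.

The protocol mirrors a standard macroecological workflow:

1.  *Correlation screen.*  Candidate predictors with pairwise |r| >= 0.60
    cannot enter the same model.  Mean annual rainfall (MAR) and soil pH
    are the canonical such pair (r ~ -0.78): selection is run once per
    branch (one branch holding MAR, the other pH) and the branch with the
    lower AIC wins.
2.  *Stepwise AIC.*  Bidirectional (drop/add) search from the full model
    for the lowest AIC, followed by iterative removal of non-significant
    terms (p > 0.05), least significant first.  A quadratic term is only
    ever present together with its linear term.
3.  *Families.*  Gaussian least squares for continuous responses;
    binomial logits on (presences, absences) counts for binary-trait
    responses, with Williams-type iterative weights applied when the
    residual deviance exceeds the residual degrees of freedom.
4.  *Effect sizes.*  Per-coefficient Pearson r derived from the t
    statistic (r = t / sqrt(t^2 + df), the partial correlation), with a
    Fisher-z confidence interval.
5.  *Dominance analysis.*  General dominance: the R^2 gain a predictor
    brings, averaged over all subsets of the other selected predictors
    (within subset size, then across sizes).  Plain R^2 for gaussian
    models — contributions then sum exactly to the full-model R^2 —
    and McFadden's pseudo-R^2 for binomial models.
6.  *Diagnostics.*  Kolmogorov–Smirnov normality, Breusch–Pagan
    heteroscedasticity and Moran's I spatial autocorrelation on the
    residuals; VIF <= 3.33 asserted for every predictor.  When BP rejects,
    coefficient tests are redone under an HC3 covariance and the p <= 0.05
    pruning loop is re-entered.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

logger = logging.getLogger(__name__)

R_SCREEN_DEFAULT = 0.60
P_DEFAULT = 0.05
VIF_MAX_DEFAULT = 3.33
QUAD_SUFFIX = "^2"


class CollinearityError(ValueError):
    """A predictor's VIF exceeds the admissible bound."""


# ---------------------------------------------------------------------------
# term bookkeeping (quadratic hierarchy)

def quad_name(base: str) -> str:
    return base + QUAD_SUFFIX


def is_quadratic(term: str) -> bool:
    return term.endswith(QUAD_SUFFIX)


def base_of(term: str) -> str:
    return term[: -len(QUAD_SUFFIX)] if is_quadratic(term) else term


def add_quadratic_terms(X: pd.DataFrame, bases) -> pd.DataFrame:
    """Append squared (z-scored) columns ``<base>^2`` for the given bases."""
    out = X.copy()
    for b in bases:
        if b not in X.columns:
            raise ValueError(f"cannot square unknown predictor {b!r}")
        z = (X[b] - X[b].mean()) / X[b].std(ddof=0)
        out[quad_name(b)] = z**2
    return out


def _droppable(terms) -> list[str]:
    return [t for t in terms if not (not is_quadratic(t) and quad_name(t) in terms)]


def _addable(candidates, terms) -> list[str]:
    out = []
    for t in candidates:
        if t in terms:
            continue
        if is_quadratic(t) and base_of(t) not in terms:
            continue
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# screening

@dataclass
class ScreenResult:
    branches: list  # list of candidate-term lists
    flagged: list  # (a, b, r) pairs with |r| >= threshold
    dropped_constant: list


def correlation_screen(
    X: pd.DataFrame,
    threshold: float = R_SCREEN_DEFAULT,
    branch_pair: tuple[str, str] | None = ("MAR", "pH"),
) -> ScreenResult:
    """Flag collinear predictor pairs and split MAR/pH into branches.

    Constant predictors are dropped with a warning.  When both members of
    ``branch_pair`` are present and their |r| reaches the threshold, two
    candidate sets are emitted, one per member; otherwise one set.  Other
    flagged pairs are reported for the caller to resolve.
    """
    X = X.copy()
    dropped = [c for c in X.columns if X[c].std(ddof=0) == 0 or X[c].isna().all()]
    if dropped:
        logger.warning("dropping constant predictors: %s", dropped)
        X = X.drop(columns=dropped)
    corr = X.corr()
    flagged = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    branches = [cols]
    if branch_pair is not None:
        a, b = branch_pair
        if a in cols and b in cols:
            pair_flagged = any({p, q} == {a, b} for p, q, _ in flagged)
            if pair_flagged:
                branches = [
                    [c for c in cols if c != b],
                    [c for c in cols if c != a],
                ]
    return ScreenResult(branches=branches, flagged=flagged, dropped_constant=dropped)


# ---------------------------------------------------------------------------
# model containers

@dataclass
class FitResult:
    """A selected model with everything downstream stages need."""

    response: str
    family: str  # "gaussian" | "binomial_counts"
    predictors: list
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    fit_stat: dict
    n_obs: int
    df_resid: int
    result: object = None  # statsmodels results
    branch: str | None = None
    delta_aic: float | None = None
    weights: np.ndarray | None = None
    phi: float = 0.0
    cov_type: str = "nonrobust"
    flags: list = field(default_factory=list)
    effect_table: pd.DataFrame | None = None
    contributions: pd.Series | None = None
    diagnostics: dict | None = None

    @property
    def empty(self) -> bool:
        return len(self.predictors) == 0

    def design(self, X: pd.DataFrame) -> np.ndarray:
        M = np.column_stack([np.ones(len(X))] + [X[t].to_numpy(float) for t in self.predictors])
        return M

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Linear prediction (gaussian) or probability (binomial)."""
        eta = self.design(X) @ self.params.reindex(["const"] + self.predictors).to_numpy()
        if self.family == "gaussian":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# fast gaussian machinery

def _gaussian_rss(y: np.ndarray, M: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - M @ beta) ** 2))


def _gaussian_aic(y: np.ndarray, M: np.ndarray) -> float:
    n = len(y)
    rss = max(_gaussian_rss(y, M), 1e-300)
    return n * np.log(rss / n) + 2 * (M.shape[1] + 1)


def _design_matrix(X: pd.DataFrame, terms) -> np.ndarray:
    return np.column_stack([np.ones(len(X))] + [X[t].to_numpy(float) for t in terms])


# ---------------------------------------------------------------------------
# overdispersed binomial

@dataclass
class OverdispersedFit:
    result: object
    weights: np.ndarray
    phi: float
    converged: bool
    deviance: float
    df_resid: int


def _binomial_glm(successes, failures, M, weights=None):
    n_trials = successes + failures
    y = successes / n_trials
    vw = n_trials if weights is None else n_trials * weights
    model = sm.GLM(y, M, family=sm.families.Binomial(), var_weights=vw)
    return model.fit()


def overdispersed_binomial_fit(
    presences,
    absences,
    M: np.ndarray,
    max_phi: float = 1e3,
    tol: float = 1e-8,
) -> OverdispersedFit:
    """Binomial logit with Williams-type iterative weights.

    Weights w_i = 1 / (1 + phi * (n_i - 1)) are tuned (bracket + bisection
    on phi) until the weighted residual deviance falls below the residual
    degrees of freedom; with no overdispersion phi stays 0 and the fit is
    the plain logit.  A fit that cannot be driven below df within the phi
    bound is returned flagged, at the last iterate.
    """
    successes = np.asarray(presences, dtype=float)
    failures = np.asarray(absences, dtype=float)
    if successes.shape != failures.shape:
        raise ValueError("presences and absences differ in length")
    n_obs = len(successes)
    k = M.shape[1]
    df_resid = n_obs - k
    if df_resid <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n_obs}, parameters={k})")
    n_trials = successes + failures
    if np.any(n_trials <= 0):
        raise ValueError("each observation needs at least one trial")

    def fit_at(phi: float):
        w = 1.0 / (1.0 + phi * (n_trials - 1.0))
        res = _binomial_glm(successes, failures, M, weights=w)
        return res, w

    res0, w0 = fit_at(0.0)
    if res0.deviance < df_resid:
        return OverdispersedFit(res0, w0, 0.0, True, float(res0.deviance), df_resid)

    # bracket: deviance(phi) is decreasing in phi
    lo, hi = 0.0, 1e-3
    res_hi, w_hi = fit_at(hi)
    while res_hi.deviance >= df_resid and hi < max_phi:
        lo, hi = hi, hi * 4
        res_hi, w_hi = fit_at(hi)
    if res_hi.deviance >= df_resid:
        logger.warning("overdispersion weighting failed to converge (phi bound reached)")
        return OverdispersedFit(res_hi, w_hi, hi, False, float(res_hi.deviance), df_resid)

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        res_mid, w_mid = fit_at(mid)
        if res_mid.deviance >= df_resid:
            lo = mid
        else:
            hi, res_hi, w_hi = mid, res_mid, w_mid
        if hi - lo < tol * (1 + hi):
            break
    return OverdispersedFit(res_hi, w_hi, hi, True, float(res_hi.deviance), df_resid)


# ---------------------------------------------------------------------------
# stepwise selection

def _fit_terms(response, X, terms, family, overdisperse=True):
    """Fit one model; returns (statsmodels results, extras dict)."""
    M = _design_matrix(X, terms)
    if family == "gaussian":
        res = sm.OLS(np.asarray(response, float), M).fit()
        return res, {"weights": None, "phi": 0.0, "flags": []}
    successes = np.asarray(response[0], float)
    failures = np.asarray(response[1], float)
    if overdisperse:
        od = overdispersed_binomial_fit(successes, failures, M)
        flags = [] if od.converged else ["overdispersion_not_converged"]
        return od.result, {"weights": od.weights, "phi": od.phi, "flags": flags}
    res = _binomial_glm(successes, failures, M)
    return res, {"weights": None, "phi": 0.0, "flags": []}


def _aic_of(response, X, terms, family) -> float:
    M = _design_matrix(X, terms)
    if family == "gaussian":
        y = np.asarray(response, float)
        return _gaussian_aic(y, M)
    # selection AIC on the plain (unit-weight) binomial likelihood
    return float(_binomial_glm(np.asarray(response[0], float), np.asarray(response[1], float), M).aic)


def _stepwise_terms(response, X, candidates, family) -> list:
    """Bidirectional AIC search from the full admissible model."""
    terms = list(candidates)
    current = _aic_of(response, X, terms, family)
    while True:
        best_move, best_aic = None, current
        for t in _droppable(terms):
            trial = [u for u in terms if u != t]
            a = _aic_of(response, X, trial, family)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("drop", t), a
        for t in _addable(candidates, terms):
            trial = terms + [t]
            a = _aic_of(response, X, trial, family)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("add", t), a
        if best_move is None:
            return terms
        op, t = best_move
        terms = [u for u in terms if u != t] if op == "drop" else terms + [t]
        current = best_aic


def _prune_terms(response, X, terms, family, p_threshold):
    """Drop the least significant droppable term until all p <= threshold."""
    terms = list(terms)
    while terms:
        res, extras = _fit_terms(response, X, terms, family)
        pvals = pd.Series(res.pvalues[1:], index=terms)
        cand = pvals.loc[_droppable(terms)]
        worst = cand.idxmax() if len(cand) else None
        if worst is None or cand.max() <= p_threshold:
            return terms, res, extras
        terms.remove(worst)
    return [], None, {"weights": None, "phi": 0.0, "flags": []}


def _mcfadden(res) -> float:
    return float(1.0 - res.llf / res.llnull)


def _build_fitresult(response_name, response, X, terms, family, res, extras, branch, delta_aic):
    if res is None:
        return FitResult(
            response=response_name, family=family, predictors=[],
            params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float), aic=np.nan, fit_stat={},
            n_obs=len(X), df_resid=len(X) - 1, branch=branch,
            delta_aic=delta_aic, flags=["empty_model"],
        )
    names = ["const"] + list(terms)
    if family == "gaussian":
        stat = {"adj_r2": float(res.rsquared_adj), "r2": float(res.rsquared)}
    else:
        plain = _binomial_glm(np.asarray(response[0], float), np.asarray(response[1], float),
                              _design_matrix(X, terms))
        stat = {"mcfadden": _mcfadden(plain)}
    return FitResult(
        response=response_name,
        family=family,
        predictors=list(terms),
        params=pd.Series(np.asarray(res.params), index=names),
        bse=pd.Series(np.asarray(res.bse), index=names),
        pvalues=pd.Series(np.asarray(res.pvalues), index=names),
        aic=_aic_of(response, X, terms, family),
        fit_stat=stat,
        n_obs=len(X),
        df_resid=int(res.df_resid),
        result=res,
        branch=branch,
        delta_aic=delta_aic,
        weights=extras.get("weights"),
        phi=extras.get("phi", 0.0),
        flags=list(extras.get("flags", [])),
    )


def fit_model(response, X: pd.DataFrame, terms, family="gaussian", response_name="y") -> FitResult:
    """Fit one fixed-formula model (no selection)."""
    res, extras = _fit_terms(response, X, list(terms), family)
    return _build_fitresult(response_name, response, X, list(terms), family, res, extras, None, None)


def stepwise_select(
    response,
    X: pd.DataFrame,
    family: str = "gaussian",
    response_name: str = "y",
    forced_quadratics=(),
    branch_pair=("MAR", "pH"),
    r_threshold: float = R_SCREEN_DEFAULT,
    p_threshold: float = P_DEFAULT,
    expected_signs: dict | None = None,
) -> FitResult:
    """Full selection protocol: screen, per-branch stepwise AIC + pruning,
    branch competition, and the herbivory sign-discard rule.

    ``expected_signs`` maps herbivory predictors to the coefficient sign
    that would indicate a defence response; a selected, significant term
    with the opposite sign is discarded (with its quadratic) and the
    selection re-run without it.
    """
    for q in forced_quadratics:
        if quad_name(q) not in X.columns:
            X = add_quadratic_terms(X, [q])
    n_min = len(X.columns) + 2
    if len(X) < n_min:
        raise ValueError(f"need n >= predictors + 2 ({n_min}), got {len(X)}")

    base_cols = [c for c in X.columns if not is_quadratic(c)]
    screen = correlation_screen(X[base_cols], threshold=r_threshold, branch_pair=branch_pair)
    banned: set = set()

    def run_once():
        results = []
        for branch_cols in screen.branches:
            cand = [c for c in branch_cols if c not in banned]
            cand += [quad_name(q) for q in forced_quadratics
                     if q in cand and quad_name(q) not in cand]
            terms = _stepwise_terms(response, X, cand, family)
            terms, res, extras = _prune_terms(response, X, terms, family, p_threshold)
            aic = _aic_of(response, X, terms, family) if terms else np.inf
            branch_tag = None
            if branch_pair is not None and len(screen.branches) > 1:
                branch_tag = branch_pair[0] if branch_pair[0] in branch_cols else branch_pair[1]
            results.append((aic, terms, res, extras, branch_tag))
        results.sort(key=lambda r: r[0])
        best = results[0]
        delta = results[1][0] - results[0][0] if len(results) > 1 else None
        return best, delta

    for _ in range(4):
        (aic, terms, res, extras, branch_tag), delta = run_once()
        if expected_signs is None or res is None:
            break
        offenders = []
        for t in terms:
            want = expected_signs.get(base_of(t))
            if want is None:
                continue
            i = 1 + terms.index(t)
            if res.pvalues[i] <= p_threshold and np.sign(res.params[i]) != np.sign(want):
                offenders.append(t)
        if not offenders:
            break
        for t in offenders:
            banned.add(base_of(t))
            banned.add(quad_name(base_of(t)))
        logger.info("discarding herbivory terms with non-defensive sign: %s", offenders)

    fr = _build_fitresult(response_name, response, X, terms, family, res, extras, branch_tag, delta)
    if fr.empty:
        fr.flags.append("no_significant_predictors")
        logger.warning("stepwise selection for %s retained no predictors", response_name)
    return fr


# ---------------------------------------------------------------------------
# effect sizes

def effect_sizes(fit: FitResult) -> pd.DataFrame:
    """Pearson-r effect size (partial correlation) with 95% CI per predictor.

    r = t / sqrt(t^2 + df_resid); the CI comes from the Fisher-z
    transform with standard error 1/sqrt(df_resid - 1).
    """
    rows = []
    df = max(fit.df_resid, 1)
    for term in fit.predictors:
        t = fit.params[term] / fit.bse[term] if fit.bse[term] > 0 else 0.0
        r = t / np.sqrt(t**2 + df)
        if df > 2:
            z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
            se = 1.0 / np.sqrt(df - 1)
            lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
        else:
            lo = hi = np.nan
        rows.append((term, float(r), float(lo), float(hi)))
    out = pd.DataFrame(rows, columns=["predictor", "r", "ci_low", "ci_high"]).set_index("predictor")
    fit.effect_table = out
    return out


# ---------------------------------------------------------------------------
# dominance analysis

def _subset_fit_stat(response, X, terms, family) -> float:
    if not terms:
        return 0.0
    M = _design_matrix(X, list(terms))
    if family == "gaussian":
        y = np.asarray(response, float)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return 0.0
        return 1.0 - _gaussian_rss(y, M) / tss
    res = _binomial_glm(np.asarray(response[0], float), np.asarray(response[1], float), M)
    return _mcfadden(res)


def dominance_contributions(response, X: pd.DataFrame, terms, family="gaussian") -> pd.Series:
    """General-dominance average contribution of each selected predictor.

    For every predictor, the gain in fit statistic from adding it is
    averaged over all subsets of the remaining predictors of a given
    size, then across sizes (the empty model included).  For gaussian
    models the statistic is plain R^2, so contributions sum exactly to
    the full-model R^2; binomial models use McFadden's pseudo-R^2.
    """
    terms = list(terms)
    k = len(terms)
    if k == 0:
        return pd.Series(dtype=float)
    if k > 12:
        raise ValueError(f"{k} predictors: subset enumeration capped at 12; reduce the model")
    cache: dict = {}

    def stat(sub: frozenset) -> float:
        if sub not in cache:
            cache[sub] = _subset_fit_stat(response, X, sorted(sub), family)
        return cache[sub]

    out = {}
    for t in terms:
        others = [u for u in terms if u != t]
        level_means = []
        for size in range(len(others) + 1):
            gains = [
                stat(frozenset(S) | {t}) - stat(frozenset(S))
                for S in itertools.combinations(others, size)
            ]
            level_means.append(float(np.mean(gains)))
        out[t] = float(np.mean(level_means))
    return pd.Series(out, name="avg_contribution")


# ---------------------------------------------------------------------------
# diagnostics

def variance_inflation(X: pd.DataFrame, terms) -> pd.Series:
    """VIF_j = 1 / (1 - R^2 of predictor j on the others)."""
    out = {}
    for t in terms:
        others = [u for u in terms if u != t]
        if not others:
            out[t] = 1.0
            continue
        M = _design_matrix(X, others)
        y = X[t].to_numpy(float)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if tss == 0 else 1.0 - _gaussian_rss(y, M) / tss
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _largest_component(ids, adjacency):
    ids = list(ids)
    id_set = set(ids)
    seen, components = set(), []
    for start in ids:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in adjacency.get(u, ()) if v in id_set and v not in comp)
        seen |= comp
        components.append(comp)
    return max(components, key=len), len(components)


def morans_i(values: pd.Series, adjacency: dict) -> tuple[float, float, bool]:
    """Moran's I with binary symmetric weights and the analytic normal test.

    Returns (I, two-sided p, flagged) where ``flagged`` is True when the
    adjacency graph was disconnected and only the largest component used.
    """
    comp, n_comp = _largest_component(values.index, adjacency)
    flagged = n_comp > 1
    if flagged:
        logger.warning("adjacency disconnected (%d components); Moran's I on largest", n_comp)
    v = values.loc[sorted(comp)]
    ids = list(v.index)
    pos = {e: i for i, e in enumerate(ids)}
    n = len(ids)
    e = v.to_numpy(float) - v.mean()
    s0 = 0.0
    cross = 0.0
    deg = np.zeros(n)
    for u in ids:
        for w in adjacency.get(u, ()):
            if w in pos:
                s0 += 1.0
                cross += e[pos[u]] * e[pos[w]]
                deg[pos[u]] += 1.0
    if s0 == 0 or np.sum(e**2) == 0:
        return np.nan, np.nan, flagged
    I = (n / s0) * cross / float(np.sum(e**2))
    EI = -1.0 / (n - 1)
    s1 = 2.0 * s0  # binary symmetric: sum (w_ij + w_ji)^2 / 2 = 4E = 2*S0
    s2 = float(np.sum((2.0 * deg) ** 2))
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - EI**2
    if var <= 0:
        return float(I), np.nan, flagged
    z = (I - EI) / np.sqrt(var)
    p = 2 * st.norm.sf(abs(z))
    return float(I), float(p), flagged


@dataclass
class DiagnosticsRecord:
    ks_p: float | None
    bp_p: float | None
    moran_i: float | None
    moran_p: float | None
    max_vif: float
    hc_used: bool
    moran_flagged: bool = False
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ks_p": self.ks_p, "bp_p": self.bp_p, "moran_i": self.moran_i,
            "moran_p": self.moran_p, "max_vif": self.max_vif,
            "hc_used": self.hc_used, "moran_flagged": self.moran_flagged,
            "notes": list(self.notes),
        }


def diagnostics(
    fit: FitResult,
    X: pd.DataFrame,
    response,
    adjacency: dict | None = None,
    index=None,
    p_threshold: float = P_DEFAULT,
    vif_max: float = VIF_MAX_DEFAULT,
    refit: bool = True,
) -> tuple[FitResult, DiagnosticsRecord]:
    """Residual diagnostics, VIF assertion and the HC-covariance refit path.

    For gaussian fits: KS on standardized residuals against N(0,1) (the
    estimated-parameter caveat applies and is noted), Breusch–Pagan, and
    Moran's I over ``adjacency`` (ecoregion ids taken from ``index`` or
    ``X.index``).  If BP rejects at ``p_threshold`` the coefficient tests
    are redone under HC3 and non-significant terms pruned again.  VIF is
    computed for every selected predictor; exceeding ``vif_max`` raises
    :class:`CollinearityError`.
    """
    notes = []
    if fit.empty:
        rec = DiagnosticsRecord(None, None, None, None, 0.0, False, notes=["empty model"])
        fit.diagnostics = rec.as_dict()
        return fit, rec

    vif = variance_inflation(X, [t for t in fit.predictors])
    max_vif = float(vif.max())
    if max_vif > vif_max:
        raise CollinearityError(
            f"VIF above {vif_max}: {vif[vif > vif_max].to_dict()}"
        )

    ks_p = bp_p = moran_val = moran_p = None
    moran_flagged = False
    if fit.family == "gaussian":
        res = fit.result
        resid = np.asarray(res.resid)
        sigma = np.sqrt(res.ssr / res.df_resid)
        std_resid = resid / sigma
        ks_p = float(st.kstest(std_resid, "norm").pvalue)
        notes.append("KS against N(0,1) with estimated parameters")
        M = _design_matrix(X, fit.predictors)
        bp_p = float(sm.stats.diagnostic.het_breuschpagan(resid, M)[1])
        if adjacency is not None:
            idx = index if index is not None else X.index
            moran_val, moran_p, moran_flagged = morans_i(pd.Series(resid, index=idx), adjacency)
    else:
        resid = np.asarray(fit.result.resid_deviance)
        if adjacency is not None:
            idx = index if index is not None else X.index
            moran_val, moran_p, moran_flagged = morans_i(pd.Series(resid, index=idx), adjacency)
        notes.append("KS/BP not applied to binomial fits")

    hc_used = False
    if fit.family == "gaussian" and bp_p is not None and bp_p <= p_threshold and refit:
        hc_used = True
        terms = list(fit.predictors)
        while terms:
            M = _design_matrix(X, terms)
            res = sm.OLS(np.asarray(response, float), M).fit(cov_type="HC3")
            pvals = pd.Series(res.pvalues[1:], index=terms)
            cand = pvals.loc[_droppable(terms)]
            if not len(cand) or cand.max() <= p_threshold:
                break
            terms.remove(cand.idxmax())
        if terms:
            names = ["const"] + terms
            fit = FitResult(
                response=fit.response, family=fit.family, predictors=terms,
                params=pd.Series(np.asarray(res.params), index=names),
                bse=pd.Series(np.asarray(res.bse), index=names),
                pvalues=pd.Series(np.asarray(res.pvalues), index=names),
                aic=_aic_of(response, X, terms, "gaussian"),
                fit_stat={"adj_r2": float(res.rsquared_adj), "r2": float(res.rsquared)},
                n_obs=fit.n_obs, df_resid=int(res.df_resid), result=res,
                branch=fit.branch, delta_aic=fit.delta_aic, cov_type="HC3",
                flags=fit.flags + ["hc_refit"],
            )
        else:
            fit.flags.append("hc_refit_emptied_model")
            fit.predictors = []

    rec = DiagnosticsRecord(
        ks_p=ks_p, bp_p=bp_p, moran_i=moran_val, moran_p=moran_p,
        max_vif=max_vif, hc_used=hc_used, moran_flagged=moran_flagged, notes=notes,
    )
    fit.diagnostics = rec.as_dict()
    return fit, rec
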