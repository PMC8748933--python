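"""Randomization test for trait–herbivory coefficients.

The observed regression coefficients are compared with coefficients
re-estimated after randomizing the species-abundance-by-ecoregion
matrix.  Each replicate redoes the full downstream path — trait
aggregation to ecoregion values, then a refit of the *selected* model
formula — and a coefficient is judged robust when the observed value
falls outside the 0.05–0.95 quantile band of the replicate coefficients.

Randomization schemes (conserved quantities in parentheses):

* ``shuffle_species_columns`` — permute each species' abundances across
  ecoregions (per-species totals).  The default: it decouples trait
  geography from ecoregion identity while preserving every species'
  prevalence profile.
* ``shuffle_ecoregion_rows`` — permute each ecoregion's abundances
  across species (per-ecoregion totals).
* ``fixed_marginals_swap`` — repeated 2x2 unit swaps (both row and
  column totals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import trait_scaling
from .assoc_models import FitResult, _design_matrix, overdispersed_binomial_fit

logger = logging.getLogger(__name__)

SCHEMES = ("shuffle_species_columns", "shuffle_ecoregion_rows", "fixed_marginals_swap")


def randomize_matrix(
    occ: pd.DataFrame,
    scheme: str = "shuffle_species_columns",
    rng: np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Return a randomized copy of an abundance matrix under one scheme."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; options: {SCHEMES}")
    rng = np.random.default_rng() if rng is None else rng
    A = occ.to_numpy().copy()
    n_rows, n_cols = A.shape
    if scheme == "shuffle_species_columns":
        perm = np.argsort(rng.random((n_rows, n_cols)), axis=0)
        A = A[perm, np.arange(n_cols)[None, :]]
    elif scheme == "shuffle_ecoregion_rows":
        perm = np.argsort(rng.random((n_rows, n_cols)), axis=1)
        A = A[np.arange(n_rows)[:, None], perm]
    else:  # fixed_marginals_swap
        if n_swaps is None:
            n_swaps = 10 * int(np.count_nonzero(A))
        if n_rows > 1 and n_cols > 1:
            r1 = rng.integers(0, n_rows, size=n_swaps)
            r2 = rng.integers(0, n_rows, size=n_swaps)
            c1 = rng.integers(0, n_cols, size=n_swaps)
            c2 = rng.integers(0, n_cols, size=n_swaps)
            for a, b, c, d in zip(r1, r2, c1, c2):
                if a == b or c == d:
                    continue
                if A[a, c] > 0 and A[b, d] > 0:
                    A[a, c] -= 1
                    A[b, d] -= 1
                    A[a, d] += 1
                    A[b, c] += 1
    return pd.DataFrame(A, index=occ.index, columns=occ.columns)


@dataclass
class NullTestResult:
    table: pd.DataFrame  # per coefficient: observed, q05, q95, outside
    n_requested: int
    n_effective: int
    scheme: str

    @property
    def all_outside(self) -> bool:
        return bool(self.table["outside"].all())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["n_effective_reps"] = self.n_effective
        out["scheme"] = self.scheme
        out.to_csv(path)


def _recompute_response(fit: FitResult, occ, traits, palm_species):
    """Re-derive the model response from a (randomized) abundance matrix."""
    name = fit.response
    if fit.family == "gaussian":
        return trait_scaling.ecoregion_weighted_mean(occ, traits, name)
    if name == "LeafSpines":
        counts = trait_scaling.ecoregion_presence_fraction(
            occ, traits, name, palm_species=palm_species
        )
        return counts[f"{name}_present_species"], counts[f"{name}_absent_species"]
    counts = trait_scaling.ecoregion_binary_counts(occ, traits, name)
    return counts[f"{name}_presences"], counts[f"{name}_absences"]


def coefficient_null_test(
    observed: FitResult,
    occ: pd.DataFrame,
    traits: pd.DataFrame,
    predictors: pd.DataFrame,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    scheme: str = "shuffle_species_columns",
    palm_species=None,
    max_failure_rate: float = 0.05,
) -> NullTestResult:
    """Per-coefficient null-band verdicts against matrix randomizations.

    The selected model's predictor set is held fixed; each replicate
    recomputes the response from a randomized matrix and re-estimates the
    coefficients.  Verdict ``outside`` is True when the observed
    coefficient lies below the 0.05 or above the 0.95 quantile of the
    replicate coefficients.  Replicates whose refit fails (e.g. all
    response values missing) are dropped; more than ``max_failure_rate``
    failures aborts.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if observed.empty:
        raise ValueError("observed model has no predictors to test")
    if n_reps < 100:
        logger.warning("n_reps=%d < 100: quantile band will be unstable", n_reps)
    rng = np.random.default_rng() if rng is None else rng

    terms = observed.predictors
    reps = np.full((n_reps, len(terms)), np.nan)
    pred_index = predictors.index

    gaussian = observed.family == "gaussian"
    X_full = _design_matrix(predictors, terms)
    pinv_cache = None

    failures = 0
    for r in range(n_reps):
        occ_r = randomize_matrix(occ, scheme=scheme, rng=rng)
        try:
            resp = _recompute_response(observed, occ_r, traits, palm_species)
            if gaussian:
                y = resp.reindex(pred_index).to_numpy(float)
                ok = np.isfinite(y)
                if ok.sum() < len(terms) + 2:
                    raise ValueError("too few complete ecoregions")
                if ok.all():
                    if pinv_cache is None:
                        pinv_cache = np.linalg.pinv(X_full)
                    beta = pinv_cache @ y
                else:
                    beta = np.linalg.lstsq(X_full[ok], y[ok], rcond=None)[0]
                reps[r] = beta[1:]
            else:
                succ = resp[0].reindex(pred_index).to_numpy(float)
                fail = resp[1].reindex(pred_index).to_numpy(float)
                ok = np.isfinite(succ) & np.isfinite(fail) & (succ + fail > 0)
                if ok.sum() < len(terms) + 2:
                    raise ValueError("too few complete ecoregions")
                od = overdispersed_binomial_fit(succ[ok], fail[ok], X_full[ok])
                reps[r] = np.asarray(od.result.params)[1:]
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            logger.debug("replicate %d failed: %s", r, exc)
            if failures > max_failure_rate * n_reps:
                raise RuntimeError(
                    f"{failures} of {r + 1} randomization replicates failed"
                ) from exc

    good = ~np.isnan(reps).any(axis=1)
    reps = reps[good]
    obs = observed.params.loc[terms].to_numpy(float)
    q05 = np.quantile(reps, 0.05, axis=0)
    q95 = np.quantile(reps, 0.95, axis=0)
    table = pd.DataFrame(
        {
            "observed": obs,
            "q05": q05,
            "q95": q95,
            "outside": (obs < q05) | (obs > q95),
        },
        index=pd.Index(terms, name="coefficient"),
    )
    return NullTestResult(table=table, n_requested=n_reps, n_effective=int(good.sum()), scheme=scheme)
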