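"""Staged propensity models: web-panel membership vs the reference survey.

A propensity score here is the fitted probability of being a *web-panel*
participant (rather than a reference-survey participant) given auxiliary
variables, from a logistic regression fitted to the pooled, weighted data of
both surveys.  Models are built in five cumulative stages — demographics
first, then sexual identity, non-sexual lifestyle behaviours, attitudes, and
finally selected sexual behaviour variables — with backward stepwise
selection at each stage and the previous stage's selected variables forced
in.  Fitting is done separately by gender.

Because the fitting weights are survey weights, not frequencies of i.i.d.
observations, inference uses the weighted pseudo-likelihood: point estimates
maximise the weight-multiplied log-likelihood and variable-level tests are
joint Wald tests on a design-consistent (sandwich) covariance.  Multi-level
categorical variables enter and leave the model as whole variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "StageSpec",
    "PropensityFit",
    "SeparationWarning",
    "build_design",
    "fit_weighted_logistic",
    "backward_stepwise",
    "run_stages",
    "score_participants",
]

#: |coefficient| beyond which a binary/categorical term is treated as evidence
#: of (quasi-)separation; on the logit scale this is an odds ratio > 1e5.
_SEPARATION_COEF = 12.0


class SeparationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class StageSpec:
    """Ordered candidate-variable pools for the five propensity stages.

    ``stages`` maps stage number (1-5) to that stage's own candidate pool.
    Pools are disjoint; cumulative availability is implied — stage k's model
    starts from the variables selected at stage k-1 (forced) plus stage k's
    pool (candidates).
    """

    stages: dict[int, tuple[str, ...]]

    def __post_init__(self) -> None:
        if sorted(self.stages) != [1, 2, 3, 4, 5]:
            raise ValueError("stage spec must define exactly stages 1..5")
        seen: set[str] = set()
        for k in sorted(self.stages):
            pool = self.stages[k]
            overlap = seen & set(pool)
            if overlap:
                raise ValueError(f"stage {k} pool repeats variables {sorted(overlap)}")
            seen |= set(pool)

    def all_variables(self) -> list[str]:
        return [v for k in sorted(self.stages) for v in self.stages[k]]


@dataclass
class PropensityFit:
    """One fitted stage model: selected variables, coefficients, level coding."""

    gender: str
    stage: int
    forced: tuple[str, ...]
    selected: tuple[str, ...]
    params: pd.Series  # coefficient per design column (incl. 'const')
    levels: dict[str, list]  # variable -> full level list; first is reference
    pvalues: dict[str, float]  # per-variable joint Wald p in the final model
    n_obs: int
    survey_id: str = "web"
    dropped_for_separation: tuple[str, ...] = field(default=())
    candidates: tuple[str, ...] = field(default=())  # the pool stepwise started from

    def model_variables(self) -> tuple[str, ...]:
        return self.selected


def _variable_levels(values: pd.Series) -> list:
    """Observed levels, reference first, in deterministic (string-sorted) order."""
    lv = sorted(values.dropna().unique(), key=str)
    return lv


def build_design(
    table: pd.DataFrame,
    variables: list[str],
    levels: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]], np.ndarray]:
    """Dummy-coded design matrix (with intercept) for the given variables.

    Returns ``(X, columns_by_variable, complete_mask)`` where ``X`` covers the
    complete-case rows only and each variable's first level is the reference.
    ``levels`` fixes the coding (used when scoring with a previously fitted
    model); otherwise levels are taken from the data.
    """
    complete = np.ones(len(table), dtype=bool)
    for var in variables:
        complete &= table[var].notna().to_numpy()
    sub = table.loc[complete]
    cols: dict[str, np.ndarray] = {"const": np.ones(len(sub))}
    by_var: dict[str, list[str]] = {}
    for var in variables:
        var_levels = levels[var] if levels is not None else _variable_levels(table[var])
        names = []
        for level in var_levels[1:]:
            name = f"{var}[{level}]"
            cols[name] = (sub[var].to_numpy() == level).astype(float)
            names.append(name)
        by_var[var] = names
    X = pd.DataFrame(cols, index=sub.index)
    return X, by_var, complete


@dataclass
class WeightedLogit:
    """Weighted logistic fit with sandwich covariance and per-variable Wald tests."""

    params: pd.Series
    results: object  # statsmodels GLMResults
    by_var: dict[str, list[str]]

    def variable_pvalue(self, var: str) -> float:
        """Joint Wald p-value for all dummy terms of one variable."""
        names = [c for c in self.by_var[var] if c in self.params.index]
        if not names:
            return 1.0  # aliased variable contributes nothing testable
        k = len(self.params)
        R = np.zeros((len(names), k))
        for i, name in enumerate(names):
            R[i, self.params.index.get_loc(name)] = 1.0
        test = self.results.wald_test(R, scalar=True)
        return float(test.pvalue)

    def max_abs_coef(self, var: str) -> float:
        names = [c for c in self.by_var[var] if c in self.params.index]
        if not names:
            return 0.0
        return float(self.params[names].abs().max())


def fit_weighted_logistic(
    X: pd.DataFrame,
    membership: np.ndarray,
    weights: np.ndarray,
    by_var: dict[str, list[str]] | None = None,
) -> WeightedLogit:
    """Maximise the weight-multiplied binomial log-likelihood.

    ``membership`` is 1 for web rows, 0 for reference rows.  The covariance is
    the HC0 sandwich under the fitting weights, so per-term and per-variable
    tests are design-consistent Wald tests.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("fitting weights must be positive")
    y = np.asarray(membership, dtype=float)
    if y.min() == y.max():
        raise ValueError("both membership classes must be present")
    # drop constant non-intercept columns (aliased levels in the complete cases)
    keep = ["const"] + [
        c for c in X.columns if c != "const" and X[c].to_numpy().std() > 0
    ]
    dropped = set(X.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping aliased design columns {sorted(dropped)}", stacklevel=2)
    Xk = X[keep]
    model = sm.GLM(y, Xk, family=sm.families.Binomial(), freq_weights=weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels may warn on near-separation
        res = model.fit(cov_type="HC0", maxiter=100, tol=1e-8)
    params = pd.Series(res.params, index=Xk.columns)
    return WeightedLogit(params=params, results=res, by_var=by_var or {})


def backward_stepwise(
    data: pd.DataFrame,
    weights: np.ndarray,
    forced: list[str],
    candidates: list[str],
    alpha: float = 0.05,
    gender: str = "",
    stage: int = 0,
    survey_id: str = "web",
) -> PropensityFit:
    """Backward stepwise selection over whole variables at significance alpha.

    Starts from forced + all candidates; repeatedly removes the candidate with
    the largest joint-Wald p-value >= alpha (ties broken by removing the
    variable later in the candidate ordering); forced variables are never
    removed.  A candidate whose fit shows (quasi-)separation is removed with a
    warning — an unbounded coefficient would give degenerate 0/1 scores.
    """
    if set(forced) & set(candidates):
        raise ValueError("candidates must be disjoint from forced variables")
    remaining = list(candidates)
    dropped_sep: list[str] = []
    membership = (data["source"].to_numpy() == "web").astype(int)

    while True:
        variables = list(forced) + remaining
        X, by_var, mask = build_design(data, variables)
        fit = fit_weighted_logistic(X, membership[mask], np.asarray(weights)[mask], by_var)

        separated = [v for v in remaining if fit.max_abs_coef(v) > _SEPARATION_COEF]
        if separated:
            victim = max(separated, key=remaining.index)
            warnings.warn(
                f"removing {victim!r}: coefficient magnitude indicates separation",
                SeparationWarning,
                stacklevel=2,
            )
            remaining.remove(victim)
            dropped_sep.append(victim)
            continue

        if not remaining:
            break
        pvals = {v: fit.variable_pvalue(v) for v in remaining}
        worst_p = max(pvals.values())
        if worst_p < alpha:
            break
        tied = [v for v in remaining if pvals[v] == worst_p]
        victim = max(tied, key=remaining.index)
        remaining.remove(victim)

    selected = tuple(forced) + tuple(v for v in candidates if v in remaining)
    levels = {v: _variable_levels(data[v]) for v in selected}
    pvalues = {v: fit.variable_pvalue(v) for v in selected if v in fit.by_var}
    return PropensityFit(
        gender=gender,
        stage=stage,
        forced=tuple(forced),
        selected=selected,
        params=fit.params,
        levels=levels,
        pvalues=pvalues,
        n_obs=int(mask.sum()),
        survey_id=survey_id,
        dropped_for_separation=tuple(dropped_sep),
        candidates=tuple(candidates),
    )


def run_stages(
    reference: pd.DataFrame,
    web: pd.DataFrame,
    stage_spec: StageSpec,
    gender: str,
    alpha: float = 0.05,
    survey_id: str = "web",
) -> list[PropensityFit]:
    """Fit the five cumulative stage models for one gender.

    Stage 1 selects among its own pool with nothing forced; at stage k >= 2
    the variables selected at stage k-1 are included with certainty and stage
    k's pool provides the new candidates.
    """
    ref_g = reference[reference["gender"] == gender]
    web_g = web[web["gender"] == gender]
    if ref_g.empty or web_g.empty:
        raise ValueError(f"empty gender stratum {gender!r}")
    combined = pd.concat([ref_g, web_g], ignore_index=True)
    weights = combined["base_weight"].to_numpy(dtype=float)
    if np.isnan(weights).any():
        raise ValueError("base weights must be set on both tables before fitting")

    fits: list[PropensityFit] = []
    forced: list[str] = []
    for k in sorted(stage_spec.stages):
        pool = [v for v in stage_spec.stages[k] if v not in forced]
        fit = backward_stepwise(
            combined,
            weights,
            forced=forced,
            candidates=pool,
            alpha=alpha,
            gender=gender,
            stage=k,
            survey_id=survey_id,
        )
        fits.append(fit)
        forced = list(fit.selected)
    return fits


def score_participants(fit: PropensityFit, table: pd.DataFrame) -> pd.Series:
    """Propensity scores (fitted web-membership probabilities) for a table.

    The score is missing exactly when any model covariate is missing for that
    participant.
    """
    variables = list(fit.selected)
    X, _, mask = build_design(table, variables, levels=fit.levels)
    cols = [c for c in fit.params.index if c in X.columns]
    if set(fit.params.index) - set(X.columns):
        missing_cols = sorted(set(fit.params.index) - set(X.columns))
        raise ValueError(f"scoring table lacks design columns {missing_cols}")
    eta = X[cols].to_numpy() @ fit.params[cols].to_numpy()
    scores = pd.Series(np.nan, index=table.index, dtype=float)
    scores.loc[mask] = expit(eta)
    return scores
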