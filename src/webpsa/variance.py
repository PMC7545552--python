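"""Bootstrap replicate weights and standard errors for the absolute OR.

PSA weights carry uncertainty both from sampling and from the propensity
model whose fitted probabilities define the subclasses.  To propagate both,
web participants are resampled with replacement (the panels are unclustered
volunteer samples) and the whole weighting pipeline is rerun per replicate:
post-stratification, refit of the propensity coefficients with the stage's
selected variable set held fixed, combined quintiles, PSA ratios, final
weights.  The reference survey is treated as a fixed benchmark — its rows,
weights and prevalences are identical across replicates and its uncertainty
is ignored.  The SE of each outcome's absolute OR is the standard deviation
of the replicate absolute ORs; the average SE across outcomes is the
precision metric reported per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import absolute_or, odds_ratio, weighted_prevalence
from .propensity import (
    PropensityFit,
    backward_stepwise,
    build_design,
    fit_weighted_logistic,
    score_participants,
)
from .psa import SubclassingError, apply_psa_weights, compute_psa_ratios, make_subclasses
from .weighting import CensusMargins, post_stratify

__all__ = ["ReplicateSet", "make_replicates", "replicate_absolute_ors",
           "replicate_log_ors", "se_absolute_or", "average_se"]


@dataclass
class ReplicateSet:
    """Per-replicate resample indices and final web weight vectors."""

    B: int
    seed: int
    indices: list[np.ndarray] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)
    n_failed: int = 0


def _replicate_weights(
    web_b: pd.DataFrame,
    reference: pd.DataFrame,
    fit: PropensityFit,
    margins: CensusMargins,
    redo_selection: bool = False,
) -> np.ndarray:
    """Full weighting pipeline on one resampled web table; reference untouched."""
    ps = post_stratify(web_b, margins)
    web_b = web_b.copy()
    web_b["base_weight"] = ps.weights.to_numpy()

    combined = pd.concat([reference, web_b], ignore_index=True)
    weights_combined = combined["base_weight"].to_numpy()
    if redo_selection:
        fit_b = backward_stepwise(
            combined,
            weights_combined,
            forced=list(fit.forced),
            candidates=[c for c in fit.candidates],
            gender=fit.gender,
            stage=fit.stage,
            survey_id=fit.survey_id,
        )
    else:
        membership = (combined["source"].to_numpy() == "web").astype(int)
        X, by_var, mask = build_design(combined, list(fit.selected), levels=fit.levels)
        refit = fit_weighted_logistic(
            X, membership[mask], weights_combined[mask], by_var
        )
        fit_b = PropensityFit(
            gender=fit.gender,
            stage=fit.stage,
            forced=fit.forced,
            selected=fit.selected,
            params=refit.params,
            levels=fit.levels,
            pvalues={},
            n_obs=int(mask.sum()),
            survey_id=fit.survey_id,
        )
    ref_scores = score_participants(fit_b, reference)
    web_scores = score_participants(fit_b, web_b)
    combined_scores = pd.concat([ref_scores, web_scores], ignore_index=True)
    source = pd.Series(
        ["reference"] * len(reference) + ["web"] * len(web_b),
        index=combined_scores.index,
    )
    fit_weights = pd.Series(
        np.concatenate(
            [reference["base_weight"].to_numpy(), web_b["base_weight"].to_numpy()]
        ),
        index=combined_scores.index,
    )
    subclasses = make_subclasses(combined_scores)
    ratios = compute_psa_ratios(subclasses, source, fit_weights)
    web_assignment = subclasses.assignment.iloc[len(reference):].reset_index(drop=True)
    web_assignment.index = web_b.index
    final = apply_psa_weights(web_b, web_assignment, ratios, ps.weights)
    return final.to_numpy()


def make_replicates(
    web: pd.DataFrame,
    reference: pd.DataFrame,
    fit: PropensityFit,
    margins: CensusMargins,
    B: int,
    seed: int,
    max_failure_fraction: float = 0.10,
    redo_selection: bool = False,
) -> ReplicateSet:
    """Build B bootstrap replicates of the final web weights for one stage.

    Each replicate resamples web participants with replacement (same size),
    then reruns post-stratification, coefficient refit (selected variables
    fixed), subclassing and PSA ratios.  Replicates hitting an empty
    post-stratification cell or empty subclass are flagged failed and
    excluded; more than ``max_failure_fraction`` failures is an error.
    Replicate b uses the seed pair (seed, b), so growing B extends the
    replicate set without reshuffling earlier replicates.
    """
    if B < 2:
        raise ValueError("need at least 2 replicates")
    out = ReplicateSet(B=B, seed=seed)
    n = len(web)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        idx = np.sort(rng.integers(0, n, size=n))
        web_b = web.iloc[idx].reset_index(drop=True)
        try:
            w = _replicate_weights(web_b, reference, fit, margins, redo_selection)
        except (ValueError, SubclassingError):
            out.n_failed += 1
            continue
        out.indices.append(idx)
        out.weights.append(w)
    if out.n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{out.n_failed}/{B} bootstrap replicates failed; weighting is unstable"
        )
    return out


def replicate_absolute_ors(
    replicates: ReplicateSet,
    web: pd.DataFrame,
    reference: pd.DataFrame,
    outcomes: list[str],
    ref_weights,
) -> pd.DataFrame:
    """Absolute OR per successful replicate (rows) and outcome (columns).

    Reference prevalences are computed once — the reference is fixed by
    design.  Replicates where an outcome's OR is undefined get NaN for that
    outcome.
    """
    return replicate_ors(replicates, web, reference, outcomes, ref_weights, scale="absolute")


def replicate_log_ors(
    replicates: ReplicateSet,
    web: pd.DataFrame,
    reference: pd.DataFrame,
    outcomes: list[str],
    ref_weights,
) -> pd.DataFrame:
    """Log OR per replicate and outcome.

    The log-OR-scale SE isolates the weight-variability component of the
    bias-precision trade-off: unlike the absolute-OR SE it does not shrink
    mechanically when the adjustment moves the OR towards 1.
    """
    return replicate_ors(replicates, web, reference, outcomes, ref_weights, scale="log")


def replicate_ors(
    replicates: ReplicateSet,
    web: pd.DataFrame,
    reference: pd.DataFrame,
    outcomes: list[str],
    ref_weights,
    scale: str = "absolute",
) -> pd.DataFrame:
    if scale not in {"absolute", "log"}:
        raise ValueError("scale must be 'absolute' or 'log'")
    ref_prev = {o: weighted_prevalence(reference[o], ref_weights) for o in outcomes}
    records = []
    for idx, w in zip(replicates.indices, replicates.weights):
        row = {}
        for o in outcomes:
            p_w = weighted_prevalence(web[o].iloc[idx], w)
            if 0.0 < p_w < 1.0 and 0.0 < ref_prev[o] < 1.0:
                orr = odds_ratio(p_w, ref_prev[o])
                row[o] = absolute_or(orr) if scale == "absolute" else np.log(orr)
            else:
                row[o] = np.nan
        records.append(row)
    return pd.DataFrame(records, columns=outcomes)


def se_absolute_or(replicate_values: pd.Series) -> float:
    """SE = sample standard deviation of one outcome's replicate absolute ORs."""
    vals = replicate_values.dropna()
    if len(vals) < 2:
        raise ValueError("need at least 2 defined replicates for an SE")
    return float(vals.std(ddof=1))


def average_se(per_outcome_ses) -> float:
    """Arithmetic mean of per-outcome SEs — the precision metric."""
    ses = np.asarray(list(per_outcome_ses), dtype=float)
    if len(ses) == 0 or np.isnan(ses).any():
        raise ValueError("all per-outcome SEs must be defined")
    return float(ses.mean())
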