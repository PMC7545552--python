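"""Propensity score adjustment by quintile subclassification.

Five equally sized subclasses are defined by the quintiles of the propensity
score over participants of both surveys combined.  Within each subclass the
*PSA ratio* is the reference survey's weighted proportion in the subclass
divided by the web survey's weighted proportion (each computed with the same
weights used to fit the propensity model).  A web participant's PSA weight is
their initial weight times the ratio of their subclass, which by construction
makes the PSA-weighted web subclass distribution match the reference's
exactly.  Participants whose score is missing fall back to their age-within-
sex post-stratification weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SubclassingError", "Subclasses", "PsaWeighting", "make_subclasses",
           "compute_psa_ratios", "apply_psa_weights", "psa_weights_for_stage"]

N_SUBCLASSES = 5


class SubclassingError(ValueError):
    pass


@dataclass(frozen=True)
class Subclasses:
    """Quintile boundaries and per-participant subclass assignment.

    For continuous scores there are 4 cutpoints and 5 subclasses.  With
    heavily tied scores coincident cutpoints are merged, giving fewer, wider
    subclasses (each tie group lies wholly in one subclass); in the extreme
    all-scores-equal case (an intercept-only propensity model) there is a
    single subclass and the adjustment passes weights through unchanged.
    """

    boundaries: np.ndarray  # up to 4 cutpoints; empty means one subclass
    assignment: pd.Series  # subclass 1..n_subclasses, NaN where score missing

    @property
    def n_subclasses(self) -> int:
        return len(self.boundaries) + 1

    @property
    def degenerate(self) -> bool:
        return len(self.boundaries) == 0

    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_subclasses + 1, dtype=float)


@dataclass(frozen=True)
class PsaWeighting:
    stage: int
    subclasses: Subclasses
    ratios: pd.Series  # indexed by subclass
    final_weights: pd.Series  # per web participant, positive


def _empirical_quantile(sorted_scores: np.ndarray, cdf: np.ndarray, target: float) -> float:
    """Smallest value whose (possibly weighted) empirical CDF reaches target."""
    k = int(np.searchsorted(cdf, target - 1e-12, side="left"))
    return float(sorted_scores[min(k, len(sorted_scores) - 1)])


def make_subclasses(scores: pd.Series, weights: pd.Series | None = None) -> Subclasses:
    """Assign combined-survey scores to five quintile subclasses.

    Boundaries sit at the 20/40/60/80 empirical percentiles of the combined
    non-missing scores — unweighted by default (equal participant counts per
    subclass); pass ``weights`` for weighted quintiles.  A score equal to a
    boundary goes to the lower subclass.  With all scores identical the
    result is the degenerate single pass-through subclass.
    """
    mask = scores.notna()
    values = scores[mask].to_numpy(dtype=float)
    if len(values) < N_SUBCLASSES:
        raise SubclassingError("need at least 5 scored participants to form quintiles")
    order = np.argsort(values, kind="stable")
    srt = values[order]
    if weights is None:
        w = np.ones(len(values))
    else:
        w = weights[mask].to_numpy(dtype=float)[order]
    cdf = np.cumsum(w) / w.sum()
    raw = [_empirical_quantile(srt, cdf, k / N_SUBCLASSES) for k in range(1, N_SUBCLASSES)]
    # coincident cutpoints (heavily tied scores) merge into wider subclasses;
    # a cutpoint at the maximum would leave an empty top subclass, so drop it
    boundaries = np.unique([b for b in raw if b < srt[-1]])
    if len(boundaries) == 0:
        assignment = pd.Series(np.where(mask, 1.0, np.nan), index=scores.index)
        return Subclasses(boundaries=np.empty(0), assignment=assignment)
    # ties at a boundary belong to the lower subclass -> side='left'
    sub = np.searchsorted(boundaries, scores.to_numpy(dtype=float), side="left") + 1.0
    assignment = pd.Series(np.where(mask, sub, np.nan), index=scores.index)
    return Subclasses(boundaries=boundaries, assignment=assignment)


def _weighted_subclass_proportions(
    assignment: pd.Series, weights: pd.Series, subclass_ids: np.ndarray
) -> pd.Series:
    mass = pd.Series(0.0, index=subclass_ids)
    scored = assignment.notna()
    grouped = weights[scored].groupby(assignment[scored]).sum()
    mass.loc[grouped.index] = grouped
    total = mass.sum()
    if total <= 0:
        raise SubclassingError("no weighted mass among scored participants")
    return mass / total


def compute_psa_ratios(
    subclasses: Subclasses,
    source: pd.Series,
    fit_weights: pd.Series,
) -> pd.Series:
    """Per-subclass PSA ratios: weighted reference proportion over weighted web
    proportion, computed with the same weights used to fit the propensity
    model.  Raises if any subclass lacks participants from either survey.
    """
    ids = subclasses.ids()
    assignment = subclasses.assignment
    is_web = source == "web"
    for label, mask in (("web", is_web), ("reference", ~is_web)):
        present = assignment[mask].dropna().unique()
        empty = sorted(set(ids) - set(present))
        if empty:
            raise SubclassingError(
                f"subclass(es) {[int(s) for s in empty]} contain no {label} participants; "
                "PSA ratio undefined"
            )
    p_ref = _weighted_subclass_proportions(assignment[~is_web], fit_weights[~is_web], ids)
    p_web = _weighted_subclass_proportions(assignment[is_web], fit_weights[is_web], ids)
    return p_ref / p_web


def apply_psa_weights(
    web: pd.DataFrame,
    assignment: pd.Series,
    ratios: pd.Series,
    fallback_weights: pd.Series,
) -> pd.Series:
    """Final PSA weights for web participants.

    Scored participants get initial weight x subclass ratio; participants with
    a missing score get their age-within-sex fallback weight.
    """
    initial = web["base_weight"]
    scored = assignment.notna()
    final = pd.Series(np.nan, index=web.index, dtype=float)
    final.loc[scored] = initial[scored] * ratios.loc[assignment[scored]].to_numpy()
    missing = ~scored
    if missing.any():
        fb = fallback_weights[missing]
        if fb.isna().any():
            raise ValueError("fallback weight missing for unscored participant(s)")
        final.loc[missing] = fb
    if (final <= 0).any() or final.isna().any():
        raise ValueError("final PSA weights must all be positive")
    return final


def psa_weights_for_stage(
    fit,
    reference: pd.DataFrame,
    web: pd.DataFrame,
    fallback_weights: pd.Series,
    scorer=None,
    weighted_quintiles: bool = False,
) -> PsaWeighting:
    """Score both surveys with one stage's fit and produce the stage's weights.

    ``scorer`` defaults to :func:`webpsa.propensity.score_participants`; it is
    injectable for testing.
    """
    if scorer is None:
        from .propensity import score_participants as scorer
    ref_scores = scorer(fit, reference)
    web_scores = scorer(fit, web)
    combined = pd.concat([ref_scores, web_scores], ignore_index=True)
    source = pd.Series(
        ["reference"] * len(reference) + ["web"] * len(web), index=combined.index
    )
    weights = pd.Series(
        np.concatenate(
            [reference["base_weight"].to_numpy(), web["base_weight"].to_numpy()]
        ),
        index=combined.index,
    )
    subclasses = make_subclasses(combined, weights=weights if weighted_quintiles else None)
    ratios = compute_psa_ratios(subclasses, source, weights)
    web_assignment = subclasses.assignment.iloc[len(reference):].reset_index(drop=True)
    web_assignment.index = web.index
    final = apply_psa_weights(web, web_assignment, ratios, fallback_weights)
    return PsaWeighting(
        stage=fit.stage, subclasses=subclasses, ratios=ratios, final_weights=final
    )
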