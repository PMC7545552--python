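"""Bias metrics: weighted prevalences, odds ratios against the reference
survey, the absolute odds ratio, bias categories, and per-stage averages.

For each binary outcome the web survey's weighted prevalence is compared with
the reference survey's as an odds ratio OR = [p_w/(1-p_w)] / [p_r/(1-p_r)].
The *absolute* OR, max(OR, 1/OR), measures bias magnitude symmetrically; its
average across the preselected outcome set is the survey-level bias metric.
Bias is described as small when the absolute OR is below 1.25, moderate in
1.25-1.67, and large above 1.67 (equivalently, ORs in 0.8-1.25 are small and
0.6-0.8 or 1.25-1.67 moderate).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "weighted_prevalence",
    "odds_ratio",
    "absolute_or",
    "classify_bias",
    "average_absolute_or",
    "evaluate_outcomes",
    "load_published_table",
    "reproduce_published_table",
]

SMALL_UPPER = 1.25
MODERATE_UPPER = 1.67


def weighted_prevalence(values: pd.Series, weights) -> float:
    """Weighted proportion of 1s among non-missing binary values."""
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    v = pd.Series(values).to_numpy(dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise ValueError("all outcome values missing; prevalence undefined")
    bad = set(np.unique(v[ok])) - {0.0, 1.0}
    if bad:
        raise ValueError(f"outcome must be binary; found values {sorted(bad)}")
    return float(np.sum(w[ok] * v[ok]) / np.sum(w[ok]))


def odds_ratio(p_web: float, p_ref: float) -> float:
    """OR of the web survey relative to the reference, from two prevalences."""
    for name, p in (("web", p_web), ("reference", p_ref)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} prevalence {p} on the boundary; OR undefined")
    return (p_web / (1 - p_web)) / (p_ref / (1 - p_ref))


def absolute_or(or_value: float) -> float:
    """The OR, or 1/OR if the OR is below 1 — a symmetric bias magnitude."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return max(or_value, 1.0 / or_value)


def classify_bias(or_value: float) -> str:
    """small / moderate / large by the absolute OR (boundaries to moderate)."""
    a = absolute_or(or_value)
    if a < SMALL_UPPER:
        return "small"
    if a <= MODERATE_UPPER:
        return "moderate"
    return "large"


def average_absolute_or(or_values, geometric: bool = False) -> float:
    """Mean absolute OR across the outcome set (arithmetic by default)."""
    abs_ors = np.array([absolute_or(v) for v in or_values], dtype=float)
    if len(abs_ors) == 0:
        raise ValueError("no odds ratios to average")
    if geometric:
        return float(np.exp(np.mean(np.log(abs_ors))))
    return float(abs_ors.mean())


def evaluate_outcomes(
    web: pd.DataFrame,
    reference: pd.DataFrame,
    outcomes: list[str],
    web_weights,
    ref_weights,
    weighting_label: str = "",
) -> pd.DataFrame:
    """Per-outcome prevalences, OR, absolute OR and bias category.

    Outcomes whose OR is undefined (boundary prevalence) are flagged with
    ``defined=False`` rather than silently dropped.
    """
    rows = []
    for outcome in outcomes:
        p_w = weighted_prevalence(web[outcome], web_weights)
        p_r = weighted_prevalence(reference[outcome], ref_weights)
        defined = 0.0 < p_w < 1.0 and 0.0 < p_r < 1.0
        if defined:
            orr = odds_ratio(p_w, p_r)
            rows.append(
                {
                    "outcome": outcome,
                    "weighting": weighting_label,
                    "prev_web": p_w,
                    "prev_ref": p_r,
                    "odds_ratio": orr,
                    "absolute_or": absolute_or(orr),
                    "bias": classify_bias(orr),
                    "defined": True,
                }
            )
        else:
            rows.append(
                {
                    "outcome": outcome,
                    "weighting": weighting_label,
                    "prev_web": p_w,
                    "prev_ref": p_r,
                    "odds_ratio": np.nan,
                    "absolute_or": np.nan,
                    "bias": "undefined",
                    "defined": False,
                }
            )
    return pd.DataFrame(rows)


def load_published_table(gender: str) -> pd.DataFrame:
    """Packaged transcription of the published per-outcome results for the
    best-performing web survey: prevalences under age-sex and PSA stage 1-5
    weighting, the reference prevalence, printed ORs (2 dp) and printed bias
    categories."""
    if gender not in {"male", "female"}:
        raise ValueError("gender must be 'male' or 'female'")
    path = resources.files("webpsa.data") / f"published_tables_{gender}.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def reproduce_published_table(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute ORs and bias categories from a published-table transcription.

    ORs are recomputed from the printed prevalence columns (3 dp inputs) for
    the age-sex and final-stage PSA weightings; categories are assigned from
    the ORs rounded to 2 dp as printed, which reproduces the printed bias
    columns deterministically.
    """
    out = table.copy()
    for label, prev_col in (("agesex", "prev_agesex"), ("psa5", "prev_psa5")):
        ors = [
            odds_ratio(pw, pr)
            for pw, pr in zip(out[prev_col], out["prev_reference"])
        ]
        out[f"or_recomputed_{label}"] = ors
        out[f"bias_recomputed_{label}"] = [
            classify_bias(round(v, 2)) for v in ors
        ]
        out[f"bias_from_printed_{label}"] = [
            classify_bias(v) for v in out[f"or_printed_{label}"]
        ]
    return out


def bias_category_counts(table: pd.DataFrame, column: str) -> dict[str, int]:
    """Counts of small/moderate/large in one bias column."""
    counts = table[column].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("small", "moderate", "large")}
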