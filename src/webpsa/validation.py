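"""Validation studies: printed-table reproduction and synthetic-data recovery.

Each function here runs one self-contained validation of the pipeline:

* reproduction of the published per-outcome odds ratios and bias categories
  from the packaged prevalence transcriptions;
* the exact subclass-distribution matching invariant of PSA weighting;
* null-scenario recovery (no self-selection -> no bias beyond Monte Carlo);
* correct-specification recovery (staged PSA removes the constructed bias);
* the type-I retention rate of the backward stepwise selection;
* bootstrap-SE agreement with the closed-form binomial SE in the
  no-adjustment limit; and
* the bias-precision trade-off (weight variability inflates the log-OR SE).

All randomness is driven by a single integer seed; derived seeds stay below
2**31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    bias_category_counts,
    load_published_table,
    reproduce_published_table,
    weighted_prevalence,
)
from .pipeline import run_gender
from .propensity import backward_stepwise
from .psa import SubclassingError
from .scenarios import default_stage_spec, make_scenario
from .variance import make_replicates, replicate_log_ors
from .weighting import post_stratify

__all__ = [
    "printed_table_validation",
    "subclass_matching_deviation",
    "null_scenario_bias",
    "correct_specification_recovery",
    "stepwise_type_one_rate",
    "bootstrap_se_agreement",
    "variance_inflation",
]


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def printed_table_validation() -> dict:
    """Recompute ORs and bias categories from the published prevalence columns.

    Returns the spot-check ORs, the maximum absolute deviation of recomputed
    from printed ORs over every row of both tables, the number of category
    mismatches, and the headline category counts.
    """
    out: dict = {}
    max_dev = 0.0
    mismatches = 0
    for gender in ["male", "female"]:
        table = reproduce_published_table(load_published_table(gender))
        for label in ["agesex", "psa5"]:
            dev = (table[f"or_recomputed_{label}"] - table[f"or_printed_{label}"]).abs()
            max_dev = max(max_dev, float(dev.max()))
            mismatches += int(
                (table[f"bias_from_printed_{label}"] != table[f"bias_printed_{label}"]).sum()
            )
        out[gender] = table
    male, female = out["male"], out["female"]

    def row_or(table: pd.DataFrame, behaviour: str, label: str) -> float:
        return float(
            table.loc[table["behaviour"] == behaviour, f"or_recomputed_{label}"].iloc[0]
        )

    counts_male_psa5 = bias_category_counts(male, "bias_from_printed_psa5")
    counts_male_agesex = bias_category_counts(male, "bias_from_printed_agesex")
    counts_female_psa5 = bias_category_counts(female, "bias_from_printed_psa5")
    counts_female_agesex = bias_category_counts(female, "bias_from_printed_agesex")
    return {
        "tables": out,
        "max_or_deviation": max_dev,
        "bias_category_mismatches": mismatches,
        "n_rows": int(len(male) + len(female)),
        "or_male_mixed_experience_agesex": row_or(male, "Experience not all with opposite sex", "agesex"),
        "or_male_mixed_experience_psa5": row_or(male, "Experience not all with opposite sex", "psa5"),
        "or_male_function_problem_psa5": row_or(male, "Had a sexual function problem in last year", "psa5"),
        "or_female_talk_parents_agesex": row_or(female, "Easy to talk to parent(s) about sex at age 14", "agesex"),
        "or_female_no_partner_year_agesex": row_or(female, "0 heterosexual partners last year", "agesex"),
        "or_female_mixed_experience_psa5": row_or(female, "Experience not all with opposite sex", "psa5"),
        "male_psa5_moderate": counts_male_psa5["moderate"],
        "male_agesex_large": counts_male_agesex["large"],
        "female_psa5_moderate_or_large": counts_female_psa5["moderate"] + counts_female_psa5["large"],
        "female_agesex_large": counts_female_agesex["large"],
    }


def _subclass_distributions(result: dict) -> list[tuple[int, pd.Series, pd.Series]]:
    """(stage, reference dist, PSA-weighted web dist) for each stage of a
    per-gender run, restricted to scored participants."""
    ref = result["reference"]
    web = result["web"]
    out = []
    for stage, pw in result["stage_weightings"].items():
        assignment = pw.subclasses.assignment
        ref_assign = assignment.iloc[: len(ref)]
        web_assign = assignment.iloc[len(ref):].reset_index(drop=True)
        ref_mask = ref_assign.notna().to_numpy()
        web_mask = web_assign.notna().to_numpy()
        ref_dist = (
            pd.Series(ref["base_weight"].to_numpy()[ref_mask])
            .groupby(ref_assign[ref_mask].to_numpy())
            .sum()
        )
        ref_dist /= ref_dist.sum()
        web_dist = (
            pd.Series(pw.final_weights.to_numpy()[web_mask])
            .groupby(web_assign[web_mask].to_numpy())
            .sum()
        )
        web_dist /= web_dist.sum()
        out.append((stage, ref_dist, web_dist))
    return out


def subclass_matching_deviation(seed: int, n_population: int = 20_000,
                                n_ref: int = 2_000, n_web: int = 1_000) -> dict:
    """Max |PSA-weighted web - reference| subclass proportion over all stages
    and genders of a synthetic run (the construction guarantees ~0)."""
    sc = make_scenario(seed=_child_seed(seed, 3), n_population=n_population,
                       n_ref=n_ref, n_web=n_web)
    max_dev = 0.0
    for gender in ["male", "female"]:
        res = run_gender(sc["reference"], sc["web"], sc["margins"],
                         default_stage_spec(), sc["outcomes"], gender)
        for _, ref_dist, web_dist in _subclass_distributions(res):
            max_dev = max(max_dev, float((ref_dist - web_dist).abs().max()))
    return {"max_deviation": max_dev}


def null_scenario_bias(seed: int, n_draws: int = 5) -> dict:
    """Average absolute OR under an intercept-only (no-selection) joining model.

    Runs ``n_draws`` independent scenario draws at the default sizes
    (population 100,000; reference 5,000; panel 2,000), both genders, and
    averages the per-stratum average absolute ORs at each weighting.  With no
    self-selection every weighting should sit within Monte-Carlo distance of
    1.
    """
    per_weighting: dict[str, list[float]] = {}
    for d in range(n_draws):
        sc = make_scenario(seed=_child_seed(seed, 10 + d), selection="null")
        for gender in ["male", "female"]:
            res = run_gender(sc["reference"], sc["web"], sc["margins"],
                             default_stage_spec(), sc["outcomes"], gender)
            s = res["summary_table"].set_index("weighting")["average_absolute_or"]
            for label, value in s.items():
                per_weighting.setdefault(label, []).append(float(value))
    means = {k: float(np.mean(v)) for k, v in per_weighting.items()}
    return {
        "per_weighting": means,
        "max_average_absolute_or": max(means.values()),
        "n_strata": n_draws * 2,
    }


def correct_specification_recovery(seed: int, n_web: int = 10_000) -> dict:
    """Strong-selection scenario where selection and outcomes use only
    stage-available variables: staged PSA should take the average absolute OR
    from well above 1.3 (age-sex weighting) to near 1 by stage 5, with a
    non-increasing stage profile up to Monte-Carlo noise."""
    sc = make_scenario(seed=_child_seed(seed, 20), n_web=n_web)
    res = run_gender(sc["reference"], sc["web"], sc["margins"],
                     default_stage_spec(), sc["outcomes"], "male")
    s = res["summary_table"].set_index("weighting")["average_absolute_or"]
    labels = ["age-sex", "PSA1", "PSA2", "PSA3", "PSA4", "PSA5"]
    seq = [float(s[k]) for k in labels]
    increments = np.diff(seq)
    return {
        "sequence": dict(zip(labels, seq)),
        "agesex_average_absolute_or": seq[0],
        "psa5_average_absolute_or": seq[-1],
        "max_stage_increase": float(increments.max()),
        "n_web": n_web,
    }


def stepwise_type_one_rate(seed: int, n_replicates: int = 500, n: int = 4_000) -> dict:
    """Retention rate of a pure-noise binary candidate at alpha=0.05.

    Each replicate simulates n/2 web and n/2 reference participants with a
    candidate independent of membership, runs backward stepwise with that
    single candidate, and records whether it survived.  The rate should match
    the nominal test size.
    """
    retained = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 30, r]))
        data = pd.DataFrame(
            {
                "source": ["web"] * (n // 2) + ["reference"] * (n // 2),
                "x": np.where(rng.random(n) < 0.5, "a", "b"),
            }
        )
        fit = backward_stepwise(data, np.ones(n), forced=[], candidates=["x"])
        retained += int("x" in fit.selected)
    rate = retained / n_replicates
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_replicates)
    return {
        "retention_rate": rate,
        "n_replicates": n_replicates,
        "nominal": 0.05,
        "ci_low": 0.05 - half_width,
        "ci_high": 0.05 + half_width,
    }


def bootstrap_se_agreement(seed: int, B: int = 500, outcome: str = "out_drug_ever") -> dict:
    """No-adjustment limit: bootstrap SE of the log OR vs the closed-form
    binomial SE sqrt(1/(n p (1-p))) on the web side (the reference is fixed).

    Uses the null scenario with an intercept-only propensity model, whose
    degenerate pass-through subclassing leaves the post-stratification
    weights untouched.
    """
    sc = make_scenario(seed=_child_seed(seed, 40), selection="null")
    ref = sc["reference"].reset_index(drop=True)
    web = sc["web"].reset_index(drop=True)
    ps = post_stratify(web, sc["margins"])
    web = web.copy()
    web["base_weight"] = ps.weights.to_numpy()
    combined = pd.concat([ref, web], ignore_index=True)
    fit0 = backward_stepwise(
        combined, combined["base_weight"].to_numpy(), forced=[], candidates=[], stage=0
    )
    reps = make_replicates(web, ref, fit0, sc["margins"], B=B, seed=_child_seed(seed, 41))
    ref_w = ref["base_weight"].to_numpy()
    log_ors = replicate_log_ors(reps, web, ref, [outcome], ref_w)[outcome]
    boot_se = float(log_ors.std(ddof=1))
    p = weighted_prevalence(web[outcome], web["base_weight"].to_numpy())
    closed_se = float(np.sqrt(1.0 / (len(web) * p * (1 - p))))
    return {
        "bootstrap_se": boot_se,
        "closed_form_se": closed_se,
        "relative_error": abs(boot_se - closed_se) / closed_se,
        "B": B,
        "n_web": len(web),
    }


def variance_inflation(seed: int, B: int = 300) -> dict:
    """Bias-precision trade-off under strong selection.

    Compares the average bootstrap SE of the log OR across the 22 outcomes
    under age-sex weighting against stage-5 PSA weighting, male stratum at
    the default sizes.  The log-OR scale isolates the weight-variability
    inflation — the absolute-OR-scale SE also shrinks as the adjustment pulls
    ORs towards 1, confounding the comparison.
    """
    sc = make_scenario(seed=_child_seed(seed, 50))
    ref = sc["reference"][sc["reference"]["gender"] == "male"].reset_index(drop=True)
    web = sc["web"][sc["web"]["gender"] == "male"].reset_index(drop=True)
    ps = post_stratify(web, sc["margins"])
    web = web.copy()
    web["base_weight"] = ps.weights.to_numpy()
    from .propensity import run_stages

    fits = run_stages(ref, web, default_stage_spec(), "male")
    combined = pd.concat([ref, web], ignore_index=True)
    fit0 = backward_stepwise(
        combined, combined["base_weight"].to_numpy(), forced=[], candidates=[],
        gender="male", stage=0,
    )
    ref_w = ref["base_weight"].to_numpy()
    outcomes = sc["outcomes"]

    def avg_log_se(fit) -> float:
        reps = make_replicates(web, ref, fit, sc["margins"], B=B,
                               seed=_child_seed(seed, 51))
        log_ors = replicate_log_ors(reps, web, ref, outcomes, ref_w)
        return float(np.mean([log_ors[o].std(ddof=1) for o in outcomes]))

    se_agesex = avg_log_se(fit0)
    se_psa5 = avg_log_se(fits[4])
    return {
        "average_se_agesex": se_agesex,
        "average_se_psa5": se_psa5,
        "ratio": se_psa5 / se_agesex,
        "B": B,
    }
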