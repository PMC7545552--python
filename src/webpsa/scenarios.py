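"""Default synthetic study scenarios.

The default scenario emulates the shape of a sexual-health web-panel
evaluation: a population of 100,000 adults aged 18-44 described by
demographics (gender, age group, region, education, partnership status),
sexual identity, lifestyle variables (drinking frequency, smoking), Likert
attitude items, two sexual-behaviour auxiliaries, and 22 binary outcomes; a
probability reference sample of 5,000 with known weights; and a web panel of
2,000 participants.

Under the *strong-selection* model, panel joining propensity rises with
minority sexual identity, liberal/risk-tolerant attitudes, frequent
drinking, smoking, youth and recent partner acquisition — the self-selection
pattern in which sexual-minority identities and linked behaviours are
over-represented among panel volunteers.  Selection and all outcome models
use only variables available to the stage-5 propensity pool, so a correctly
specified staged PSA can in principle remove the bias.  Selection
coefficients were fixed by exact enumeration over the discrete cells so that
the age-sex-weighted average absolute OR across the 22 outcomes is about
1.46 (male) / 1.43 (female) at the population level.  The *null* scenario uses an intercept-only
selection model: the panel is then a simple random sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .propensity import StageSpec
from .synthesize import (
    CategoricalModel,
    LogitModel,
    PopulationSpec,
    draw_reference_sample,
    draw_web_panel,
    generate_population,
)
from .weighting import CensusMargins

__all__ = [
    "OUTCOME_NAMES",
    "strong_selection_model",
    "null_selection_model",
    "default_population_spec",
    "default_stage_spec",
    "make_scenario",
]

DEFAULT_N_POPULATION = 100_000
DEFAULT_N_REF = 5_000
DEFAULT_N_WEB = 2_000


def _demographics() -> dict[str, CategoricalModel]:
    return {
        "gender": CategoricalModel(("male", "female"), {"male": 0.49, "female": 0.51}),
        "age_group": CategoricalModel(
            ("18-24", "25-34", "35-44"),
            {"18-24": 0.25, "25-34": 0.38, "35-44": 0.37},
        ),
        "region": CategoricalModel(
            ("london", "midlands", "north", "south"),
            {"london": 0.15, "midlands": 0.25, "north": 0.30, "south": 0.30},
        ),
        "education": CategoricalModel(
            ("low", "mid", "high"), {"low": 0.25, "mid": 0.45, "high": 0.30}
        ),
        "partnership": CategoricalModel(
            ("single", "cohabiting", "married"),
            {"single": 0.35, "cohabiting": 0.25, "married": 0.40},
        ),
    }


def _identity() -> dict[str, CategoricalModel]:
    return {
        "sexual_identity": CategoricalModel(
            ("heterosexual", "gay_lesbian", "bisexual", "other"),
            {"heterosexual": 0.940, "gay_lesbian": 0.022, "bisexual": 0.028, "other": 0.010},
            shifts={("gender", "male"): {"gay_lesbian": 0.3, "bisexual": -0.3}},
        )
    }


def _lifestyle() -> dict[str, CategoricalModel]:
    return {
        "drink_freq": CategoricalModel(
            ("never", "monthly", "weekly"),
            {"never": 0.20, "monthly": 0.45, "weekly": 0.35},
            shifts={("age_group", "18-24"): {"weekly": 0.3}},
        ),
        "smokes": CategoricalModel(
            ("no", "yes"),
            {"no": 0.75, "yes": 0.25},
            shifts={("education", "low"): {"yes": 0.4}},
        ),
    }


def _attitudes() -> dict[str, CategoricalModel]:
    return {
        "att_liberal": CategoricalModel(
            ("disagree", "neutral", "agree"),
            {"disagree": 0.30, "neutral": 0.35, "agree": 0.35},
            shifts={
                ("sexual_identity", "gay_lesbian"): {"agree": 0.8},
                ("sexual_identity", "bisexual"): {"agree": 0.6},
                ("age_group", "18-24"): {"agree": 0.2},
            },
        ),
        "att_risk": CategoricalModel(
            ("low", "medium", "high"),
            {"low": 0.50, "medium": 0.30, "high": 0.20},
            shifts={
                ("sexual_identity", "gay_lesbian"): {"high": 0.4},
                ("sexual_identity", "bisexual"): {"high": 0.4},
                ("drink_freq", "weekly"): {"high": 0.3},
            },
        ),
    }


def _behaviours() -> dict[str, CategoricalModel]:
    return {
        "beh_new_partner": CategoricalModel(
            ("no", "yes"),
            {"no": 0.80, "yes": 0.20},
            shifts={
                ("partnership", "single"): {"yes": 0.6},
                ("sexual_identity", "gay_lesbian"): {"yes": 0.5},
                ("sexual_identity", "bisexual"): {"yes": 0.5},
                ("age_group", "18-24"): {"yes": 0.4},
            },
        ),
        "beh_clinic": CategoricalModel(
            ("no", "yes"),
            {"no": 0.85, "yes": 0.15},
            shifts={
                ("beh_new_partner", "yes"): {"yes": 0.8},
                ("sexual_identity", "gay_lesbian"): {"yes": 0.6},
            },
        ),
    }


def _outcome_models() -> dict[str, LogitModel]:
    gay = ("sexual_identity", "gay_lesbian")
    bi = ("sexual_identity", "bisexual")
    other = ("sexual_identity", "other")
    agree = ("att_liberal", "agree")
    high = ("att_risk", "high")
    weekly = ("drink_freq", "weekly")
    smoke = ("smokes", "yes")
    newp = ("beh_new_partner", "yes")
    clinic = ("beh_clinic", "yes")
    young = ("age_group", "18-24")
    mid_age = ("age_group", "25-34")
    old = ("age_group", "35-44")
    male = ("gender", "male")
    single = ("partnership", "single")
    married = ("partnership", "married")
    cohab = ("partnership", "cohabiting")
    edu_hi = ("education", "high")
    edu_lo = ("education", "low")

    return {
        "out_sti_last_year": LogitModel(-2.3, {gay: 1.2, bi: 1.0, newp: 0.9, high: 0.6}),
        "out_sti_ever": LogitModel(-1.8, {gay: 1.0, bi: 0.9, newp: 0.7, high: 0.5, mid_age: 0.2}),
        "out_same_gender_partner": LogitModel(-3.6, {gay: 4.0, bi: 2.6, other: 0.8}),
        "out_experience_mixed": LogitModel(-2.8, {gay: 3.2, bi: 2.8, other: 1.0, agree: 0.4}),
        "out_no_partner_last_year": LogitModel(-1.9, {single: 0.9, newp: -0.8, young: 0.4}),
        "out_many_partners": LogitModel(-2.0, {newp: 1.3, high: 0.7, single: 0.6, gay: 0.5, bi: 0.5}),
        "out_drug_ever": LogitModel(-0.9, {weekly: 0.6, smoke: 0.9, agree: 0.5, young: 0.3}),
        "out_cannabis_ever": LogitModel(-1.1, {smoke: 1.0, weekly: 0.5, agree: 0.5}),
        "out_binge_weekly": LogitModel(-1.9, {weekly: 1.6, young: 0.6, male: 0.3}),
        "out_early_first_sex": LogitModel(-1.5, {edu_lo: 0.6, high: 0.5, smoke: 0.4}),
        "out_condomless_sex": LogitModel(0.8, {married: 0.6, cohab: 0.5, newp: -0.4}),
        "out_paid_for_sex": LogitModel(-2.6, {male: 0.9, high: 0.5, newp: 0.5}),
        "out_function_problem": LogitModel(-0.6, {old: 0.3, ("drink_freq", "never"): 0.2}),
        "out_tolerant_attitude": LogitModel(-0.8, {agree: 1.2, gay: 0.8, bi: 0.8, young: 0.3}),
        "out_clinic_5_years": LogitModel(-1.9, {clinic: 2.0, newp: 0.6, gay: 0.7}),
        "out_first_sex_right_time": LogitModel(0.6, {edu_hi: 0.3, high: -0.4}),
        "out_oral_sex_last_year": LogitModel(0.9, {single: -0.3, young: -0.2, newp: 0.3}),
        "out_anal_sex_last_year": LogitModel(-1.5, {high: 0.6, newp: 0.4, agree: 0.3}),
        "out_frequent_sex": LogitModel(-0.2, {married: 0.5, cohab: 0.5, single: -0.5}),
        "out_talk_to_parents": LogitModel(-1.6, {edu_hi: 0.4, young: 0.4, agree: 0.3}),
        "out_contraception_first_sex": LogitModel(1.2, {edu_hi: 0.4, high: -0.4, young: 0.3}),
        "out_willing_first_sex": LogitModel(1.8, {high: -0.4, edu_lo: -0.3}),
    }


OUTCOME_NAMES: tuple[str, ...] = tuple(_outcome_models())


def strong_selection_model(scale: float = 1.0) -> LogitModel:
    """Self-selection into the panel; ``scale`` multiplies every coefficient.

    The low intercept keeps joining propensities far from saturation, so
    selection is effectively log-linear and the over-representation of a
    group is close to the exponential of its coefficient.
    """
    coeffs = {
        ("sexual_identity", "gay_lesbian"): 2.10,
        ("sexual_identity", "bisexual"): 1.65,
        ("sexual_identity", "other"): 0.45,
        ("att_liberal", "agree"): 0.90,
        ("att_risk", "high"): 0.60,
        ("drink_freq", "weekly"): 0.525,
        ("smokes", "yes"): 0.375,
        ("age_group", "18-24"): 0.525,
        ("education", "high"): 0.375,
        ("partnership", "single"): 0.30,
        ("region", "london"): 0.225,
        ("beh_new_partner", "yes"): 0.675,
        ("beh_clinic", "yes"): 0.45,
    }
    return LogitModel(-6.0, {k: scale * v for k, v in coeffs.items()})


def null_selection_model() -> LogitModel:
    """Intercept only: panel joining is unrelated to any variable."""
    return LogitModel(-6.0)


def default_population_spec(
    seed: int = 0,
    n_population: int = DEFAULT_N_POPULATION,
    selection: str = "strong",
) -> PopulationSpec:
    if selection == "strong":
        sel = strong_selection_model()
    elif selection == "null":
        sel = null_selection_model()
    else:
        raise ValueError("selection must be 'strong' or 'null'")
    return PopulationSpec(
        n_population=n_population,
        demographics=_demographics(),
        identity=_identity(),
        lifestyle=_lifestyle(),
        attitudes=_attitudes(),
        behaviours=_behaviours(),
        outcomes=_outcome_models(),
        selection_model=sel,
        seed=seed,
    )


def default_stage_spec() -> StageSpec:
    """Cumulative candidate pools: demographics, then sexual identity (stage
    2), lifestyle (3), attitudes (4), sexual-behaviour auxiliaries (5)."""
    return StageSpec(
        {
            1: ("age_group", "region", "education", "partnership"),
            2: ("sexual_identity",),
            3: ("drink_freq", "smokes"),
            4: ("att_liberal", "att_risk"),
            5: ("beh_new_partner", "beh_clinic"),
        }
    )


def make_scenario(
    seed: int = 0,
    n_population: int = DEFAULT_N_POPULATION,
    n_ref: int = DEFAULT_N_REF,
    n_web: int = DEFAULT_N_WEB,
    selection: str = "strong",
) -> dict:
    """Generate population, reference sample, web panel and census margins.

    Sub-draws use seeds derived from ``seed`` so the three tables are
    independently seeded but jointly reproducible.
    """
    spec = default_population_spec(seed=seed, n_population=n_population, selection=selection)
    population = generate_population(spec)
    reference = draw_reference_sample(population, n_ref, seed=[seed, 1])
    web = draw_web_panel(population, n_web, spec.selection_model, seed=[seed, 2])
    margins = CensusMargins.from_population(population)
    return {
        "spec": spec,
        "population": population,
        "reference": reference,
        "web": web,
        "margins": margins,
        "outcomes": list(OUTCOME_NAMES),
    }
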