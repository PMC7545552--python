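"""Synthetic population, probability reference sample, and self-selected web panel.

The generator emulates the data situation of a volunteer web panel study
evaluated against a probability reference survey: a finite population of
people described by categorical demographics, sexual identity, lifestyle,
attitude and behaviour variables plus binary outcomes; a reference sample
drawn by (optionally unequal-probability) sampling without replacement with
known design weights; and a web panel whose members self-select through a
logistic joining model, typically over-representing minority sexual
identities and selected attitudes and behaviours.

All variables are categorical or binary, so every population quantity
(prevalence, selected-sample prevalence, outcome odds) can be computed
exactly by enumerating the discrete cells — see :func:`enumerate_cells`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ConfigurationError",
    "LogitModel",
    "CategoricalModel",
    "PopulationSpec",
    "generate_population",
    "draw_reference_sample",
    "draw_web_panel",
    "enumerate_cells",
    "cell_bernoulli_probability",
    "data_dictionary",
    "inject_missing",
    "spec_to_dict",
    "spec_from_dict",
]

_PROB_TOL = 1e-12


class ConfigurationError(ValueError):
    """A population spec field fails validation; the message names the field."""


@dataclass(frozen=True)
class LogitModel:
    """Logistic model on categorical predictors: logit(p) = intercept + sum of
    level coefficients.

    ``coeffs`` maps ``(variable, level)`` to an additive log-odds term; levels
    not listed contribute zero (implicit reference level).
    """

    intercept: float
    coeffs: dict[tuple[str, str], float] = field(default_factory=dict)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.intercept, dtype=float)
        for (var, level), beta in self.coeffs.items():
            if var not in table.columns:
                raise ConfigurationError(f"model references unknown variable {var!r}")
            eta += beta * (table[var].to_numpy() == level)
        return eta

    def probability(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))

    def variables(self) -> set[str]:
        return {var for var, _ in self.coeffs}


@dataclass(frozen=True)
class CategoricalModel:
    """Conditional categorical distribution in multinomial-logit form.

    Cell probabilities are proportional to ``base_probs[level] *
    exp(shift)``, where the shift for a row is the sum over ``shifts`` entries
    whose ``(parent_variable, parent_level)`` key matches the row.  With no
    shifts this is a plain marginal distribution.
    """

    levels: tuple[str, ...]
    base_probs: dict[str, float]
    shifts: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def validate(self, name: str) -> None:
        if set(self.base_probs) != set(self.levels):
            raise ConfigurationError(f"{name}: base_probs levels do not match declared levels")
        probs = np.array([self.base_probs[l] for l in self.levels], dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError(f"{name}: probabilities outside [0, 1]")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(f"{name}: base_probs sum to {probs.sum()!r}, not 1")
        for (_, _), level_shift in self.shifts.items():
            unknown = set(level_shift) - set(self.levels)
            if unknown:
                raise ConfigurationError(f"{name}: shift targets unknown levels {sorted(unknown)}")

    def probability_matrix(self, table: pd.DataFrame) -> np.ndarray:
        """Row-wise conditional probabilities, shape (len(table), n_levels)."""
        base = np.array([self.base_probs[l] for l in self.levels], dtype=float)
        log_scores = np.tile(np.log(np.maximum(base, 1e-300)), (len(table), 1))
        for (parent, parent_level), level_shift in self.shifts.items():
            if parent not in table.columns:
                raise ConfigurationError(
                    f"categorical model shift references unknown parent {parent!r}"
                )
            mask = table[parent].to_numpy() == parent_level
            for level, delta in level_shift.items():
                log_scores[mask, self.levels.index(level)] += delta
        log_scores -= log_scores.max(axis=1, keepdims=True)
        probs = np.exp(log_scores)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs


@dataclass
class PopulationSpec:
    """Full recipe for a finite synthetic population.

    Variables are generated in role order (demographics, identity, lifestyle,
    attitudes, behaviours) and each conditional model may depend on any
    variable generated before it.  Outcomes are binary draws from logistic
    models; the selection model governs web-panel joining propensity.
    """

    n_population: int
    demographics: dict[str, CategoricalModel]
    identity: dict[str, CategoricalModel]
    lifestyle: dict[str, CategoricalModel]
    attitudes: dict[str, CategoricalModel]
    behaviours: dict[str, CategoricalModel]
    outcomes: dict[str, LogitModel]
    selection_model: LogitModel
    seed: int = 0

    def variable_groups(self) -> dict[str, dict[str, CategoricalModel]]:
        return {
            "demographic": self.demographics,
            "identity": self.identity,
            "lifestyle": self.lifestyle,
            "attitude": self.attitudes,
            "behaviour": self.behaviours,
        }

    def categorical_models(self) -> dict[str, CategoricalModel]:
        merged: dict[str, CategoricalModel] = {}
        for group in self.variable_groups().values():
            merged.update(group)
        return merged

    def validate(self) -> None:
        if self.n_population <= 0:
            raise ConfigurationError("n_population must be positive")
        seen: set[str] = set()
        for group in self.variable_groups().values():
            for name, model in group.items():
                if name in seen:
                    raise ConfigurationError(f"duplicate variable {name!r}")
                model.validate(name)
                for parent, _ in model.shifts:
                    if parent not in seen:
                        raise ConfigurationError(
                            f"{name}: shift parent {parent!r} not generated before it"
                        )
                seen.add(name)
        for out_name, model in self.outcomes.items():
            for var, _ in model.coeffs:
                if var not in seen:
                    raise ConfigurationError(
                        f"outcome {out_name!r} references unknown variable {var!r}"
                    )
        for var, _ in self.selection_model.coeffs:
            if var not in seen and var not in self.outcomes:
                raise ConfigurationError(f"selection_model references unknown variable {var!r}")


def _categorical_to_dict(model: CategoricalModel) -> dict:
    return {
        "levels": list(model.levels),
        "base_probs": dict(model.base_probs),
        "shifts": {
            f"{var}={level}": dict(level_shift)
            for (var, level), level_shift in model.shifts.items()
        },
    }


def _categorical_from_dict(raw: dict) -> CategoricalModel:
    shifts = {}
    for key, level_shift in raw.get("shifts", {}).items():
        var, _, level = key.partition("=")
        shifts[(var, level)] = dict(level_shift)
    return CategoricalModel(tuple(raw["levels"]), dict(raw["base_probs"]), shifts)


def _logit_to_dict(model: LogitModel) -> dict:
    return {
        "intercept": model.intercept,
        "coeffs": {f"{var}={level}": beta for (var, level), beta in model.coeffs.items()},
    }


def _logit_from_dict(raw: dict) -> LogitModel:
    coeffs = {}
    for key, beta in raw.get("coeffs", {}).items():
        var, _, level = key.partition("=")
        coeffs[(var, level)] = float(beta)
    return LogitModel(float(raw["intercept"]), coeffs)


def spec_to_dict(spec: PopulationSpec) -> dict:
    """Plain-dict form of a population spec, YAML/JSON serialisable.

    Variable groups are emitted as ordered lists of ``{"name": ..., ...}``
    entries because generation order is significant (later variables may
    condition on earlier ones).
    """
    out: dict = {"n_population": spec.n_population, "seed": spec.seed}
    for group, models in spec.variable_groups().items():
        out[group] = [
            {"name": name, **_categorical_to_dict(m)} for name, m in models.items()
        ]
    out["outcomes"] = [
        {"name": name, **_logit_to_dict(m)} for name, m in spec.outcomes.items()
    ]
    out["selection_model"] = _logit_to_dict(spec.selection_model)
    return out


def spec_from_dict(raw: dict) -> PopulationSpec:
    """Inverse of :func:`spec_to_dict`; validates on construction paths."""
    groups = {
        group: {
            entry["name"]: _categorical_from_dict(entry)
            for entry in raw.get(group, [])
        }
        for group in ("demographic", "identity", "lifestyle", "attitude", "behaviour")
    }
    spec = PopulationSpec(
        n_population=int(raw["n_population"]),
        demographics=groups["demographic"],
        identity=groups["identity"],
        lifestyle=groups["lifestyle"],
        attitudes=groups["attitude"],
        behaviours=groups["behaviour"],
        outcomes={
            entry["name"]: _logit_from_dict(entry) for entry in raw.get("outcomes", [])
        },
        selection_model=_logit_from_dict(raw["selection_model"]),
        seed=int(raw.get("seed", 0)),
    )
    spec.validate()
    return spec


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw the finite population person table; reproducible given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_population
    table = pd.DataFrame({"person_id": np.arange(n)})
    for name, model in spec.categorical_models().items():
        probs = model.probability_matrix(table)
        cum = probs.cumsum(axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum).sum(axis=1)
        table[name] = pd.Categorical.from_codes(idx, categories=list(model.levels))
        table[name] = table[name].astype(object)
    for out_name, model in spec.outcomes.items():
        table[out_name] = (rng.random(n) < model.probability(table)).astype(int)
    return table


def _gumbel_topk(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    """Weighted sampling without replacement (Efraimidis-Spirakis via Gumbel keys)."""
    if size > (weights > 0).sum():
        raise ValueError("not enough units with positive weight to draw the requested sample")
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, size - 1)[:size]


def draw_reference_sample(
    population: pd.DataFrame,
    n_ref: int,
    seed: int,
    inclusion: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Probability reference sample with known base weights.

    Equal-probability by default (all base weights 1); ``inclusion`` gives
    multiplicative relative inclusion probabilities per ``(variable, level)``.
    Base weights are inverse relative inclusion probabilities normalised to
    mean 1, standing in for a reference survey's supplied standard weights.
    """
    if n_ref > len(population):
        raise ValueError(f"n_ref={n_ref} exceeds population size {len(population)}")
    rng = np.random.default_rng(seed)
    rel = np.ones(len(population))
    if inclusion:
        for (var, level), factor in inclusion.items():
            if factor <= 0:
                raise ValueError(f"inclusion factor for {(var, level)} must be positive")
            rel = np.where(population[var].to_numpy() == level, rel * factor, rel)
        idx = np.sort(_gumbel_topk(rng, rel, n_ref))
    else:
        idx = np.sort(rng.choice(len(population), size=n_ref, replace=False))
    sample = population.iloc[idx].reset_index(drop=True)
    weights = 1.0 / rel[idx]
    sample.insert(0, "participant_id", [f"R{i:06d}" for i in range(n_ref)])
    sample.insert(1, "source", "reference")
    sample["base_weight"] = weights / weights.mean()
    return sample


def draw_web_panel(
    population: pd.DataFrame,
    n_web: int,
    selection_model: LogitModel,
    seed: int,
) -> pd.DataFrame:
    """Self-selected web panel: joining propensity is the inverse-logit of the
    selection model; members drawn without replacement with probability
    proportional to propensity.  Base weights are left unset (NaN) — the
    post-stratification step supplies the panel's initial weights.
    """
    if n_web > len(population):
        raise ValueError(f"n_web={n_web} exceeds population size {len(population)}")
    rng = np.random.default_rng(seed)
    propensity = selection_model.probability(population)
    if not (propensity > 0).any():
        raise ValueError("all joining propensities are zero; web panel undefined")
    idx = np.sort(_gumbel_topk(rng, propensity, n_web))
    sample = population.iloc[idx].reset_index(drop=True)
    sample.insert(0, "participant_id", [f"W{i:06d}" for i in range(n_web)])
    sample.insert(1, "source", "web")
    sample["base_weight"] = np.nan
    return sample


def inject_missing(
    table: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Set each listed variable missing completely at random at its rate."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for var, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missing rate for {var!r} outside [0, 1]")
        mask = rng.random(len(out)) < rate
        out.loc[mask, var] = np.nan
    return out


def enumerate_cells(spec: PopulationSpec) -> pd.DataFrame:
    """Exact joint distribution over all discrete cells.

    Returns one row per combination of every categorical variable with a
    ``probability`` column summing to 1.  This is the enumeration oracle:
    population prevalences, selected-panel prevalences (Bayes over cells) and
    outcome prevalences are all exact sums over this table.
    """
    spec.validate()
    cells = pd.DataFrame({"probability": [1.0]})
    for name, model in spec.categorical_models().items():
        probs = model.probability_matrix(cells)
        expanded = cells.loc[cells.index.repeat(len(model.levels))].reset_index(drop=True)
        expanded[name] = list(model.levels) * len(cells)
        expanded["probability"] = cells["probability"].to_numpy().repeat(
            len(model.levels)
        ) * probs.ravel()
        cells = expanded[expanded["probability"] > 0].reset_index(drop=True)
    return cells


def cell_bernoulli_probability(cells: pd.DataFrame, model: LogitModel) -> np.ndarray:
    """Per-cell success probability of a logistic outcome/selection model."""
    return model.probability(cells)


def data_dictionary(spec: PopulationSpec) -> dict[str, dict]:
    """Variable name -> {role, levels}; outcomes are binary with role 'outcome'."""
    out: dict[str, dict] = {}
    for role, group in spec.variable_groups().items():
        for name, model in group.items():
            out[name] = {"role": role, "levels": list(model.levels)}
    for name in spec.outcomes:
        out[name] = {"role": "outcome", "levels": [0, 1]}
    return out
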