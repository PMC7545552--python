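"""End-to-end PSA pipeline: configuration, orchestration and file I/O.

``run_pipeline`` drives the whole procedure — synthetic data (or supplied
CSVs) -> base weights -> staged propensity fits -> PSA weights per stage ->
odds-ratio evaluation -> optional bootstrap SEs — and writes CSV/JSON
reports plus a structured run log.  The numbered scripts under ``analysis/``
are thin drivers over this module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import average_absolute_or, evaluate_outcomes
from .propensity import PropensityFit, StageSpec, backward_stepwise, run_stages
from .psa import psa_weights_for_stage
from .scenarios import OUTCOME_NAMES, default_stage_spec, make_scenario
from .synthesize import data_dictionary
from .variance import (
    average_se,
    make_replicates,
    replicate_absolute_ors,
    replicate_log_ors,
    se_absolute_or,
)
from .weighting import CensusMargins, post_stratify

__all__ = ["RunConfig", "run_pipeline", "run_gender", "load_stage_spec", "load_margins"]

WEIGHTING_LABELS = ["age-sex", "PSA1", "PSA2", "PSA3", "PSA4", "PSA5"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    With no CSV paths the run simulates the default synthetic scenario
    (``scenario`` passes keyword arguments through to
    :func:`webpsa.scenarios.make_scenario`).  ``bootstrap_replicates=0``
    skips variance estimation.
    """

    output_dir: str | Path = "results/run"
    seed: int = 0
    genders: tuple[str, ...] = ("male", "female")
    outcomes: tuple[str, ...] | None = None
    stage_spec: StageSpec | None = None
    bootstrap_replicates: int = 0
    scenario: dict = field(default_factory=dict)
    reference_csv: str | None = None
    web_csv: str | None = None
    margins_csv: str | None = None
    dictionary_json: str | None = None
    weighted_quintiles: bool = False
    geometric_mean: bool = False
    redo_selection: bool = False

    def validate(self, outcomes: list[str], stage_spec: StageSpec) -> None:
        if not outcomes:
            raise ValueError("outcome list must be non-empty")
        overlap = set(outcomes) & set(stage_spec.all_variables())
        if overlap:
            raise ValueError(
                "outcomes must be disjoint from propensity candidate pools: "
                f"{sorted(overlap)}"
            )


def load_stage_spec(path: str | Path) -> StageSpec:
    """Stage spec from YAML: mapping of stage number -> list of variables."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return StageSpec({int(k): tuple(v) for k, v in raw["stages"].items()})


def load_margins(path: str | Path) -> CensusMargins:
    """Census margins from CSV (gender, age_group, proportion) or YAML."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cells = pd.DataFrame(raw["cells"])
    else:
        cells = pd.read_csv(path)
    return CensusMargins(cells)


def _load_inputs(config: RunConfig) -> dict:
    if config.reference_csv or config.web_csv:
        if not (config.reference_csv and config.web_csv and config.margins_csv):
            raise ValueError("reference_csv, web_csv and margins_csv must all be given")
        data = {
            "reference": pd.read_csv(config.reference_csv),
            "web": pd.read_csv(config.web_csv),
            "margins": load_margins(config.margins_csv),
            "outcomes": list(config.outcomes or []),
        }
        if config.dictionary_json:
            with open(config.dictionary_json) as fh:
                data["dictionary"] = json.load(fh)
            if not data["outcomes"]:
                data["outcomes"] = [
                    name
                    for name, meta in data["dictionary"].items()
                    if meta.get("role") == "outcome"
                ]
        return data
    data = make_scenario(seed=config.seed, **config.scenario)
    data["dictionary"] = data_dictionary(data["spec"])
    return data


def run_gender(
    reference: pd.DataFrame,
    web: pd.DataFrame,
    margins: CensusMargins,
    stage_spec: StageSpec,
    outcomes: list[str],
    gender: str,
    bootstrap_replicates: int = 0,
    seed: int = 0,
    weighted_quintiles: bool = False,
    geometric_mean: bool = False,
    redo_selection: bool = False,
) -> dict:
    """Full per-gender analysis: fits, stage weights, bias table, summaries."""
    ref_g = reference[reference["gender"] == gender].reset_index(drop=True)
    web_g = web[web["gender"] == gender].reset_index(drop=True)
    if ref_g.empty or web_g.empty:
        raise ValueError(f"empty gender stratum {gender!r}")

    ps = post_stratify(web_g, margins)
    web_g = web_g.copy()
    web_g["base_weight"] = ps.weights.to_numpy()

    fits = run_stages(ref_g, web_g, stage_spec, gender)
    ref_weights = ref_g["base_weight"].to_numpy()

    weightings: dict[str, pd.Series] = {"age-sex": web_g["base_weight"]}
    stage_weightings = {}
    for fit in fits:
        pw = psa_weights_for_stage(
            fit, ref_g, web_g, ps.weights, weighted_quintiles=weighted_quintiles
        )
        stage_weightings[fit.stage] = pw
        weightings[f"PSA{fit.stage}"] = pw.final_weights

    results = []
    summaries = []
    for label in WEIGHTING_LABELS:
        table = evaluate_outcomes(
            web_g, ref_g, outcomes, weightings[label].to_numpy(), ref_weights,
            weighting_label=label,
        )
        results.append(table)
        defined = table[table["defined"]]
        summaries.append(
            {
                "gender": gender,
                "weighting": label,
                "average_absolute_or": average_absolute_or(
                    defined["odds_ratio"], geometric=geometric_mean
                ),
                "n_outcomes": len(defined),
                "n_undefined": int((~table["defined"]).sum()),
            }
        )
    outcome_table = pd.concat(results, ignore_index=True)
    summary_table = pd.DataFrame(summaries)

    se_rows = []
    replicate_failures = {}
    if bootstrap_replicates >= 2:
        # age-sex weighting SE: degenerate intercept-only "stage 0" fit whose
        # pass-through subclassing reproduces pure post-stratification weights
        base_fit = backward_stepwise(
            pd.concat([ref_g, web_g], ignore_index=True),
            pd.concat([ref_g, web_g], ignore_index=True)["base_weight"].to_numpy(),
            forced=[],
            candidates=[],
            gender=gender,
            stage=0,
        )
        for label, fit in [("age-sex", base_fit)] + [
            (f"PSA{f.stage}", f) for f in fits
        ]:
            reps = make_replicates(
                web_g, ref_g, fit, margins, B=bootstrap_replicates,
                seed=seed, redo_selection=redo_selection and fit.stage > 0,
            )
            replicate_failures[label] = reps.n_failed
            abs_ors = replicate_absolute_ors(reps, web_g, ref_g, outcomes, ref_weights)
            log_ors = replicate_log_ors(reps, web_g, ref_g, outcomes, ref_weights)
            ses = {o: se_absolute_or(abs_ors[o]) for o in outcomes}
            log_ses = {o: se_absolute_or(log_ors[o]) for o in outcomes}
            for o in outcomes:
                se_rows.append(
                    {
                        "gender": gender,
                        "weighting": label,
                        "outcome": o,
                        "se_absolute_or": ses[o],
                        "se_log_or": log_ses[o],
                    }
                )
            sel = summary_table["weighting"] == label
            summary_table.loc[sel, "average_se"] = average_se(ses.values())
            summary_table.loc[sel, "average_se_log_or"] = average_se(log_ses.values())
    se_table = pd.DataFrame(se_rows)

    return {
        "gender": gender,
        "fits": fits,
        "stage_weightings": stage_weightings,
        "post_stratification": ps,
        "web": web_g,
        "reference": ref_g,
        "outcome_table": outcome_table,
        "summary_table": summary_table,
        "se_table": se_table,
        "replicate_failures": replicate_failures,
    }


def _selected_variables_table(fits_by_gender: dict[str, list[PropensityFit]]) -> pd.DataFrame:
    """Per-stage selected variable lists, one row per gender x stage."""
    rows = []
    for gender, fits in fits_by_gender.items():
        for fit in fits:
            rows.append(
                {
                    "gender": gender,
                    "stage": fit.stage,
                    "selected": "; ".join(fit.selected),
                    "newly_selected": "; ".join(
                        v for v in fit.selected if v not in fit.forced
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and write all reports under output_dir."""
    data = _load_inputs(config)
    stage_spec = config.stage_spec or default_stage_spec()
    outcomes = list(config.outcomes or data.get("outcomes") or OUTCOME_NAMES)
    config.validate(outcomes, stage_spec)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_gender = {}
    log_lines = [f"seed={config.seed}", f"outcomes={len(outcomes)}"]
    for gender in config.genders:
        res = run_gender(
            data["reference"],
            data["web"],
            data["margins"],
            stage_spec,
            outcomes,
            gender,
            bootstrap_replicates=config.bootstrap_replicates,
            seed=config.seed,
            weighted_quintiles=config.weighted_quintiles,
            geometric_mean=config.geometric_mean,
            redo_selection=config.redo_selection,
        )
        per_gender[gender] = res
        for fit in res["fits"]:
            log_lines.append(
                f"{gender} stage {fit.stage}: selected {', '.join(fit.selected) or '(none)'}"
            )
        for label, nf in res["replicate_failures"].items():
            log_lines.append(f"{gender} {label}: {nf} failed bootstrap replicates")

    outcome_table = pd.concat(
        [r["outcome_table"].assign(gender=g) for g, r in per_gender.items()],
        ignore_index=True,
    )
    summary_table = pd.concat(
        [r["summary_table"] for r in per_gender.values()], ignore_index=True
    )
    selected_table = _selected_variables_table({g: r["fits"] for g, r in per_gender.items()})

    outcome_table.to_csv(outdir / "outcome_results.csv", index=False)
    summary_table.to_csv(outdir / "stage_summaries.csv", index=False)
    selected_table.to_csv(outdir / "selected_variables.csv", index=False)
    se_tables = [r["se_table"] for r in per_gender.values() if len(r["se_table"])]
    if se_tables:
        pd.concat(se_tables, ignore_index=True).to_csv(
            outdir / "se_absolute_or.csv", index=False
        )
    weight_rows = []
    for gender, res in per_gender.items():
        for stage, pw in res["stage_weightings"].items():
            weight_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": res["web"]["participant_id"],
                        "gender": gender,
                        "stage": stage,
                        "subclass": pw.subclasses.assignment.iloc[
                            len(res["reference"]):
                        ].to_numpy(),
                        "final_weight": pw.final_weights.to_numpy(),
                    }
                )
            )
    pd.concat(weight_rows, ignore_index=True).to_csv(
        outdir / "psa_weights.csv", index=False
    )

    meta = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "stage_spec"
        },
        "stage_spec": {k: list(v) for k, v in stage_spec.stages.items()},
        "outcomes": outcomes,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "per_gender": per_gender,
        "outcome_table": outcome_table,
        "summary_table": summary_table,
        "selected_table": selected_table,
        "output_dir": outdir,
    }
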