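"""Base weights for the two surveys entering the PSA pipeline.

The probability reference survey arrives with its supplied standard weights.
The web panel has no design weights, so its *initial* weights come from
post-stratification of the gender x age-group cross-classification to census
margins: each participant's weight is the ratio of the census cell proportion
to the sample cell proportion, normalised to mean 1 within the table.  The
same cell weights serve as the fallback for participants whose propensity
score is missing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CensusMargins", "PostStratification", "compute_initial_weights"]

GENDER = "gender"
AGE_GROUP = "age_group"


@dataclass(frozen=True)
class CensusMargins:
    """Population proportions of the gender x age-group cells.

    ``cells`` has columns gender, age_group, proportion.  Proportions must be
    positive; they are renormalised to sum to 1 over the cells present, so
    margins supplied for both genders can be reused for a single-gender run.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {GENDER, AGE_GROUP, "proportion"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"margins table missing columns {sorted(missing)}")
        if (self.cells["proportion"] <= 0).any():
            raise ValueError("margin proportions must be positive")
        if self.cells.duplicated([GENDER, AGE_GROUP]).any():
            raise ValueError("duplicate gender x age_group cells in margins")

    def restrict(self, genders: set) -> "CensusMargins":
        sub = self.cells[self.cells[GENDER].isin(genders)].copy()
        if sub.empty:
            raise ValueError(f"margins contain no cells for genders {sorted(genders)}")
        return CensusMargins(sub.reset_index(drop=True))

    def proportions(self) -> pd.Series:
        """Normalised cell proportions indexed by (gender, age_group)."""
        p = self.cells.set_index([GENDER, AGE_GROUP])["proportion"]
        return p / p.sum()

    @classmethod
    def from_population(cls, population: pd.DataFrame) -> "CensusMargins":
        """Exact census margins of a synthetic population table."""
        counts = (
            population.groupby([GENDER, AGE_GROUP], observed=True)
            .size()
            .rename("proportion")
            .reset_index()
        )
        counts["proportion"] /= counts["proportion"].sum()
        return cls(counts)


@dataclass(frozen=True)
class PostStratification:
    """Result of post-stratifying one table: per-cell weights plus the
    per-participant weight vector (mean 1)."""

    cell_weights: pd.Series  # indexed by (gender, age_group)
    weights: pd.Series  # indexed like the input table

    def fallback_weight(self, gender, age_group) -> float:
        """Age-within-sex cell weight, used when a propensity score is missing."""
        if pd.isna(gender) or pd.isna(age_group):
            raise ValueError("gender and age group are required for the fallback weight")
        try:
            return float(self.cell_weights.loc[(gender, age_group)])
        except KeyError:
            raise ValueError(f"cell ({gender!r}, {age_group!r}) absent from margins") from None


def post_stratify(table: pd.DataFrame, margins: CensusMargins) -> PostStratification:
    """Weights making the weighted gender x age-group distribution match margins.

    Raises if a margin cell has no sample members, or a participant falls in a
    cell absent from the margins.
    """
    margins = margins.restrict(set(table[GENDER].unique()))
    target = margins.proportions()
    cell_index = pd.MultiIndex.from_frame(table[[GENDER, AGE_GROUP]])
    sample_counts = cell_index.value_counts()
    sample_props = sample_counts / sample_counts.sum()

    extra = set(sample_props.index) - set(target.index)
    if extra:
        raise ValueError(f"participants in cells absent from margins: {sorted(extra)}")
    empty = set(target.index) - set(sample_props.index)
    if empty:
        raise ValueError(f"margin cells with no sample members: {sorted(empty)}")

    cell_weights = target / sample_props.reindex(target.index)
    weights = pd.Series(cell_weights.loc[cell_index].to_numpy(), index=table.index)
    norm = weights.mean()
    return PostStratification(cell_weights=cell_weights / norm, weights=weights / norm)


def compute_initial_weights(web: pd.DataFrame, margins: CensusMargins) -> pd.DataFrame:
    """Return the web table with ``base_weight`` set to post-stratification
    weights (mean 1)."""
    ps = post_stratify(web, margins)
    out = web.copy()
    out["base_weight"] = ps.weights.to_numpy()
    return out


def weighted_cell_distribution(table: pd.DataFrame, weights: np.ndarray) -> pd.Series:
    """Weighted gender x age-group proportions (diagnostic for the matching
    invariant)."""
    df = table[[GENDER, AGE_GROUP]].copy()
    df["w"] = np.asarray(weights, dtype=float)
    dist = df.groupby([GENDER, AGE_GROUP], observed=True)["w"].sum()
    return dist / dist.sum()
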