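"""Component scores and questionnaire composite scores.

A performance component score is the mean of the pooled z-standardised raw
items that load |.| > 0.5 on that component. Standardisation pools both
test occasions, so a genuine occasion shift survives into the scores
instead of being normalised away. Items with loadings below -0.5 are
sign-flipped before averaging so that every included item points in the
component's direction.

Missingness rule: at most one item may be missing per dog per component,
and only when the component has three or more items; otherwise the score
is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psychometrics import LoadingTable
from .synthetic_cohort import VOCAB

__all__ = [
    "pooled_standardize",
    "component_score",
    "health_status_composite",
    "training_level_composite",
    "questionnaire_composites",
    "HEALTH_ITEMS",
    "TRAINING_ITEMS",
]

HEALTH_ITEMS = ("medication", "vitamins", "health_problems")
TRAINING_ITEMS = (
    "commands_reliable", "commands_known", "trainings_finished",
    "trainings_current", "leisure_activities", "owner_experience",
)


def pooled_standardize(values: pd.Series | np.ndarray, name: str | None = None) -> pd.Series:
    """Z-scores over all pooled observations (both occasions together).

    Missing values stay missing. Raises on zero variance, naming the
    variable, because a constant item carries no performance signal.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    label = name or (s.name if s.name is not None else "<unnamed>")
    if s.notna().sum() < 2:
        raise ValueError(f"variable {label!r}: need >= 2 non-missing values")
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"variable {label!r} has zero variance")
    return (s - s.mean()) / sd


def component_score(
    z_items: pd.DataFrame,
    loading_table: LoadingTable,
    component: str,
) -> pd.Series:
    """Mean of the z-scored items included in one component.

    ``z_items`` holds pooled z-scores, one row per dog x occasion. The
    component's inclusion mask comes from the loading table; negatively
    loading items are sign-flipped. Applies the one-missing-of-three rule.
    """
    mask = loading_table.mask[component]
    items = [v for v in mask.index if mask[v]]
    if not items:
        raise ValueError(f"component {component!r} has an empty item mask")
    signs = np.sign(loading_table.loadings.loc[items, component]).replace(0, 1.0)
    block = z_items[items] * signs
    n_missing = block.isna().sum(axis=1)
    score = block.mean(axis=1, skipna=True)
    allowed = (n_missing == 0) | ((n_missing == 1) & (len(items) >= 3))
    return score.where(allowed)


def _code(item: str, value) -> float:
    if pd.isna(value) or value == "":
        return np.nan
    levels = VOCAB[item]
    try:
        return float(levels.index(value))
    except ValueError:
        raise ValueError(f"unknown level {value!r} for item {item!r}") from None


def _composite(df_or_values, items: tuple[str, ...], kind: str) -> pd.Series | float:
    if isinstance(df_or_values, pd.DataFrame):
        codes = pd.DataFrame(
            {it: df_or_values[it].map(lambda v, it=it: _code(it, v)) for it in items}
        )
        out = codes.mean(axis=1)
        out = out.where(codes.notna().all(axis=1))
        out.name = kind
        return out
    values = df_or_values
    codes = [_code(it, v) for it, v in zip(items, values)]
    if any(pd.isna(c) for c in codes):
        return float("nan")
    return float(np.mean(codes))


def health_status_composite(medication, vitamins=None, health_problems=None):
    """Mean of the integer-coded health items (medication, vitamins,
    number of health problems); higher = more health problems/medication.

    Accepts either three scalar levels or a DataFrame with the item columns.
    """
    if isinstance(medication, pd.DataFrame):
        return _composite(medication, HEALTH_ITEMS, "health_status")
    return _composite((medication, vitamins, health_problems), HEALTH_ITEMS, "health_status")


def training_level_composite(*args):
    """Mean of the six integer-coded training items; higher = more trained.

    Accepts the six scalar levels in :data:`TRAINING_ITEMS` order or a
    DataFrame with the item columns.
    """
    if len(args) == 1 and isinstance(args[0], pd.DataFrame):
        return _composite(args[0], TRAINING_ITEMS, "training_level")
    if len(args) != len(TRAINING_ITEMS):
        raise ValueError(f"expected {len(TRAINING_ITEMS)} items, got {len(args)}")
    return _composite(args, TRAINING_ITEMS, "training_level")


def questionnaire_composites(df: pd.DataFrame) -> pd.DataFrame:
    """Both composites for every row of a cohort table."""
    return pd.DataFrame(
        {
            "health_status": health_status_composite(df),
            "training_level": training_level_composite(df),
        }
    )
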