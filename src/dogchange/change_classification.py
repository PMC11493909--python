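"""Declining / stable / improving classification of pre–post change.

The classifier separates genuine performance change from intra-individual
variation with a band of +-10% of the baseline score range, centred on the
cohort-wide "experience effect" (the median shift between the first and
second occasions, attributable to test familiarity):

    range                 = max(baseline) - min(baseline)
    percentage            = range / 100
    experience effect     = median(second) - median(baseline)
    decrease threshold    = -pct * percentage + experience effect
    improvement threshold = +pct * percentage + experience effect
    change value          = second - baseline

    declining  iff  change <= decrease threshold
    stable     iff  decrease threshold < change <= improvement threshold
    improving  iff  improvement threshold < change

Boundary conventions follow the inequalities exactly: a change sitting on
the decrease threshold is declining; one sitting on the improvement
threshold is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "ChangeThresholds",
    "compute_thresholds",
    "categorize",
    "make_change_pairs",
    "categorize_cohort",
    "threshold_balance_search",
]

CATEGORIES = ("declining", "stable", "improving")


@dataclass(frozen=True)
class ChangeThresholds:
    """Classification band for one performance component."""

    range: float
    percentage: float
    experience_effect: float
    threshold_decrease: float
    threshold_improvement: float
    pct: float = 10.0


def compute_thresholds(baseline, second, pct: float = 10.0) -> ChangeThresholds:
    """Band parameters from the cohort's baseline and second-occasion scores."""
    b = pd.Series(np.asarray(baseline, dtype=float)).dropna()
    s = pd.Series(np.asarray(second, dtype=float)).dropna()
    if len(b) < 2 or len(s) == 0:
        raise ValueError("need >= 2 baseline and >= 1 second-occasion values")
    rng = float(b.max() - b.min())
    if rng == 0:
        raise ValueError("degenerate scale: baseline range is zero")
    percentage = rng / 100.0
    experience = float(s.median() - b.median())
    return ChangeThresholds(
        range=rng,
        percentage=percentage,
        experience_effect=experience,
        threshold_decrease=-pct * percentage + experience,
        threshold_improvement=pct * percentage + experience,
        pct=pct,
    )


def categorize(change_value: float, thresholds: ChangeThresholds) -> str | float:
    """One of 'declining', 'stable', 'improving'; NaN for a missing change."""
    if pd.isna(change_value):
        return np.nan
    if change_value <= thresholds.threshold_decrease:
        return "declining"
    if change_value <= thresholds.threshold_improvement:
        return "stable"
    return "improving"


def make_change_pairs(scores: pd.DataFrame) -> pd.DataFrame:
    """Baseline→second pairs from long-format component scores.

    ``scores`` has columns dog_id, occasion, component, value. Consecutive
    occasions form a pair, so a re-enrolled control with three occasions
    contributes two pairs (1→2 and 2→3), the second using its pre-therapy
    measurement as the new baseline.
    """
    out = []
    for (dog, comp), grp in scores.groupby(["dog_id", "component"], sort=True):
        grp = grp.sort_values("occasion")
        occ = grp["occasion"].to_numpy()
        val = grp["value"].to_numpy(dtype=float)
        for a, b in zip(range(len(occ) - 1), range(1, len(occ))):
            out.append(
                {
                    "dog_id": dog,
                    "component": comp,
                    "baseline_occasion": int(occ[a]),
                    "second_occasion": int(occ[b]),
                    "baseline": val[a],
                    "second": val[b],
                }
            )
    pairs = pd.DataFrame(
        out,
        columns=[
            "dog_id", "component", "baseline_occasion", "second_occasion",
            "baseline", "second",
        ],
    )
    pairs["change_value"] = pairs["second"] - pairs["baseline"]
    return pairs


def categorize_cohort(
    scores: pd.DataFrame, pct: float = 10.0
) -> tuple[pd.DataFrame, dict[str, ChangeThresholds], pd.DataFrame]:
    """Classify every baseline→second pair of every component.

    Thresholds are computed once per component from the baselines and
    second values of all analysed pairs (re-enrolled controls contribute
    both their pairs). Returns (records, thresholds per component, counts
    per component x category).
    """
    pairs = make_change_pairs(scores)
    thresholds: dict[str, ChangeThresholds] = {}
    cats = pd.Series(np.nan, index=pairs.index, dtype=object)
    for comp, grp in pairs.groupby("component", sort=True):
        thr = compute_thresholds(grp["baseline"], grp["second"], pct=pct)
        thresholds[comp] = thr
        cats.loc[grp.index] = [categorize(c, thr) for c in grp["change_value"]]
    records = pairs.assign(category=cats)
    counts = (
        records.dropna(subset=["category"])
        .groupby(["component", "category"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    counts.columns.name = None
    return records, thresholds, counts


def threshold_balance_search(
    scores: pd.DataFrame, candidate_pcts=tuple(range(5, 26, 5))
) -> tuple[float, pd.DataFrame]:
    """Pick the band width whose three categories are closest to balanced.

    For each candidate pct, every component's pairs are classified and a
    chi-square distance from uniform thirds is accumulated:
    sum_components sum_categories (n_cat - N/3)^2 / (N/3). The candidate
    with the smallest total wins; ties go to the earliest candidate in the
    list. Returns (chosen pct, per-candidate diagnostics).
    """
    candidate_pcts = list(candidate_pcts)
    if len(candidate_pcts) < 2:
        raise ValueError("need >= 2 candidate percentages")
    rows = []
    for pct in candidate_pcts:
        _, _, counts = categorize_cohort(scores, pct=pct)
        total = 0.0
        for comp, row in counts.iterrows():
            n = row.sum()
            if n == 0:
                continue
            expected = n / 3.0
            total += float(((row - expected) ** 2 / expected).sum())
        rows.append({"pct": pct, "balance_chi2": total})
    diagnostics = pd.DataFrame(rows)
    best = diagnostics.loc[diagnostics["balance_chi2"].idxmin(), "pct"]
    return float(best), diagnostics
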