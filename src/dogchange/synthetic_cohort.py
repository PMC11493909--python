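"""Synthetic cohorts with the pre/post intervention study design.

The generator emulates a cohort of old family dogs tested twice on a
behavioural battery, four months apart, with four arms (physical therapy,
cognitive therapy, combined, control) and a subsample of controls that
re-enrol into a therapy arm and receive a third test occasion. Each
re-enrolled control therefore contributes two baseline→second pairs
downstream (occasion 1→2 as a control, 2→3 as a treated dog), which is why
the default design of 72 dogs yields 84 change records.

The generative model is a classical true-score model: each dog carries a
latent ability per performance component; an occasion's observed component
score is the latent ability plus an occasion ("experience") shift, any
intervention effect for therapies completed before that occasion, and
fresh measurement noise. The noise share is set so that the test–retest
correlation of observed scores equals the configured latent ICC, and the
independent per-occasion noise reproduces regression to the mean without
any extra machinery. Raw task items are noisy linear images of the
occasion score; ordinal items are produced by thresholding latent
Gaussians so the polychoric estimator has a correctly specified target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortTable",
    "VOCAB",
    "ITEM_TYPES",
    "generate_cohort",
    "generate_ordinal_pair",
]

GROUPS = ("physical", "cognitive", "combined", "control")

#: questionnaire vocabularies (levels ascend in code order)
VOCAB: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "group": GROUPS,
    "medication": ("no", "yes"),
    "vitamins": ("almost never", "rarely", "often", "regularly"),
    "health_problems": ("no problems", "1", "2", "3 or more"),
    "commands_reliable": ("maximum 3", "4", "5", "6", "7 or more"),
    "commands_known": ("less than 10", "10 or more"),
    "trainings_finished": ("0", "1", "2 or more"),
    "trainings_current": ("0", "1", "2 or more"),
    "leisure_activities": ("1 or less", "2", "3 or more"),
    "owner_experience": ("minimal", "moderate", "professional"),
    "daily_play": ("<1 h", ">1 h"),
    "daily_offleash": ("<1 h", "1-3 h", ">3 h"),
}

ITEM_TYPES = ("ordinal", "duration", "frequency", "latency")


def _default_group_sizes() -> dict[str, int]:
    return {"physical": 20, "cognitive": 19, "combined": 24, "control": 21}


def _default_reenrol_split() -> dict[str, int]:
    return {"physical": 4, "cognitive": 2, "combined": 6}


def _default_icc() -> dict[str, float]:
    return {"greeting": 0.75, "persistency": 0.65, "problem_solving": 0.55,
            "exploration": 0.35}


def _default_experience() -> dict[str, float]:
    return {"greeting": 0.10, "persistency": -0.50, "problem_solving": 0.15,
            "exploration": 0.20}


def _default_intervention() -> dict[str, dict[str, float]]:
    return {"greeting": {"physical": 0.6}, "problem_solving": {"cognitive": 0.6}}


@dataclass
class SimulationConfig:
    """Design and latent-model parameters of a synthetic cohort.

    ``group_sizes`` are therapy-exposure counts: re-enrolled controls are
    counted both in the control arm and in the arm they later join, so the
    sizes sum to ``n_dogs + n_reenrolled_controls`` (84 exposure slots for
    72 dogs by default). ``latent_icc`` is the target test–retest
    reliability of each component score; ``experience_effect`` and
    ``intervention_effects`` are shifts of the second-occasion score in
    latent SD units.
    """

    n_dogs: int = 72
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_reenrolled_controls: int = 12
    reenrol_split: dict[str, int] = field(default_factory=_default_reenrol_split)
    items_per_component: int = 4
    item_type_mix: dict[str, float] = field(
        default_factory=lambda: {t: 0.25 for t in ITEM_TYPES}
    )
    ordinal_components: tuple[str, ...] = ("greeting",)
    ordinal_levels: int = 4
    item_loading: float = 0.8
    latent_icc: dict[str, float] = field(default_factory=_default_icc)
    experience_effect: dict[str, float] = field(default_factory=_default_experience)
    intervention_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_intervention
    )
    age_range: tuple[float, float] = (7.7, 14.5)
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def components(self) -> list[str]:
        return list(self.latent_icc)

    def validate(self) -> None:
        if sum(self.group_sizes.values()) != self.n_dogs + self.n_reenrolled_controls:
            raise ValueError(
                "group sizes (exposure counts) must sum to "
                "n_dogs + n_reenrolled_controls"
            )
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must have keys {GROUPS}")
        if self.n_reenrolled_controls > self.group_sizes["control"]:
            raise ValueError("more re-enrolled controls than controls")
        if sum(self.reenrol_split.values()) != self.n_reenrolled_controls:
            raise ValueError("reenrol_split must sum to n_reenrolled_controls")
        for c, icc in self.latent_icc.items():
            if not 0.0 <= icc <= 1.0:
                raise ValueError(f"latent_icc[{c!r}] must lie in [0, 1]")
        if self.ordinal_levels < 2:
            raise ValueError("ordinal_levels must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("ordinal_components", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortTable:
    """A cohort: one row per dog x occasion, plus (for synthetic data) the
    true latent component scores used to generate it."""

    data: pd.DataFrame
    true_scores: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "cohort.csv", index=False)
        if self.true_scores is not None:
            self.true_scores.to_csv(outdir / "true_scores.csv", index=False)
        if self.config is not None:
            self.config.to_json(outdir / "simulation_config.json")


def _item_schema(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(column name, component, item type) for every raw task variable."""
    mix_types = [t for t in ITEM_TYPES if config.item_type_mix.get(t, 0) > 0]
    schema: list[tuple[str, str, str]] = []
    counter = 0
    for comp in config.components:
        for j in range(config.items_per_component):
            if comp in config.ordinal_components:
                itype = "ordinal"
            else:
                itype = mix_types[counter % len(mix_types)]
                counter += 1
            schema.append((f"{comp}_v{j + 1}_{itype}", comp, itype))
    return schema


def _exposures(group: str) -> tuple[str, ...]:
    """Therapy modalities a group is exposed to."""
    return {
        "physical": ("physical",),
        "cognitive": ("cognitive",),
        "combined": ("physical", "cognitive"),
        "control": (),
    }[group]


def _intervention_shift(config: SimulationConfig, comp: str, group: str) -> float:
    eff = config.intervention_effects.get(comp, {})
    return sum(eff.get(m, 0.0) for m in _exposures(group))


def _ordinal_cuts(levels: int) -> np.ndarray:
    return np.array([-1.0, 0.0, 1.0]) if levels == 4 else \
        np.linspace(-1.5, 1.5, levels - 1)


def _discretization_corr(levels: int) -> float:
    """Correlation between a standard normal and its digitised version."""
    from scipy.stats import norm

    cuts = _ordinal_cuts(levels)
    edges = np.concatenate(([-np.inf], cuts, [np.inf]))
    probs = np.diff(norm.cdf(edges))
    scores = np.arange(levels, dtype=float)
    # E[d * x] = sum_j j * (phi(lower_j) - phi(upper_j)) for x ~ N(0,1)
    pdf = norm.pdf(np.clip(edges, -40, 40))
    e_dx = float(np.sum(scores * (pdf[:-1] - pdf[1:])))
    var_d = float(np.sum(probs * scores**2) - np.sum(probs * scores) ** 2)
    return e_dx / np.sqrt(var_d)


def _latent_variance(config: SimulationConfig, comp: str) -> float:
    """Latent true-score variance producing the requested observed-score ICC.

    Item noise and ordinal discretisation attenuate the test–retest
    correlation of the mean-of-items component score relative to the
    latent occasion scores; the latent variance is inflated to compensate,
    so that the *observed* component scores' retest correlation
    approximates ``latent_icc`` by construction.
    """
    target = config.latent_icc[comp]
    lam = config.item_loading
    r_disc = _discretization_corr(config.ordinal_levels)
    lams = []
    for _, c, itype in _item_schema(config):
        if c != comp:
            continue
        lams.append(lam * r_disc if itype == "ordinal" else lam)
    lams = np.asarray(lams)
    k = lams.size
    s = lams.sum()
    attenuation = s**2 / (k + s**2 - np.sum(lams**2))
    return float(min(target / attenuation, 0.97))


def _render_item(latent: np.ndarray, itype: str, levels: int) -> np.ndarray:
    """Map a latent N(0,1)-scale item to its raw observation scale."""
    if itype == "ordinal":
        return np.digitize(latent, _ordinal_cuts(levels)).astype(float)
    if itype == "duration":  # seconds spent on the task
        return np.round(np.clip(30.0 + 12.0 * latent, 0.0, None), 2)
    if itype == "frequency":  # count of behaviour occurrences
        return np.round(np.clip(4.0 + 2.0 * latent, 0.0, None))
    if itype == "latency":  # seconds until first success; longer = worse
        return np.round(np.clip(60.0 - 15.0 * latent, 0.0, 120.0), 2)
    raise ValueError(f"unknown item type {itype!r}")


def generate_cohort(config: SimulationConfig | None = None) -> CohortTable:
    """Simulate a cohort under the configured design.

    Deterministic in ``config.seed``. Returns the dog x occasion table with
    raw task items and questionnaire covariates, alongside the true latent
    component scores per occasion (the quantity the scoring pipeline
    estimates).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    schema = _item_schema(config)
    meta_cols = [
        "dog_id", "occasion", "group", "later_group", "age", "sex",
        "medication", "vitamins", "health_problems", "commands_reliable",
        "commands_known", "trainings_finished", "trainings_current",
        "leisure_activities", "owner_experience", "daily_play",
        "daily_offleash", "activity_excitability", "responsiveness_training",
    ]
    columns = meta_cols + [name for name, _, _ in schema]
    if config.n_dogs == 0:
        empty = pd.DataFrame(columns=columns)
        truth = pd.DataFrame(columns=["dog_id", "occasion"] + config.components)
        return CohortTable(empty, truth, config)

    # --- dog-level design -------------------------------------------------
    fresh = {g: config.group_sizes[g] - config.reenrol_split.get(g, 0)
             for g in ("physical", "cognitive", "combined")}
    groups = (["control"] * config.group_sizes["control"]
              + ["physical"] * fresh["physical"]
              + ["cognitive"] * fresh["cognitive"]
              + ["combined"] * fresh["combined"])
    later: list[str | None] = [None] * config.n_dogs
    idx = 0
    for g in ("physical", "cognitive", "combined"):
        for _ in range(config.reenrol_split.get(g, 0)):
            later[idx] = g
            idx += 1

    dog_ids = [f"dog{i + 1:03d}" for i in range(config.n_dogs)]
    age = np.round(rng.uniform(*config.age_range, size=config.n_dogs), 2)
    sex = rng.choice(VOCAB["sex"], size=config.n_dogs, p=[0.47, 0.53])
    quest = {
        "medication": rng.choice(VOCAB["medication"], config.n_dogs, p=[0.7, 0.3]),
        "vitamins": rng.choice(VOCAB["vitamins"], config.n_dogs),
        "health_problems": rng.choice(
            VOCAB["health_problems"], config.n_dogs, p=[0.4, 0.3, 0.2, 0.1]
        ),
        "commands_reliable": rng.choice(VOCAB["commands_reliable"], config.n_dogs),
        "commands_known": rng.choice(VOCAB["commands_known"], config.n_dogs),
        "trainings_finished": rng.choice(VOCAB["trainings_finished"], config.n_dogs),
        "trainings_current": rng.choice(VOCAB["trainings_current"], config.n_dogs),
        "leisure_activities": rng.choice(VOCAB["leisure_activities"], config.n_dogs),
        "owner_experience": rng.choice(VOCAB["owner_experience"], config.n_dogs),
        "daily_play": rng.choice(VOCAB["daily_play"], config.n_dogs),
        "daily_offleash": rng.choice(VOCAB["daily_offleash"], config.n_dogs),
        # DPQ trait scores: sums of 12 and 6 Likert(1..7) items
        "activity_excitability": rng.integers(1, 8, (config.n_dogs, 12)).sum(axis=1),
        "responsiveness_training": rng.integers(1, 8, (config.n_dogs, 6)).sum(axis=1),
    }

    # --- latent component scores per occasion -----------------------------
    comps = config.components
    latent_var = {c: _latent_variance(config, c) for c in comps}
    true_ability = {
        c: rng.normal(0.0, np.sqrt(latent_var[c]), config.n_dogs)
        for c in comps
    }

    rows = []
    truth_rows = []
    for i, dog in enumerate(dog_ids):
        occasions = [1, 2] if later[i] is None else [1, 2, 3]
        for occ in occasions:
            row = {
                "dog_id": dog, "occasion": occ, "group": groups[i],
                "later_group": later[i] if later[i] is not None else "",
                "age": age[i], "sex": sex[i],
            }
            for key, vals in quest.items():
                row[key] = vals[i]
            truth = {"dog_id": dog, "occasion": occ}
            occ_scores = {}
            for c in comps:
                noise = rng.normal(0.0, np.sqrt(max(1.0 - latent_var[c], 1e-3)))
                shift = 0.0
                if occ >= 2:
                    # familiarity gained at the first retest; assumed saturated after
                    shift += config.experience_effect.get(c, 0.0)
                if occ == 2:
                    shift += _intervention_shift(config, c, groups[i])
                elif occ == 3:
                    shift += _intervention_shift(config, c, later[i])
                score = true_ability[c][i] + shift + noise
                occ_scores[c] = score
                truth[c] = score
            lam = config.item_loading
            for name, comp, itype in schema:
                latent = lam * occ_scores[comp] + np.sqrt(1 - lam**2) * rng.normal()
                value = _render_item(np.array([latent]), itype, config.ordinal_levels)[0]
                if config.missing_rate and rng.random() < config.missing_rate:
                    value = np.nan
                row[name] = value
            rows.append(row)
            truth_rows.append(truth)

    data = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(truth_rows)
    return CohortTable(data, truth, config)


def generate_ordinal_pair(
    rho: float, n: int, levels: int = 4, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired ordinal sample discretised from a bivariate normal.

    Both margins are cut at equal-probability normal quantiles, so the
    polychoric estimate of the sample should recover ``rho``. Intended as a
    fixture generator for the polychoric estimator.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    cuts = norm.ppf(np.arange(1, levels) / levels)
    return np.digitize(z[:, 0], cuts), np.digitize(z[:, 1], cuts)
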