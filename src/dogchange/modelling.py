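"""Multinomial log-linear modelling of the three-category change outcome.

The outcome (declining / stable / improving) is modelled by softmax
regression with "stable" as the reference category, fitted by maximum
likelihood through statsmodels' MNLogit. On top of the fit this module
provides: the four intervention codings, pairwise contrast odds ratios
with Wald confidence intervals (the third contrast via the delta method),
likelihood-ratio tests, forward model selection requiring both a
significant LRT and an AIC drop of at least two, and a VIF collinearity
diagnostic computed on binomial GLMs because VIF is undefined for
multinomial fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CATEGORIES",
    "INTERVENTION_CODINGS",
    "ModelSpec",
    "ModelFit",
    "ContrastEstimate",
    "DiagnosticsResult",
    "SelectionResult",
    "intervention_coding",
    "add_intervention_codings",
    "fit_multinomial",
    "wald_odds_ratio",
    "pairwise_contrasts",
    "lrt",
    "forward_aic_select",
    "vif_binomial",
]

CATEGORIES = ("stable", "declining", "improving")  # reference first
INTERVENTION_CODINGS = ("group4", "any_physical", "any_cognitive", "any_intervention")


@dataclass(frozen=True)
class ModelSpec:
    """Outcome and predictor set of one multinomial model."""

    outcome: str
    predictors: tuple[str, ...] = ()
    reference: str = "stable"

    def __post_init__(self) -> None:
        codings = [p for p in self.predictors if p in INTERVENTION_CODINGS]
        if len(codings) > 1:
            raise ValueError("at most one intervention coding per model")


@dataclass
class ModelFit:
    """A fitted multinomial model.

    ``params``/``bse``/``zvalues``/``pvalues`` are DataFrames indexed by
    design column, one column per non-reference outcome category. ``cov``
    is the full coefficient covariance with a (category, design column)
    MultiIndex.
    """

    spec: ModelSpec
    params: pd.DataFrame
    bse: pd.DataFrame
    zvalues: pd.DataFrame
    pvalues: pd.DataFrame
    llf: float
    aic: float
    n_params: int
    n_obs: int
    cov: pd.DataFrame
    categories: tuple[str, ...]
    term_columns: dict[str, list[str]]
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ContrastEstimate:
    """One pairwise category contrast for one predictor."""

    predictor: str
    contrast: str           # e.g. "improving vs stable"
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DiagnosticsResult:
    """Generalized VIFs from category-vs-rest binomial GLMs."""

    vif: pd.DataFrame        # predictors x binary models
    max_vif: float


@dataclass
class SelectionResult:
    """Outcome of forward AIC/LRT selection."""

    spec: ModelSpec
    fit: "ModelFit"
    history: list[dict]


# ---------------------------------------------------------------------------
# intervention codings
# ---------------------------------------------------------------------------

def intervention_coding(group: str) -> dict[str, str]:
    """The four codings of one therapy-exposure label."""
    if group not in {"physical", "cognitive", "combined", "control"}:
        raise ValueError(f"unknown group label {group!r}")
    physical = "yes" if group in ("physical", "combined") else "no"
    cognitive = "yes" if group in ("cognitive", "combined") else "no"
    return {
        "group4": group,
        "any_physical": physical,
        "any_cognitive": cognitive,
        "any_intervention": "no" if group == "control" else "yes",
    }


def add_intervention_codings(df: pd.DataFrame, column: str = "exposure") -> pd.DataFrame:
    """Append the four coding columns derived from a group-label column."""
    coded = pd.DataFrame(
        [intervention_coding(g) for g in df[column]], index=df.index
    )
    return pd.concat([df, coded], axis=1)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design_matrix(
    data: pd.DataFrame, predictors: tuple[str, ...]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix with intercept; categoricals dummy-coded
    (first sorted level dropped). Returns the matrix and the mapping from
    predictor name to its design columns."""
    cols: dict[str, list[str]] = {}
    parts = [pd.Series(1.0, index=data.index, name="const")]
    for p in predictors:
        s = data[p]
        if s.dtype.kind in "ifub" and s.dtype.kind != "b":
            parts.append(s.astype(float).rename(p))
            cols[p] = [p]
        else:
            dummies = pd.get_dummies(
                pd.Categorical(s.astype(str)), prefix=p, drop_first=True
            ).astype(float)
            dummies.index = data.index
            parts.append(dummies)
            cols[p] = list(dummies.columns)
    x = pd.concat(parts, axis=1)
    return x, cols


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_multinomial(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood softmax regression of the change category.

    Rows with a missing outcome or any missing predictor are dropped
    listwise. The reference category is ``spec.reference`` ("stable" by
    default). Non-convergence or quasi-separation is flagged rather than
    raised, matching how sparse 84-record designs behave in practice.
    """
    use = data.dropna(subset=[spec.outcome, *spec.predictors])
    observed = [c for c in CATEGORIES if (use[spec.outcome] == c).any()]
    if len(observed) < 2:
        raise ValueError("outcome must have >= 2 observed categories")
    order = [spec.reference] + [c for c in observed if c != spec.reference]
    if spec.reference not in observed:
        raise ValueError(f"reference category {spec.reference!r} not observed")
    y = pd.Categorical(use[spec.outcome], categories=order).codes
    x, term_columns = _design_matrix(use, spec.predictors)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")

    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MNLogit(y, x.to_numpy())
        result = model.fit(method="newton", maxiter=500, tol=1e-8, disp=0)
    for w in caught:
        if "converge" in str(w.message).lower() or "separation" in str(w.message).lower():
            flags.append(str(w.message))
    converged = bool(result.mle_retvals.get("converged", True))
    if not converged:
        flags.append("optimizer did not converge")

    cat_names = order[1:]
    params = pd.DataFrame(result.params, index=x.columns, columns=cat_names)
    bse = pd.DataFrame(result.bse, index=x.columns, columns=cat_names)
    zvals = params / bse
    pvals = pd.DataFrame(
        2 * stats.norm.sf(np.abs(zvals.to_numpy())), index=x.columns, columns=cat_names
    )
    n_params = int(params.size)
    llf = float(result.llf)
    aic = -2.0 * llf + 2.0 * n_params

    # statsmodels flattens (category, column) in column-major category blocks
    idx = pd.MultiIndex.from_product([cat_names, x.columns], names=["category", "term"])
    cov = pd.DataFrame(np.asarray(result.cov_params()), index=idx, columns=idx)

    return ModelFit(
        spec=spec, params=params, bse=bse, zvalues=zvals, pvalues=pvals,
        llf=llf, aic=aic, n_params=n_params, n_obs=int(use.shape[0]),
        cov=cov, categories=tuple(order), term_columns=term_columns,
        converged=converged, flags=flags,
    )


def wald_odds_ratio(beta: float, se: float, z_crit: float = 1.96) -> tuple[float, float, float]:
    """(OR, CI low, CI high) = exp(beta), exp(beta -+ z_crit * se)."""
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z_crit * se)),
        float(np.exp(beta + z_crit * se)),
    )


def pairwise_contrasts(fit: ModelFit) -> list[ContrastEstimate]:
    """All pairwise category contrasts for every non-intercept design column.

    Contrasts against the reference read the coefficients directly; the
    contrast between the two non-reference categories uses the coefficient
    difference with a delta-method standard error from the coefficient
    covariance.
    """
    if len(fit.categories) != 3:
        raise ValueError("pairwise contrasts require a 3-category fit")
    ref = fit.categories[0]
    c1, c2 = fit.categories[1], fit.categories[2]
    out: list[ContrastEstimate] = []
    for term in fit.params.index:
        if term == "const":
            continue
        for cat in (c1, c2):
            b = float(fit.params.loc[term, cat])
            se = float(fit.bse.loc[term, cat])
            out.append(_contrast(term, f"{cat} vs {ref}", b, se))
        b_diff = float(fit.params.loc[term, c2] - fit.params.loc[term, c1])
        var = (
            fit.cov.loc[(c2, term), (c2, term)]
            + fit.cov.loc[(c1, term), (c1, term)]
            - 2.0 * fit.cov.loc[(c2, term), (c1, term)]
        )
        out.append(_contrast(term, f"{c2} vs {c1}", b_diff, float(np.sqrt(var))))
    return out


def _contrast(term: str, label: str, beta: float, se: float) -> ContrastEstimate:
    z = beta / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    or_, lo, hi = wald_odds_ratio(beta, se)
    return ContrastEstimate(
        predictor=term, contrast=label, beta=beta, se=se, z=float(z), p=p,
        odds_ratio=or_, ci_low=lo, ci_high=hi,
    )


def lrt(nested: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller model."""
    if nested.n_obs != full.n_obs:
        raise ValueError("models must be fitted on the same rows")
    if not set(nested.spec.predictors) <= set(full.spec.predictors):
        raise ValueError("models are not nested")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("models are not nested")
    statistic = max(0.0, 2.0 * (full.llf - nested.llf))
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


def forward_aic_select(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    alpha: float = 0.05,
    min_delta_aic: float = 2.0,
    reference: str = "stable",
) -> SelectionResult:
    """Bottom-up model selection under a joint LRT + AIC criterion.

    Starting from the intercept-only model, each step fits every remaining
    candidate added to the current model, keeps those whose likelihood-
    ratio test is significant at ``alpha`` AND whose AIC drops by at least
    ``min_delta_aic``, and enters the one with the greatest AIC reduction
    (ties broken by candidate list order). At most one of the four
    mutually exclusive intervention codings may enter. Rows missing any
    candidate are dropped once up front so every compared model sees the
    same records.
    """
    use = data.dropna(subset=[outcome, *candidates])
    selected: list[str] = []
    current = fit_multinomial(use, ModelSpec(outcome, (), reference))
    history: list[dict] = []
    remaining = list(candidates)
    while remaining:
        best: tuple[float, int, str, ModelFit] | None = None
        for pos, cand in enumerate(remaining):
            spec = ModelSpec(outcome, tuple(selected + [cand]), reference)
            try:
                trial = fit_multinomial(use, spec)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not trial.converged:
                continue
            _, _, p = lrt(current, trial)
            delta = current.aic - trial.aic
            if p < alpha and delta >= min_delta_aic:
                key = (-delta, pos)
                if best is None or key < (-best[0], best[1]):
                    best = (delta, pos, cand, trial)
        if best is None:
            break
        delta, _, cand, trial = best
        selected.append(cand)
        history.append({"added": cand, "delta_aic": delta, "aic": trial.aic})
        current = trial
        remaining.remove(cand)
        if cand in INTERVENTION_CODINGS:
            remaining = [c for c in remaining if c not in INTERVENTION_CODINGS]
    return SelectionResult(spec=current.spec, fit=current, history=history)


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------

def vif_binomial(data: pd.DataFrame, spec: ModelSpec) -> DiagnosticsResult:
    """Generalized VIFs via category-vs-rest binomial GLMs.

    VIF is undefined for a multinomial fit, so each outcome category is
    dichotomised against the rest, a binomial GLM with the model's
    predictors is fitted, and the generalized VIF of each predictor is
    computed from the correlation matrix of the coefficient estimates
    (determinant ratio), which reduces to the classical 1/(1-R^2) for
    single-column predictors.
    """
    if len(spec.predictors) < 2:
        raise ValueError("VIF needs >= 2 predictors")
    use = data.dropna(subset=[spec.outcome, *spec.predictors])
    x, term_columns = _design_matrix(use, spec.predictors)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        # identify aliased predictors by incremental rank
        aliased = []
        seen = x[["const"]].to_numpy()
        for p, cols in term_columns.items():
            cand = np.hstack([seen, x[cols].to_numpy()])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                aliased.append(p)
            else:
                seen = cand
        raise ValueError(f"aliased predictors: {aliased}")

    results = {}
    for cat in CATEGORIES:
        y = (use[spec.outcome] == cat).astype(float)
        if y.nunique() < 2:
            continue
        glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        cov = np.asarray(glm.cov_params())
        keep = [i for i, c in enumerate(x.columns) if c != "const"]
        sub = cov[np.ix_(keep, keep)]
        d = np.sqrt(np.diag(sub))
        corr = sub / np.outer(d, d)
        names = [x.columns[i] for i in keep]
        det_all = np.linalg.det(corr)
        vifs = {}
        for p, cols in term_columns.items():
            ii = [names.index(c) for c in cols]
            jj = [k for k in range(len(names)) if k not in ii]
            det_i = np.linalg.det(corr[np.ix_(ii, ii)])
            det_j = np.linalg.det(corr[np.ix_(jj, jj)]) if jj else 1.0
            gvif = det_i * det_j / det_all
            vifs[p] = float(gvif ** (1.0 / len(cols)) if len(cols) > 1 else gvif)
        results[f"{cat}_vs_rest"] = vifs
    vif_df = pd.DataFrame(results)
    return DiagnosticsResult(vif=vif_df, max_vif=float(vif_df.to_numpy().max()))
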