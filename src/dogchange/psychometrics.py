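"""Measurement-model derivation and reliability statistics.

This module derives the measurement model behind the behavioural test
battery: correlation matrices (Pearson for metric items, polychoric for
ordinal ones), principal component analysis with Horn's parallel analysis
for component retention and direct-quartimin (Oblimin, gamma = 0) rotation,
sampling-adequacy diagnostics (KMO, Bartlett sphericity, Cronbach's alpha),
and intraclass correlations for inter-observer and test–retest reliability.

The polychoric estimator is the classic two-step maximum-likelihood
procedure: thresholds are fixed at normal quantiles of the marginal
proportions, then the latent correlation maximises the bivariate-normal
cell likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "CorrelationMatrix",
    "LoadingTable",
    "ReliabilityResult",
    "polychoric_correlation",
    "correlation_matrix",
    "parallel_analysis",
    "oblimin_rotation",
    "pca_components",
    "kmo",
    "bartlett_sphericity",
    "cronbach_alpha",
    "icc_two_way",
    "reliability_gate",
]

_RHO_BOUND = 0.999
_TAU_CLIP = 8.0  # standard-normal quantile beyond which the CDF is numerically 0/1


@dataclass(frozen=True)
class CorrelationMatrix:
    """A square symmetric correlation matrix with its estimation kind."""

    values: pd.DataFrame
    kind: str  # "pearson" or "polychoric"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LoadingTable:
    """Rotated component loadings with the |loading| > 0.5 inclusion mask."""

    loadings: pd.DataFrame          # variables x components
    mask: pd.DataFrame              # same shape, True iff |loading| > 0.5
    n_retained: int
    alpha: pd.Series                # standardized Cronbach's alpha per component
    kmo: float
    bartlett_statistic: float
    bartlett_p: float
    flags: list[str] = field(default_factory=list)

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    def items_for(self, component: str, signed: bool = True) -> pd.Series:
        """Masked loadings of one component (items that load |.| > 0.5)."""
        col = self.loadings[component]
        return col[self.mask[component]]


@dataclass(frozen=True)
class ReliabilityResult:
    """An intraclass correlation with its model label and design size."""

    icc: float
    model: str
    n_subjects: int
    n_raters: int


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

def _thresholds(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Normal quantiles of the cumulative marginal proportions (step one)."""
    counts = np.bincount(codes, minlength=n_levels)
    cum = np.cumsum(counts)[:-1] / codes.size
    return np.clip(stats.norm.ppf(cum), -_TAU_CLIP, _TAU_CLIP)


def _cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a standard bivariate normal on a threshold grid."""
    gx = np.concatenate(([-_TAU_CLIP], tau_x, [_TAU_CLIP]))
    gy = np.concatenate(([-_TAU_CLIP], tau_y, [_TAU_CLIP]))
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    cdf = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf(pts)
    cdf = cdf.reshape(gx.size, gy.size)
    return cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]


def polychoric_correlation(x, y) -> float:
    """Two-step ML estimate of the latent correlation of two ordinal variables.

    Thresholds are fixed at the normal quantiles of each margin; rho then
    maximises the multinomial likelihood of the observed contingency table
    under a standard bivariate normal. Estimates that run into the +-1
    boundary (e.g. tables with empty discordant cells) are clipped to
    +-0.999 and flagged with a RuntimeWarning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(pd.isna(x) | pd.isna(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no complete observations")
    cx, levels_x = pd.factorize(x, sort=True)
    cy, levels_y = pd.factorize(y, sort=True)
    if len(levels_x) < 2 or len(levels_y) < 2:
        raise ValueError("polychoric correlation needs >= 2 observed levels per variable")

    table = np.zeros((len(levels_x), len(levels_y)))
    np.add.at(table, (cx, cy), 1.0)
    tau_x = _thresholds(cx, len(levels_x))
    tau_y = _thresholds(cy, len(levels_y))

    def nll(rho: float) -> float:
        p = np.clip(_cell_probabilities(tau_x, tau_y, rho), 1e-12, None)
        return -float(np.sum(table * np.log(p)))

    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_BOUND - 1e-3:
        rho = float(np.sign(rho)) * _RHO_BOUND
        warnings.warn(
            "polychoric estimate at the +-1 boundary; clipped to +-0.999",
            RuntimeWarning,
            stacklevel=2,
        )
    return rho


def correlation_matrix(items: pd.DataFrame, kind: str = "pearson") -> CorrelationMatrix:
    """Correlation matrix of an item block; polychoric pairs or plain Pearson."""
    if kind == "pearson":
        r = items.astype(float).corr(method="pearson")
        return CorrelationMatrix(r, "pearson")
    if kind != "polychoric":
        raise ValueError(f"unknown correlation kind {kind!r}")
    cols = list(items.columns)
    r = np.eye(len(cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r[i, j] = r[j, i] = polychoric_correlation(
                    items.iloc[:, i], items.iloc[:, j]
                )
    return CorrelationMatrix(pd.DataFrame(r, index=cols, columns=cols), "polychoric")


# ---------------------------------------------------------------------------
# PCA, parallel analysis, Oblimin rotation
# ---------------------------------------------------------------------------

def parallel_analysis(
    observed_eigenvalues: np.ndarray,
    n_obs: int,
    n_vars: int,
    n_draws: int = 1000,
    quantile: float = 95.0,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Horn's parallel analysis: retain components whose eigenvalues exceed
    the given percentile of eigenvalues from random normal data of the same
    shape. Returns (n_retained, per-rank thresholds)."""
    rng = np.random.default_rng(rng)
    sims = np.empty((n_draws, n_vars))
    for d in range(n_draws):
        z = rng.standard_normal((n_obs, n_vars))
        ev = np.linalg.eigvalsh(np.corrcoef(z, rowvar=False))[::-1]
        sims[d] = ev
    thresholds = np.percentile(sims, quantile, axis=0)
    obs = np.sort(np.asarray(observed_eigenvalues))[::-1]
    above = obs > thresholds
    # retention stops at the first eigenvalue that fails the criterion
    n_retained = int(np.argmin(above)) if not above.all() else n_vars
    return n_retained, thresholds


def _quartimin(loadings: np.ndarray) -> tuple[float, np.ndarray]:
    """Direct quartimin criterion (Oblimin with gamma = 0) and its gradient."""
    l2 = loadings**2
    k = loadings.shape[1]
    n = np.ones((k, k)) - np.eye(k)
    inner = l2 @ n
    return float(np.sum(l2 * inner)) / 4.0, loadings * inner


def oblimin_rotation(
    loadings: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation minimising the quartimin criterion.

    Returns the rotated pattern matrix and the factor correlation matrix Phi.
    With a single column the input is returned unchanged.
    """
    a = np.asarray(loadings, dtype=float)
    if a.shape[1] < 2:
        return a, np.ones((1, 1))
    t = np.eye(a.shape[1])
    ti = np.linalg.inv(t)
    lam = a @ ti.T
    f, gq = _quartimin(lam)
    g = -(lam.T @ gq @ ti).T
    al = 1.0
    for _ in range(max_iter):
        gp = g - t * np.sum(t * g, axis=0)
        s = np.sqrt(np.sum(gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            x = t - al * gp
            x = x / np.sqrt(np.sum(x**2, axis=0))
            ti = np.linalg.inv(x)
            lam = a @ ti.T
            fn, gq = _quartimin(lam)
            if fn < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        t = x
        f = fn
        g = -(lam.T @ gq @ np.linalg.inv(t)).T
    phi = t.T @ t
    return lam, phi


def _standardized_alpha(r_sub: np.ndarray) -> float:
    """Cronbach's alpha from a correlation submatrix (standardized items)."""
    k = r_sub.shape[0]
    if k < 2:
        return float("nan")
    off = r_sub[~np.eye(k, dtype=bool)]
    rbar = float(off.mean())
    return k * rbar / (1.0 + (k - 1) * rbar)


def pca_components(
    corr: CorrelationMatrix,
    n_obs: int,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
    loading_cutoff: float = 0.5,
) -> LoadingTable:
    """PCA on a correlation matrix with parallel-analysis retention.

    Components are retained while their eigenvalues exceed the 95th
    percentile of eigenvalues from random data of the same shape; when two
    or more are retained the loadings are Oblimin-rotated. The inclusion
    mask marks |loading| > 0.5. Indefinite matrices (possible for
    polychoric estimates) are repaired by clipping negative eigenvalues at
    zero and re-standardising, with a flag.
    """
    names = corr.variables
    r = corr.values.to_numpy(dtype=float)
    p = r.shape[0]
    if n_obs <= p:
        raise ValueError("n_obs must exceed the number of variables")
    flags: list[str] = []

    eigval, eigvec = linalg.eigh(r)
    if eigval[0] < -1e-10:
        flags.append("indefinite matrix repaired by eigenvalue clipping")
        eigval_c = np.clip(eigval, 0.0, None)
        r = eigvec @ np.diag(eigval_c) @ eigvec.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        eigval, eigvec = linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    n_retained, _ = parallel_analysis(eigval, n_obs, p, n_draws=n_draws, rng=rng)

    kmo_value = kmo(CorrelationMatrix(pd.DataFrame(r, index=names, columns=names), corr.kind))
    bart_stat, bart_p = bartlett_sphericity(corr, n_obs)

    if n_retained == 0:
        flags.append("no component retained by parallel analysis")
        empty = pd.DataFrame(index=names, columns=[], dtype=float)
        return LoadingTable(
            loadings=empty, mask=empty.astype(bool), n_retained=0,
            alpha=pd.Series(dtype=float), kmo=kmo_value,
            bartlett_statistic=bart_stat, bartlett_p=bart_p, flags=flags,
        )

    lam = eigvec[:, :n_retained] * np.sqrt(eigval[:n_retained])
    if n_retained >= 2:
        lam, _ = oblimin_rotation(lam)
        # deterministic order and sign: columns by explained SS, dominant loading positive
        order = np.argsort(-np.sum(lam**2, axis=0))
        lam = lam[:, order]
    signs = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(lam.shape[1])])
    signs[signs == 0] = 1.0
    lam = lam * signs

    comp_names = [f"pc{i + 1}" for i in range(lam.shape[1])]
    loadings = pd.DataFrame(lam, index=names, columns=comp_names)
    mask = loadings.abs() > loading_cutoff
    alpha = pd.Series(
        {
            c: _standardized_alpha(r[np.ix_(mask[c].to_numpy(), mask[c].to_numpy())])
            for c in comp_names
        },
        dtype=float,
    )
    return LoadingTable(
        loadings=loadings, mask=mask, n_retained=int(lam.shape[1]), alpha=alpha,
        kmo=kmo_value, bartlett_statistic=bart_stat, bartlett_p=bart_p, flags=flags,
    )


# ---------------------------------------------------------------------------
# adequacy and reliability statistics
# ---------------------------------------------------------------------------

def kmo(corr: CorrelationMatrix) -> float:
    """Overall Kaiser–Meyer–Olkin sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations obtained from the inverse of R.
    """
    r = corr.values.to_numpy(dtype=float)
    try:
        inv = linalg.inv(r)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular correlation matrix") from exc
    if not np.all(np.isfinite(inv)):
        raise ValueError("singular correlation matrix")
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    q = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(q[off] ** 2)
    if r2 + q2 == 0:  # exactly uncorrelated variables: adequacy undefined
        return float("nan")
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr: CorrelationMatrix, n_obs: int) -> tuple[float, float]:
    """Bartlett's test of sphericity against the identity correlation matrix.

    chi^2 = -(n - 1 - (2p + 5)/6) * ln det(R) on p(p-1)/2 degrees of freedom.
    """
    r = corr.values.to_numpy(dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    statistic = -(n_obs - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(stats.chi2.sf(statistic, df))
    return float(statistic), pval


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x items matrix with >= 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def icc_two_way(
    ratings,
    agreement: bool = False,
) -> ReliabilityResult:
    """Intraclass correlation from a two-way mixed model, single rater.

    The default is the consistency form ICC(3,1) =
    (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error); with
    ``agreement=True`` the absolute-agreement form, which additionally
    charges the rater (occasion) variance, is returned. Rows with any
    missing rating are dropped.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 2 columns")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 complete subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    if agreement:
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )
        label = "two-way mixed, single rater, absolute agreement"
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        label = "two-way mixed, single rater, consistency"
    return ReliabilityResult(icc=float(icc), model=label, n_subjects=n, n_raters=k)


def reliability_gate(
    results: dict[str, ReliabilityResult | float],
    cutoff: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split components into retained (ICC >= cutoff) and excluded (< cutoff)."""
    retained: list[str] = []
    excluded: list[str] = []
    for name, res in results.items():
        icc = res.icc if isinstance(res, ReliabilityResult) else float(res)
        (retained if icc >= cutoff else excluded).append(name)
    if not retained:
        warnings.warn("all components fall below the reliability cutoff", stacklevel=2)
    return retained, excluded
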