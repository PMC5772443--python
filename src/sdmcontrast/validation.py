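"""Statistical layer: null-model significance, GLM, Spearman, quantile
regression, and the environmental collinearity screen.

The null-model test asks whether a fitted presence-background model beats
models fitted to random pseudo-presences. Because collections are spatially
biased, the null draws its pseudo-presences from the survey-effort (bias)
layer rather than the whole grid — a bias-corrected null: a model must beat
random *collecting*, not random geography. The observed training AUC is ranked
among itself plus 99 null AUCs; rank >= 95 of 100 (upper one-sided 95% level)
counts as significantly better than random, with ties ranked conservatively
low.

The comparison statistics mirror the contrast between the two mapping
approaches: a binomial GLM of per-cell collection probability on interpolated
relative abundance, a Spearman rank correlation between suitability and plot
relative abundance (each plot one observation, even when plots share a cell),
and a linear 90th-percentile quantile regression of plot abundance on
suitability whose slope CI and p-value come from a nonparametric pairs
bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .maxent import MaxentLQ, training_auc

__all__ = [
    "NullModelResult",
    "null_model_test",
    "GlmResult",
    "glm_collection_vs_abundance",
    "spearman_suit_vs_abundance",
    "QuantRegResult",
    "quantile_reg_90",
    "CollinearityScreen",
    "collinearity_screen",
]


@dataclass
class NullModelResult:
    observed_auc: float
    null_aucs: np.ndarray
    rank: int  # position of the observed AUC among all n_null+1, ascending
    significant: bool
    n: int  # geographically unique presences used


def null_model_test(presence_idx, features, bias, background_idx,
                    n_null: int = 99, reg_multiplier: float = 1.0,
                    seed=None, whole_grid: bool = False,
                    tol: float = 1e-7, max_iter: int = 500,
                    min_presences: int = 5) -> NullModelResult:
    """Bias-corrected null-model significance test for one species.

    Parameters
    ----------
    presence_idx : flat indices (into ``features`` rows) of the unique
        presence cells of the observed model.
    features : (n_cells, d) scaled feature matrix over all candidate cells.
    bias : flat 0/1 survey-effort values aligned with ``features``; null
        pseudo-presences are drawn from its positive cells without
        replacement (or from all cells when ``whole_grid``).
    background_idx : flat indices of the background sample; identical for the
        observed model and every null replicate.

    The observed rank uses the lowest position among ties, so equalling a
    null AUC never helps significance. Significant iff rank >= n_null - 3
    out of n_null + 1 (95 of 100 at the default).
    """
    rng = np.random.default_rng(seed)
    features = np.asarray(features, dtype=float)
    presence_idx = np.asarray(presence_idx, dtype=int)
    n = presence_idx.size
    pool = (np.arange(features.shape[0]) if whole_grid
            else np.flatnonzero(np.asarray(bias) > 0))
    if n > pool.size:
        raise ValueError(
            f"{n} presences exceed the {pool.size} candidate null cells"
        )

    bg = features[np.asarray(background_idx, dtype=int)]

    def fit_auc(pres_rows: np.ndarray) -> float:
        X = np.vstack([bg, pres_rows])
        y = np.concatenate([np.zeros(len(bg)), np.ones(len(pres_rows))])
        model = MaxentLQ(reg_multiplier=reg_multiplier, tol=tol,
                         max_iter=max_iter, min_presences=min_presences)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        scores_pres = model.decision_function(pres_rows)
        scores_bg = model.decision_function(bg)
        return training_auc(scores_pres, scores_bg)

    observed = fit_auc(features[presence_idx])
    nulls = np.empty(n_null)
    for i in range(n_null):
        draw = rng.choice(pool, size=n, replace=False)
        nulls[i] = fit_auc(features[draw])

    rank = 1 + int((nulls < observed).sum())  # lowest position among ties
    crit = (n_null + 1) - int(round(0.05 * (n_null + 1)))
    return NullModelResult(
        observed_auc=float(observed),
        null_aucs=nulls,
        rank=rank,
        significant=rank >= crit,
        n=n,
    )


@dataclass
class GlmResult:
    slope: float
    p_value: float
    intercept: float
    flag: str = ""  # "separation" or "degenerate" when the fit is unstable

    @property
    def significant_positive(self) -> bool:
        return self.slope > 0 and self.p_value < 0.05 and not self.flag


def glm_collection_vs_abundance(collected, ra) -> GlmResult:
    """Binomial GLM (logit) of the collection indicator on interpolated RA.

    ``collected`` is the per-cell 0/1 indicator of holding at least one
    cleaned collection; ``ra`` the interpolated relative abundance at the
    same cells. Reports the ML slope and its two-sided Wald p-value.
    """
    y = np.asarray(collected, dtype=float)
    x = np.asarray(ra, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValueError("need matched collected/ra vectors of length >= 2")
    if not (0 < y.sum() < y.size):
        raise ValueError("need at least one collected and one uncollected cell")
    if np.ptp(x) == 0:
        return GlmResult(slope=0.0, p_value=1.0, intercept=float("nan"),
                         flag="degenerate")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception:
            return GlmResult(slope=float("inf"), p_value=0.0,
                             intercept=float("nan"), flag="separation")
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    flag = ""
    if not np.isfinite(res.bse[1]) or res.bse[1] > 1e6:
        flag = "separation"
        p = 0.0 if abs(slope) > 0 else 1.0
    return GlmResult(slope=slope, p_value=p,
                     intercept=float(res.params[0]), flag=flag)


def spearman_suit_vs_abundance(suitability, ra):
    """Midrank Spearman rho (with large-sample p) between suitability and RA.

    Returns (rho, p); rho is NaN when either vector is constant.
    """
    x = np.asarray(suitability, dtype=float)
    y = np.asarray(ra, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _quantreg_line(x: np.ndarray, y: np.ndarray,
                   tau: float = 0.9) -> tuple[float, float]:
    """Exact (intercept, slope) minimizing the check loss, by linear program.

    min sum tau*u_i + (1-tau)*v_i  s.t.  y_i = a + b x_i + u_i - v_i,
    u, v >= 0, a and b free. Solved with HiGHS, so the reported optimum is a
    vertex of the LP — a line through two sample points — to solver precision.
    """
    from scipy.optimize import linprog

    n = x.size
    # variables: a, b (free), u (n), v (n)
    c = np.concatenate([[0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.zeros((n, 2 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = x
    A_eq[np.arange(n), 2 + np.arange(n)] = 1.0
    A_eq[np.arange(n), 2 + n + np.arange(n)] = -1.0
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    return float(res.x[0]), float(res.x[1])


@dataclass
class QuantRegResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    tau: float = 0.9
    boot_slopes: np.ndarray = field(default=None, repr=False)  # type: ignore


def quantile_reg_90(x, y, tau: float = 0.9, n_boot: int = 200,
                    seed=None) -> QuantRegResult:
    """Linear tau-quantile regression of y on x with pairs-bootstrap CI.

    Minimizes the check loss sum rho_tau(y - a - b x); the slope's percentile
    CI and a sign-based p-value (two-sided doubling of the bootstrap fraction
    of slopes at or below zero) come from resampling (x, y) pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")

    def fit(xs, ys):
        return _quantreg_line(xs, ys, tau)

    intercept, slope = fit(x, y)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = x.size
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(x[idx]) == 0:  # degenerate resample: redraw
            idx = rng.integers(0, n, size=n)
        boot[b] = fit(x[idx], y[idx])[1]
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    frac_le = float((boot <= 0).mean())
    p = min(1.0, 2.0 * min(frac_le, 1.0 - frac_le + (boot == 0).mean()))
    return QuantRegResult(slope=slope, intercept=intercept,
                          ci_low=float(ci_low), ci_high=float(ci_high),
                          p_value=p, tau=tau, boot_slopes=boot)


@dataclass
class CollinearityScreen:
    spearman: pd.DataFrame  # pairwise rho, layers x layers
    retained: list
    dropped: list
    loadings: pd.DataFrame  # PCA loadings, layers x components
    threshold: float


def collinearity_screen(env_values, names=None,
                        threshold: float = 0.7) -> CollinearityScreen:
    """Greedy |rho| > threshold elimination plus a PCA loadings report.

    ``env_values`` is (n_cells, n_layers) over valid cells. Repeatedly drops
    the variable with the most over-threshold partners (ties broken by larger
    mean |rho|) until every retained pair has |rho| < threshold. The PCA
    loadings of *all* variables are reported to inform the (manual) choice of
    biologically relevant variables; the screen itself never uses them.
    """
    X = np.asarray(env_values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two layers")
    names = list(names) if names is not None else [
        f"env{j}" for j in range(X.shape[1])
    ]
    r = stats.spearmanr(X).statistic
    if np.ndim(r) == 0:  # scipy collapses the 2-layer case to a scalar
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
    rho = pd.DataFrame(r, index=names, columns=names)
    retained = list(names)
    dropped: list = []
    while True:
        sub = rho.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        partners = (sub > threshold).sum(axis=1)
        if partners.max() == 0:
            break
        worst = partners.max()
        cands = partners[partners == worst].index
        victim = sub.loc[cands].mean(axis=1).idxmax()
        retained.remove(victim)
        dropped.append(victim)

    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA(n_components=min(X.shape[1], X.shape[0]))
    pca.fit(Xs)
    loadings = pd.DataFrame(
        pca.components_.T * np.sqrt(pca.explained_variance_),
        index=names,
        columns=[f"PC{i+1}" for i in range(pca.n_components_)],
    )
    return CollinearityScreen(spearman=rho, retained=retained,
                              dropped=dropped, loadings=loadings,
                              threshold=threshold)
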