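"""Minimal presence-background maximum-entropy SDM with linear+quadratic features.

The model is the Gibbs distribution q(x) = exp(lambda . f(x)) / Z over a set of
background cells B, fitted by maximizing the L1-regularized log-likelihood of
the presence cells

    (1/m) sum_presences lambda . f(x)  -  log Z  -  sum_j beta_j |lambda_j|

with beta_j = reg_multiplier * s_j / sqrt(m), where s_j is the feature's
standard deviation over the presences. The feature class is deliberately
restricted to linear and quadratic terms of the climate variables, min-max
scaled over the background. The objective is concave; the optimizer works on
the smooth split lambda = u - v with u, v >= 0 so plain box-constrained
L-BFGS-B applies, and its objective trace is recorded.

Suitability is reported through the logistic transform
l(x) = e^H q~(x) / (1 + e^H q~(x)) with H the entropy of q over B, which puts
a "typical" presence near 0.5 at default prevalence; it is a strictly monotone
transform of q, so rank statistics (AUC, Spearman) are identical between raw
and logistic output.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LinearQuadraticFeatures",
    "MaxentLQ",
    "sample_background",
    "training_auc",
    "threshold_10pct",
]


class LinearQuadraticFeatures(BaseEstimator, TransformerMixin):
    """Expand climate variables into [v, v^2] features, min-max scaled.

    Scaling parameters are learned on the background sample (``fit``) and the
    identical affine map is applied to presences (``transform``), so presences
    may fall slightly outside [0, 1]. Variables constant on the background
    carry no information and are dropped with a warning.
    """

    def __init__(self, feature_names=None):
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x variables)")
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"var{j}" for j in range(X.shape[1])]
        )
        raw = np.concatenate([X, X**2], axis=1)
        raw_names = [n for n in names] + [f"{n}^2" for n in names]
        lo = raw.min(axis=0)
        hi = raw.max(axis=0)
        keep = hi > lo
        if not np.all(keep):
            dropped = [raw_names[j] for j in np.flatnonzero(~keep)]
            warnings.warn(f"dropping constant features: {dropped}")
        self.keep_ = keep
        self.min_ = lo[keep]
        self.scale_ = hi[keep] - lo[keep]
        self.feature_names_ = [raw_names[j] for j in np.flatnonzero(keep)]
        self.n_features_out_ = int(keep.sum())
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        raw = np.concatenate([X, X**2], axis=1)
        return (raw[:, self.keep_] - self.min_) / self.scale_


class MaxentLQ(BaseEstimator):
    """L1-regularized Gibbs (maximum entropy) presence-background model.

    Follows the sklearn estimator protocol: ``fit(X, y)`` takes the stacked
    feature rows of background and presence cells with ``y = 0`` marking
    background and ``y = 1`` presence. The background rows define the state
    space of the Gibbs distribution.

    Parameters
    ----------
    reg_multiplier : float
        Global multiplier c on the per-feature penalty beta_j = c * s_j/sqrt(m).
        0 disables regularization; -> infinity forces the uniform distribution.
    tol : float
        Convergence tolerance on the change in penalized objective.
    max_iter : int
        L-BFGS-B iteration cap; non-convergence warns and keeps the best iterate.
    min_presences : int
        Species with fewer presence cells are refused (raises ``ValueError``).

    Attributes
    ----------
    lambda_ : (n_features,) fitted feature weights.
    z_ : normalizer Z = sum_B exp(lambda . f).
    entropy_ : entropy H of q over the background.
    objective_trace_ : penalized objective at each optimizer iterate
        (non-decreasing, first entry = value at lambda = 0).
    """

    def __init__(self, reg_multiplier=1.0, tol=1e-7, max_iter=500,
                 min_presences=5):
        self.reg_multiplier = reg_multiplier
        self.tol = tol
        self.max_iter = max_iter
        self.min_presences = min_presences

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n, d) with matching y of 0/1 labels")
        bg = X[y == 0]
        pres = X[y == 1]
        m, d = pres.shape
        if m < self.min_presences:
            raise ValueError(
                f"insufficient presences: {m} < {self.min_presences}"
            )
        if bg.shape[0] < 2:
            raise ValueError("background must contain at least 2 cells")

        pbar = pres.mean(axis=0)  # empirical feature constraints
        s = pres.std(axis=0, ddof=0)
        beta = self.reg_multiplier * s / np.sqrt(m)

        def neg_objective(lam):
            a = bg @ lam
            amax = a.max()
            logz = amax + np.log(np.exp(a - amax).sum())
            return -(pbar @ lam - logz - beta @ np.abs(lam))

        # smooth split lam = u - v, u,v >= 0; |lam| <= u + v with equality
        # at any optimum, so the box-constrained problem is equivalent
        def fun(uv):
            u, v = uv[:d], uv[d:]
            lam = u - v
            a = bg @ lam
            amax = a.max()
            ea = np.exp(a - amax)
            logz = amax + np.log(ea.sum())
            q = ea / ea.sum()
            eq = q @ bg
            f = -(pbar @ lam - logz - beta @ (u + v))
            grad_lam = -(pbar - eq)
            g = np.concatenate([grad_lam + beta, -grad_lam + beta])
            return f, g

        trace = [-neg_objective(np.zeros(d))]

        def cb(uv):
            trace.append(-neg_objective(uv[:d] - uv[d:]))

        res = minimize(
            fun,
            np.zeros(2 * d),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0, None)] * (2 * d),
            callback=cb,
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "gtol": 1e-10},
        )
        if not res.success and "MAXLS" not in str(res.message):
            if res.nit >= self.max_iter:
                warnings.warn(
                    f"maxent did not converge in {self.max_iter} iterations; "
                    "keeping best iterate"
                )
        lam = res.x[:d] - res.x[d:]

        self.n_features_in_ = d
        self.m_ = m
        self.beta_ = beta
        self.lambda_ = lam
        self.background_ = bg
        a = bg @ lam
        amax = a.max()
        ea = np.exp(a - amax)
        self.log_z_ = amax + np.log(ea.sum())
        self.z_ = float(np.exp(self.log_z_))
        q = ea / ea.sum()
        self.q_ = q
        with np.errstate(divide="ignore", invalid="ignore"):
            lq = np.where(q > 0, np.log(q), 0.0)
        self.entropy_ = float(-(q * lq).sum())
        self.objective_trace_ = np.asarray(trace)
        return self

    def decision_function(self, X):
        """Linear score lambda . f(x) (monotone in q)."""
        return np.asarray(X, dtype=float) @ self.lambda_

    def predict_raw(self, X):
        """q~(x) = exp(lambda . f(x)) / Z at arbitrary cells."""
        return np.exp(self.decision_function(X) - self.log_z_)

    def predict_logistic(self, X):
        """Logistic suitability l(x) in (0, 1) at default prevalence 0.5."""
        # e^H q~ can overflow far outside the training range; work in logs
        t = self.entropy_ + self.decision_function(X) - self.log_z_
        out = np.empty_like(t)
        pos = t >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
        out[~pos] = np.exp(t[~pos]) / (1.0 + np.exp(t[~pos]))
        return out


def sample_background(bias_values: np.ndarray, n_bg: int, rng) -> np.ndarray:
    """Indices of background cells drawn from the survey-effort (bias) layer.

    ``bias_values`` is a flat 0/1 array over candidate cells; cells with any
    collection (bias = 1) form the target-group background. Draws ``n_bg``
    cells uniformly without replacement, or all of them if fewer exist.
    """
    rng = np.random.default_rng(rng)
    candidates = np.flatnonzero(np.asarray(bias_values) > 0)
    if candidates.size == 0:
        raise ValueError("bias layer has no positive cells")
    if candidates.size <= n_bg:
        return candidates
    return np.sort(rng.choice(candidates, size=n_bg, replace=False))


def training_auc(pres_scores, bg_scores) -> float:
    """Probability a random presence outranks a random background cell.

    Midrank (Mann-Whitney) formulation: ties count one half. Invariant under
    any strictly monotone transform of the scores.
    """
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    if pres_scores.size == 0 or bg_scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    n1, n0 = pres_scores.size, bg_scores.size
    ranks = rankdata(np.concatenate([pres_scores, bg_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def threshold_10pct(pres_scores, q: float = 0.10) -> float:
    """Ten-percent training-presence threshold.

    The largest score t such that at least 90% of training presences score
    >= t; a cell is then predicted present iff its suitability >= t. With n
    presences sorted ascending this is the value at index floor(q*n) when
    q*n is fractional, and index q*n when exact (so exactly 10% fall below).
    """
    s = np.sort(np.asarray(pres_scores, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("need at least one presence score")
    k = int(np.floor(q * n + 1e-12))
    if k >= n:
        k = n - 1
    return float(s[k])
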