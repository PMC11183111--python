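"""Regression stage with spatial diagnostics.

Per-site diversity responses are modeled with Gaussian identity-link GLMs
(a landform-only model versus a full model with tectonic, geographic and
climate covariates and landform x climate interactions), selected by
stepwise AIC, and summarized by deviance explained and leave-one-out term
importance.  Residual spatial autocorrelation is quantified with Moran's I
on k-nearest-neighbour row-standardized weights, and absorbed with a
maximum-likelihood spatial error model (SEM)

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I),

whose concentrated log-likelihood is profiled over lambda with the
log-determinant evaluated from the eigenvalues of W.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class DegenerateColumnError(ValueError):
    """A numeric column cannot be standardized (max == min)."""


# ----------------------------------------------------------------------
# predictor preparation
# ----------------------------------------------------------------------


def minmax_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Map every column affinely onto [0, 1] via (x - min)/(max - min)."""
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise DegenerateColumnError(f"column {col!r} is constant")
        out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


class CollinearityFilter(BaseEstimator, TransformerMixin):
    """Drop columns until no pair correlates beyond ``threshold``.

    While any pair has |Pearson r| > threshold, the most correlated pair
    is examined and the member with the larger mean absolute correlation
    to all remaining columns is dropped (ties keep the earlier column).
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "CollinearityFilter":
        if X.shape[1] < 2:
            raise ValueError("need at least two columns")
        kept = list(X.columns)
        dropped: list[str] = []
        while len(kept) >= 2:
            corr = X[kept].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] <= self.threshold:
                break
            mean_i = corr[i].sum() / (len(kept) - 1)
            mean_j = corr[j].sum() / (len(kept) - 1)
            # drop the member with larger mean |r|; ties -> later position
            if mean_i > mean_j:
                loser = i
            elif mean_j > mean_i:
                loser = j
            else:
                loser = max(i, j)
            dropped.append(kept.pop(loser))
        self.kept_ = kept
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_]


def filter_collinear(table: pd.DataFrame, threshold: float = 0.95
                     ) -> tuple[pd.DataFrame, list[str]]:
    """(kept columns, dropped column names) under the pairwise |r| filter."""
    f = CollinearityFilter(threshold=threshold).fit(table)
    return table[f.kept_], f.dropped_


# ----------------------------------------------------------------------
# design construction over named term groups
# ----------------------------------------------------------------------

DEFAULT_REFERENCES = {"landform": "Danxia", "tectonic": "craton"}


def _is_interaction(term: str) -> bool:
    return ":" in term


def interaction_parts(term: str) -> tuple[str, str]:
    a, b = term.split(":", 1)
    return a, b


def build_design(
    predictors: pd.DataFrame,
    terms: list[str],
    references: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand term names into a dummy-coded design with intercept.

    Categorical columns (non-numeric dtype) are treatment-coded against
    the reference level in ``references`` (falling back to the first
    sorted level).  An interaction term ``"a:b"`` expands to the products
    of the expanded columns of ``a`` and ``b``.  Returns the design and a
    map from term name to its design columns.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}

    def expand(term: str) -> pd.DataFrame:
        if _is_interaction(term):
            a, b = interaction_parts(term)
            left, right = expand(a), expand(b)
            cols = {}
            for ca in left.columns:
                for cb in right.columns:
                    cols[f"{ca}:{cb}"] = left[ca] * right[cb]
            return pd.DataFrame(cols, index=predictors.index)
        col = predictors[term]
        if pd.api.types.is_numeric_dtype(col):
            return col.astype(float).to_frame(term)
        levels = sorted(col.astype(str).unique())
        ref = references.get(term, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {term!r}")
        dummies = {}
        for lev in levels:
            if lev == ref:
                continue
            dummies[f"{term}[{lev}]"] = (col.astype(str) == lev).astype(float)
        return pd.DataFrame(dummies, index=predictors.index)

    design = pd.DataFrame({"Intercept": np.ones(len(predictors))},
                          index=predictors.index)
    term_map: dict[str, list[str]] = {}
    for term in terms:
        block = expand(term)
        term_map[term] = list(block.columns)
        design = pd.concat([design, block], axis=1)
    return design, term_map


@dataclass
class ModelFit:
    """Gaussian identity-link GLM fit over named term groups."""

    terms: list[str]
    references: dict[str, str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    llf: float
    null_deviance: float
    deviance: float
    residuals: pd.Series
    fitted: pd.Series
    nobs: int
    term_map: dict[str, list[str]] = field(repr=False, default_factory=dict)
    dropped_aliased: list[str] = field(default_factory=list)

    @property
    def deviance_explained(self) -> float:
        """100 * (1 - residual deviance / null deviance), i.e. R^2 in %."""
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)


def fit_glm(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    terms: list[str],
    references: dict[str, str] | None = None,
) -> ModelFit:
    """Least-squares Gaussian GLM of ``response`` on the expanded terms.

    Aliased (rank-deficient) design columns are dropped with a warning.
    """
    y = pd.Series(np.asarray(response, dtype=float), index=predictors.index)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    design, term_map = build_design(predictors, terms, references)
    if len(y) <= design.shape[1]:
        raise ValueError("need more observations than design columns")
    dropped = _drop_aliased(design)
    if dropped:
        logger.warning("dropping aliased design columns: %s", dropped)
        design = design.drop(columns=dropped)
        term_map = {t: [c for c in cols if c not in dropped]
                    for t, cols in term_map.items()}
    model = sm.GLM(y, design, family=sm.families.Gaussian())
    res = model.fit()
    return ModelFit(
        terms=list(terms),
        references={**DEFAULT_REFERENCES, **(references or {})},
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        aic=float(res.aic),
        llf=float(res.llf),
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        residuals=pd.Series(res.resid_response, index=design.index),
        fitted=pd.Series(res.fittedvalues, index=design.index),
        nobs=int(res.nobs),
        term_map=term_map,
        dropped_aliased=dropped,
    )


def _drop_aliased(design: pd.DataFrame) -> list[str]:
    X = design.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    dropped = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            dropped.append(design.columns[j])
    return dropped


def standardized_coefficients(fit: ModelFit, response: pd.Series,
                              predictors: pd.DataFrame) -> pd.Series:
    """beta * sd(x)/sd(y) for each design column (dummies included)."""
    design, _ = build_design(predictors, fit.terms, fit.references)
    design = design[fit.params.index]
    sy = float(np.std(np.asarray(response, dtype=float), ddof=1))
    out = {}
    for col in fit.params.index:
        if col == "Intercept":
            continue
        sx = float(design[col].std(ddof=1))
        out[col] = fit.params[col] * sx / sy
    return pd.Series(out)


# ----------------------------------------------------------------------
# stepwise selection and leave-one-out importance
# ----------------------------------------------------------------------


def _valid_drop(term: str, current: list[str]) -> bool:
    if _is_interaction(term):
        return True
    return not any(_is_interaction(t) and term in interaction_parts(t)
                   for t in current)


def _valid_add(term: str, current: list[str]) -> bool:
    if not _is_interaction(term):
        return True
    a, b = interaction_parts(term)
    return a in current and b in current


def step_aic(
    response,
    predictors: pd.DataFrame,
    initial_terms: list[str],
    scope: list[str] | None = None,
    references: dict[str, str] | None = None,
) -> ModelFit:
    """Backward-forward stepwise AIC over term groups.

    Moves respect marginality: a main effect is never dropped while one
    of its interactions remains, and an interaction is only added once
    both main effects are present.  Deterministic: the move with the
    lowest AIC is taken, ties resolved by scope order, until no move
    improves the current AIC.
    """
    scope = list(scope or initial_terms)
    current = list(initial_terms)
    best = fit_glm(response, predictors, current, references)
    while True:
        candidates: list[tuple[float, list[str]]] = []
        for term in current:
            if _valid_drop(term, [t for t in current if t != term]):
                trial = [t for t in current if t != term]
                fit = fit_glm(response, predictors, trial, references)
                candidates.append((fit.aic, trial))
        for term in scope:
            if term not in current and _valid_add(term, current):
                trial = current + [term]
                fit = fit_glm(response, predictors, trial, references)
                candidates.append((fit.aic, trial))
        if not candidates:
            break
        aic, trial = min(candidates, key=lambda c: c[0])
        if aic < best.aic - 1e-9:
            current = trial
            best = fit_glm(response, predictors, current, references)
        else:
            break
    return best


def loo_importance(
    response,
    predictors: pd.DataFrame,
    terms: list[str],
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Drop in deviance explained (percentage points) when a term leaves.

    Each term group (a categorical's dummies, or an interaction) is
    removed in turn; removing a main effect also removes interactions
    that contain it, keeping the reduced model hierarchical.
    """
    full = fit_glm(response, predictors, terms, references)
    rows = []
    for term in terms:
        reduced = [t for t in terms
                   if t != term and not (
                       _is_interaction(t) and not _is_interaction(term)
                       and term in interaction_parts(t))]
        if reduced:
            fit = fit_glm(response, predictors, reduced, references)
            de = fit.deviance_explained
        else:
            de = 0.0
        rows.append({"term": term,
                     "delta_deviance_explained": full.deviance_explained - de})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# spatial weights and Moran's I
# ----------------------------------------------------------------------


@dataclass
class SpatialWeights:
    """Row-standardized k-nearest-neighbour weights."""

    ids: list
    matrix: np.ndarray  # (n, n), rows sum to 1
    k: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self.matrix[i])[0]


def great_circle_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Dense pairwise haversine distance matrix in kilometres."""
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * \
        np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def knn_weights(coords: pd.DataFrame | np.ndarray, k: int = 8) -> SpatialWeights:
    """k nearest neighbours by great-circle distance, row-standardized.

    ``coords`` holds (lon, lat) in degrees, one row per site.  Distance
    ties are broken by site order.
    """
    if isinstance(coords, pd.DataFrame):
        ids = list(coords.index)
        lon = coords.iloc[:, 0].to_numpy(dtype=float)
        lat = coords.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(coords, dtype=float)
        ids = list(range(arr.shape[0]))
        lon, lat = arr[:, 0], arr[:, 1]
    n = len(lon)
    if not (1 <= k < n):
        raise ValueError(f"require 1 <= k < n, got k={k}, n={n}")
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("coordinates must be finite")
    D = great_circle_km(lon, lat)
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(D[i], kind="stable")[:k]  # stable -> site-order ties
        W[i, order] = 1.0 / k
    return SpatialWeights(ids=ids, matrix=W, k=k)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float


def morans_i(values, weights: SpatialWeights) -> MoranResult:
    """Moran's I with z and two-sided p under the normality approximation."""
    x = np.asarray(values, dtype=float)
    W = weights.matrix
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if W.shape[0] != n:
        raise ValueError("weights do not match values")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise ValueError("constant input has no spatial autocorrelation")
    s0 = W.sum()
    I = (n / s0) * float(z @ W @ z) / den
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i ** 2
    zscore = (I - e_i) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(I=float(I), expected=e_i, variance=float(var),
                       z=float(zscore), p=float(p))


# ----------------------------------------------------------------------
# spatial error model (maximum likelihood)
# ----------------------------------------------------------------------


class SpatialErrorRegression(BaseEstimator, RegressorMixin):
    """ML spatial error model y = X beta + u, u = lambda W u + eps.

    The log-likelihood is concentrated in lambda: for each candidate the
    spatially filtered system (I - lambda W) is applied to y and X, beta
    and sigma^2 follow by least squares, and log|I - lambda W| is the sum
    of log(1 - lambda e_i) over the (possibly complex) eigenvalues of W.
    lambda is found by bounded scalar minimization.

    Parameters
    ----------
    weights : SpatialWeights
        Row-standardized neighbour weights; must match the rows of X.
    fit_intercept : bool
        Prepend an intercept column (default True).
    lambda_bounds : (float, float)
        Search interval for lambda, strictly inside (-1, 1).
    tol : float
        Absolute tolerance of the lambda search.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_, lambda_, sigma2_, llf_, aic_, residuals_,
    pseudo_r2_ (Nagelkerke-style, in percent, against the intercept-only
    non-spatial null).
    """

    def __init__(self, weights: SpatialWeights | None = None,
                 fit_intercept: bool = True,
                 lambda_bounds: tuple[float, float] = (-0.999, 0.999),
                 tol: float = 1e-6):
        self.weights = weights
        self.fit_intercept = fit_intercept
        self.lambda_bounds = lambda_bounds
        self.tol = tol

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y) -> "SpatialErrorRegression":
        if self.weights is None:
            raise ValueError("weights are required")
        Xd = self._design(X)
        y = np.asarray(y, dtype=float)
        n, p = Xd.shape
        if len(y) != n or self.weights.n != n:
            raise ValueError("X, y and weights must agree in length")
        if np.linalg.matrix_rank(Xd) < p:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        W = self.weights.matrix
        eigs = np.linalg.eigvals(W)

        def neg_concentrated(lam: float) -> float:
            A = np.eye(n) - lam * W
            ys, Xs = A @ y, A @ Xd
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            e = ys - Xs @ beta
            sigma2 = float(e @ e) / n
            if sigma2 <= 0:
                sigma2 = np.finfo(float).tiny
            logdet = float(np.sum(np.log(1.0 - lam * eigs)).real)
            llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet
            return -llf

        res = optimize.minimize_scalar(
            neg_concentrated, bounds=self.lambda_bounds, method="bounded",
            options={"xatol": self.tol},
        )
        if not res.success:
            raise RuntimeError(f"lambda search failed: {res.message}")
        lam = float(res.x)
        A = np.eye(n) - lam * W
        ys, Xs = A @ y, A @ Xd
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        self.lambda_ = lam
        self.sigma2_ = float(e @ e) / n
        self.llf_ = -float(res.fun)
        self.aic_ = -2.0 * self.llf_ + 2.0 * (p + 2)  # beta..., lambda, sigma2
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self.n_features_in_ = Xd.shape[1] - (1 if self.fit_intercept else 0)
        self.residuals_ = y - Xd @ beta
        # Nagelkerke-style pseudo R^2 vs the intercept-only non-spatial null
        mu0, s20 = y.mean(), y.var()
        llf0 = -0.5 * n * (math.log(2 * math.pi * max(s20, np.finfo(float).tiny)) + 1)
        self.pseudo_r2_ = 100.0 * (1.0 - math.exp(-2.0 * (self.llf_ - llf0) / n))
        return self

    def predict(self, X) -> np.ndarray:
        return self._design(X) @ np.concatenate(
            [[self.intercept_], np.atleast_1d(self.coef_)]
        ) if self.fit_intercept else self._design(X) @ np.atleast_1d(self.coef_)


@dataclass
class SEMFit:
    """Functional summary of a fitted spatial error model."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    sigma2: float
    llf: float
    aic: float
    pseudo_r2: float
    residuals: np.ndarray
    residual_moran: MoranResult


def fit_sem_ml(response, design, weights: SpatialWeights,
               fit_intercept: bool = True) -> SEMFit:
    """Fit the ML spatial error model and report residual Moran's I.

    The Moran diagnostic uses the spatially filtered innovations
    eps = (I - lambda W) u, which the model claims are independent.
    """
    est = SpatialErrorRegression(weights=weights, fit_intercept=fit_intercept)
    est.fit(design, response)
    A = np.eye(weights.n) - est.lambda_ * weights.matrix
    innovations = A @ est.residuals_
    return SEMFit(
        coefficients=est.coef_,
        intercept=est.intercept_,
        lam=est.lambda_,
        sigma2=est.sigma2_,
        llf=est.llf_,
        aic=est.aic_,
        pseudo_r2=est.pseudo_r2_,
        residuals=est.residuals_,
        residual_moran=morans_i(innovations, weights),
    )
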