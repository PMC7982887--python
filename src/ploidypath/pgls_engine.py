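"""Weighted phylogenetic generalized least squares (PGLS).

The error covariance is modeled as sigma^2 * V with V = D^{1/2} R D^{1/2},
where R is the Brownian correlation matrix from the tree and D holds
per-observation variance multipliers derived from known weights
(multiplier 1/w_i by default). Estimation is exact GLS via a Cholesky
factorization of V; V is never inverted explicitly.

Inference convention: standard errors and t tests always use the residual
variance estimate with n - p in the denominator (the unbiased, exact-t
convention), for both ML and REML fits; the two methods differ in the
reported log-likelihood and in the sigma^2 they quote.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .lineage_data import ANALYSIS_ARCHIPELAGOS, AnalysisDataset

logger = logging.getLogger("ploidypath")

CHOLESKY_JITTER = 1e-10
CONDITION_WARN = 1e10


class FitError(ValueError):
    """Estimation cannot proceed (singular design, bad covariance...)."""


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One design-matrix column."""

    name: str
    kind: str  # intercept | archipelago | continuous | binary | interaction
    base: str | None = None   # for interactions: the continuous base term
    arch: str | None = None   # for archipelago contrasts / interactions


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one PGLS submodel.

    ``varying`` lists predictors whose slope differs by archipelago (coded
    as a main, reference-averaged slope plus deviation contrasts against the
    reference archipelago). ``log_ploidy`` log-transforms ploidy levels
    wherever they appear (predictor and response); ``log_pool`` enters the
    source pool as ln(1 + pool).
    """

    response: str                      # "log_endemic" | "ploidy_levels"
    predictors: tuple[str, ...]
    varying: tuple[str, ...] = ()
    reference: str = "NZ"
    log_ploidy: bool = False
    log_pool: bool = False


def endemic_spec(reference: str = "NZ", log_ploidy: bool = False,
                 log_pool: bool = False) -> ModelSpec:
    """Endemic-diversity submodel: ln(endemic species) on log stem age,
    ploidy levels (slope varying by archipelago), source-pool size, island
    monophyly and ploidy change, with archipelago intercepts."""
    return ModelSpec(
        response="log_endemic",
        predictors=("log_stem_age", "ploidy_levels", "source_pool",
                    "monophyletic", "ploidy_change"),
        varying=("ploidy_levels",),
        reference=reference, log_ploidy=log_ploidy, log_pool=log_pool)


def ploidy_spec(reference: str = "NZ", log_ploidy: bool = False,
                log_pool: bool = False) -> ModelSpec:
    """Ploidy-levels submodel: same structure minus ploidy levels and
    monophyly, with the stem-age slope varying by archipelago."""
    return ModelSpec(
        response="ploidy_levels",
        predictors=("log_stem_age", "source_pool", "ploidy_change"),
        varying=("log_stem_age",),
        reference=reference, log_ploidy=log_ploidy, log_pool=log_pool)


def predictor_values(dataset: AnalysisDataset, name: str,
                     spec: ModelSpec) -> np.ndarray:
    """Column of predictor values on the analysis scale, canonical order."""
    recs = dataset.records
    if name == "log_stem_age":
        return np.log([r.stem_age for r in recs])
    if name == "ploidy_levels":
        v = np.asarray([r.n_ploidy_levels for r in recs], dtype=float)
        return np.log(v) if spec.log_ploidy else v
    if name == "source_pool":
        v = np.asarray([r.source_pool_size for r in recs], dtype=float)
        return np.log1p(v) if spec.log_pool else v
    if name == "monophyletic":
        return np.asarray([float(bool(r.monophyletic_on_island))
                           for r in recs])
    if name == "ploidy_change":
        return np.asarray([float(bool(r.ploidy_change_vs_sister))
                           for r in recs])
    raise KeyError(f"unknown predictor {name!r}")


def response_values(dataset: AnalysisDataset, spec: ModelSpec) -> np.ndarray:
    recs = dataset.records
    if spec.response == "log_endemic":
        counts = np.asarray([r.n_endemic for r in recs], dtype=float)
        if np.any(counts <= 0):
            raise FitError("log endemic response requires positive counts")
        return np.log(counts)
    if spec.response == "ploidy_levels":
        v = np.asarray([r.n_ploidy_levels for r in recs], dtype=float)
        return np.log(v) if spec.log_ploidy else v
    raise KeyError(f"unknown response {spec.response!r}")


_BINARY_PREDICTORS = {"monophyletic", "ploidy_change"}


def build_design(dataset: AnalysisDataset, spec: ModelSpec,
                 ) -> tuple[np.ndarray, np.ndarray, list[Term]]:
    """Design matrix, response vector and term map for one submodel.

    Archipelagos are coded as treatment contrasts against the reference;
    by-archipelago slopes as the main slope plus deviation contrasts.
    Raises :class:`FitError` if the design is rank deficient, naming the
    offending columns.
    """
    if not dataset.records:
        raise FitError("empty dataset")
    archs = [r.archipelago for r in dataset.records]
    present = [a for a in ANALYSIS_ARCHIPELAGOS if a in set(archs)]
    if spec.reference not in present:
        raise FitError(f"reference archipelago {spec.reference!r} absent "
                       f"from dataset")
    contrast_archs = [a for a in present if a != spec.reference]

    cols: list[np.ndarray] = [np.ones(len(archs))]
    terms: list[Term] = [Term("intercept", "intercept")]
    for a in contrast_archs:
        cols.append(np.asarray([1.0 if x == a else 0.0 for x in archs]))
        terms.append(Term(f"arch_{a}", "archipelago", arch=a))
    for name in spec.predictors:
        v = predictor_values(dataset, name, spec)
        kind = "binary" if name in _BINARY_PREDICTORS else "continuous"
        cols.append(v)
        terms.append(Term(name, kind))
        if name in spec.varying:
            for a in contrast_archs:
                ind = np.asarray([1.0 if x == a else 0.0 for x in archs])
                cols.append(v * ind)
                terms.append(Term(f"{name}:arch_{a}", "interaction",
                                  base=name, arch=a))
    X = np.column_stack(cols)
    y = response_values(dataset, spec)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify columns involved via pivoted QR.
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        dropped = sorted(terms[j].name for j in piv[rank:])
        raise FitError(f"rank-deficient design; collinear columns: {dropped}")
    return X, y, terms


# ---------------------------------------------------------------------------
# GLS estimation
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    """Results of one weighted PGLS fit."""

    terms: list[Term]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    sigma2: float             # per quoted method (REML: rss/(n-p); ML: rss/n)
    sigma2_resid: float       # rss/(n-p); the scale behind SEs
    loglik_ml: float
    loglik_reml: float
    fitted: np.ndarray
    resid: np.ndarray
    resid_normalized: np.ndarray
    V: np.ndarray
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1
    method: str
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    _rss: float = 0.0
    _lndetV: float = 0.0
    _lndetG: float = 0.0

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coefficients_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "estimate": self.beta, "se": self.se,
            "t": self.t, "p": self.p,
        })

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return np.column_stack([self.beta - q * self.se,
                                self.beta + q * self.se])

    def reml_loglik(self, sigma2: float) -> float:
        """Restricted log-likelihood profiled over beta, at a given sigma2."""
        n, p = self.X.shape
        return -0.5 * ((n - p) * math.log(2 * math.pi * sigma2)
                       + self._lndetV + self._lndetG + self._rss / sigma2)

    def ml_loglik(self, sigma2: float) -> float:
        n = self.X.shape[0]
        return -0.5 * (n * math.log(2 * math.pi * sigma2)
                       + self._lndetV + self._rss / sigma2)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficients": self.coefficients_table().to_dict("records"),
            "sigma2": self.sigma2,
            "df_resid": self.df_resid,
            "loglik_ml": self.loglik_ml,
            "loglik_reml": self.loglik_reml,
        }


def fit_weighted_pgls(X: np.ndarray, y: np.ndarray, R: np.ndarray,
                      weights: np.ndarray, method: str = "REML",
                      terms: list[Term] | None = None,
                      variance_power: float = 1.0) -> PglsFit:
    """Exact weighted GLS under correlation R and known observation weights.

    The variance multiplier of observation i is ``(1/w_i)**variance_power``
    (default 1: variance inversely proportional to the weight), so
    ``V = D^{1/2} R D^{1/2}`` with ``D = diag((1/w)**variance_power)``.
    ``beta = (X'V^-1X)^-1 X'V^-1 y`` via Cholesky whitening.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, p = X.shape
    if len(y) != n or len(w) != n or R.shape != (n, n):
        raise FitError("dimension mismatch between X, y, R, weights")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise FitError("weights must be strictly positive and finite")
    if n <= p:
        raise FitError(f"need n > p (n={n}, p={p})")
    if method.upper() not in ("ML", "REML"):
        raise FitError(f"unknown method {method!r}")
    method = method.upper()
    if terms is None:
        terms = [Term(f"x{j}", "continuous") for j in range(p)]

    s = w ** (-variance_power / 2.0)       # per-observation sd multiplier
    V = R * np.outer(s, s)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        logger.warning("V not positive definite; adding %g jitter",
                       CHOLESKY_JITTER)
        try:
            L = linalg.cholesky(V + CHOLESKY_JITTER * np.eye(n), lower=True)
        except linalg.LinAlgError as exc:
            raise FitError("covariance V is not positive definite") from exc
    cond = (np.max(np.diag(L)) / np.min(np.diag(L))) ** 2
    if cond > CONDITION_WARN:
        logger.warning("V badly conditioned (approx. condition %.3g)", cond)

    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    G = Xw.T @ Xw                          # X' V^-1 X
    try:
        cf = linalg.cho_factor(G)
    except linalg.LinAlgError as exc:
        raise FitError("singular X' V^-1 X (collinear design)") from exc
    beta = linalg.cho_solve(cf, Xw.T @ yw)
    cov_unscaled = linalg.cho_solve(cf, np.eye(p))

    fitted = X @ beta
    resid = y - fitted
    rw = yw - Xw @ beta
    rss = float(rw @ rw)                   # e' V^-1 e
    sigma2_resid = rss / (n - p)
    sigma2_ml = rss / n
    lndetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    lndetG = float(np.linalg.slogdet(G)[1])

    se = np.sqrt(sigma2_resid * np.diag(cov_unscaled))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)

    loglik_ml = -0.5 * (n * math.log(2 * math.pi * sigma2_ml)
                        + lndetV + n)
    loglik_reml = -0.5 * ((n - p) * math.log(2 * math.pi * sigma2_resid)
                          + lndetV + lndetG + (n - p))
    return PglsFit(
        terms=list(terms), beta=beta, se=se, t=tvals, p=pvals,
        df_resid=n - p,
        sigma2=sigma2_resid if method == "REML" else sigma2_ml,
        sigma2_resid=sigma2_resid,
        loglik_ml=loglik_ml, loglik_reml=loglik_reml,
        fitted=fitted, resid=resid,
        resid_normalized=rw / math.sqrt(sigma2_resid),
        V=V, cov_unscaled=cov_unscaled, method=method, X=X, y=y,
        _rss=rss, _lndetV=lndetV, _lndetG=lndetG)


def fit_submodel(dataset: AnalysisDataset, spec: ModelSpec, R: np.ndarray,
                 weights: np.ndarray, method: str = "REML",
                 variance_power: float = 1.0) -> PglsFit:
    """Convenience wrapper: build the design for ``spec`` and fit it."""
    X, y, terms = build_design(dataset, spec)
    return fit_weighted_pgls(X, y, R, weights, method=method, terms=terms,
                             variance_power=variance_power)


# ---------------------------------------------------------------------------
# Marginal predictions
# ---------------------------------------------------------------------------

def marginal_prediction(fit: PglsFit, term: str, grid: np.ndarray,
                        back_transform: bool = False) -> dict:
    """Predicted response over a grid of one predictor's values.

    All other predictors sit at reference values: continuous predictors at
    their dataset mean, binary predictors at 0, and archipelago effects
    averaged over the observed archipelago frequencies (including the
    focal term's by-archipelago slope deviations). ``back_transform``
    exponentiates a log-scale response. Returns the per-grid predictions and
    the mean and 95% CI of the change from the first to the last grid point.
    """
    names = fit.names
    if term not in names:
        raise KeyError(f"term {term!r} not in fitted model")
    X = fit.X
    grid = np.asarray(grid, dtype=float)
    focal = names.index(term)
    col = X[:, focal]
    if grid.min() < col.min() or grid.max() > col.max():
        logger.warning("grid [%g, %g] extends beyond observed range [%g, %g]",
                       grid.min(), grid.max(), col.min(), col.max())

    base = np.zeros(X.shape[1])
    for j, t in enumerate(fit.terms):
        if t.kind == "intercept":
            base[j] = 1.0
        elif t.kind == "archipelago":
            base[j] = float(X[:, j].mean())      # observed frequency
        elif t.kind == "continuous":
            base[j] = float(X[:, j].mean())
        elif t.kind == "binary":
            base[j] = 0.0
        elif t.kind == "interaction":
            if t.base == term:
                base[j] = 0.0                    # filled per grid point below
            else:
                base[j] = float(X[:, j].mean())

    rows = []
    for g in grid:
        x = base.copy()
        x[focal] = g
        for j, t in enumerate(fit.terms):
            if t.kind == "interaction" and t.base == term:
                arch_col = names.index(f"arch_{t.arch}")
                x[j] = g * float(X[:, arch_col].mean())
        rows.append(x)
    Xg = np.vstack(rows)
    eta = Xg @ fit.beta
    var = np.einsum("ij,jk,ik->i", Xg, fit.cov_unscaled, Xg) \
        * fit.sigma2_resid
    se = np.sqrt(var)

    c = Xg[-1] - Xg[0]
    delta = float(c @ fit.beta)
    se_d = math.sqrt(float(c @ fit.cov_unscaled @ c) * fit.sigma2_resid)
    q = stats.t.ppf(0.975, fit.df_resid)
    d_lo, d_hi = delta - q * se_d, delta + q * se_d

    if back_transform:
        pred = np.exp(eta)
        lo0 = float(np.exp(eta[0]))
        change = float(pred[-1] - pred[0])
        change_ci = (math.exp(eta[0] + d_lo) - lo0,
                     math.exp(eta[0] + d_hi) - lo0)
    else:
        pred = eta
        change = delta
        change_ci = (d_lo, d_hi)
    return {
        "grid": grid, "prediction": pred, "se_link": se,
        "change": change, "change_ci": change_ci,
        "back_transformed": back_transform,
    }
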