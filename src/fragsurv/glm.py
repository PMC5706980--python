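"""Maximum-likelihood discrete-time hazard regression with a cloglog link.

The hazard of the event at presentation ``t`` given survival to ``t`` is
modelled as ``h = 1 - exp(-exp(eta))`` with ``eta = X @ beta`` built from a
:class:`~fragsurv.model_spec.HazardModelSpec`. The Bernoulli likelihood over
person-period rows is maximized by Newton-Raphson with step-halving; model
covariance is the inverse observed information and a cluster-robust sandwich
covariance (scores summed within clusters, default cluster = participant)
is provided for repeated-measures inference.

On the cloglog scale an additive coefficient shift exponentiates to the
"hazard ratio" reported in this literature (strictly, a ratio of
cumulative-hazard increments).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .model_spec import HazardModelSpec, Term, parse_term, recenter_matrix

__all__ = [
    "cloglog",
    "inverse_cloglog",
    "FitResult",
    "fit_hazard_model",
    "predict_functions",
    "CloglogHazardGLM",
    "SingularDesignError",
    "SeparationError",
    "ConvergenceError",
]

_ETA_CLIP = 30.0
_SEPARATION_BOUND = 15.0


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


class SeparationError(RuntimeError):
    """Estimates diverged on the cloglog scale (complete separation)."""


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


def cloglog(p):
    """Complementary log-log transform ``ln(-ln(1-p))`` for p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("cloglog requires probabilities strictly inside (0, 1)")
    out = np.log(-np.log1p(-p))
    return float(out) if out.ndim == 0 else out

def inverse_cloglog(eta):
    """Inverse map ``1 - exp(-exp(eta))``, monotone from R onto (0, 1)."""
    eta = np.asarray(eta, dtype=float)
    out = -np.expm1(-np.exp(np.clip(eta, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def _loglik_score_info(eta: np.ndarray, y: np.ndarray):
    """Per-row log-likelihood pieces of the Bernoulli-cloglog model.

    Returns (loglik, score dl/deta, observed info -d2l/deta2, Fisher weight).
    """
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    u = np.exp(eta)          # cumulative-hazard increment
    r = np.exp(-u)           # 1 - h
    h = -np.expm1(-u)
    h_safe = np.maximum(h, 1e-300)
    logh = np.where(u < 1e-8, eta, np.log(h_safe))  # log h ~ eta for tiny u
    ll = float(np.sum(y * logh - (1.0 - y) * u))
    f = u * r / h_safe                               # d log h / d eta
    score = y * f - (1.0 - y) * u
    info_obs = y * f * (u + f - 1.0) + (1.0 - y) * u
    fisher = u * u * r / h_safe
    return ll, score, info_obs, fisher


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    _, sv, vt = np.linalg.svd(x, full_matrices=False)
    bad = sv < sv[0] * 1e-9 if sv[0] > 0 else np.ones_like(sv, dtype=bool)
    if bad.any():
        null = np.abs(vt[bad]).sum(axis=0)
        cols = [n for n, w in zip(names, null) if w > 1e-6 * null.max()]
        raise SingularDesignError(f"design matrix is rank deficient; collinear columns: {cols}")


@dataclass(frozen=True)
class FitResult:
    """Fitted discrete-time cloglog hazard model."""

    spec: HazardModelSpec
    names: tuple[str, ...]
    estimates: np.ndarray
    cov_model: np.ndarray
    cov_cluster_robust: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    n_obs: int
    n_clusters: int
    cluster_col: str

    # -- accessors ----------------------------------------------------------
    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.estimates, index=list(self.names))

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.cov_cluster_robust if robust else self.cov_model
        return pd.Series(np.sqrt(np.diag(cov)), index=list(self.names))

    def wald(self, robust: bool = True) -> pd.DataFrame:
        """Per-term Wald chi-square ``(PE/SE)^2`` with p from chi2(1)."""
        se = self.se(robust)
        stat = (self.coef / se) ** 2
        return pd.DataFrame(
            {"estimate": self.coef, "se": se, "wald_chi2": stat, "p": stats.chi2.sf(stat, df=1)}
        )

    def hazard_ratio(self, term: str) -> float:
        """``exp(PE)``: multiplicative hazard shift for the named term."""
        if term not in self.names:
            raise KeyError(f"unknown term {term!r}")
        return float(np.exp(self.coef[term]))

    def conf_int(self, level: float = 0.95, robust: bool = True) -> pd.DataFrame:
        """Wald intervals; cluster-robust intervals use t(G-1) critical values."""
        se = self.se(robust)
        if robust and self.n_clusters > 1:
            crit = stats.t.ppf(0.5 + level / 2, df=self.n_clusters - 1)
        else:
            crit = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.coef - crit * se, "upper": self.coef + crit * se}
        )

    # -- recentring ---------------------------------------------------------
    def recenter(self, new_center: int) -> "FitResult":
        """Exact polynomial-shift reparameterization around a new presentation.

        Log-likelihood and every predicted function are unchanged; power-0
        coefficients now describe effects at ``new_center``.
        """
        terms = [parse_term(n) for n in self.names]
        m = recenter_matrix(terms, self.spec.center, new_center)
        return _dc_replace(
            self,
            spec=self.spec.with_center(new_center),
            estimates=m @ self.estimates,
            cov_model=m @ self.cov_model @ m.T,
            cov_cluster_robust=m @ self.cov_cluster_robust @ m.T,
        )

    # -- prediction ---------------------------------------------------------
    def predict_functions(
        self, conditions, horizon: int = 10, reference: dict | None = None
    ) -> pd.DataFrame:
        return predict_functions(
            self.coef, conditions, horizon=horizon, center=self.spec.center, reference=reference
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        w_rob, w_mod = self.wald(robust=True), self.wald(robust=False)
        return {
            "spec": self.spec.to_dict(),
            "cluster": self.cluster_col,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "loglik": self.loglik,
            "n_iterations": self.n_iterations,
            "converged": bool(self.converged),
            "coefficients": [
                {
                    "term": n,
                    "estimate": float(self.coef[n]),
                    "se_model": float(w_mod["se"][n]),
                    "se_robust": float(w_rob["se"][n]),
                    "wald_chi2": float(w_rob["wald_chi2"][n]),
                    "p": float(w_rob["p"][n]),
                }
                for n in self.names
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _fit_arrays(
    x: np.ndarray,
    y: np.ndarray,
    names: list[str],
    groups: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Newton-Raphson with observed information and step-halving."""
    _check_rank(x, names)
    beta = np.zeros(x.shape[1])
    ll, score, info_obs, fisher = _loglik_score_info(x @ beta, y)
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = x.T @ score
        hess = x.T * info_obs @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(x.T * fisher @ x, grad)
        # step-halving on the log-likelihood
        scale, ll_new = 1.0, -np.inf
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _loglik_score_info(x @ cand, y)[0]
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_prev, (ll, score, info_obs, fisher) = ll, _loglik_score_info(x @ beta, y)
        trace.append(ll)
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"estimates diverging (|beta| > {_SEPARATION_BOUND} for {worst!r}); "
                "likely complete separation"
            )
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence after {max_iter} iterations", trace)

    a = x.T * info_obs @ x
    cov_model = np.linalg.inv(a)
    # cluster-robust sandwich: scores summed within clusters, G/(G-1) correction
    sx = x * score[:, None]
    gdf = pd.DataFrame(sx).groupby(groups, sort=False).sum().to_numpy()
    g = gdf.shape[0]
    meat = gdf.T @ gdf
    corr = g / (g - 1) if g > 1 else 1.0
    cov_robust = corr * cov_model @ meat @ cov_model
    return beta, cov_model, cov_robust, ll, n_iter, g


def fit_hazard_model(
    table: pd.DataFrame,
    spec: HazardModelSpec,
    cluster: str = "participant_id",
    event_col: str = "EVENT",
    time_col: str = "TIME",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the cloglog hazard model to a person-period table."""
    y = np.asarray(table[event_col], dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"{event_col} must be binary 0/1")
    x, names = spec.design_matrix(table, time_col=time_col)
    if not np.all(np.isfinite(x)):
        bad = [n for n, col in zip(names, x.T) if not np.all(np.isfinite(col))]
        raise ValueError(f"non-finite design values in terms {bad}")
    if cluster in table.columns:
        groups = table[cluster].to_numpy()
    else:
        groups = np.arange(len(table))  # every row its own cluster
    beta, cov_m, cov_r, ll, n_iter, g = _fit_arrays(
        x, y, names, groups, max_iter=max_iter, tol=tol
    )
    return FitResult(
        spec=spec,
        names=tuple(names),
        estimates=beta,
        cov_model=cov_m,
        cov_cluster_robust=cov_r,
        loglik=ll,
        n_iterations=n_iter,
        converged=True,
        n_obs=len(table),
        n_clusters=g,
        cluster_col=cluster,
    )


def predict_functions(
    coefficients,
    conditions,
    horizon: int = 10,
    center: int = 1,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Model-implied cloglog[h(t)], h(t), S(t), and HR(t) per condition.

    ``coefficients`` is any mapping term-name -> estimate (a fit's coefficient
    vector or an externally transcribed table). ``conditions`` maps condition
    labels to covariate assignments; covariates not mentioned default to 0,
    so ``{}`` is the baseline condition. Hazard ratios are relative to
    ``reference`` (default: the all-zero baseline).
    """
    coefs = pd.Series(coefficients, dtype=float)
    terms = [parse_term(n) for n in coefs.index]
    known = {c for t in terms for c in t.covariates}
    if isinstance(conditions, dict) and conditions and not all(
        isinstance(v, dict) for v in conditions.values()
    ):
        conditions = {"condition": conditions}
    if not isinstance(conditions, dict):
        conditions = {f"condition_{i}": c for i, c in enumerate(conditions)}

    def eta_fn(assign: dict, t: np.ndarray) -> np.ndarray:
        unknown = set(assign) - known
        if unknown:
            raise KeyError(f"covariates not in the model: {sorted(unknown)}")
        eta = np.zeros_like(t, dtype=float)
        for term, b in zip(terms, coefs.to_numpy()):
            xprod = 1.0
            for c in term.covariates:
                xprod *= float(assign.get(c, 0))
            if xprod:
                eta += b * xprod * (t - center) ** term.power
        return eta

    t = np.arange(1, horizon + 1, dtype=float)
    eta_ref = eta_fn(reference or {}, t)
    rows = []
    for label, assign in conditions.items():
        eta = eta_fn(assign, t)
        h = inverse_cloglog(eta)
        s = np.cumprod(1.0 - h)
        hr = np.exp(eta - eta_ref)
        for i, ti in enumerate(t):
            rows.append(
                {
                    "condition": label,
                    "TIME": int(ti),
                    "cloglog_hazard": eta[i],
                    "hazard": h[i],
                    "survivor": s[i],
                    "hazard_ratio": hr[i],
                }
            )
    return pd.DataFrame(rows)


class CloglogHazardGLM(BaseEstimator):
    """Scikit-learn style estimator for the discrete-time cloglog hazard model.

    Parameters
    ----------
    spec : HazardModelSpec
        Baseline time polynomial plus covariate terms.
    cluster : column defining the sandwich-covariance cluster unit
        (participant by default; falls back to independent rows if absent).
    event_col, time_col : person-period column names.
    max_iter, tol : Newton-Raphson controls (relative log-likelihood change).
    """

    def __init__(
        self,
        spec: HazardModelSpec | None = None,
        cluster: str = "participant_id",
        event_col: str = "EVENT",
        time_col: str = "TIME",
        max_iter: int = 100,
        tol: float = 1e-10,
    ):
        self.spec = spec
        self.cluster = cluster
        self.event_col = event_col
        self.time_col = time_col
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None):
        spec = self.spec if self.spec is not None else HazardModelSpec()
        table = X
        if y is not None:
            table = X.copy()
            table[self.event_col] = np.asarray(y)
        self.result_ = fit_hazard_model(
            table,
            spec,
            cluster=self.cluster,
            event_col=self.event_col,
            time_col=self.time_col,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.coef_ = self.result_.estimates
        self.coef_names_ = list(self.result_.names)
        self.loglik_ = self.result_.loglik
        self.n_iter_ = self.result_.n_iterations
        self.converged_ = self.result_.converged
        return self

    def predict_hazard(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted hazard probability for each person-period row."""
        x, _ = self.result_.spec.design_matrix(X, time_col=self.time_col)
        return inverse_cloglog(x @ self.coef_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_hazard(X)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean Bernoulli log-likelihood per person-period row."""
        table = X if y is None else X.assign(**{self.event_col: np.asarray(y)})
        yy = np.asarray(table[self.event_col], dtype=float)
        x, _ = self.result_.spec.design_matrix(table, time_col=self.time_col)
        return _loglik_score_info(x @ self.coef_, yy)[0] / len(table)
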