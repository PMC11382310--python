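"""Censored-data estimators shared by screening, tables, and mediation.

Four regression families and two nonparametric tools, each returning a
:class:`FitResult` (coefficients + covariance + log-likelihood) so that
downstream delta-method machinery can treat them uniformly:

* logistic regression (mediator model, propensity model, odds-ratio tables),
* exponential accelerated-failure-time regression — Weibull with the shape
  parameter fixed at 1 — whose log-time coefficients convert to log hazard
  ratios by negation (outcome model of the mediation analysis),
* Cox proportional hazards (screening and hazard-ratio tables),
* Kaplan-Meier estimation and the log-rank test.

Logistic and Cox fits are delegated to statsmodels and lifelines; the
exponential AFT likelihood is maximised here by Newton iteration because the
mediation decomposition lives on its coefficient scale and no installed
fitter exposes a fixed-shape AFT with full covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import lifelines
from lifelines.statistics import multivariate_logrank_test
import statsmodels.api as sm


class FitError(RuntimeError):
    """A regression fit could not be completed."""


class SeparationError(FitError):
    """Perfect or quasi-perfect separation in a binary-outcome model."""


class RankDeficiencyError(FitError):
    """Design matrix is rank deficient; names the offending columns."""


MAX_ITER = 100
LOGLIK_RTOL = 1e-10  # relative log-likelihood change declaring convergence
GRAD_TOL = 1e-8


@dataclass
class FitResult:
    """Fitted coefficients with covariance, from any of the three families.

    ``coefficients`` are on the linear-predictor scale of the family:
    log-odds (logistic), log-time (exp_aft), log-hazard (cox).
    """

    model_kind: str  # {"logistic", "exp_aft", "cox"}
    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        cov = self.covariance.to_numpy()
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.n_events > self.n:
            raise ValueError("n_events cannot exceed n")

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())),
            index=self.coefficients.index,
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.coefficients / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coefficients.index)

    def summary(self, conf_level: float = 0.95) -> pd.DataFrame:
        """Regression table: coefficient, ratio (OR or HR), CI, Wald p.

        For the exponential AFT the reported ratio is the hazard ratio
        ``exp(-coef)`` (shape 1), mirroring how such models are read in the
        clinical literature.
        """
        zcrit = stats.norm.ppf(0.5 + conf_level / 2)
        coef = self.coefficients
        se = self.se
        if self.model_kind == "exp_aft":
            ratio = np.exp(-coef)
            lo, hi = np.exp(-coef - zcrit * se), np.exp(-coef + zcrit * se)
            lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
            label = "HR"
        else:
            ratio = np.exp(coef)
            lo, hi = np.exp(coef - zcrit * se), np.exp(coef + zcrit * se)
            label = "OR" if self.model_kind == "logistic" else "HR"
        return pd.DataFrame(
            {
                "coef": coef,
                label: ratio,
                "ci_lower": lo,
                "ci_upper": hi,
                "p": self.pvalues,
            }
        )


def _as_design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept and "intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR identifies which columns are redundant
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
        bad = [X.columns[piv[i]] for i in range(len(keep)) if not keep[i]]
        bad += [X.columns[p] for p in piv[len(keep):]]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {arr.shape[1]} columns; "
            f"redundant columns: {sorted(set(map(str, bad)))}"
        )


def fit_logistic(y, X, add_intercept: bool = True) -> FitResult:
    """Maximum-likelihood logistic regression with Wald covariance.

    Raises :class:`SeparationError` when the outcome is constant or the MLE
    diverges (perfect separation), :class:`RankDeficiencyError` for collinear
    designs.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    X = _as_design(X, add_intercept)
    if len(y) != len(X):
        raise ValueError("y and X lengths differ")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; logistic MLE undefined")
    _check_rank(X)

    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=MAX_ITER, tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation detected: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 25:
        raise SeparationError(
            "diverging coefficient (|beta| > 25); data are separated or nearly so"
        )
    return FitResult(
        model_kind="logistic",
        coefficients=pd.Series(params, index=X.columns),
        covariance=pd.DataFrame(
            np.asarray(res.cov_params()), index=X.columns, columns=X.columns
        ),
        loglik=float(res.llf),
        n=len(y),
        n_events=int(y.sum()),
    )


def exp_aft_loglik(theta, times, events, X) -> float:
    """Censored exponential-AFT log-likelihood at ``theta``.

    With linear predictor mu_i = x_i . theta on the log-time scale, the
    hazard is lambda_i = exp(-mu_i) and

        l(theta) = sum_i [ d_i * (-mu_i) - T_i * exp(-mu_i) ].
    """
    mu = X @ theta
    return float(np.sum(-events * mu - times * np.exp(-mu)))


def fit_exp_aft(times, events, X, add_intercept: bool = True) -> FitResult:
    """Exponential AFT regression (Weibull with shape fixed at 1) by Newton.

    Coefficients are on the log-time scale; the log hazard ratio of any
    covariate is the negated coefficient. The likelihood is globally concave,
    so Newton iteration from the intercept-only MLE converges in a handful of
    steps; covariance is the inverse observed information.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    if not np.isin(events, [0.0, 1.0]).all():
        raise ValueError("events must be binary 0/1")
    d = events.sum()
    if d == 0:
        raise FitError("no events: exponential-AFT MLE undefined")
    X = _as_design(X, add_intercept)
    _check_rank(X)
    A = X.to_numpy()
    p = A.shape[1]

    theta = np.zeros(p)
    if "intercept" in X.columns:
        theta[X.columns.get_loc("intercept")] = np.log(times.sum() / d)
    ll = exp_aft_loglik(theta, times, events, A)
    for _ in range(MAX_ITER):
        lam_t = times * np.exp(-(A @ theta))  # T_i * exp(-mu_i)
        grad = A.T @ (lam_t - events)
        info = A.T @ (A * lam_t[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        theta_new = theta + step
        ll_new = exp_aft_loglik(theta_new, times, events, A)
        # concave likelihood: halve the step if it overshoots
        halvings = 0
        while ll_new < ll and halvings < 30:
            step /= 2
            theta_new = theta + step
            ll_new = exp_aft_loglik(theta_new, times, events, A)
            halvings += 1
        done = abs(ll_new - ll) < LOGLIK_RTOL * (abs(ll) + 1.0)
        theta, ll = theta_new, ll_new
        if done:
            break
    else:
        gnorm = float(np.linalg.norm(grad))
        raise FitError(
            f"exponential-AFT Newton failed to converge in {MAX_ITER} "
            f"iterations (gradient norm {gnorm:.3e})"
        )
    lam_t = times * np.exp(-(A @ theta))
    grad = A.T @ (lam_t - events)
    if np.linalg.norm(grad) > 1e-6 * (1 + abs(ll)):
        raise FitError(
            f"exponential-AFT gradient norm {np.linalg.norm(grad):.3e} at optimum"
        )
    info = A.T @ (A * lam_t[:, None])
    cov = np.linalg.inv(info)
    return FitResult(
        model_kind="exp_aft",
        coefficients=pd.Series(theta, index=X.columns),
        covariance=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        loglik=ll,
        n=len(times),
        n_events=int(d),
    )


def fit_cox(times, events, X, ties: str = "efron") -> FitResult:
    """Cox proportional-hazards partial-likelihood fit (Efron ties default)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if events.sum() == 0:
        raise FitError("no events: Cox partial likelihood undefined")
    X = _as_design(X, add_intercept=False)
    _check_rank(X)
    # monotone-likelihood guard: a binary covariate level with zero events
    # drives its coefficient to +/- infinity
    for col in X.columns:
        v = X[col].to_numpy()
        levels = np.unique(v)
        if len(levels) == 2:
            for lev in levels:
                if events[v == lev].sum() == 0:
                    raise FitError(
                        f"monotone partial likelihood: no events at {col}={lev:g}"
                    )
    df = X.copy()
    df["_time"] = times
    df["_event"] = events
    cph = lifelines.CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.95},
            )
        except lifelines.exceptions.ConvergenceError as exc:
            raise FitError(f"Cox fit did not converge: {exc}") from exc
    if ties == "breslow":
        # lifelines uses Efron; Breslow via its low-level option is not
        # exposed, so refit through the counting-process approximation:
        # statsmodels PHReg supports Breslow directly.
        import statsmodels.duration.hazard_regression as hr

        mod = hr.PHReg(times, X.to_numpy(), status=events, ties="breslow")
        res = mod.fit()
        return FitResult(
            model_kind="cox",
            coefficients=pd.Series(res.params, index=X.columns),
            covariance=pd.DataFrame(
                res.cov_params(), index=X.columns, columns=X.columns
            ),
            loglik=float(mod.loglike(res.params)),
            n=len(times),
            n_events=int(events.sum()),
        )
    if ties != "efron":
        raise ValueError("ties must be 'efron' or 'breslow'")
    return FitResult(
        model_kind="cox",
        coefficients=pd.Series(cph.params_.to_numpy(), index=X.columns),
        covariance=pd.DataFrame(
            cph.variance_matrix_.to_numpy(), index=X.columns, columns=X.columns
        ),
        loglik=float(cph.log_likelihood_),
        n=len(times),
        n_events=int(events.sum()),
    )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood-based intervals."""

    times: np.ndarray  # distinct observed times, ascending
    surv: np.ndarray  # S(t) just after each time
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple  # (lower, upper); NaN where undetermined
    _fitter: "lifelines.KaplanMeierFitter" = field(repr=False, default=None)

    def rate_at(self, t: float, conf_level: float = 0.95):
        """Survival probability at ``t`` with a log-log (Greenwood) CI."""
        s = float(self._fitter.survival_function_at_times(t).iloc[0])
        ci = self._fitter.confidence_interval_survival_function_
        idx = ci.index[ci.index <= t]
        if len(idx) == 0:
            return s, 0.0, 1.0
        row = ci.loc[idx[-1]]
        return s, float(row.iloc[0]), float(row.iloc[1])


def km_estimate(times, events, conf_level: float = 0.95) -> KMCurve:
    """Kaplan-Meier estimate; median CI from the Brookmeyer-Crowley-style
    inversion of the pointwise survival band."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if len(times) == 0:
        raise ValueError("empty sample")
    kmf = lifelines.KaplanMeierFitter(alpha=1 - conf_level)
    kmf.fit(times, events)
    sf = kmf.survival_function_
    med = float(kmf.median_survival_time_)
    med = np.nan if np.isinf(med) else med
    ci_df = lifelines.utils.median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    lo = np.nan if np.isinf(lo) else lo
    hi = np.nan if np.isinf(hi) else hi
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMCurve(
        times=t[keep], surv=s[keep], median=med, median_ci=(lo, hi), _fitter=kmf
    )


def logrank_test(times, events, group):
    """k-sample log-rank test; returns (chi-square statistic, p-value)."""
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    counts = pd.Series(group).value_counts()
    if counts.min() == 0:
        raise ValueError("empty group")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), group, np.asarray(events, dtype=float)
    )
    return float(res.test_statistic), float(res.p_value)
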