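"""Natural direct and indirect effects for a binary mediator and an
exponential accelerated-failure-time outcome.

The decomposition follows the regression-based counterfactual approach for
survival mediation: a logistic model for the mediator M given exposure A and
covariates C, and a Weibull AFT model with shape fixed at 1 (exponential)
for the outcome T given A, M (optionally A x M) and C. Because M is
Bernoulli, the counterfactual mean survival times integrate in closed form:
with L_x = beta0 + beta1*x + beta_C' c the mediator's linear predictor and
k_x = theta2 + theta3*x the mediator's log-time effect under exposure x,

    TR_NIE = [(1 + e^{L_a + k_a}) (1 + e^{L_a*})]
           / [(1 + e^{L_a* + k_a}) (1 + e^{L_a})]
    TR_NDE = e^{theta1 (a - a*)} (1 + e^{L_a* + k_a}) / (1 + e^{L_a* + k_a*})

are time ratios, and with shape 1 the hazard ratio of any time ratio is its
reciprocal: log HR = -log TR. The total effect decomposes exactly,
TE = NDE x NIE on the hazard-ratio scale. Confidence intervals come from
the delta method over the stacked (beta, theta) with block-diagonal
covariance (the two fits share no parameters); a seeded nonparametric
bootstrap is offered for small samples. The proportion mediated is computed
on the excess-relative-hazard scale,

    PM = exp(NDE) [exp(NIE) - 1] / [exp(NDE) exp(NIE) - 1],

with NDE/NIE as log hazard ratios, and the indirect effect converts to a
median-survival difference by scaling a reference-arm exponential hazard:
delta_median = (ln 2 / lambda) (1 / HR_NIE - 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from . import survival_core as sc

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class MediationConfig:
    """Exposure coding, interaction switch, conditioning values, CI method."""

    a: float = 1.0        # exposed level (protons)
    astar: float = 0.0    # reference level (photons)
    interaction: bool = False  # include exposure x mediator term
    c_cond: dict | None = None  # covariate -> conditioning value; default:
    #                             sample means of the adjustment covariates
    ci_method: str = "delta"    # {"delta", "bootstrap"}
    bootstrap_reps: int = 1000
    seed: int = 0
    exposure: str = "modality"
    mediator: str = "g4ril"
    event_floor: int = 10  # strata with fewer events are flagged underpowered

    def __post_init__(self) -> None:
        if self.a == self.astar:
            raise ValueError("exposed and reference levels must differ")
        if self.ci_method not in ("delta", "bootstrap"):
            raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    @property
    def interaction_term(self) -> str:
        return f"{self.exposure}:{self.mediator}"


def _split_params(fit: sc.FitResult, drop: tuple) -> list:
    """Covariate names of a fit excluding structural terms."""
    return [c for c in fit.coefficients.index if c not in drop]


def _log_effects(bvec: np.ndarray, bnames: list, tvec: np.ndarray,
                 tnames: list, config: MediationConfig, c_cond: dict
                 ) -> tuple[float, float]:
    """(logTR_nde, logTR_nie) from raw coefficient vectors.

    Written as a pure function of the stacked parameters so the delta-method
    gradient can difference it directly.
    """
    b = dict(zip(bnames, bvec))
    t = dict(zip(tnames, tvec))
    exposure, mediator = config.exposure, config.mediator
    inter = config.interaction_term
    a, astar = config.a, config.astar

    def L(x):
        val = b["intercept"] + b[exposure] * x
        for name in bnames:
            if name not in ("intercept", exposure):
                val += b[name] * c_cond[name]
        return val

    theta1 = t[exposure]
    theta2 = t[mediator]
    theta3 = t.get(inter, 0.0)

    def k(x):
        return theta2 + theta3 * x

    La, Lastar = L(a), L(astar)
    sp = lambda x: np.logaddexp(0.0, x)  # log(1 + e^x), overflow-safe
    logtr_nie = sp(La + k(a)) + sp(Lastar) - sp(Lastar + k(a)) - sp(La)
    logtr_nde = theta1 * (a - astar) + sp(Lastar + k(a)) - sp(Lastar + k(astar))
    return float(logtr_nde), float(logtr_nie)


def _resolve_c_cond(mediator_fit, outcome_fit, config) -> dict:
    exposure, mediator = config.exposure, config.mediator
    inter = config.interaction_term
    bcovs = _split_params(mediator_fit, ("intercept", exposure))
    tcovs = _split_params(outcome_fit, ("intercept", exposure, mediator, inter))
    covs = sorted(set(bcovs) | set(tcovs))
    c_cond = dict(config.c_cond or {})
    missing = [c for c in covs if c not in c_cond]
    if missing:
        raise ValueError(
            f"no conditioning value for covariate(s) {missing}; "
            "set MediationConfig.c_cond"
        )
    return c_cond


def natural_effects(mediator_fit: sc.FitResult, outcome_fit: sc.FitResult,
                    config: MediationConfig) -> tuple[float, float]:
    """Closed-form (logTR_nde, logTR_nie) at the conditioning values.

    ``mediator_fit`` must be a logistic fit of M on (A, C); ``outcome_fit``
    an exponential-AFT fit of T on (A, M[, A x M], C). The interaction flag
    must agree with the outcome design.
    """
    if mediator_fit.model_kind != "logistic":
        raise ValueError("mediator_fit must be a logistic fit")
    if outcome_fit.model_kind != "exp_aft":
        raise ValueError("outcome_fit must be an exponential-AFT fit")
    if config.mediator not in outcome_fit.coefficients.index:
        raise ValueError(
            f"outcome fit lacks the mediator term {config.mediator!r}"
        )
    has_inter = config.interaction_term in outcome_fit.coefficients.index
    if has_inter != config.interaction:
        raise ValueError(
            "interaction flag inconsistent with the outcome design "
            f"(flag={config.interaction}, design has term={has_inter})"
        )
    c_cond = _resolve_c_cond(mediator_fit, outcome_fit, config)
    return _log_effects(
        mediator_fit.coefficients.to_numpy(), list(mediator_fit.coefficients.index),
        outcome_fit.coefficients.to_numpy(), list(outcome_fit.coefficients.index),
        config, c_cond,
    )


def to_hazard_scale(logtr: float, shape: float = 1.0) -> float:
    """Log hazard ratio of a log time-ratio under Weibull shape ``shape``."""
    if shape <= 0:
        raise ValueError("shape must be positive")
    return -shape * logtr


def effect_cis(mediator_fit: sc.FitResult, outcome_fit: sc.FitResult,
               config: MediationConfig, conf_level: float = 0.95
               ) -> pd.DataFrame:
    """Delta-method intervals for NDE/NIE/TE over the stacked (beta, theta).

    The two fits are estimated on disjoint parameter blocks, so the joint
    covariance is block diagonal. Gradients by central differences with
    step 1e-6 * max(1, |param|). Rows: nde, nie, te; columns: logTR, se,
    hr, hr_lower, hr_upper, p.
    """
    c_cond = _resolve_c_cond(mediator_fit, outcome_fit, config)
    bnames = list(mediator_fit.coefficients.index)
    tnames = list(outcome_fit.coefficients.index)
    b0 = mediator_fit.coefficients.to_numpy(dtype=float)
    t0 = outcome_fit.coefficients.to_numpy(dtype=float)
    x0 = np.concatenate([b0, t0])
    nb = len(b0)

    def f(x):
        nde, nie = _log_effects(x[:nb], bnames, x[nb:], tnames, config, c_cond)
        return np.array([nde, nie, nde + nie])

    grad = np.zeros((3, len(x0)))
    for j in range(len(x0)):
        h = 1e-6 * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        grad[:, j] = (f(xp) - f(xm)) / (2 * h)

    cov_b = mediator_fit.covariance.to_numpy()
    cov_t = outcome_fit.covariance.to_numpy()
    sigma = np.zeros((len(x0), len(x0)))
    sigma[:nb, :nb] = cov_b
    sigma[nb:, nb:] = cov_t
    try:
        np.linalg.cholesky(sigma + 1e-14 * np.eye(len(x0)))
    except np.linalg.LinAlgError as exc:
        raise sc.FitError(f"singular joint covariance: {exc}") from exc

    logtr = f(x0)
    var = np.einsum("ij,jk,ik->i", grad, sigma, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    # log HR = -logTR, so the HR interval endpoints swap
    hr = np.exp(-logtr)
    hr_lo = np.exp(-logtr - z * se)
    hr_hi = np.exp(-logtr + z * se)
    hr_lo, hr_hi = np.minimum(hr_lo, hr_hi), np.maximum(hr_lo, hr_hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, logtr / se, np.inf * np.sign(logtr))
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(zstat)),
                 np.where(logtr == 0, 1.0, 0.0))
    return pd.DataFrame(
        {"logTR": logtr, "se": se, "hr": hr, "hr_lower": hr_lo,
         "hr_upper": hr_hi, "p": p},
        index=["nde", "nie", "te"],
    )


def proportion_mediated(loghr_nde: float, loghr_nie: float
                        ) -> tuple[float, bool]:
    """Proportion mediated on the excess-relative-hazard scale.

    PM = exp(NDE)[exp(NIE) - 1] / [exp(NDE + NIE) - 1] with both arguments
    log hazard ratios. Returns (pm, valid); ``valid`` is False when the
    total-effect HR is >= 1 (the decomposition describes a harmful or null
    total effect and the share is not interpretable as a fraction) or when
    pm falls outside [0, 1]. A total-effect HR of exactly 1 leaves PM
    undefined (nan, invalid).
    """
    hr_te = np.exp(loghr_nde + loghr_nie)
    if hr_te == 1.0:
        return float("nan"), False
    pm = np.exp(loghr_nde) * (np.exp(loghr_nie) - 1.0) / (hr_te - 1.0)
    valid = bool(hr_te < 1.0 and 0.0 <= pm <= 1.0)
    return float(pm), valid


def nie_to_median_diff(hr_nie: float, ci_nie: tuple | None = None,
                       reference_hazard: float | None = None,
                       reference_median: float | None = None
                       ) -> tuple[float, tuple | None]:
    """Months of median survival attributable to the mediated path.

    The reference arm's survival is summarised by an exponential hazard
    lambda (given directly, or as ln2 / median); scaling that hazard by the
    indirect-effect HR gives delta_median = (ln2/lambda)(1/HR_NIE - 1).
    CI endpoints substitute the NIE interval endpoints (a larger HR gives a
    smaller gain, so the endpoints swap).
    """
    if (reference_hazard is None) == (reference_median is None):
        raise ValueError("give exactly one of reference_hazard / reference_median")
    if reference_median is not None:
        if reference_median <= 0:
            raise ValueError("reference_median must be positive")
        reference_hazard = LN2 / reference_median
    if reference_hazard <= 0 or hr_nie <= 0:
        raise ValueError("hazard and HR must be positive")
    base = LN2 / reference_hazard

    def delta(hr):
        return base * (1.0 / hr - 1.0)

    ci = None
    if ci_nie is not None:
        lo, hi = delta(ci_nie[1]), delta(ci_nie[0])
        ci = (min(lo, hi), max(lo, hi))
    return delta(hr_nie), ci


@dataclass
class MediationResult:
    """Full decomposition on log-time-ratio and hazard-ratio scales."""

    logtr_nde: float
    logtr_nie: float
    logtr_te: float
    hr_nde: float
    hr_nie: float
    hr_te: float
    ci: dict            # effect -> (hr_lower, hr_upper)
    se: dict            # effect -> SE of the logTR
    p: dict             # effect -> Wald p
    pm: float
    pm_valid: bool
    median_diff: float  # months gained through the mediated path
    median_diff_ci: tuple | None
    reference_hazard: float  # per-month exponential rate, reference arm
    n: int
    n_events: int
    mediator_table: pd.DataFrame = field(repr=False, default=None)
    outcome_table: pd.DataFrame = field(repr=False, default=None)
    c_cond: dict = field(default_factory=dict)
    interaction: bool = False
    underpowered: bool = False

    def __post_init__(self) -> None:
        if abs(self.logtr_te - self.logtr_nde - self.logtr_nie) > 1e-12:
            raise ValueError("decomposition identity violated")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("mediator_table", "outcome_table")}
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        d["median_diff_ci"] = (list(self.median_diff_ci)
                               if self.median_diff_ci else None)
        d["mediator_model"] = json.loads(
            self.mediator_table.to_json(orient="index"))
        d["outcome_model"] = json.loads(
            self.outcome_table.to_json(orient="index"))
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _mediation_designs(df: pd.DataFrame, ps: np.ndarray,
                       config: MediationConfig):
    a = df[config.exposure].to_numpy(dtype=float)
    m = df[config.mediator].to_numpy(dtype=float)
    Xm = pd.DataFrame({config.exposure: a, "ps": ps})
    Xo = pd.DataFrame({config.exposure: a, config.mediator: m, "ps": ps})
    if config.interaction:
        Xo[config.interaction_term] = a * m
        Xo = Xo[[config.exposure, config.mediator, config.interaction_term, "ps"]]
    return Xm, Xo


def mediate(cohort: Cohort, ps_scores: pd.Series,
            config: MediationConfig | None = None) -> MediationResult:
    """Fit both models on the (matched) cohort and decompose the effect.

    Mediator model: logistic M ~ A + propensity score. Outcome model:
    exponential AFT T ~ A + M [+ A x M] + propensity score. Conditioning
    values default to the sample mean of the propensity score. The reference
    hazard for the median-survival conversion is the intercept-only
    exponential fit on the reference arm.
    """
    config = config or MediationConfig()
    df = cohort.df
    ps = ps_scores.reindex(df["id"]).to_numpy(dtype=float)
    if np.isnan(ps).any():
        raise ValueError("ps_scores missing for some cohort ids")

    Xm, Xo = _mediation_designs(df, ps, config)
    mediator_fit = sc.fit_logistic(df[config.mediator], Xm)
    outcome_fit = sc.fit_exp_aft(df["os_months"], df["event"], Xo)

    if config.c_cond is None:
        config_eval = MediationConfig(
            **{**asdict(config), "c_cond": {"ps": float(np.mean(ps))}})
    else:
        config_eval = config

    logtr_nde, logtr_nie = natural_effects(mediator_fit, outcome_fit, config_eval)
    logtr_te = logtr_nde + logtr_nie

    if config.ci_method == "delta":
        table = effect_cis(mediator_fit, outcome_fit, config_eval)
    else:
        table = _bootstrap_cis(cohort, ps_scores, config_eval)

    hr = {e: float(np.exp(-lt)) for e, lt in
          zip(["nde", "nie", "te"], [logtr_nde, logtr_nie, logtr_te])}
    pm, pm_valid = proportion_mediated(to_hazard_scale(logtr_nde),
                                       to_hazard_scale(logtr_nie))

    ref = df[df[config.exposure] == config.astar]
    ref_fit = sc.fit_exp_aft(ref["os_months"], ref["event"],
                             pd.DataFrame(index=ref.index))
    lam = float(np.exp(-ref_fit.coefficients["intercept"]))
    md, md_ci = nie_to_median_diff(
        hr["nie"], ci_nie=tuple(table.loc["nie", ["hr_lower", "hr_upper"]]),
        reference_hazard=lam)

    return MediationResult(
        logtr_nde=logtr_nde, logtr_nie=logtr_nie, logtr_te=logtr_te,
        hr_nde=hr["nde"], hr_nie=hr["nie"], hr_te=hr["te"],
        ci={e: (float(table.loc[e, "hr_lower"]), float(table.loc[e, "hr_upper"]))
            for e in table.index},
        se={e: float(table.loc[e, "se"]) for e in table.index},
        p={e: float(table.loc[e, "p"]) for e in table.index},
        pm=pm, pm_valid=pm_valid, median_diff=md, median_diff_ci=md_ci,
        reference_hazard=lam, n=len(df), n_events=int(df["event"].sum()),
        mediator_table=mediator_fit.summary(),
        outcome_table=outcome_fit.summary(),
        c_cond=config_eval.c_cond, interaction=config.interaction,
    )


def _bootstrap_cis(cohort: Cohort, ps_scores: pd.Series,
                   config: MediationConfig, conf_level: float = 0.95
                   ) -> pd.DataFrame:
    """Seeded nonparametric bootstrap percentile intervals (row resampling)."""
    rng = np.random.default_rng(config.seed)
    df = cohort.df.reset_index(drop=True)
    ps = ps_scores.reindex(df["id"]).to_numpy(dtype=float)
    draws = np.empty((config.bootstrap_reps, 3))
    draws.fill(np.nan)
    for r in range(config.bootstrap_reps):
        idx = rng.integers(0, len(df), len(df))
        bdf, bps = df.iloc[idx], ps[idx]
        try:
            Xm, Xo = _mediation_designs(bdf, bps, config)
            mfit = sc.fit_logistic(bdf[config.mediator], Xm)
            ofit = sc.fit_exp_aft(bdf["os_months"], bdf["event"], Xo)
            nde, nie = natural_effects(mfit, ofit, config)
            draws[r] = [nde, nie, nde + nie]
        except sc.FitError:
            continue  # degenerate resample; skipped, reflected in the count
    ok = ~np.isnan(draws[:, 0])
    if ok.sum() < config.bootstrap_reps * 0.5:
        raise sc.FitError("more than half of bootstrap resamples failed")
    lo_q, hi_q = (1 - conf_level) / 2, 1 - (1 - conf_level) / 2
    # point estimates from the full sample
    Xm, Xo = _mediation_designs(df, ps, config)
    mfit = sc.fit_logistic(df[config.mediator], Xm)
    ofit = sc.fit_exp_aft(df["os_months"], df["event"], Xo)
    nde, nie = natural_effects(mfit, ofit, config)
    logtr = np.array([nde, nie, nde + nie])
    se = np.std(draws[ok], axis=0, ddof=1)
    # percentile interval on the logTR scale, then mapped to HR (swap)
    tr_lo = np.quantile(draws[ok], lo_q, axis=0)
    tr_hi = np.quantile(draws[ok], hi_q, axis=0)
    hr_lo, hr_hi = np.exp(-tr_hi), np.exp(-tr_lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, logtr / se, np.inf * np.sign(logtr))
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(zstat)),
                 np.where(logtr == 0, 1.0, 0.0))
    return pd.DataFrame(
        {"logTR": logtr, "se": se, "hr": np.exp(-logtr), "hr_lower": hr_lo,
         "hr_upper": hr_hi, "p": p},
        index=["nde", "nie", "te"],
    )


def subgroup_mediation(cohort: Cohort, ps_scores: pd.Series, strata: str,
                       config: MediationConfig | None = None) -> dict:
    """Run the decomposition independently within each stratum.

    Strata with no events are skipped with a warning; strata with fewer
    events than ``config.event_floor`` are returned flagged underpowered.
    """
    config = config or MediationConfig()
    df = cohort.df
    if strata not in df.columns:
        raise KeyError(f"strata column {strata!r} not in cohort")
    out = {}
    for level in sorted(df[strata].unique(), key=str):
        sub = df[df[strata] == level]
        if sub["event"].sum() == 0:
            log.warning("stratum %s=%r has no events; skipped", strata, level)
            continue
        sub_cohort = Cohort(df=sub.reset_index(drop=True),
                            provenance=cohort.provenance,
                            note=f"{strata}={level}")
        res = mediate(sub_cohort, ps_scores, config)
        if res.n_events < config.event_floor:
            res.underpowered = True
        out[level] = res
    return out
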