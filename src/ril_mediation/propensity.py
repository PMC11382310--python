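"""Propensity-score construction and optimal 1:1 matching.

The propensity model follows the two-step screening convention of
retrospective modality comparisons: univariate screening of candidate
confounders against both treatment assignment (logistic) and overall
survival (Cox), then a multivariable logistic model reduced by backward
elimination with a set of mandatorily retained covariates (age and surgical
status by default). Matching solves the bipartite assignment problem that
minimises the total absolute pairwise distance between propensity scores —
"optimal" matching, as opposed to greedy nearest-neighbour — via the
Jonker-Volgenant solver in scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logit

from .cohort_io import Cohort
from .synthetic_cohort import CovariateSpec, feature_matrix
from . import survival_core as sc

log = logging.getLogger(__name__)

#: cohort columns usable as candidates -> design-matrix feature columns
CANDIDATE_FEATURES = {
    "age": ["z_age"],
    "sex": ["male"],
    "baseline_alc": ["z_alc"],
    "ptv": ["z_logptv"],
    "ecog": ["ecog0"],
    "location": ["lower"],
    "stage": ["stage_ii", "stage_iii"],
    "chemo_cycles": ["z_chemo"],
    "barretts": ["barretts"],
    "histology": ["scc"],
    "surgery": ["surgery"],
}

DEFAULT_FORCED = ("age", "surgery")


def design_matrix(cohort: Cohort, candidates) -> pd.DataFrame:
    """Dummy-coded / standardized design columns for the given candidates."""
    unknown = set(candidates) - set(CANDIDATE_FEATURES)
    if unknown:
        raise KeyError(f"unknown candidate covariate(s): {sorted(unknown)}")
    Z = feature_matrix(cohort.df, CovariateSpec())
    cols = [f for c in candidates for f in CANDIDATE_FEATURES[c]]
    return Z[cols]


@dataclass
class PSModel:
    """Fitted propensity model: P(A=1 | C) per patient."""

    selected_covariates: list
    fit: sc.FitResult | None
    scores: pd.Series  # indexed by patient id, strictly in (0, 1)
    forced: tuple = ()

    def __post_init__(self) -> None:
        s = self.scores.to_numpy()
        if np.any(s <= 0) or np.any(s >= 1):
            raise ValueError("propensity scores must lie strictly in (0, 1)")
        if not set(self.forced) <= set(self.selected_covariates):
            raise ValueError("forced covariates must be among the selected")

    @property
    def coefficients(self) -> pd.Series:
        return self.fit.coefficients


@dataclass
class MatchedPairs:
    """Globally optimal 1:1 pairing of exposed and unexposed patients."""

    pairs: list  # [(treated_id, control_id), ...]
    total_distance: float
    distance_scale: str  # {"probability", "logit"}

    def __post_init__(self) -> None:
        ids = [i for p in self.pairs for i in p]
        if len(ids) != len(set(ids)):
            raise ValueError("a patient id appears in more than one pair")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


def univariate_screen(cohort: Cohort, candidates, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Screen candidates against exposure (logistic) and survival (Cox).

    Per candidate: the log-OR for treatment assignment and the log-HR for
    overall survival with their Wald p-values (for multi-level candidates,
    the minimum p across dummy columns), plus a ``significant`` flag at
    level ``alpha`` for either endpoint. Constant covariates are excluded
    with a warning; separation trips a guard and flags the candidate.
    """
    df = cohort.df
    a = df["modality"].to_numpy(dtype=float)
    rows = []
    for cand in candidates:
        X = design_matrix(cohort, [cand])
        if X.nunique().max() <= 1:
            log.warning("candidate %s is constant; excluded from screening", cand)
            rows.append({"candidate": cand, "logor": np.nan, "logor_p": np.nan,
                         "loghr": np.nan, "loghr_p": np.nan,
                         "significant": False, "note": "constant; excluded"})
            continue
        note = ""
        try:
            lfit = sc.fit_logistic(a, X)
            j = lfit.pvalues.drop("intercept").idxmin()
            logor, logor_p = lfit.coefficients[j], lfit.pvalues[j]
        except sc.SeparationError as exc:
            log.warning("separation guard for %s: %s", cand, exc)
            logor, logor_p, note = np.nan, 0.0, "separation guard"
        try:
            cfit = sc.fit_cox(df["os_months"], df["event"], X)
            j = cfit.pvalues.idxmin()
            loghr, loghr_p = cfit.coefficients[j], cfit.pvalues[j]
        except sc.FitError as exc:
            log.warning("Cox screen guard for %s: %s", cand, exc)
            loghr, loghr_p = np.nan, np.nan
            note = (note + "; " if note else "") + "cox guard"
        rows.append({
            "candidate": cand, "logor": logor, "logor_p": logor_p,
            "loghr": loghr, "loghr_p": loghr_p,
            "significant": bool(min(logor_p, loghr_p) < alpha), "note": note,
        })
    return pd.DataFrame(rows)


def fit_ps_model(cohort: Cohort, candidates, forced=DEFAULT_FORCED,
                 criterion: str = "wald_p", threshold: float = 0.05) -> PSModel:
    """Backward elimination from the full multivariable logistic model.

    Repeatedly drops the non-forced candidate whose worst dummy-column Wald
    p exceeds ``threshold`` (criterion "wald_p") or whose removal lowers the
    AIC (criterion "aic"), refitting after each removal; forced covariates
    are never candidates for removal.
    """
    if not set(forced) <= set(candidates):
        raise ValueError("candidates must include every forced covariate")
    if criterion not in ("wald_p", "aic"):
        raise ValueError("criterion must be 'wald_p' or 'aic'")
    current = list(candidates)
    a = cohort.df["modality"].to_numpy(dtype=float)

    def _fit(cands):
        try:
            return sc.fit_logistic(a, design_matrix(cohort, cands))
        except sc.FitError as exc:
            raise sc.FitError(
                f"propensity refit failed for covariate set {cands}: {exc}"
            ) from exc

    fit = _fit(current)
    while True:
        removable = [c for c in current if c not in forced]
        if not removable:
            break
        if criterion == "wald_p":
            # worst candidate = largest minimum-p across its dummy columns
            worst, worst_p = None, threshold
            for c in removable:
                p = min(fit.pvalues[f] for f in CANDIDATE_FEATURES[c])
                if p > worst_p:
                    worst, worst_p = c, p
            if worst is None:
                break
            current.remove(worst)
            fit = _fit(current)
        else:
            aic = 2 * len(fit.coefficients) - 2 * fit.loglik
            best, best_fit, best_aic = None, None, aic
            for c in removable:
                trial = [x for x in current if x != c]
                tfit = _fit(trial)
                taic = 2 * len(tfit.coefficients) - 2 * tfit.loglik
                if taic < best_aic:
                    best, best_fit, best_aic = c, tfit, taic
            if best is None:
                break
            current.remove(best)
            fit = best_fit

    X = design_matrix(cohort, current)
    from scipy.special import expit
    eta = fit.coefficients["intercept"] + X.to_numpy() @ fit.coefficients.drop(
        "intercept").to_numpy()
    scores = pd.Series(expit(eta), index=cohort.df["id"].to_numpy(),
                       name="propensity")
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    return PSModel(selected_covariates=current, fit=fit, scores=scores,
                   forced=tuple(forced))


def optimal_match(ps_model: PSModel, cohort: Cohort,
                  distance_scale: str = "logit",
                  caliper: float | None = None) -> MatchedPairs:
    """1:1 matching minimising the total absolute pairwise distance.

    Solves the rectangular assignment problem exactly; the logit scale is the
    default distance (more uniform discrimination near scores of 0 and 1),
    with the raw probability scale available. Patients are ordered by id
    before solving so ties break deterministically. An optional caliper
    (same scale as the distance) drops matched pairs wider than the caliper
    after the optimal solution is found.
    """
    if distance_scale not in ("probability", "logit"):
        raise ValueError("distance_scale must be 'probability' or 'logit'")
    df = cohort.df
    treated = sorted(df.loc[df["modality"] == 1, "id"])
    control = sorted(df.loc[df["modality"] == 0, "id"])
    if not treated or not control:
        raise ValueError("both exposure arms must be non-empty")
    s = ps_model.scores
    d = s if distance_scale == "probability" else pd.Series(
        logit(s.to_numpy()), index=s.index)
    cost = np.abs(d[treated].to_numpy()[:, None] - d[control].to_numpy()[None, :])
    ri, ci = linear_sum_assignment(cost)
    pairs = [(treated[i], control[j]) for i, j in zip(ri, ci)]
    dists = cost[ri, ci]
    if caliper is not None:
        keep = dists <= caliper
        pairs = [p for p, k in zip(pairs, keep) if k]
        dists = dists[keep]
    pairs.sort()
    return MatchedPairs(pairs=pairs, total_distance=float(dists.sum()),
                        distance_scale=distance_scale)


def matched_cohort(cohort: Cohort, matches: MatchedPairs) -> Cohort:
    """Restrict the cohort to matched patients (provenance 'matched')."""
    keep = {i for p in matches.pairs for i in p}
    df = cohort.df[cohort.df["id"].isin(keep)].reset_index(drop=True)
    return Cohort(df=df, provenance="matched",
                  note=f"{len(matches.pairs)} pairs from {cohort.provenance} cohort")


def standardized_mean_differences(cohort: Cohort, candidates) -> pd.Series:
    """Per-feature SMD between exposure arms: (mean1 - mean0) / pooled SD."""
    Z = design_matrix(cohort, candidates)
    a = cohort.df["modality"].to_numpy()
    z1, z0 = Z[a == 1], Z[a == 0]
    num = z1.mean() - z0.mean()
    den = np.sqrt((z1.var(ddof=1) + z0.var(ddof=1)) / 2)
    smd = num / den
    return smd.where(den > 0, 0.0)


def match_diagnostics(cohort: Cohort, matches: MatchedPairs,
                      candidates=None) -> pd.DataFrame:
    """Covariate balance before vs after matching.

    Standardized mean differences per design feature in the full and matched
    cohorts; |SMD| < 0.1 is the usual benchmark for adequate balance.
    """
    if candidates is None:
        candidates = list(CANDIDATE_FEATURES)
    before = standardized_mean_differences(cohort, candidates)
    after = standardized_mean_differences(matched_cohort(cohort, matches),
                                          candidates)
    out = pd.DataFrame({"smd_before": before, "smd_after": after})
    out["balanced_after"] = out["smd_after"].abs() < 0.1
    return out


def greedy_match_distance(ps_model: PSModel, cohort: Cohort,
                          distance_scale: str = "logit") -> float:
    """Total distance of greedy nearest-neighbour matching (benchmark only:
    optimal matching is never worse)."""
    df = cohort.df
    treated = sorted(df.loc[df["modality"] == 1, "id"])
    control = sorted(df.loc[df["modality"] == 0, "id"])
    s = ps_model.scores
    d = s if distance_scale == "probability" else pd.Series(
        logit(s.to_numpy()), index=s.index)
    avail = {c: d[c] for c in control}
    total = 0.0
    for t in treated[: min(len(treated), len(control))]:
        best = min(avail, key=lambda c: (abs(d[t] - avail[c]), c))
        total += abs(d[t] - avail.pop(best))
        if not avail:
            break
    return total
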