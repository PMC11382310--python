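"""Natural-effect closed forms vs brute-force oracles, delta/bootstrap CIs,
proportion mediated, and the median-survival conversion."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ril_mediation import (
    MediationConfig, default_paper_params, fit_exp_aft, fit_logistic,
    mediate, natural_effects, nie_to_median_diff, null_mediation_params,
    proportion_mediated, simulate_cohort, subgroup_mediation, to_hazard_scale,
)
from ril_mediation.mediation import _log_effects, effect_cis
from ril_mediation.survival_core import FitResult


def summation_oracle(b0, b1, bc, t1, t2, t3, tc, c, a=1.0, astar=0.0):
    """Counterfactual mean survival by direct summation over M in {0, 1}."""

    def expected_time(x_outcome, x_mediator):
        p = expit(b0 + b1 * x_mediator + np.dot(bc, c))
        k = t2 + t3 * x_outcome
        return np.exp(t1 * x_outcome + np.dot(tc, c)) * (
            (1 - p) + p * np.exp(k))

    nie = np.log(expected_time(a, a) / expected_time(a, astar))
    nde = np.log(expected_time(a, astar) / expected_time(astar, astar))
    return nde, nie


def _random_fits(rng, n_cov, interaction=True):
    bc = rng.normal(0, 0.5, n_cov)
    tc = rng.normal(0, 0.5, n_cov)
    b0, b1 = rng.normal(0, 1, 2)
    t1, t2, t3 = rng.normal(0, 0.5, 3)
    if not interaction:
        t3 = 0.0
    c = rng.normal(0, 1, n_cov)
    return b0, b1, bc, t1, t2, t3, tc, c


def _make_fit(kind, names, values, cov=None):
    k = len(values)
    cov = np.eye(k) * 0.01 if cov is None else cov
    return FitResult(
        model_kind=kind,
        coefficients=pd.Series(values, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik=0.0, n=100, n_events=50,
    )


@pytest.mark.parametrize("interaction", [True, False])
def test_closed_form_equals_summation_oracle(interaction):
    rng = np.random.default_rng(0)
    for _ in range(100):
        n_cov = int(rng.integers(0, 3))
        b0, b1, bc, t1, t2, t3, tc, c = _random_fits(rng, n_cov, interaction)
        covn = [f"c{i}" for i in range(n_cov)]
        cfg = MediationConfig(interaction=interaction,
                              c_cond=dict(zip(covn, c)))
        tnames = ["intercept", "modality", "g4ril"]
        tvals = [0.0, t1, t2]
        if interaction:
            tnames += ["modality:g4ril"]
            tvals += [t3]
        nde, nie = _log_effects(
            np.r_[b0, b1, bc], ["intercept", "modality", *covn],
            np.r_[tvals, tc], tnames + covn, cfg, dict(zip(covn, c)))
        onde, onie = summation_oracle(b0, b1, bc, t1, t2, t3, tc, c)
        assert abs(nde - onde) < 1e-10
        assert abs(nie - onie) < 1e-10


def test_closed_form_within_monte_carlo_error():
    """Counterfactual simulation oracle: draw M from its counterfactual
    distribution and T from the AFT model, 10^6 draws per expectation."""
    rng = np.random.default_rng(1)
    for _ in range(3):
        b0, b1, bc, t1, t2, t3, tc, c = _random_fits(rng, 0)
        n = 10 ** 6
        u = rng.random(n)  # common random numbers across counterfactuals
        e = rng.standard_exponential(n)

        def mc_expected_time(x_outcome, x_mediator):
            m = u < expit(b0 + b1 * x_mediator)
            t = np.exp(t1 * x_outcome + (t2 + t3 * x_outcome) * m) * e
            return t.mean(), t.std() / np.sqrt(n)

        (maa, saa), (mas, sas), (mss, sss) = (
            mc_expected_time(1, 1), mc_expected_time(1, 0),
            mc_expected_time(0, 0))
        cfg = MediationConfig(interaction=True, c_cond={})
        nde, nie = _log_effects(
            np.r_[b0, b1], ["intercept", "modality"],
            np.r_[0.0, t1, t2, t3],
            ["intercept", "modality", "g4ril", "modality:g4ril"], cfg, {})
        se_nie = np.hypot(saa / maa, sas / mas)
        se_nde = np.hypot(sas / mas, sss / mss)
        assert abs(np.log(maa / mas) - nie) < 3 * se_nie
        assert abs(np.log(mas / mss) - nde) < 3 * se_nde


def test_zero_mediator_effect_forces_null_nie():
    mfit = _make_fit("logistic", ["intercept", "modality"], [0.3, -1.0])
    ofit = _make_fit("exp_aft", ["intercept", "modality", "g4ril"],
                     [3.0, 0.2, 0.0])
    nde, nie = natural_effects(mfit, ofit, MediationConfig(c_cond={}))
    assert abs(nie) < 1e-15
    assert abs(nde - 0.2) < 1e-15


def test_zero_exposure_mediator_path_forces_null_nie():
    mfit = _make_fit("logistic", ["intercept", "modality"], [0.3, 0.0])
    ofit = _make_fit("exp_aft", ["intercept", "modality", "g4ril"],
                     [3.0, 0.2, -0.4])
    _, nie = natural_effects(mfit, ofit, MediationConfig(c_cond={}))
    assert abs(nie) < 1e-15


def test_interaction_flag_must_match_design():
    mfit = _make_fit("logistic", ["intercept", "modality"], [0.3, -1.0])
    ofit = _make_fit("exp_aft", ["intercept", "modality", "g4ril"],
                     [3.0, 0.2, -0.4])
    with pytest.raises(ValueError, match="interaction"):
        natural_effects(mfit, ofit, MediationConfig(interaction=True,
                                                    c_cond={}))
    no_mediator = _make_fit("exp_aft", ["intercept", "modality"], [3.0, 0.2])
    with pytest.raises(ValueError, match="mediator"):
        natural_effects(mfit, no_mediator, MediationConfig(c_cond={}))


def test_to_hazard_scale():
    assert to_hazard_scale(0.0) == 0.0
    assert np.isclose(np.exp(to_hazard_scale(np.log(2.0))), 0.5)
    assert np.isclose(to_hazard_scale(0.1, shape=2.0), -0.2)


def test_proportion_mediated_identities():
    pm, valid = proportion_mediated(np.log(0.8), 0.0)
    assert pm == 0.0 and valid
    pm, _ = proportion_mediated(0.0, np.log(0.9))
    assert abs(pm - 1.0) < 1e-12
    pm, valid = proportion_mediated(np.log(0.79), np.log(0.95))
    assert round(pm, 3) == 0.158
    assert valid
    # harmful total effect: share not interpretable
    _, valid = proportion_mediated(np.log(1.3), np.log(1.1))
    assert not valid
    pm, valid = proportion_mediated(0.0, 0.0)
    assert np.isnan(pm) and not valid


def test_median_difference_conversion():
    d, _ = nie_to_median_diff(1.0, reference_median=40.9)
    assert d == 0.0
    d, _ = nie_to_median_diff(0.95, reference_median=40.9)
    assert round(d, 2) == 2.15
    d, _ = nie_to_median_diff(0.5, reference_hazard=np.log(2) / 50)
    assert abs(d - 50.0) < 1e-12
    d, ci = nie_to_median_diff(0.95, ci_nie=(0.91, 0.99),
                               reference_median=40.9)
    assert ci[0] < d < ci[1]
    with pytest.raises(ValueError):
        nie_to_median_diff(-0.5, reference_median=40.9)
    with pytest.raises(ValueError):
        nie_to_median_diff(0.9)


def test_delta_ci_degenerate_when_mediator_coefficients_fixed_zero():
    mfit = _make_fit("logistic", ["intercept", "modality"], [0.3, -1.0])
    names = ["intercept", "modality", "g4ril"]
    cov = np.diag([0.01, 0.01, 0.0])  # mediator coefficient known exactly
    ofit = _make_fit("exp_aft", names, [3.0, 0.2, 0.0], cov)
    table = effect_cis(mfit, ofit, MediationConfig(c_cond={}))
    assert table.loc["nie", "se"] < 1e-9
    assert np.allclose(table.loc["nie", ["hr_lower", "hr", "hr_upper"]], 1.0)


def test_mediate_decomposition_identity_and_recovery(matched_setup,
                                                     default_cohort):
    ps, matches = matched_setup
    from ril_mediation.propensity import matched_cohort

    mc = matched_cohort(default_cohort, matches)
    res = mediate(mc, ps.scores)
    assert abs(res.logtr_te - res.logtr_nde - res.logtr_nie) < 1e-12
    assert abs(res.hr_te - res.hr_nde * res.hr_nie) < 1e-12
    # generator has a protective direct effect and a harmful mediator that
    # protons avoid: both components should point below 1
    assert res.hr_nie < 1
    assert res.hr_nde < 1
    assert res.ci["nie"][0] < res.hr_nie < res.ci["nie"][1]
    assert res.pm_valid
    assert res.median_diff > 0


def test_mediate_null_calibration():
    """With no exposure->mediator path the NIE interval should cover the
    null in about 95% of replicates."""
    covered = 0
    reps = 100
    rng = np.random.default_rng(99)
    for seed in range(reps):
        cohort = simulate_cohort(null_mediation_params(n=800, seed=300 + seed))
        # assignment is unconfounded, so any score column is pure noise
        ps = pd.Series(rng.uniform(0.3, 0.7, len(cohort)),
                       index=cohort.df["id"].to_numpy())
        res = mediate(cohort, ps)
        lo, hi = res.ci["nie"]
        covered += lo <= 1.0 <= hi
    assert covered >= 0.89 * reps


def test_effects_invariant_to_time_units(matched_setup, default_cohort):
    ps, matches = matched_setup
    from ril_mediation.cohort_io import Cohort
    from ril_mediation.propensity import matched_cohort

    mc = matched_cohort(default_cohort, matches)
    res_months = mediate(mc, ps.scores)
    days = mc.df.copy()
    days["os_months"] = days["os_months"] * 30.4375
    res_days = mediate(Cohort(df=days, provenance="matched"), ps.scores)
    assert abs(res_months.logtr_nie - res_days.logtr_nie) < 1e-8
    assert abs(res_months.logtr_nde - res_days.logtr_nde) < 1e-8
    assert abs(res_months.pm - res_days.pm) < 1e-8


def test_bootstrap_agrees_with_delta(matched_setup, default_cohort):
    ps, matches = matched_setup
    from ril_mediation.propensity import matched_cohort

    mc = matched_cohort(default_cohort, matches)
    delta = mediate(mc, ps.scores, MediationConfig(ci_method="delta"))
    boot = mediate(mc, ps.scores, MediationConfig(
        ci_method="bootstrap", bootstrap_reps=400, seed=17))
    for eff in ("nie", "nde"):
        for i in (0, 1):
            assert abs(boot.ci[eff][i] - delta.ci[eff][i]) \
                / delta.ci[eff][i] < 0.15


def test_subgroup_constant_stratum_matches_pooled(matched_setup,
                                                  default_cohort):
    ps, matches = matched_setup
    from ril_mediation.propensity import matched_cohort

    mc = matched_cohort(default_cohort, matches)
    pooled = mediate(mc, ps.scores)
    const = mc.df.copy()
    const["barretts"] = 0
    from ril_mediation.cohort_io import Cohort

    subs = subgroup_mediation(Cohort(df=const, provenance="matched"),
                              ps.scores, "barretts")
    assert list(subs) == [0]
    assert abs(subs[0].logtr_nie - pooled.logtr_nie) < 1e-12


def test_subgroup_exchangeable_strata_agree():
    """Identical mechanisms in both strata: NIE estimates within 3 SEs."""
    p = default_paper_params(n=8000, seed=77)
    beta = {k: v for k, v in p.beta.items() if k != "surgery"}
    theta = {k: v for k, v in p.theta.items() if k != "surgery"}
    cohort = simulate_cohort(replace(p, beta=beta, theta=theta))
    ps = pd.Series(np.random.default_rng(5).uniform(0.3, 0.7, len(cohort)),
                   index=cohort.df["id"].to_numpy())
    subs = subgroup_mediation(cohort, ps, "surgery")
    r0, r1 = subs[0], subs[1]
    se = np.hypot(r0.se["nie"], r1.se["nie"])
    assert abs(r0.logtr_nie - r1.logtr_nie) < 3 * se
    assert r0.hr_nie < 1 and r1.hr_nie < 1


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(hr_nie=st.floats(0.2, 3.0), ref_median=st.floats(5.0, 120.0))
def test_median_gain_sign_and_scaling(hr_nie, ref_median):
    """The mediated median gain is positive exactly when the indirect effect
    is protective, and scales linearly with the reference median."""
    d1, _ = nie_to_median_diff(hr_nie, reference_median=ref_median)
    d2, _ = nie_to_median_diff(hr_nie, reference_median=2 * ref_median)
    if hr_nie < 1:
        assert d1 > 0
    elif hr_nie > 1:
        assert d1 < 0
    assert np.isclose(d2, 2 * d1)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(loghr_nde=st.floats(-1.0, 1.0), loghr_nie=st.floats(-1.0, -1e-3))
def test_pm_between_zero_and_one_for_concordant_protective_effects(
        loghr_nde, loghr_nie):
    """When both components are protective the mediated share is a proper
    fraction and the validity flag is set."""
    if loghr_nde > -1e-3:
        loghr_nde = -1e-3  # keep both effects strictly protective
    pm, valid = proportion_mediated(loghr_nde, loghr_nie)
    assert 0.0 < pm < 1.0
    assert valid


def test_subgroup_underpowered_flag(default_cohort, matched_setup):
    ps, matches = matched_setup
    from ril_mediation.propensity import matched_cohort

    mc = matched_cohort(default_cohort, matches)
    cfg = MediationConfig(event_floor=10 ** 6)
    subs = subgroup_mediation(mc, ps.scores, "surgery", cfg)
    assert all(r.underpowered for r in subs.values())
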