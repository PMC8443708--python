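"""Decision-tree cost-effectiveness model: enumeration, payoffs, NMB, PSA."""

import dataclasses
import json

import numpy as np
import pytest

from cusdvt import econ
from cusdvt.econ import (DistributionSpec, EconConfig, OUTCOMES, OutcomePayoff,
                         PathwaySpec, TestSpec)


@pytest.fixture(scope="module")
def params():
    return econ.load_params(warn=False)


@pytest.fixture(scope="module")
def tests_ml(params):
    return econ.default_tests(params, ml_sensitivity=0.89, ml_specificity=0.76)


# ---------------------------------------------------------------------------
# Parameter encodings
# ---------------------------------------------------------------------------

def test_flagged_rows_are_exactly_the_documented_inconsistencies(params):
    assert set(params.flagged_specs()) == {
        "wells_cost", "us_cost", "treated_fatal_pe", "warfarin_split"}


def test_load_emits_warnings_for_flagged_rows():
    with pytest.warns(econ.InconsistentParameterWarning):
        econ.load_params(warn=True)


def test_unflagged_means_match_printed(params):
    for spec in params.all_specs():
        if spec.flagged or isinstance(spec, econ.DirichletSpec):
            continue
        if spec.printed_mean is None or spec.family == "fixed":
            continue
        tol = max(0.005, 0.005 * abs(spec.printed_mean))
        assert abs(spec.analytic_mean() - spec.printed_mean) <= tol, spec.name


def test_dirichlet_means_are_count_fractions(params):
    w = params.wells_dvt_split
    assert w.analytic_mean() == pytest.approx(
        np.asarray(w.counts) / np.sum(w.counts))
    assert np.isclose(sum(w.mean().values()), 1.0)


def test_beta_and_dirichlet_sampling_match_analytic_means(params, rng):
    n = 20_000
    draws = params.prevalence.sample(np.random.default_rng(0), n)
    a, b = params.prevalence.params["a"], params.prevalence.params["b"]
    mean, var = a / (a + b), a * b / ((a + b) ** 2 * (a + b + 1))
    assert abs(draws.mean() - mean) < 3 * np.sqrt(var / n)

    d = params.warfarin_split.sample(np.random.default_rng(1), n)
    target = params.warfarin_split.analytic_mean()
    se = np.sqrt(target * (1 - target) / n)
    assert np.all(np.abs(d.mean(axis=0) - target) < 4 * se + 1e-4)


# ---------------------------------------------------------------------------
# Outcome enumeration
# ---------------------------------------------------------------------------

def test_single_perfect_test_splits_by_prevalence():
    t = {"t": TestSpec(name="t", cost=0.0, sensitivity=1.0, specificity=1.0)}
    pw = PathwaySpec("x", "single perfect test", {
        "test": "t", "children": {"positive": {"leaf": "treat"},
                                  "negative": {"leaf": "no_treat"}}})
    lik, usage = econ.outcome_likelihoods(pw, 0.147, t)
    assert lik == pytest.approx({"tp": 0.147, "fp": 0.0, "tn": 0.853, "fn": 0.0})
    assert usage["t"] == 1.0


def test_single_ultrasound_test_two_by_two():
    t = {"us": TestSpec(name="us", cost=77.19, sensitivity=0.95, specificity=0.94)}
    pw = PathwaySpec("x", "ultrasound only", {
        "test": "us", "children": {"positive": {"leaf": "treat"},
                                   "negative": {"leaf": "no_treat"}}})
    lik, _ = econ.outcome_likelihoods(pw, 0.147, t)
    assert lik["tp"] == pytest.approx(0.13965)
    assert lik["fn"] == pytest.approx(0.00735)
    assert lik["tn"] == pytest.approx(0.80182)
    assert lik["fp"] == pytest.approx(0.05118)


@pytest.mark.parametrize("variant", list("abcdef"))
def test_conservation_for_every_preset(params, tests_ml, variant):
    pw = econ.build_pathway_preset(variant)
    lik, usage = econ.outcome_likelihoods(pw, 0.147, tests_ml)
    assert sum(lik.values()) == pytest.approx(1.0, abs=1e-12)
    assert lik["tp"] + lik["fn"] == pytest.approx(0.147, abs=1e-12)
    assert all(0 <= u <= 1 for u in usage.values())


def test_rule_out_step_only_adds_false_negatives(params):
    """A perfectly sensitive triage exam introduces no new missed cases."""
    tests_perfect = econ.default_tests(params, ml_sensitivity=1.0,
                                       ml_specificity=0.76)
    us_only = PathwaySpec("x", "us", {
        "test": "ultrasound", "children": {"positive": {"leaf": "treat"},
                                           "negative": {"leaf": "no_treat"}}})
    lik_direct, _ = econ.outcome_likelihoods(us_only, 0.147, tests_perfect)
    lik_triaged, _ = econ.outcome_likelihoods(
        econ.build_pathway_preset("b"), 0.147, tests_perfect)
    assert lik_triaged["fn"] == pytest.approx(lik_direct["fn"], abs=1e-12)


def test_pathway_validation_rejects_malformed_trees(tests_ml):
    bad_leaf = PathwaySpec("x", "bad", {"leaf": "maybe_treat"})
    with pytest.raises(ValueError):
        econ.outcome_likelihoods(bad_leaf, 0.1, tests_ml)
    missing_result = PathwaySpec("x", "bad", {
        "test": "ultrasound", "children": {"positive": {"leaf": "treat"}}})
    with pytest.raises(ValueError, match="result map"):
        econ.outcome_likelihoods(missing_result, 0.1, tests_ml)


def test_pathway_json_round_trip():
    pw = econ.build_pathway_preset("c")
    again = PathwaySpec.from_json(pw.to_json())
    assert again == pw


# ---------------------------------------------------------------------------
# Expected outcomes / NMB / ICER
# ---------------------------------------------------------------------------

def test_all_true_negative_cohort(params):
    lik = {"tp": 0.0, "fp": 0.0, "tn": 1.0, "fn": 0.0}
    r = econ.expected_outcomes(lik, {}, params.payoffs, {},
                               EconConfig(prevalence=1e-9))
    assert r.expected_qalys == pytest.approx(11.580)
    assert r.expected_cost == 0.0


def test_outcome_cost_projection(params, tests_ml):
    pw = econ.build_pathway_preset("a")
    lik, usage = econ.outcome_likelihoods(pw, 0.147, tests_ml)
    r = econ.expected_outcomes(lik, usage, params.payoffs,
                               {k: 0.0 for k in usage}, EconConfig())
    pure = sum(lik[o] * params.payoffs.costs[o] for o in OUTCOMES)
    assert r.expected_cost == pytest.approx(pure)


def test_nmb_identical_results_is_zero(params, tests_ml):
    r = econ.evaluate_pathway(econ.build_pathway_preset("b"), tests_ml,
                              params.payoffs, EconConfig())
    assert econ.nmb(r, r, 20_000.0, 0.0) == pytest.approx(0.0)


def test_nmb_affine_in_software_cost(params, tests_ml):
    cfg = EconConfig()
    base = econ.evaluate_pathway(econ.build_pathway_preset("a"), tests_ml,
                                 params.payoffs, cfg)
    for variant in "bcdef":
        r = econ.evaluate_pathway(econ.build_pathway_preset(variant), tests_ml,
                                  params.payoffs, cfg)
        n0 = econ.nmb(r, base, 20_000.0, 0.0)
        n50 = econ.nmb(r, base, 20_000.0, 50.0)
        n100 = econ.nmb(r, base, 20_000.0, 100.0)
        slope = (n50 - n0) / 50.0
        assert slope == pytest.approx(-r.software_usage, abs=1e-9)
        assert n100 == pytest.approx(n0 + 100 * slope, abs=1e-9)


def test_nmb_curve_break_even(params, tests_ml):
    cfg = EconConfig()
    base = econ.evaluate_pathway(econ.build_pathway_preset("a"), tests_ml,
                                 params.payoffs, cfg)
    r = econ.evaluate_pathway(econ.build_pathway_preset("b"), tests_ml,
                              params.payoffs, cfg)
    curves = econ.nmb_curve({"b": r}, base, 20_000.0, np.arange(0, 301, 10))
    c = curves["b"]
    assert np.all(np.diff(c["nmb"]) <= 1e-12)
    if c["break_even"] is not None:
        assert econ.nmb(r, base, 20_000.0, c["break_even"]) == pytest.approx(0.0, abs=1e-9)


def test_icer_quadrants():
    def result(cost, qalys):
        lik = {"tp": 0.1, "fp": 0.0, "tn": 0.9, "fn": 0.0}
        return econ.EconResult(likelihoods=lik, usage={}, expected_qalys=qalys,
                               expected_cost=cost, base_cost=cost,
                               software_usage=0.0, prevalence=0.1)
    a, b = result(100.0, 11.5), result(160.0, 11.5)
    assert econ.icer(a, b)["flag"] == "cost_saving"
    assert econ.icer(b, a)["flag"] == "cost_minimisation"
    c = result(90.0, 11.6)
    assert econ.icer(c, b)["flag"] == "dominant"
    assert econ.icer(b, c)["flag"] == "dominated"
    d = result(200.0, 11.51)
    out = econ.icer(d, a)
    assert out["ratio"] == pytest.approx(100.0 / 0.01)
    swapped = econ.icer(a, d)
    assert swapped["delta_cost"] == -out["delta_cost"]
    assert swapped["delta_qalys"] == pytest.approx(-out["delta_qalys"])


# ---------------------------------------------------------------------------
# Payoff derivation
# ---------------------------------------------------------------------------

def test_derive_payoffs_limits(params):
    q, c = econ.derive_payoffs({}, {}, base_qale=11.58,
                               event_costs=params.event_costs, treated=False)
    assert (q, c) == (11.58, 0.0)
    q, _ = econ.derive_payoffs({"fatal_pe": 1.0}, {}, base_qale=11.58,
                               event_costs=params.event_costs, treated=False)
    assert q == 0.0
    with pytest.raises(ValueError):
        econ.derive_payoffs({"fatal_pe": 1.2}, {}, 11.58,
                            params.event_costs, False)


def test_derived_payoffs_near_printed_table(params):
    derived = econ.derive_all_payoffs(params)
    for o in OUTCOMES:
        assert abs(derived.qalys[o] - params.payoffs.qalys[o]) <= 0.15, o
    # ordering is preserved: untreated DVT worst, true negative best
    assert derived.qalys["fn"] < derived.qalys["tp"]
    assert derived.qalys["tn"] >= derived.qalys["fp"]


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def _all_fixed(params):
    """Replace every sampled distribution with its deterministic value."""
    def fix(spec):
        if isinstance(spec, econ.DirichletSpec):
            return dataclasses.replace(spec, fixed=True)
        return DistributionSpec(name=spec.name, family="fixed",
                                params={"value": spec.mean()},
                                printed_mean=spec.mean())
    changes = {}
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if isinstance(v, (DistributionSpec, econ.DirichletSpec)):
            changes[f.name] = fix(v)
        elif f.name == "ddimer_specificity_by_wells":
            changes[f.name] = {k: fix(s) for k, s in v.items()}
    return dataclasses.replace(params, **changes)


def test_degenerate_psa_equals_deterministic(params):
    fixed = _all_fixed(params)
    pw_b = econ.build_pathway_preset("b")
    pw_a = econ.build_pathway_preset("a")
    cfg = EconConfig()
    out = econ.sample_psa(fixed, pw_b, pw_a, 0.89, 0.76, n_draws=8, seed=3,
                          config=cfg, use_printed_payoffs=True)
    tests = econ.default_tests(fixed, 0.89, 0.76)
    cfg_det = dataclasses.replace(cfg, prevalence=fixed.prevalence.mean())
    det_b = econ.evaluate_pathway(pw_b, tests, fixed.payoffs, cfg_det)
    det_a = econ.evaluate_pathway(pw_a, tests, fixed.payoffs, cfg_det)
    # fixed distributions and fixed prevalence: every draw is the point run
    # (the prevalence beta remains stochastic only if left unfixed)
    assert np.allclose(out["draws"]["cost_with"], det_b.expected_cost)
    assert np.allclose(out["draws"]["qalys_with"], det_b.expected_qalys)
    assert np.allclose(out["draws"]["nmb"],
                       econ.nmb(det_b, det_a, cfg.willingness_to_pay))


def test_psa_summary_shape_and_determinism(params):
    pw_b, pw_a = econ.build_pathway_preset("b"), econ.build_pathway_preset("a")
    o1 = econ.sample_psa(params, pw_b, pw_a, 0.89, 0.76, n_draws=40, seed=9)
    o2 = econ.sample_psa(params, pw_b, pw_a, 0.89, 0.76, n_draws=40, seed=9)
    assert np.array_equal(o1["draws"]["nmb"], o2["draws"]["nmb"])
    s = o1["summary"]["nmb"]
    assert s["q2.5"] <= s["mean"] <= s["q97.5"]
    assert 0.0 <= o1["summary"]["p_nmb_positive"] <= 1.0
    with pytest.raises(ValueError):
        econ.sample_psa(params, pw_b, pw_a, 0.89, 0.76, n_draws=0, seed=1)
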