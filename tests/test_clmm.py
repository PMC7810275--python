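"""Mixed cumulative-link model: probabilities, quadrature, fitting, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logsumexp

import weeddyn as wd
from weeddyn.clmm import (
    FitOptions,
    ModelSpec,
    _log_category_probs,
    aic,
    backward_select,
    conditional_transition_probs,
    encode_design,
    fit_model,
    marginal_loglik,
    selection_table,
    site_marginal_loglik,
)

# --------------------------------------------------------------------------
# design encoding
# --------------------------------------------------------------------------

def _one_pair(**kw):
    base = dict(site_id="A", year=2001, from_level=0, to_level=1,
                land_use="wheat", irrigation=0, delayed_sowing=0,
                temp_dec_apr=7.19, gap=1)
    base.update(kw)
    return pd.DataFrame([base])


def test_baseline_profile_encodes_to_zero_row():
    spec = ModelSpec()
    data = encode_design(_one_pair(), spec)
    # all fixed-effect entries zero except the raw temperature column
    for name, val in zip(data.names, data.X[0]):
        if name == "temperature":
            assert val == 7.19
        else:
            assert val == 0.0


def test_barley_with_irrigation_sets_exactly_two_dummies():
    spec = ModelSpec(terms=frozenset({"irrigation", "land_use"}))
    data = encode_design(_one_pair(land_use="barley", irrigation=1), spec)
    row = dict(zip(data.names, data.X[0]))
    assert row["irrigation"] == 1.0 and row["land_use[barley]"] == 1.0
    assert sum(row.values()) == 2.0


def test_temperature_term_with_missing_value_names_the_site_year():
    spec = ModelSpec()
    with pytest.raises(ValueError, match="A/2001"):
        encode_design(_one_pair(temp_dec_apr=np.nan), spec)


# --------------------------------------------------------------------------
# conditional transition probabilities
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "thresholds, expected",
    [
        ((-1.0, 0.0, 1.0), (0.26894, 0.23106, 0.23106, 0.26894)),
        ((0.0, 1.0, 2.0), (0.50000, 0.23106, 0.14974, 0.11920)),
    ],
)
def test_probabilities_match_hand_evaluated_logistic(thresholds, expected):
    model = wd.make_true_model(thresholds, (0.0, 0.0, 0.0), {}, 0.0,
                               spec=ModelSpec(terms=frozenset()))
    p = conditional_transition_probs(model, 0, {})
    assert np.allclose(p, expected, atol=5e-6)
    assert abs(p.sum() - 1.0) < 1e-12


def test_extreme_negative_predictor_saturates_to_level_zero(toy_model):
    # paddy-like coefficient drives the whole column to "absent"
    p = conditional_transition_probs(
        toy_model, 1, {"land_use[paddy_rice]": 1.0, "irrigation": 0.0})
    assert p[0] > 0.99
    p_inf = conditional_transition_probs(toy_model, 0, {"irrigation": 1e9})
    assert np.allclose(p_inf, [1, 0, 0, 0])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.floats(-8, 8), st.floats(0.01, 6), st.floats(-6, 6), st.floats(-6, 6))
def test_stochastic_monotonicity_in_the_linear_predictor(c1, gap, eta, deta):
    """A larger predictor shifts the whole 4-vector toward higher levels."""
    thresholds = np.array([c1, c1 + gap / 2, c1 + gap])
    lo, hi = min(eta, eta + abs(deta) + 1e-3), max(eta, eta + abs(deta) + 1e-3)
    cum_lo = expit(thresholds - lo)
    cum_hi = expit(thresholds - hi)
    assert np.all(cum_hi < cum_lo)  # stochastic dominance of the shifted vector


def test_probability_vector_sums_to_one_for_every_level(toy_model):
    for i in range(4):
        p = conditional_transition_probs(toy_model, i, {"irrigation": 1.0})
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------

def _toy_loglik(toy_model, toy_site_pairs, sigma, quadrature, n_nodes):
    model = wd.make_true_model(toy_model.thresholds, toy_model.alpha,
                               toy_model.coefs, sigma, spec=toy_model.spec)
    return site_marginal_loglik(model, toy_site_pairs,
                                quadrature=quadrature, n_nodes=n_nodes)


def test_sigma_zero_marginal_is_conditional_sum(toy_model, toy_site_pairs):
    ll0 = _toy_loglik(toy_model, toy_site_pairs, 0.0, "gh", 15)
    spec = toy_model.spec
    data = encode_design(toy_site_pairs, spec)
    beta = np.array([toy_model.coefs.get(n, 0.0) for n in data.names])
    eta = data.X @ beta + np.concatenate(([0.0], toy_model.alpha))[data.from_level]
    direct = _log_category_probs(toy_model.thresholds, eta, data.y).sum()
    assert ll0 == pytest.approx(direct, abs=1e-12)


def _trapezoid_site_loglik(toy_model, toy_site_pairs, sigma):
    """Brute-force oracle: 100 001-point trapezoid over eps in [-8, 8]."""
    data = encode_design(toy_site_pairs, toy_model.spec)
    beta = np.array([toy_model.coefs.get(n, 0.0) for n in data.names])
    eta = data.X @ beta + np.concatenate(([0.0], toy_model.alpha))[data.from_level]
    eps = np.linspace(-8.0, 8.0, 100_001)
    lp = np.array([
        _log_category_probs(toy_model.thresholds, eta + e, data.y).sum()
        for e in eps
    ])
    dens = lp - 0.5 * eps**2 / sigma**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    w = np.full(eps.size, eps[1] - eps[0])
    w[0] /= 2
    w[-1] /= 2
    return float(logsumexp(dens + np.log(w)))


def test_gauss_hermite_agrees_with_trapezoid_oracle(toy_model, toy_site_pairs):
    ll_gh = _toy_loglik(toy_model, toy_site_pairs, 1.0, "gh", 31)
    ll_trap = _trapezoid_site_loglik(toy_model, toy_site_pairs, 1.0)
    assert ll_gh == pytest.approx(ll_trap, abs=1e-6)


def test_quadrature_self_convergence_and_monotone_accuracy(toy_model, toy_site_pairs):
    ll_trap = _trapezoid_site_loglik(toy_model, toy_site_pairs, 1.0)
    errs = [abs(_toy_loglik(toy_model, toy_site_pairs, 1.0, "gh", n) - ll_trap)
            for n in (3, 7, 15, 31)]
    assert abs(_toy_loglik(toy_model, toy_site_pairs, 1.0, "gh", 15)
               - _toy_loglik(toy_model, toy_site_pairs, 1.0, "gh", 31)) < 1e-6
    assert all(errs[i + 1] <= errs[i] + 1e-12 for i in range(len(errs) - 1))


def test_site_loglik_rejects_mixed_or_empty_sites(toy_model, toy_site_pairs):
    with pytest.raises(ValueError):
        site_marginal_loglik(toy_model, toy_site_pairs.iloc[:0])
    mixed = toy_site_pairs.copy()
    mixed.loc[mixed.index[-1], "site_id"] = "B"
    with pytest.raises(ValueError):
        site_marginal_loglik(toy_model, mixed)


def test_negative_sigma_is_rejected(toy_model, toy_site_pairs):
    data = encode_design(toy_site_pairs, toy_model.spec)
    with pytest.raises(ValueError):
        marginal_loglik(toy_model.thresholds, toy_model.alpha,
                        np.zeros(len(data.names)), -1.0, data)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_fit(small_dataset):
    cfg, ds, _ = small_dataset
    pairs = wd.build_transition_pairs(ds)
    spec = ModelSpec(terms=frozenset({"prev_coverage", "irrigation", "land_use"}))
    return pairs, fit_model(pairs, spec, FitOptions(n_starts=2))


def test_fit_enforces_threshold_ordering_and_aic_identity(small_fit):
    _, fit = small_fit
    assert fit.thresholds[0] < fit.thresholds[1] < fit.thresholds[2]
    assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.n_params
    assert fit.n_params == 3 + 3 + len(fit.coefs) + 1
    assert aic(fit) == fit.aic


def test_fit_is_deterministic_given_fixed_starts(small_fit):
    pairs, fit = small_fit
    again = fit_model(pairs, fit.spec, FitOptions(n_starts=2))
    assert again.loglik == fit.loglik
    assert np.array_equal(again.thresholds, fit.thresholds)


def test_sigma_zero_fit_matches_fixed_effects_proportional_odds_oracle(small_dataset):
    """With the intercept variance pinned at zero the marginal fit must equal
    an independent fixed-effects proportional-odds maximum likelihood."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    _, ds, _ = small_dataset
    pairs = wd.build_transition_pairs(ds)
    spec = ModelSpec(terms=frozenset({"prev_coverage", "irrigation"}))
    ours = fit_model(pairs, spec, FitOptions(n_starts=2, fix_sigma=0.0))
    X = pd.DataFrame({
        "prev1": (pairs["from_level"] == 1).astype(float),
        "prev2": (pairs["from_level"] == 2).astype(float),
        "prev3": (pairs["from_level"] == 3).astype(float),
        "irrigation": pairs["irrigation"].astype(float),
    })
    oracle = OrderedModel(pairs["to_level"].astype(int), X, distr="logit").fit(
        method="bfgs", disp=0)
    assert ours.loglik == pytest.approx(oracle.llf, abs=1e-6)


def test_json_round_trip_preserves_the_fit(small_fit, tmp_path):
    _, fit = small_fit
    path = tmp_path / "model.json"
    fit.to_json(path)
    back = wd.FittedModel.from_json(path)
    assert back.loglik == fit.loglik and back.aic == fit.aic
    assert np.array_equal(back.thresholds, fit.thresholds)
    assert back.coefs == fit.coefs and back.sigma == fit.sigma
    assert back.spec.terms == fit.spec.terms


def test_quasi_separated_category_is_flagged_not_penalized(survey_emulation, projection_fit):
    # paddy-rice transitions are deterministic in the emulation, so the
    # coefficient runs to the box bound and is reported as-is with a warning
    assert any("paddy" in w for w in projection_fit.warnings)
    assert projection_fit.coefs["land_use[paddy_rice]"] < -10


# --------------------------------------------------------------------------
# backward selection
# --------------------------------------------------------------------------

def test_strongly_predictive_single_term_survives_selection():
    cfg = wd.SimulationConfig(
        n_sites=60, years=(2001, 2007),
        true_model=wd.make_true_model(
            (-1.0, 0.0, 1.0), (0.0, 0.0, 0.0), {"irrigation": -3.0}, 0.5,
            spec=ModelSpec(terms=frozenset({"irrigation"}))),
        management=wd.ManagementProcess(land_use_probs={"wheat": 1.0},
                                        irrigation_rate=0.5),
        seed=5,
    )
    ds, _ = wd.simulate_dataset(cfg)
    pairs = wd.build_transition_pairs(ds)
    spec = ModelSpec(terms=frozenset({"irrigation"}))
    result = backward_select(pairs, spec, FitOptions(n_starts=1))
    assert result.best_spec.terms == frozenset({"irrigation"})
    # the intercept-only candidate was evaluated and lost
    assert any(s.terms == frozenset() for s, _ in result.ladder)


def test_selection_ladder_table_has_blanks_for_excluded_terms(small_fit):
    pairs, _ = small_fit
    spec = ModelSpec(terms=frozenset({"prev_coverage", "irrigation"}))
    result = backward_select(pairs, spec, FitOptions(n_starts=1))
    table = selection_table(result)
    assert {"prev_lv1", "irrigation", "threshold_0|1", "aic"} <= set(table.columns)
    assert table["aic"].is_monotonic_increasing
    assert table["land_use[barley]"].isna().all()
    # every candidate row present
    assert len(table) == len(result.ladder)
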