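"""Stage-1 choice models: Laplace fits, BLUP extraction, BIC, combined model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import regretchoice as rc
from regretchoice.choice_model import GAMBLE_STATISTICS, ModelSpec, _design, _prepare
from regretchoice.dataset import CONDITIONS
from regretchoice.mixedlogit import fit_mixed_logit
from regretchoice.simulate import CellParams

POOLED = ModelSpec(random=())  # all random-effect variances constrained to zero


def swap_sides(dataset: rc.Dataset) -> rc.Dataset:
    df = dataset.df.rename(columns={
        "xL": "xR", "yL": "yR", "pL": "pR", "xR": "xL", "yR": "yL", "pR": "pL",
        "obtained": "counterfactual", "counterfactual": "obtained"})
    df["choice"] = 1 - df["choice"]
    return rc.Dataset(df)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_zero_variance_fit_matches_independent_logistic_mle(seed):
    ds = rc.simulate_dataset(rc.SimulationConfig(seed=seed, n_subjects=10, n_trials_per_condition=16))
    m = rc.fit_condition(ds, ("self", "absent"), POOLED)
    df, _, _ = _prepare(ds.condition("self", "absent"))
    X = _design(df, POOLED.fixed)
    glm = sm.GLM(df["choice"].to_numpy(float), X, family=sm.families.Binomial()).fit()
    assert np.abs(m.fit.beta - glm.params).max() < 1e-3
    assert m.fit.loglik == pytest.approx(glm.llf, abs=1e-6)


def test_laplace_objective_beats_null_point(default_dataset):
    m = rc.fit_condition(default_dataset, ("self", "absent"))
    df, _, groups = _prepare(default_dataset.condition("self", "absent"))
    n = len(df)
    # log-likelihood of the all-zero model is n log(1/2)
    assert m.fit.loglik >= n * np.log(0.5)


def test_left_right_symmetry_is_exact(default_dataset):
    """The fit is invariant under swapping sides and recoding the choice:
    gamble-statistic coefficients unchanged (their regressors negate with
    the swap), intercept negated."""
    m1 = rc.fit_condition(default_dataset, ("self", "absent"))
    m2 = rc.fit_condition(swap_sides(default_dataset), ("self", "absent"))
    assert m1.beta["const"] == pytest.approx(-m2.beta["const"], abs=1e-3)
    for stat in GAMBLE_STATISTICS:
        assert m1.beta[stat] == pytest.approx(m2.beta[stat], abs=1e-5)


def test_parameter_recovery_large_sample():
    """At 200 subjects each fixed effect lands within 3 SEs of truth."""
    ds = rc.simulate_dataset(rc.SimulationConfig(seed=17, n_subjects=200))
    m = rc.fit_condition(ds, ("self", "absent"))
    true = np.array(rc.PopulationSpec.default().cells[("self", "absent")].beta)
    assert np.all(np.abs(m.fit.beta - true) < 3 * m.fit.se)


def test_null_coefficients_yield_calibrated_wald(rng):
    """Choices from beta = 0: fixed-effect Wald tests reject rarely."""
    n_hits, n_total = 0, 0
    for seed in range(8):
        cells = {c: CellParams(beta=(0, 0, 0, 0), tau=(0, 0.001, 0.0005, 0.001))
                 for c in CONDITIONS}
        ds = rc.simulate_dataset(rc.SimulationConfig(
            seed=100 + seed, n_subjects=15, n_trials_per_condition=24,
            population=rc.PopulationSpec(cells=cells)))
        m = rc.fit_condition(ds, ("self", "absent"))
        n_hits += int((np.abs(m.fit.wald_z) > 1.96).sum())
        n_total += len(m.fit.wald_z)
    # ~5% nominal; allow generous binomial slack on 32 tests
    assert n_hits <= 5


def test_extract_subject_coefficients(default_dataset):
    m = rc.fit_condition(default_dataset, ("self", "absent"))
    coefs = rc.extract_subject_coefficients(m)
    assert list(coefs.columns) == list(GAMBLE_STATISTICS)
    assert len(coefs) == 50
    # composite mean tracks the fixed effect: conditional-mode deviations
    # need not sum exactly to zero at the marginal optimum, but their mean
    # stays well inside the fixed effect's sampling uncertainty
    se = pd.Series(m.fit.se, index=m.term_names)[list(GAMBLE_STATISTICS)]
    assert ((coefs.mean() - m.beta[list(GAMBLE_STATISTICS)]).abs() < 0.5 * se).all()
    # true vs extracted AR weights agree in rank
    truth = default_dataset.provenance["truth"]
    cell = truth[(truth.beneficiary == "self") & (truth.audience == "absent")]
    cell = cell.set_index("subject_id").loc[coefs.index]
    rho = pd.Series(cell["AR"]).corr(pd.Series(coefs["AR"], index=coefs.index), method="spearman")
    assert rho > 0.5


def test_pooled_fit_gives_identical_rows(small_dataset):
    m = rc.fit_condition(small_dataset, ("self", "absent"), POOLED)
    coefs = rc.extract_subject_coefficients(m)
    assert len(coefs) == 12
    assert coefs.std().max() < 1e-15
    assert np.allclose(coefs.iloc[0].to_numpy(), m.beta[list(GAMBLE_STATISTICS)].to_numpy())


def test_precondition_on_subjects_and_trials():
    ds = rc.simulate_dataset(rc.SimulationConfig(seed=1, n_subjects=2, n_trials_per_condition=4))
    with pytest.raises(ValueError, match="trials"):
        rc.fit_condition(ds, ("self", "absent"))


def test_bic_comparison_disappointment_regressor():
    """Data without any disappointment sensitivity: adding AD costs BIC;
    data generated with a strong AD effect: the augmentation wins."""
    null_dbics = []
    for seed in (1, 2, 3, 4, 5):
        ds = rc.simulate_dataset(rc.SimulationConfig(
            seed=seed, n_subjects=15, n_trials_per_condition=24,
            population=rc.PopulationSpec.null()))
        null_dbics.append(rc.compare_models_bic(ds, ("self", "absent")))
    assert sum(d > 0 for d in null_dbics) >= 4

    cells = {c: CellParams(beta=(0, 0.01, -0.002, 0.01), tau=(0, 0.005, 0.001, 0.005),
                           beta_ad=0.02) for c in CONDITIONS}
    ds = rc.simulate_dataset(rc.SimulationConfig(
        seed=6, n_subjects=25, n_trials_per_condition=48,
        population=rc.PopulationSpec(cells=cells)))
    assert rc.compare_models_bic(ds, ("self", "absent")) < 0


def test_bic_identical_specs_and_nesting_check(small_dataset):
    spec = ModelSpec()
    assert rc.compare_models_bic(small_dataset, ("self", "absent"), spec, spec) == 0.0
    with pytest.raises(ValueError, match="nest"):
        rc.compare_models_bic(small_dataset, ("self", "absent"),
                              base=ModelSpec(), augmented=ModelSpec(fixed=("const", "dEV"),
                                                                    random=("const",)))


def test_combined_model_null_and_alternative():
    ds_null = rc.simulate_dataset(rc.SimulationConfig(
        seed=13, n_subjects=25, n_trials_per_condition=24,
        population=rc.PopulationSpec.null()))
    comb = rc.fit_combined(ds_null)
    inter = comb.wald.loc[[t for t in comb.term_names if ":" in t]]
    assert inter["z"].abs().max() < 3.0  # no spurious condition interactions

    ds_alt = rc.simulate_dataset(rc.SimulationConfig(
        seed=14, n_subjects=40,
        population=rc.PopulationSpec.null().with_audience_effect(0.006)))
    comb2 = rc.fit_combined(ds_alt)
    assert comb2.wald.loc["audience[present]:AR", "p"] < 0.05


def test_combined_model_requires_all_cells(small_dataset):
    partial = rc.Dataset(small_dataset.df[small_dataset.df.audience == "absent"])
    with pytest.raises(ValueError, match="missing"):
        rc.fit_combined(partial)


def test_separation_triggers_ridge_stabilised_refit(rng):
    """A regressor that perfectly predicts the response is flagged, not fatal."""
    n = 200
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = (x > 0).astype(float)
    fit = fit_mixed_logit(y, X)
    assert fit.diagnostics.get("ridge_stabilised") is True
    assert np.isfinite(fit.beta).all()
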