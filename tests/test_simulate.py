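"""The generative model: stimulus lists, choices, ratings, full datasets."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import regretchoice as rc
from regretchoice.dataset import CONDITIONS, derive_trial_statistics
from regretchoice.simulate import (
    CellParams,
    GenerationError,
    generate_gamble_list,
    simulate_choice,
    simulate_rating,
)
from regretchoice.task import Lottery, TrialPair, TrialRecord, decision_variables


def test_gamble_list_constraints_and_determinism():
    rng = np.random.default_rng(1)
    pairs = generate_gamble_list(48, rng=rng)
    assert len(pairs) == 48
    dv = np.array([[d.dEV, d.dSD, d.AR] for d in map(decision_variables, pairs)])
    # each regressor spans both signs; dEV and AR not confounded
    assert ((dv > 0).any(axis=0) & (dv < 0).any(axis=0)).all()
    assert abs(np.corrcoef(dv[:, 0], dv[:, 2])[0, 1]) < 0.95
    for p in pairs:
        assert p.left.x > p.left.y and p.right.x > p.right.y
        assert (p.left.x, p.left.y, p.left.p) != (p.right.x, p.right.y, p.right.p)
    again = generate_gamble_list(48, rng=np.random.default_rng(1))
    assert pairs == again


def test_gamble_list_infeasible_alphabet():
    # two outcome values make AR identically zero: constraints unsatisfiable
    with pytest.raises(GenerationError):
        generate_gamble_list(16, alphabet=(-50.0, 50.0), rng=np.random.default_rng(0))
    with pytest.raises(GenerationError):
        generate_gamble_list(16, alphabet=(50.0,), rng=np.random.default_rng(0))


def test_simulate_choice_probabilities():
    rng = np.random.default_rng(5)
    pair = TrialPair(Lottery(250, -50, 0.5), Lottery(50, -50, 0.5))  # dEV = 100
    assert decision_variables(pair).dEV == 100.0
    n = 20_000
    # null coefficients: coin flip
    freq0 = np.mean([simulate_choice(pair, [0, 0, 0, 0], rng) for _ in range(n)])
    assert abs(freq0 - 0.5) < 3 * np.sqrt(0.25 / n)
    # beta_e = 0.01 on dEV = 100 -> P(left) = logistic(1)
    target = expit(1.0)
    freq = np.mean([simulate_choice(pair, [0, 0.01, 0, 0], rng) for _ in range(n)])
    assert abs(freq - target) < 3 * np.sqrt(target * (1 - target) / n)
    # swapping sides maps P(left) to 1 - P(left) when the intercept is 0
    freq_sw = np.mean([simulate_choice(pair.swapped(), [0, 0.01, 0, 0], rng) for _ in range(n)])
    assert abs(freq_sw - (1 - target)) < 3 * np.sqrt(target * (1 - target) / n)


def test_regret_aversion_prefers_lower_max_regret_option():
    """With b_r > 0 and dEV = dSD = 0, choices favour the option whose worst
    case leaves less room for regret."""
    # EV_L = EV_R = 0 and SD_L = SD_R = 100, but AR = 150 > 0
    pair = TrialPair(Lottery(200, -50, 0.2), Lottery(100, -100, 0.5))
    d = decision_variables(pair)
    assert d.dEV == pytest.approx(0) and d.dSD == pytest.approx(0) and d.AR == 150.0
    rng = np.random.default_rng(11)
    freq = np.mean([simulate_choice(pair, [0, 0, 0, 0.01], rng) for _ in range(5000)])
    assert freq > 0.5
    assert freq == pytest.approx(expit(1.5), abs=3 * np.sqrt(0.25 / 5000))


def test_simulate_rating_contract():
    pair = TrialPair(Lottery(200, -200, 0.5), Lottery(50, -200, 0.3))
    rec = TrialRecord(pair, choice=0, obtained=-200.0, counterfactual=200.0)
    assert rec.experienced_regret == 400.0 and rec.experienced_disappointment == 250.0
    rng = np.random.default_rng(0)
    assert simulate_rating(rec, (0, 0, 0, 1e-12), rng) == 0
    # the published baseline slopes drive this worked trial far past the axis: clamped
    assert simulate_rating(rec, (0, -0.25, -0.59, 1e-12), rng) == -50
    vals = [simulate_rating(rec, (0, -0.06, -0.10, 30), rng) for _ in range(500)]
    assert all(-50 <= v <= 50 for v in vals)


def test_dataset_bookkeeping_and_determinism(default_dataset):
    df = default_dataset.df
    assert len(df) == 50 * 4 * 48
    counts = df.groupby(["subject_id", "beneficiary", "audience"]).size()
    assert (counts == 48).all()
    assert len(counts) == 50 * 4
    again = rc.simulate_dataset(rc.SimulationConfig(seed=7))
    assert df.to_csv(index=False) == again.df.to_csv(index=False)


def test_zero_tau_gives_identical_subjects():
    cells = {c: CellParams(beta=(0, 0.01, -0.002, 0.01), tau=(0, 0, 0, 0)) for c in CONDITIONS}
    ds = rc.simulate_dataset(rc.SimulationConfig(
        seed=2, n_subjects=6, n_trials_per_condition=8,
        population=rc.PopulationSpec(cells=cells)))
    truth = ds.provenance["truth"]
    for _, cell in truth.groupby(["beneficiary", "audience"]):
        assert cell[["const", "dEV", "dSD", "AR"]].std().max() == 0.0


def test_random_effect_moments_match_tau():
    """Across many subjects the spread of true coefficients approaches tau."""
    ds = rc.simulate_dataset(rc.SimulationConfig(seed=4, n_subjects=400, n_trials_per_condition=4))
    truth = ds.provenance["truth"]
    cell = truth[(truth.beneficiary == "self") & (truth.audience == "absent")]
    tau = np.asarray(rc.PopulationSpec.default().cells[("self", "absent")].tau)
    sd = cell[["const", "dEV", "dSD", "AR"]].std().to_numpy()
    # relative Monte-Carlo error of an SD at n=400 is ~1/sqrt(2n) ~ 3.5%
    assert np.allclose(sd[tau > 0], tau[tau > 0], rtol=0.15)
    assert sd[tau == 0].max() == 0.0


def test_condition_labels_share_stimulus_distribution(small_dataset):
    """All four cells present the same stimulus list (order aside)."""
    df = small_dataset.df
    key = ["xL", "yL", "pL", "xR", "yR", "pR"]
    ref = None
    for _, cell in df.groupby(["beneficiary", "audience"]):
        stims = cell[cell.subject_id == 1][key].sort_values(key).reset_index(drop=True)
        if ref is None:
            ref = stims
        else:
            pd.testing.assert_frame_equal(ref, stims)


def test_shared_random_effects_switch():
    ds = rc.simulate_dataset(rc.SimulationConfig(
        seed=9, n_subjects=5, n_trials_per_condition=8, shared_random_effects=True))
    truth = ds.provenance["truth"]
    base = rc.PopulationSpec.default().cells
    # deviations from each cell's beta are perfectly correlated across cells
    dev = {
        cond: (cell.sort_values("subject_id")[["dEV"]].to_numpy().ravel()
               - base[cond].beta[1])
        for cond, cell in truth.groupby(["beneficiary", "audience"])
    }
    mats = np.array(list(dev.values()))
    c = np.corrcoef(mats)
    assert np.allclose(c, 1.0, atol=1e-9)


def test_derived_columns_match_scalar_calculus(small_dataset):
    """Vectorised trial statistics agree with the scalar operations."""
    df = derive_trial_statistics(small_dataset.df.head(100))
    for _, row in df.iterrows():
        pair = TrialPair(Lottery(row.xL, row.yL, row.pL), Lottery(row.xR, row.yR, row.pR))
        d = decision_variables(pair)
        assert (row.dEV, row.dSD, row.AR) == pytest.approx((d.dEV, d.dSD, d.AR), abs=1e-10)
        rec = TrialRecord(pair, int(row.choice), row.obtained, row.counterfactual)
        assert row.regret == rec.experienced_regret
        assert row.disappointment == rec.experienced_disappointment
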