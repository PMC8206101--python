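"""Stage 2: within-subject ANOVA, effect sizes, contrasts, harnesses."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

import regretchoice as rc
from regretchoice.simulate import SimulationConfig
from regretchoice.stage2 import (
    eta_sq_ci,
    f_and_eta_from_ss,
    posthoc_contrast,
    rm_anova_2x2,
)

# Published 2x2 ANOVA rows on the choice coefficients (DFn=1, DFd=49):
# (SSn, SSd, printed F, printed eta^2)
PUBLISHED_ROWS = [
    # dEV factor
    (0.443, 6.56, 3.31, 0.063), (1.35, 3.80, 17.47, 0.263), (0.12, 4.56, 1.30, 0.026),
    # dSD factor
    (0.60, 8.70, 3.40, 0.065), (0.74, 8.17, 4.42, 0.083), (0.15, 7.21, 1.01, 0.020),
    # AR factor
    (0.85, 10.29, 4.03, 0.076), (1.83, 10.43, 8.61, 0.149), (0.026, 6.89, 0.19, 0.004),
]

# Published F(1,49) values with their eta^2 95% CIs
PUBLISHED_CIS = [
    (17.47, 0.078, 0.447),
    (8.61, 0.015, 0.335),
    (4.42, 0.000, 0.255),
    (18.77, 0.088, 0.459),
]


def random_table(rng, n=20, shift=None):
    rows = []
    for b in ("self", "partner"):
        for a in ("absent", "present"):
            vals = rng.normal(size=n)
            if shift and (b, a) in shift:
                vals = vals + shift[(b, a)]
            rows.append(pd.DataFrame({
                "subject_id": np.arange(n), "beneficiary": b, "audience": a, "value": vals}))
    return pd.concat(rows, ignore_index=True)


@pytest.mark.parametrize("ssn, ssd, F, eta", PUBLISHED_ROWS)
def test_published_table_internal_identities(ssn, ssd, F, eta):
    """Our F and partial-eta² formulas reproduce every published row."""
    F_calc, _, eta_calc = f_and_eta_from_ss(ssn, ssd, 1, 49)
    assert F_calc == pytest.approx(F, abs=0.1)
    assert eta_calc == pytest.approx(eta, abs=0.005)


@pytest.mark.parametrize("F, lo, hi", PUBLISHED_CIS)
def test_eta_ci_matches_published_intervals(F, lo, hi):
    lo_c, hi_c = eta_sq_ci(F, 1, 49)
    assert lo_c == pytest.approx(lo, abs=0.02)
    assert hi_c == pytest.approx(hi, abs=0.02)


def test_eta_ci_properties():
    lo, hi = eta_sq_ci(0.0, 1, 30)
    assert lo == 0.0 and hi == 0.0
    lo, hi = eta_sq_ci(6.0, 1, 30)
    assert 0.0 <= lo < hi < 1.0
    w30 = np.subtract(*eta_sq_ci(6.0, 1, 30)[::-1])
    w300 = np.subtract(*eta_sq_ci(6.0, 1, 300)[::-1])
    assert w300 < w30
    with pytest.raises(ValueError):
        eta_sq_ci(-1.0, 1, 10)
    with pytest.raises(ValueError):
        eta_sq_ci(1.0, 0, 10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_every_f_equals_squared_paired_t(seed, rng):
    """With two levels per factor each within-subject F is a squared paired t."""
    tab = random_table(np.random.default_rng(seed))
    res = rm_anova_2x2(tab)
    wide = tab.pivot_table(index="subject_id", columns=["beneficiary", "audience"],
                           values="value")
    y = {c: wide[c].to_numpy() for c in wide.columns}
    contrasts = {
        "beneficiary": (y[("partner", "absent")] + y[("partner", "present")]
                        - y[("self", "absent")] - y[("self", "present")]) / 2,
        "audience": (y[("self", "present")] + y[("partner", "present")]
                     - y[("self", "absent")] - y[("partner", "absent")]) / 2,
        "beneficiary × audience": (y[("partner", "present")] - y[("partner", "absent")]
                                   - y[("self", "present")] + y[("self", "absent")]) / 2,
    }
    for effect, d in contrasts.items():
        t = stats.ttest_1samp(d, 0.0)
        assert res[effect]["F"] == pytest.approx(t.statistic**2, abs=1e-10)
        assert res[effect]["p"] == pytest.approx(t.pvalue, abs=1e-12)


def test_agreement_with_pingouin(rng):
    """Independent route: pingouin's two-way rm_anova on the same table."""
    tab = random_table(rng, n=25, shift={("self", "present"): 0.6, ("partner", "present"): 0.6})
    res = rm_anova_2x2(tab)
    pgres = pg.rm_anova(data=tab, dv="value", within=["beneficiary", "audience"],
                        subject="subject_id", detailed=True)
    for ours, theirs in [("beneficiary", "beneficiary"), ("audience", "audience"),
                         ("beneficiary × audience", "beneficiary * audience")]:
        row = pgres[pgres.Source == theirs].iloc[0]
        assert res[ours]["F"] == pytest.approx(row["F"], rel=1e-6)
        assert res[ours]["p"] == pytest.approx(row["p_unc"], rel=1e-6)


def test_null_table_gives_zero_f():
    tab = random_table(np.random.default_rng(0), n=10)
    # identical value in all four cells per subject
    base = tab[(tab.beneficiary == "self") & (tab.audience == "absent")]["value"].to_numpy()
    tab["value"] = np.tile(base, 4)
    res = rm_anova_2x2(tab)
    for effect in ("beneficiary", "audience", "beneficiary × audience"):
        assert res[effect]["SSn"] == pytest.approx(0.0, abs=1e-20)


def test_incomplete_design_errors():
    tab = random_table(np.random.default_rng(0), n=8)
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova_2x2(tab[~((tab.beneficiary == "self") & (tab.audience == "present"))])
    with pytest.raises(ValueError, match="subjects missing"):
        drop_one = tab.drop(tab[(tab.subject_id == 0) & (tab.audience == "present")
                                & (tab.beneficiary == "self")].index)
        rm_anova_2x2(drop_one)


def test_posthoc_contrast_properties(rng):
    tab = random_table(rng, n=15, shift={("partner", "absent"): 0.8})
    res = posthoc_contrast(tab, "audience", "absent")
    assert res["F"] > 0 and res["DFd"] == 14
    shuffled = tab.sample(frac=1.0, random_state=0)
    res2 = posthoc_contrast(shuffled, "audience", "absent")
    assert res["F"] == pytest.approx(res2["F"], abs=1e-12)
    # identical paired values -> F = 0
    same = tab.copy()
    same.loc[same.beneficiary == "partner", "value"] = (
        same[same.beneficiary == "self"]["value"].to_numpy())
    assert posthoc_contrast(same, "audience", "absent")["F"] == 0.0
    with pytest.raises(ValueError):
        posthoc_contrast(tab, "audience", "nowhere")


def test_posthoc_matches_noncentral_expectation(rng):
    """Across replicates the contrast F tracks its noncentral-F expectation."""
    n, delta, sigma = 12, 0.8, 1.0
    lam = n * delta**2 / (2 * sigma**2)  # contrast of two cells, each var sigma^2
    Fs = []
    for _ in range(400):
        rows = []
        for b in ("self", "partner"):
            for a in ("absent", "present"):
                mu = delta if (b, a) == ("partner", "absent") else 0.0
                rows.append(pd.DataFrame({
                    "subject_id": np.arange(n), "beneficiary": b, "audience": a,
                    "value": rng.normal(mu, sigma, n)}))
        Fs.append(posthoc_contrast(pd.concat(rows), "audience", "absent")["F"])
    dfd = n - 1
    expect = dfd * (1 + lam) / (dfd - 2)
    assert np.mean(Fs) == pytest.approx(expect, rel=0.15)


def _tiny_null_config(seed=55):
    return SimulationConfig(seed=seed, n_subjects=8, n_trials_per_condition=12,
                            population=rc.PopulationSpec.null())


def test_type1_requires_null_population():
    cfg = SimulationConfig(seed=1, n_subjects=8, n_trials_per_condition=12)
    with pytest.raises(ValueError, match="identical"):
        rc.type1_simulation(cfg, n_replicates=2)


def test_type1_alpha_monotonicity_and_determinism():
    cfg = _tiny_null_config()
    r5 = rc.type1_simulation(cfg, n_replicates=12, alpha=0.05)
    r1 = rc.type1_simulation(cfg, n_replicates=12, alpha=0.01)
    merged = r5.merge(r1, on=["coefficient", "effect"], suffixes=("_5", "_1"))
    assert (merged.rejection_rate_1 <= merged.rejection_rate_5).all()
    again = rc.type1_simulation(cfg, n_replicates=12, alpha=0.05)
    pd.testing.assert_frame_equal(r5, again)


def test_power_simulation_output_structure():
    cfg = SimulationConfig(seed=77, n_subjects=8, n_trials_per_condition=12,
                           population=rc.PopulationSpec.null().with_audience_effect(0.01))
    out = rc.power_simulation(cfg, n_subjects=(8, 12), n_replicates=6)
    assert list(out.n_subjects) == [8, 12]
    assert ((out.power >= 0) & (out.power <= 1)).all()
    assert (out.ci_low <= out.power).all() and (out.power <= out.ci_high).all()
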