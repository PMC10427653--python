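"""Statistical pipeline: centering, MLM, rmANOVA, choice models, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cadkit.strategies import CANONICAL_ORDER
from cadkit.synthetic_study import StudyConfig, generate_study
from cadkit.analysis import (
    center_within_cluster,
    effect_size_f2,
    fit_sv_mlm,
    flexer_regression,
    null_model_icc,
    ordinal_choice_model,
    predicted_vs_actual_chi2,
    rm_anova,
)

LABELS = [s.value for s in CANONICAL_ORDER]


# ---------------------------------------------------------------------------
# Centering


def test_center_within_cluster_arithmetic_and_idempotence():
    df = pd.DataFrame({"participant_id": ["a"] * 3 + ["b"] * 3,
                       "x": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0]})
    c1 = center_within_cluster(df, ["x"])
    assert list(c1.loc[c1.participant_id == "a", "x"]) == [-1.0, 0.0, 1.0]
    assert c1.groupby("participant_id")["x"].mean().abs().max() <= 1e-12
    c2 = center_within_cluster(c1, ["x"])
    pd.testing.assert_frame_equal(c1, c2)


def test_center_within_cluster_rejects_empty_cluster():
    df = pd.DataFrame({"participant_id": ["a", "a", "b"],
                       "x": [1.0, 2.0, np.nan]})
    with pytest.raises(ValueError, match="entirely missing"):
        center_within_cluster(df, ["x"])


# ---------------------------------------------------------------------------
# Multilevel model


def _flat_table(seed, n_subj=40, per=6, b_x=0.4, group_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        g = rng.normal(0, group_sd)
        for _ in range(per):
            x = rng.normal()
            rows.append({"participant_id": f"s{i}", "x": x,
                         "sv": 0.5 + b_x * x + g + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


def test_mlm_reduces_to_ols_without_subject_variance():
    """With zero true subject variance the REML fit sits on the boundary
    and the fixed effects coincide with ordinary least squares."""
    import statsmodels.api as sm

    table = _flat_table(0)
    res = fit_sv_mlm(table, ["x"], center_level1=False, compute_f2=False)
    centered = table
    X = sm.add_constant(centered["x"].to_numpy())
    ols = sm.OLS(centered["sv"].to_numpy(), X).fit()
    assert res.singular
    assert res.fixed_effects.loc["intercept", "estimate"] == pytest.approx(
        ols.params[0], abs=1e-6)
    assert res.fixed_effects.loc["x", "estimate"] == pytest.approx(
        ols.params[1], abs=1e-6)


def test_mlm_recovers_weight_signs_and_icc_structure():
    study = generate_study(StudyConfig(), 17)
    res = fit_sv_mlm(study.table, ["effort", "arousal", "utility",
                                   "corrugator", "levator"], compute_f2=False)
    fe = res.fixed_effects
    assert fe.loc["effort", "estimate"] < 0 and fe.loc["effort", "p"] < 0.05
    assert fe.loc["utility", "estimate"] > 0 and fe.loc["utility", "p"] < 0.05
    assert 0.0 < res.icc < 1.0
    assert res.r2_conditional >= res.r2_marginal
    assert res.n_groups == 120 and not res.singular


def test_mlm_accepts_level2_covariates():
    study = generate_study(StudyConfig(n_participants=40), 23)
    res = fit_sv_mlm(study.table, ["effort", "utility"],
                     level2_predictors=["self_control", "nfc"], compute_f2=False)
    assert {"self_control", "nfc"}.issubset(res.fixed_effects.index)


def test_null_weights_keep_type_one_error_in_check():
    """With all generator weights zero the MLM must not flag effort or
    utility beyond the nominal 5% level (checked at condition granularity,
    where observations are not duplicated across trials)."""
    cfg = dict(n_participants=60, granularity="condition",
               w_effort=0.0, w_utility=0.0, w_corrugator=0.0)
    rejections = {"effort": 0, "utility": 0}
    reps = 60
    for rep in range(reps):
        study = generate_study(StudyConfig(**cfg), 1000 + rep)
        res = fit_sv_mlm(study.table, ["effort", "utility"],
                         compute_f2=False, compute_icc=False)
        for term in rejections:
            rejections[term] += res.fixed_effects.loc[term, "p"] < 0.05
    for term, count in rejections.items():
        assert count / reps <= 0.14, (term, count)


def test_null_icc_near_zero_without_subject_structure():
    table = _flat_table(3, n_subj=60, per=5, b_x=0.0, group_sd=0.0)
    assert null_model_icc(table) <= 0.05


def test_f2_null_small_and_monotone_in_effect_size():
    null_f2, ladder = [], []
    for rep in range(6):
        study = generate_study(StudyConfig(n_participants=80, granularity="condition",
                                           w_utility=0.0), 300 + rep)
        f2, _ = effect_size_f2(study.table, ["effort", "utility"], "utility")
        null_f2.append(f2)
    assert np.median(null_f2) <= 0.005
    for w in (0.7e-3, 1.42e-3, 2.8e-3):
        vals = []
        for rep in range(5):
            study = generate_study(StudyConfig(n_participants=80,
                                               granularity="condition",
                                               w_utility=w), 600 + rep)
            f2, _ = effect_size_f2(study.table, ["effort", "utility"], "utility")
            vals.append(f2)
        ladder.append(np.median(vals))
    assert ladder[0] < ladder[1] < ladder[2]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


FIXTURE_5x3 = pd.DataFrame(
    [(f"S{i}", c, v)
     for i, row in enumerate([[3, 5, 9], [4, 6, 7], [2, 4, 8], [5, 8, 12], [3, 4, 6]])
     for c, v in zip(["c1", "c2", "c3"], row)],
    columns=["participant_id", "condition", "y"],
)

# independent oracle: exact rational sums of squares and the
# Greenhouse-Geisser epsilon from the condition covariance matrix
ORACLE_F = 31.666666666666668
ORACLE_EPS = 0.5714285714285714  # 4/7
ORACLE_P_GG = 0.0029776182868723753
ORACLE_NG2 = 0.6274768824306473
ORACLE_NP2 = 0.8878504672897196


def test_rm_anova_matches_hand_oracle_to_six_decimals():
    res = rm_anova(FIXTURE_5x3, "y")
    assert res.F == pytest.approx(ORACLE_F, abs=1e-6)
    assert res.epsilon == pytest.approx(ORACLE_EPS, abs=1e-6)
    assert res.df_num == pytest.approx(2 * ORACLE_EPS, abs=1e-6)
    assert res.df_den == pytest.approx(8 * ORACLE_EPS, abs=1e-6)
    assert res.p == pytest.approx(ORACLE_P_GG, abs=1e-6)
    assert res.eta2_generalized == pytest.approx(ORACLE_NG2, abs=1e-6)
    assert res.eta2_partial == pytest.approx(ORACLE_NP2, abs=1e-6)


def test_rm_anova_two_levels_equals_squared_paired_t():
    sub = FIXTURE_5x3[FIXTURE_5x3.condition.isin(["c1", "c3"])]
    res = rm_anova(sub, "y")
    wide = sub.pivot(index="participant_id", columns="condition", values="y")
    t = stats.ttest_rel(wide["c1"], wide["c3"])
    assert res.epsilon == 1.0
    assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
    assert res.p == pytest.approx(t.pvalue, rel=1e-10)


def test_rm_anova_flat_data_gives_zero_f():
    df = pd.DataFrame([(f"S{i}", c, 2.5) for i in range(6) for c in "abc"],
                      columns=["participant_id", "condition", "y"])
    res = rm_anova(df, "y")
    assert res.F == pytest.approx(0.0, abs=1e-12)


def test_rm_anova_rejects_incomplete_design():
    broken = FIXTURE_5x3.drop(index=0)
    with pytest.raises(ValueError, match="incomplete"):
        rm_anova(broken, "y")


def test_posthoc_bonferroni_scales_uncorrected_p():
    res = rm_anova(FIXTURE_5x3, "y", padjust="bonferroni")
    ph = res.posthoc
    np.testing.assert_allclose(
        ph.p_adjusted, np.minimum(1.0, ph.p_uncorrected * len(ph)))


# ---------------------------------------------------------------------------
# Choice prediction


def test_chi2_closed_forms():
    pred = [l for l in LABELS for _ in range(10)]
    res = predicted_vs_actual_chi2(pred, pred)
    assert res.chi2 == pytest.approx(2 * 30)  # perfect balanced diagonal
    assert res.df == 4
    pred2 = [l for l in LABELS for _ in range(9)]
    act2 = LABELS * 9
    res2 = predicted_vs_actual_chi2(pred2, act2)
    assert res2.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res2.p == pytest.approx(1.0)


def test_chi2_matches_textbook_oracle_and_scipy(rng):
    for _ in range(20):
        pred = rng.choice(LABELS, size=60)
        act = rng.choice(LABELS, size=60)
        res = predicted_vs_actual_chi2(pred, act)
        obs = res.contingency.to_numpy(float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        manual = np.sum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
        assert res.chi2 == pytest.approx(manual, abs=1e-10)
        if (obs.sum(0) > 0).all() and (obs.sum(1) > 0).all():
            scipy_chi2 = stats.chi2_contingency(obs, correction=False)[0]
            assert res.chi2 == pytest.approx(scipy_chi2, abs=1e-10)


def test_chi2_keeps_structural_zero_levels():
    # one strategy never predicted nor chosen: table stays 3x3, df stays 4
    pred = ["distraction"] * 5 + ["distancing"] * 5
    act = ["distraction"] * 5 + ["distancing"] * 5
    res = predicted_vs_actual_chi2(pred, act)
    assert res.contingency.shape == (3, 3)
    assert res.df == 4
    assert res.chi2 == pytest.approx(10.0)  # 2n on the 2x2 sub-diagonal


def _separated_cohort(n, rng, agreement=1.0):
    rows, choices = [], []
    for i in range(n):
        svs = {l: v for l, v in zip(LABELS, rng.uniform(0.0, 0.4, 3))}
        winner = LABELS[int(rng.integers(3))]
        svs[winner] = 1.0
        rows.append({"participant_id": f"p{i}",
                     **{f"sv_{l}": svs[l] for l in LABELS}})
        if rng.random() < agreement:
            choices.append(winner)
        else:
            choices.append(rng.choice([l for l in LABELS if l != winner]))
    return pd.DataFrame(rows), choices


def test_multinomial_choice_model_recovers_own_sv_signs(rng):
    profiles, choices = _separated_cohort(300, rng, agreement=0.85)
    res = ordinal_choice_model(profiles, choices, mode="multinomial")
    # choosing a non-reference strategy becomes more likely as its own SV rises
    for outcome in LABELS[1:]:
        mask = (res.coefficients["outcome"] == outcome) & (
            res.coefficients["term"] == f"sv_{outcome}")
        assert res.coefficients.loc[mask, "estimate"].iloc[0] > 0
    assert 0.0 < res.pseudo_r2 <= 1.0


def test_ordinal_choice_model_null_permutation_type_one(rng):
    profiles, choices = _separated_cohort(120, rng, agreement=0.8)
    hits = total = 0
    for _ in range(60):
        permuted = list(rng.permutation(choices))
        res = ordinal_choice_model(profiles, permuted)
        hits += int((res.coefficients["p"] < 0.05).sum())
        total += len(res.coefficients)
    assert hits / total <= 0.12


def test_constant_svs_flag_degenerate_model():
    profiles = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(30)],
        **{f"sv_{l}": [0.5] * 30 for l in LABELS},
    })
    choices = [LABELS[i % 3] for i in range(30)]
    res = ordinal_choice_model(profiles, choices)
    assert res.degenerate
    assert res.warning


# ---------------------------------------------------------------------------
# Flexibility regression


def _profile_frame(rng, n, b_int=0.0, b_slope=0.0, noise=1.0):
    intercept = rng.uniform(0.4, 1.0, n)
    slope = -rng.uniform(0.0, 0.5, n)
    flexer = 50 + b_int * intercept + b_slope * slope + rng.normal(0, noise, n)
    return pd.DataFrame({"ordered_intercept": intercept, "ordered_slope": slope,
                         "flexer": flexer})


def test_flexer_regression_perfect_fit():
    rng = np.random.default_rng(5)
    df = _profile_frame(rng, 50, b_int=2.0, b_slope=-1.0, noise=0.0)
    res = flexer_regression(df)
    assert res.r2 == pytest.approx(1.0)
    assert res.coefficients.loc["b_intercept", "estimate"] == pytest.approx(2.0)
    assert res.coefficients.loc["b_slope", "estimate"] == pytest.approx(-1.0)


def test_flexer_regression_ci_coverage():
    rng = np.random.default_rng(8)
    covered = 0
    reps = 40
    for _ in range(reps):
        df = _profile_frame(rng, 120, b_int=2.0, noise=0.5)
        res = flexer_regression(df)
        row = res.coefficients.loc["b_intercept"]
        covered += row["ci_low"] <= 2.0 <= row["ci_high"]
    assert covered / reps >= 0.90


def test_flexer_regression_null_r2_small():
    rng = np.random.default_rng(9)
    r2s = [flexer_regression(_profile_frame(rng, 120)).r2 for _ in range(60)]
    assert np.median(r2s) <= 0.03


def test_flexer_regression_needs_enough_participants():
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError, match="more than 3"):
        flexer_regression(_profile_frame(rng, 3))
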