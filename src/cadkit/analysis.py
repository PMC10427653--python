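"""Statistical pipeline over a study table.

Implements the manipulation-check repeated-measures ANOVAs (with
Greenhouse-Geisser correction and post-hoc contrasts), the random-
intercept multilevel model predicting subjective values from
within-cluster-centred block ratings and EMG activity (REML, with ICC,
marginal/conditional R-squared and Cohen's f2 per predictor), the
predicted-versus-actual choice chi-square, the ordinal (or multinomial)
choice regression on SVs, and the flexibility regression of the FlexER
score on each participant's ordered-SV intercept and slope.

Bayes factors are not computed; result bundles carry an explicit note.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .strategies import CANONICAL_ORDER

BAYES_NOTE = "Bayes factors are not computed by this pipeline."


# ---------------------------------------------------------------------------
# Centering


def center_within_cluster(table: pd.DataFrame, columns, cluster="participant_id"):
    """Center the listed columns at zero within every cluster (participant).

    Idempotent; raises on a cluster whose values are all missing, since
    its centred values would be undefined.
    """
    out = table.copy()
    grouped = out.groupby(cluster, observed=True)
    for col in columns:
        counts = grouped[col].count()
        if (counts == 0).any():
            bad = counts.index[counts == 0].tolist()
            raise ValueError(f"column {col!r} entirely missing in clusters {bad}")
        out[col] = out[col] - grouped[col].transform("mean")
    return out


# ---------------------------------------------------------------------------
# Multilevel model


@dataclass
class MLMResult:
    """Random-intercept mixed-model summary."""

    fixed_effects: pd.DataFrame  # estimate, se, df, t, p per term
    random_intercept_sd: float
    residual_sd: float
    icc: float  # null-model intraclass correlation
    icc_full: float
    r2_marginal: float
    r2_conditional: float
    f2: dict = field(default_factory=dict)
    delta_r2: dict = field(default_factory=dict)
    df_method: str = "residual"
    singular: bool = False
    converged: bool = True
    n_obs: int = 0
    n_groups: int = 0
    note: str = BAYES_NOTE

    def __post_init__(self):
        if np.isfinite(self.icc) and not 0.0 <= self.icc <= 1.0:
            raise ValueError("ICC outside [0, 1]")


def _fit_mixedlm(y, X, groups, reml=True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM(endog=np.asarray(y, float), exog=np.asarray(X, float),
                           groups=np.asarray(groups))
        # lbfgs tends to stall on the variance boundary here; bfgs is reliable
        return model.fit(reml=reml, method=["bfgs", "cg", "powell"])


def _variance_components(res):
    var_re = float(np.asarray(res.cov_re).ravel()[0])
    var_resid = float(res.scale)
    return var_re, var_resid


def _r2_nakagawa(res, X):
    """Marginal/conditional R2: fixed-effect, random-intercept and residual
    variance shares of the total."""
    var_re, var_resid = _variance_components(res)
    fitted_fixed = np.asarray(X, float) @ np.asarray(res.fe_params)
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + var_re + var_resid
    return var_fixed / total, (var_fixed + var_re) / total


def null_model_icc(table, dv="sv", cluster="participant_id", reml=True) -> float:
    """ICC of the intercept-only random-intercept model."""
    X = np.ones((len(table), 1))
    res = _fit_mixedlm(table[dv], X, table[cluster], reml=reml)
    var_re, var_resid = _variance_components(res)
    return var_re / (var_re + var_resid) if (var_re + var_resid) > 0 else 0.0


def fit_sv_mlm(
    table: pd.DataFrame,
    predictors,
    level2_predictors=(),
    dv="sv",
    cluster="participant_id",
    reml=True,
    center_level1=True,
    compute_f2=True,
    compute_icc=True,
) -> MLMResult:
    """Random-intercept multilevel model of SVs, fitted by REML.

    Level-1 predictors are centred within cluster (unless already
    centred by the caller); level-2 covariates such as self-control or
    need-for-cognition enter uncentred.  t-statistics use residual
    degrees of freedom (recorded in ``df_method``).  Cohen's f2 per
    predictor is computed from the drop in marginal R-squared when the
    predictor is removed.  A boundary (singular) random-effect estimate
    is flagged, never silently dropped.
    """
    predictors = list(predictors)
    level2 = list(level2_predictors)
    cols = [dv, cluster] + predictors + level2
    data = table[cols].dropna().reset_index(drop=True)
    if center_level1 and predictors:
        data = center_within_cluster(data, predictors, cluster=cluster)
    terms = predictors + level2

    def fit(subset):
        X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy() for t in subset])
        res = _fit_mixedlm(data[dv], X, data[cluster], reml=reml)
        return res, X

    res, X = fit(terms)
    var_re, var_resid = _variance_components(res)
    r2m, r2c = _r2_nakagawa(res, X)
    n_groups = data[cluster].nunique()
    df_resid = len(data) - (len(terms) + 1)
    names = ["intercept"] + terms
    est = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    tvals = est / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    fixed = pd.DataFrame(
        {"estimate": est, "se": se, "df": float(df_resid), "t": tvals, "p": pvals},
        index=pd.Index(names, name="term"),
    )
    f2, delta = {}, {}
    if compute_f2:
        for term in terms:
            res_r, X_r = fit([t for t in terms if t != term])
            r2m_r, _ = _r2_nakagawa(res_r, X_r)
            delta[term] = r2m - r2m_r
            f2[term] = (r2m - r2m_r) / (1.0 - r2m) if r2m < 1.0 else np.inf
    icc_full = var_re / (var_re + var_resid) if (var_re + var_resid) > 0 else 0.0
    return MLMResult(
        fixed_effects=fixed,
        random_intercept_sd=float(np.sqrt(var_re)),
        residual_sd=float(np.sqrt(var_resid)),
        icc=(null_model_icc(data, dv=dv, cluster=cluster, reml=reml)
             if compute_icc else float("nan")),
        icc_full=icc_full,
        r2_marginal=r2m,
        r2_conditional=r2c,
        f2=f2,
        delta_r2=delta,
        singular=bool(var_re < 1e-10),
        converged=bool(res.converged),
        n_obs=len(data),
        n_groups=int(n_groups),
    )


def effect_size_f2(
    table, predictors, predictor, dv="sv", cluster="participant_id", **kwargs
):
    """Cohen's f2 of one predictor: (R2_full - R2_reduced) / (1 - R2_full),
    on the marginal R-squared.  Returns ``(f2, delta_r2)``."""
    full = fit_sv_mlm(table, predictors, dv=dv, cluster=cluster,
                      compute_f2=False, compute_icc=False, **kwargs)
    reduced = fit_sv_mlm(table, [p for p in predictors if p != predictor],
                         dv=dv, cluster=cluster, compute_f2=False,
                         compute_icc=False, **kwargs)
    delta = full.r2_marginal - reduced.r2_marginal
    return delta / (1.0 - full.r2_marginal), delta


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA


@dataclass
class AnovaResult:
    """One-factor repeated-measures ANOVA with sphericity correction."""

    F: float
    df_num: float  # Greenhouse-Geisser corrected
    df_den: float
    p: float  # at the corrected dfs
    p_uncorrected: float
    epsilon: float
    eta2_generalized: float
    eta2_partial: float
    sphericity_W: float
    sphericity_p: float
    posthoc: pd.DataFrame | None = None
    note: str = BAYES_NOTE

    def __post_init__(self):
        if not 0.0 < self.epsilon <= 1.0 + 1e-12:
            raise ValueError("epsilon outside (0, 1]")


def _tukey_p(tval, k, df):
    """Tukey-style adjusted p for a pairwise contrast among k levels."""
    return float(stats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df))


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within="condition",
    subject="participant_id",
    levels=None,
    padjust="tukey",
) -> AnovaResult:
    """One-factor repeated-measures ANOVA with Greenhouse-Geisser correction.

    Requires a complete within-subject design over ``levels``.  Reports
    generalized and partial eta squared and pairwise paired-t post-hoc
    contrasts with Tukey (default) or Bonferroni adjustment.
    """
    data = table[[subject, within, dv]].dropna()
    if levels is not None:
        data = data[data[within].isin(levels)]
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-subject design for subjects {missing}")
    long = wide.reset_index().melt(id_vars=subject, var_name=within, value_name=dv)
    aov = pg.rm_anova(
        data=long, dv=dv, within=within, subject=subject,
        detailed=True, correction=True, effsize="ng2",
    ).set_index("Source")
    row = aov.iloc[0]
    ss_effect, ss_error = float(row["SS"]), float(aov.iloc[1]["SS"])
    eps = float(pg.epsilon(wide, correction="gg"))
    if k == 2 or not np.isfinite(eps):
        eps = 1.0
    sph = pg.sphericity(long, dv=dv, within=within, subject=subject)
    df_num, df_den = float(row["DF"]), float(aov.iloc[1]["DF"])
    if "F" in row and np.isfinite(row["F"]):
        F = float(row["F"])
        p_unc = float(row["p_unc"])
        p_gg = (float(row["p_GG_corr"])
                if "p_GG_corr" in row and np.isfinite(row["p_GG_corr"]) else p_unc)
        ng2 = float(row["ng2"])
    else:
        # degenerate zero-variance input: no effect by definition
        F, p_unc, p_gg, ng2 = 0.0, 1.0, 1.0, 0.0

    pairs = list(itertools.combinations(wide.columns, 2))
    rows = []
    n = wide.shape[0]
    for a, b in pairs:
        diff = wide[a] - wide[b]
        denom = diff.std(ddof=1) / np.sqrt(n)
        tval = float(diff.mean() / denom) if denom > 0 else 0.0
        p_unc = 2.0 * stats.t.sf(abs(tval), n - 1)
        if padjust == "tukey":
            p_adj = _tukey_p(tval, k, n - 1)
        elif padjust == "bonferroni":
            p_adj = min(1.0, p_unc * len(pairs))
        else:
            raise ValueError("padjust must be 'tukey' or 'bonferroni'")
        rows.append({"A": a, "B": b, "mean_diff": float(diff.mean()),
                     "t": tval, "df": n - 1, "p_uncorrected": p_unc,
                     "p_adjusted": min(1.0, p_adj), "adjust": padjust})
    return AnovaResult(
        F=F,
        df_num=df_num * eps,
        df_den=df_den * eps,
        p=p_gg,
        p_uncorrected=p_unc,
        epsilon=eps,
        eta2_generalized=ng2,
        eta2_partial=(ss_effect / (ss_effect + ss_error)
                      if (ss_effect + ss_error) > 0 else 0.0),
        sphericity_W=float(getattr(sph, "W", np.nan)),
        sphericity_p=float(getattr(sph, "pval", np.nan)),
        posthoc=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Choice prediction


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    contingency: pd.DataFrame
    n: int


def predicted_vs_actual_chi2(predicted, actual) -> Chi2Result:
    """Pearson chi-square of predicted (highest-SV) against actual choice.

    The contingency table always spans the full 3x3 strategy grid;
    levels absent from both margins stay as structural zeros (cells with
    zero expectation contribute nothing), so df stays (3-1)x(3-1) = 4.
    """
    labels = [s.value for s in CANONICAL_ORDER]
    pred = pd.Categorical([getattr(p, "value", p) for p in predicted], categories=labels)
    act = pd.Categorical([getattr(a, "value", a) for a in actual], categories=labels)
    if len(pred) == 0 or len(pred) != len(act):
        raise ValueError("predicted and actual choices must align and be non-empty")
    obs = pd.crosstab(pred, act, dropna=False).reindex(
        index=labels, columns=labels, fill_value=0
    )
    o = obs.to_numpy(dtype=float)
    n = o.sum()
    expected = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (o - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = (len(labels) - 1) ** 2
    obs.index.name, obs.columns.name = "predicted", "actual"
    return Chi2Result(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
                      contingency=obs, n=int(n))


@dataclass
class ChoiceModelResult:
    coefficients: pd.DataFrame  # per predictor (and outcome, if multinomial)
    pseudo_r2: float
    mode: str
    degenerate: bool = False
    warning: str = ""
    note: str = BAYES_NOTE


def _sv_matrix(profiles_table: pd.DataFrame):
    cols = [f"sv_{s.value}" for s in CANONICAL_ORDER]
    missing = [c for c in cols if c not in profiles_table.columns]
    if missing:
        raise ValueError(f"profile table lacks columns {missing}")
    return profiles_table[cols]


def ordinal_choice_model(profiles_table: pd.DataFrame, actual_choices,
                         mode="ordinal") -> ChoiceModelResult:
    """Regress last-block choice on the three per-strategy SVs.

    ``mode='ordinal'`` fits a proportional-odds logit over the canonical
    strategy order (the choice variable is nominally scaled, so a
    multinomial alternative is provided with ``mode='multinomial'``).
    Separation or collinearity is flagged rather than raised.
    """
    X = _sv_matrix(profiles_table)
    labels = [s.value for s in CANONICAL_ORDER]
    y = pd.Categorical([getattr(a, "value", a) for a in actual_choices],
                       categories=labels, ordered=True)
    if len(y) != len(X):
        raise ValueError("choices must align with the profile table")
    degenerate, warning = False, ""
    if (X.std(ddof=0) < 1e-12).any():
        degenerate = True
        warning = "constant SV predictor(s); coefficients unidentified"
    counts = pd.Series(y).value_counts()
    ll_null = float(np.sum(counts * np.log(counts / counts.sum())))
    def _failed(msg):
        coef = pd.DataFrame(
            {"estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
             "odds_ratio": np.nan},
            index=pd.Index(X.columns, name="term"),
        )
        return ChoiceModelResult(coefficients=coef, pseudo_r2=np.nan, mode=mode,
                                 degenerate=True, warning=msg)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mode == "ordinal":
            try:
                model = OrderedModel(np.asarray(y.codes), X.to_numpy(), distr="logit")
                res = model.fit(method="bfgs", maxiter=500, disp=False)
            except (ValueError, np.linalg.LinAlgError) as exc:
                return _failed(warning or f"model could not be fitted: {exc}")
            params = res.params[: X.shape[1]]
            bse = res.bse[: X.shape[1]]
            coef = pd.DataFrame(
                {"estimate": params, "se": bse, "z": params / bse,
                 "p": 2 * stats.norm.sf(np.abs(params / bse)),
                 "odds_ratio": np.exp(params)},
                index=pd.Index(X.columns, name="term"),
            )
        elif mode == "multinomial":
            try:
                model = sm.MNLogit(np.asarray(y.codes), sm.add_constant(X.to_numpy()))
                res = model.fit(method="newton", maxiter=200, disp=False)
            except (ValueError, np.linalg.LinAlgError) as exc:
                return _failed(warning or f"model could not be fitted: {exc}")
            names = ["intercept"] + list(X.columns)
            frames = []
            for j, outcome in enumerate(labels[1:]):
                frames.append(pd.DataFrame({
                    "outcome": outcome, "term": names,
                    "estimate": np.asarray(res.params)[:, j],
                    "se": np.asarray(res.bse)[:, j],
                }))
            coef = pd.concat(frames, ignore_index=True)
            coef["z"] = coef["estimate"] / coef["se"]
            coef["p"] = 2 * stats.norm.sf(np.abs(coef["z"]))
            coef["odds_ratio"] = np.exp(coef["estimate"])
        else:
            raise ValueError("mode must be 'ordinal' or 'multinomial'")
    est = coef["estimate"].to_numpy(dtype=float)
    if not np.all(np.isfinite(est)) or np.any(np.abs(est) > 50):
        degenerate = True
        warning = warning or "possible separation: extreme coefficient magnitudes"
    pseudo_r2 = 1.0 - float(res.llf) / ll_null if ll_null != 0 else np.nan
    return ChoiceModelResult(coefficients=coef, pseudo_r2=pseudo_r2, mode=mode,
                             degenerate=degenerate, warning=warning)


# ---------------------------------------------------------------------------
# Flexibility regression


@dataclass
class RegressionResult:
    coefficients: pd.DataFrame  # estimate, se, t, p, ci_low, ci_high
    r2: float
    F: float
    p: float
    n: int
    note: str = BAYES_NOTE


def flexer_regression(profiles_table: pd.DataFrame, flexer_scores=None) -> RegressionResult:
    """OLS of the FlexER score on the ordered-SV intercept and slope.

    The intercept predictor indexes how valuable regulation is overall;
    the slope predictor indexes preference strength (less negative =
    more flexible use of the repertoire).
    """
    data = profiles_table.copy()
    if flexer_scores is not None:
        data = data.assign(flexer=np.asarray(flexer_scores, dtype=float))
    data = data[["ordered_intercept", "ordered_slope", "flexer"]].dropna()
    if len(data) <= 3:
        raise ValueError("need more than 3 participants for the flexibility regression")
    X = sm.add_constant(data[["ordered_intercept", "ordered_slope"]])
    res = sm.OLS(data["flexer"], X).fit()
    ci = res.conf_int()
    coef = pd.DataFrame({
        "estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
        "ci_low": ci[0], "ci_high": ci[1],
    })
    coef.index = ["intercept", "b_intercept", "b_slope"]
    return RegressionResult(coefficients=coef, r2=float(res.rsquared),
                            F=float(res.fvalue), p=float(res.f_pvalue), n=len(data))


# ---------------------------------------------------------------------------
# Full pipeline


MLM_PREDICTORS = ["effort", "arousal", "utility", "corrugator", "levator"]


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate SVProfile objects (one row per participant)."""
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id}
        for s in CANONICAL_ORDER:
            row[f"sv_{s.value}"] = p.sv[s]
            row[f"rank_{s.value}"] = p.rank_code[s]
        row["ordered_intercept"] = p.ordered_intercept
        row["ordered_slope"] = p.ordered_slope
        row["predicted_choice"] = p.predicted_choice.value
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(table: pd.DataFrame, blocks: pd.DataFrame | None = None,
            profiles_table: pd.DataFrame | None = None,
            padjust="tukey") -> dict:
    """Run the full pipeline on a study table; returns a results bundle.

    ``table`` is the long-format strategy table; ``blocks`` the
    five-condition block table for the manipulation checks;
    ``profiles_table`` the per-participant SV profile table for choice
    prediction and the flexibility regression.
    """
    bundle: dict = {"note": BAYES_NOTE}
    if blocks is not None:
        checks = {}
        for dv in ("arousal", "corrugator", "levator"):
            checks[f"valence_{dv}"] = rm_anova(
                blocks, dv, levels=["view_neu", "view_neg"], padjust=padjust)
        strat_levels = ["view_neg", "distraction", "distancing", "suppression"]
        for dv in ("arousal", "corrugator", "levator", "effort"):
            checks[f"strategy_{dv}"] = rm_anova(
                blocks, dv, levels=strat_levels, padjust=padjust)
        bundle["manipulation_checks"] = checks
    bundle["mlm"] = fit_sv_mlm(table, MLM_PREDICTORS)
    if {"self_control", "nfc"}.issubset(table.columns):
        bundle["mlm_level2"] = fit_sv_mlm(
            table, ["effort", "utility", "corrugator"],
            level2_predictors=["self_control", "nfc"])
    if profiles_table is not None:
        merged = profiles_table.merge(
            table[["participant_id", "actual_choice", "flexer"]].drop_duplicates(),
            on="participant_id", how="inner")
        bundle["choice_chi2"] = predicted_vs_actual_chi2(
            merged["predicted_choice"], merged["actual_choice"])
        bundle["choice_model"] = ordinal_choice_model(merged, merged["actual_choice"])
        bundle["flexer_regression"] = flexer_regression(merged)
    return bundle
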