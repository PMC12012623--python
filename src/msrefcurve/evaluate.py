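"""Statistical battery comparing HC-based and MS-specific deviation quartiles.

Cross-sectional analyses relate quartile membership to severity outcomes
(one-way ANOVA with eta-squared and Tukey HSD post hocs gated on the omnibus
test; ANCOVA with type-II sums of squares for outcomes that need covariate
adjustment), the *added value* of the MS-specific quartiles beyond the
HC-based ones is a partial F-test between nested linear models, and the
longitudinal analyses predict 5-year outcomes from baseline quartiles with
baseline value and follow-up time as covariates (multinomial / binary
logistic for categorical outcomes, with quartile as a single ordinal
predictor).  Missing outcomes are dropped listwise per analysis;
significance is alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Input with no usable variation (constant outcome, single category...)."""


@dataclass
class GroupComparison:
    """Omnibus group test with effect size and optional post-hoc table."""

    outcome: str
    grouping: str
    F: float
    df: tuple[float, float]
    p: float
    eta_squared: float
    posthoc: list[dict] = field(default_factory=list)
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "grouping": self.grouping,
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
            "eta_squared": self.eta_squared,
            "posthoc": self.posthoc,
            "group_means": {str(k): v for k, v in self.group_means.items()},
            "group_sizes": {str(k): v for k, v in self.group_sizes.items()},
            "note": self.note,
        }


@dataclass
class AddedValueResult:
    """Partial F-test for a block added to a base linear model."""

    outcome: str
    base_terms: tuple[str, ...]
    added_term: str
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_squared: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "base_terms": list(self.base_terms),
            "added_term": self.added_term,
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
            "partial_eta_squared": self.partial_eta_squared,
            "note": self.note,
        }


@dataclass
class OddsResult:
    """Odds ratio per unit increase of the (ordinal) quartile predictor."""

    outcome: str
    predictor: str
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "odds_ratio": self.odds_ratio,
            "ci": list(self.ci),
            "p": self.p,
            "converged": self.converged,
            "note": self.note,
        }


@dataclass
class ChiSquareResult:
    """Contingency chi-square between quartiles and a categorical field."""

    chi2: float
    df: int
    p: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    low_expected: bool

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "observed": self.observed.to_dict(),
            "low_expected": self.low_expected,
        }


def _listwise(*arrays):
    cols = [np.asarray(a) for a in arrays]
    mask = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        if c.dtype.kind == "f":
            mask &= ~np.isnan(c)
        else:
            mask &= pd.notna(c)
    return [c[mask] for c in cols]


def _anova_decomposition(values: np.ndarray, groups: np.ndarray):
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_between = 0.0
    means, sizes = {}, {}
    levels = np.unique(groups)
    for g in levels:
        v = values[groups == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        means[g.item() if hasattr(g, "item") else g] = float(v.mean())
        sizes[g.item() if hasattr(g, "item") else g] = int(len(v))
    return ss_total, float(ss_between), levels, means, sizes


def quartile_anova(values, quartiles, outcome: str = "outcome",
                   grouping: str = "quartile", alpha: float = ALPHA) -> GroupComparison:
    """One-way ANOVA of an outcome across quartile groups.

    Reports F, p and eta-squared (SS_between / SS_total); Tukey HSD pairwise
    differences with family-adjusted CIs and p-values are computed only when
    the omnibus test is significant at ``alpha``.  Groups with fewer than two
    observations are excluded (noted in the result).
    """
    v, q = _listwise(np.asarray(values, dtype=float), np.asarray(quartiles))
    note = ""
    levels, counts = np.unique(q, return_counts=True)
    small = levels[counts < 2]
    if small.size:
        keep = ~np.isin(q, small)
        v, q = v[keep], q[keep]
        note = f"excluded groups with <2 values: {small.tolist()}"
        levels = np.unique(q)
    if levels.size < 2:
        raise DegenerateInputError("need at least 2 non-empty quartile groups")
    ss_total, ss_between, levels, means, sizes = _anova_decomposition(v, q)
    if ss_total == 0:
        raise DegenerateInputError("constant outcome (zero total sum of squares)")
    df_b = levels.size - 1
    df_w = len(v) - levels.size
    ss_within = ss_total - ss_between
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    posthoc = []
    if p < alpha:
        tuk = pairwise_tukeyhsd(v, q, alpha=alpha)
        frame = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        for _, row in frame.iterrows():
            posthoc.append({
                "pair": (row["group1"], row["group2"]),
                "difference": float(row["meandiff"]),
                "ci": (float(row["lower"]), float(row["upper"])),
                "p_adjusted": float(row["p-adj"]),
            })
    return GroupComparison(outcome, grouping, float(F), (float(df_b), float(df_w)),
                           p, float(ss_between / ss_total), posthoc, means, sizes,
                           note)


def added_value_test(outcome, base_quartiles, added_quartiles,
                     outcome_name: str = "outcome",
                     added_name: str = "ms_quartile") -> AddedValueResult:
    """Partial F-test: does a second quartile coding add explanatory value?

    Nested linear models ``outcome ~ C(base)`` versus
    ``outcome ~ C(base) + C(added)`` with quartiles coded as categorical
    contrasts.  If the added coding is aliased with the base (identical
    grouping), the added sum of squares is zero and F = 0 is reported rather
    than raised.
    """
    y, qb, qa = _listwise(np.asarray(outcome, dtype=float),
                          np.asarray(base_quartiles), np.asarray(added_quartiles))
    if len(y) == 0:
        raise DegenerateInputError("no complete cases")
    df = pd.DataFrame({"y": y, "qb": qb.astype(str), "qa": qa.astype(str)})
    m0 = smf.ols("y ~ C(qb)", df).fit()
    m1 = smf.ols("y ~ C(qb) + C(qa)", df).fit()
    ss_added = float(m0.ssr - m1.ssr)
    df_added = float(m0.df_resid - m1.df_resid)
    base_terms = ("hc_quartile",)
    if df_added <= 0 or ss_added <= 1e-12:
        return AddedValueResult(outcome_name, base_terms, added_name, 0.0,
                                (0.0, float(m1.df_resid)), 1.0, 0.0,
                                note="added quartile coding aliased with base")
    F = (ss_added / df_added) / (m1.ssr / m1.df_resid)
    p = float(stats.f.sf(F, df_added, m1.df_resid))
    pes = ss_added / (ss_added + float(m1.ssr))
    return AddedValueResult(outcome_name, base_terms, added_name, float(F),
                            (df_added, float(m1.df_resid)), p, float(pes))


_COVARIATE_TERMS = {
    "age": "age",
    "sex": "C(sex)",
    "disease_duration": "disease_duration",
    "phenotype": "C(phenotype)",
}


def ancova_quartiles(outcome, quartiles, covariates: pd.DataFrame,
                     outcome_name: str = "outcome",
                     grouping: str = "quartile",
                     alpha: float = ALPHA) -> GroupComparison:
    """Covariate-adjusted quartile comparison (type-II sums of squares).

    The quartile effect is tested with age, sex, disease duration and
    phenotype (whichever are present in ``covariates``) in the model.
    Eta-squared is the quartile type-II SS over the total SS.  Tukey post
    hocs on the raw outcome are attached when the adjusted omnibus test is
    significant.
    """
    cov = covariates.reset_index(drop=True)
    arrays = [np.asarray(outcome, dtype=float), np.asarray(quartiles)]
    arrays += [cov[c].to_numpy() for c in cov.columns]
    cleaned = _listwise(*arrays)
    y, q = cleaned[0], cleaned[1]
    if len(y) == 0:
        raise DegenerateInputError("no complete cases")
    data = pd.DataFrame({"y": y, "q": q.astype(str)})
    terms = []
    for j, c in enumerate(cov.columns):
        col = cleaned[2 + j]
        data[c] = col
        nuniq = pd.Series(col).nunique()
        if nuniq < 2:
            if np.issubdtype(np.asarray(col).dtype, np.number):
                raise DegenerateInputError(f"zero-variance covariate {c!r}")
            continue  # single-level categorical (e.g. one phenotype subset)
        terms.append(_COVARIATE_TERMS.get(c, c))
    formula = "y ~ " + " + ".join(terms + ["C(q)"])
    model = smf.ols(formula, data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    row = table.loc["C(q)"]
    ss_total = float(table["sum_sq"].sum())
    F, p = float(row["F"]), float(row["PR(>F)"])
    df_q, df_r = float(row["df"]), float(table.loc["Residual", "df"])
    eta2 = float(row["sum_sq"]) / ss_total if ss_total > 0 else 0.0
    if float(table.loc["Residual", "sum_sq"]) <= 1e-10 * ss_total \
            and float(row["sum_sq"]) <= 1e-10 * ss_total:
        # covariates reproduce the outcome exactly; the quartile F would be a
        # ratio of rounding noise
        return GroupComparison(outcome_name, grouping, 0.0, (df_q, df_r), 1.0,
                               0.0, [], {}, {},
                               note="degenerate: covariates fit the outcome exactly")
    posthoc = []
    if p < alpha and np.unique(q).size > 1:
        tuk = pairwise_tukeyhsd(y, q, alpha=alpha)
        frame = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        posthoc = [{
            "pair": (r["group1"], r["group2"]),
            "difference": float(r["meandiff"]),
            "ci": (float(r["lower"]), float(r["upper"])),
            "p_adjusted": float(r["p-adj"]),
        } for _, r in frame.iterrows()]
    _, _, _, means, sizes = _anova_decomposition(y, q)
    return GroupComparison(outcome_name, grouping, F, (df_q, df_r), p, eta2,
                           posthoc, means, sizes,
                           note=f"ANCOVA type-II; covariates: {terms}")


def longitudinal_quartiles(fu_outcome, quartiles, baseline, fu_time,
                           outcome_name: str = "fu_outcome",
                           grouping: str = "quartile",
                           alpha: float = ALPHA) -> GroupComparison:
    """Baseline-quartile effect on a follow-up outcome.

    Linear model of the follow-up value on the baseline value, the follow-up
    time and the quartile coding (type-II F-test for the quartile block).
    """
    y, q, b, t = _listwise(np.asarray(fu_outcome, dtype=float),
                           np.asarray(quartiles),
                           np.asarray(baseline, dtype=float),
                           np.asarray(fu_time, dtype=float))
    if len(y) == 0:
        raise DegenerateInputError("empty follow-up subset")
    cov = pd.DataFrame({"baseline": b, "fu_time": t})
    return ancova_quartiles(y, q, cov, outcome_name, grouping, alpha)


def longitudinal_added_value(fu_outcome, hc_quartiles, ms_quartiles,
                             baseline, fu_time,
                             outcome_name: str = "fu_outcome") -> AddedValueResult:
    """Added value of MS-specific over HC-based baseline quartiles at follow-up.

    Both nested models keep baseline value and follow-up time as covariates.
    """
    y, qh, qm, b, t = _listwise(np.asarray(fu_outcome, dtype=float),
                                np.asarray(hc_quartiles), np.asarray(ms_quartiles),
                                np.asarray(baseline, dtype=float),
                                np.asarray(fu_time, dtype=float))
    if len(y) == 0:
        raise DegenerateInputError("empty follow-up subset")
    df = pd.DataFrame({"y": y, "qh": qh.astype(str), "qm": qm.astype(str),
                       "baseline": b, "fu_time": t})
    m0 = smf.ols("y ~ baseline + fu_time + C(qh)", df).fit()
    m1 = smf.ols("y ~ baseline + fu_time + C(qh) + C(qm)", df).fit()
    ss_added = float(m0.ssr - m1.ssr)
    df_added = float(m0.df_resid - m1.df_resid)
    base_terms = ("baseline", "fu_time", "hc_quartile")
    if df_added <= 0 or ss_added <= 1e-12:
        return AddedValueResult(outcome_name, base_terms, "ms_quartile", 0.0,
                                (0.0, float(m1.df_resid)), 1.0, 0.0,
                                note="added quartile coding aliased with base")
    F = (ss_added / df_added) / (m1.ssr / m1.df_resid)
    p = float(stats.f.sf(F, df_added, m1.df_resid))
    pes = ss_added / (ss_added + float(m1.ssr))
    return AddedValueResult(outcome_name, base_terms, "ms_quartile", float(F),
                            (df_added, float(m1.df_resid)), p, float(pes))


def _logit_ci(beta: float, se: float):
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    # clip the log-odds bounds: exp of a wildly unstable small-sample CI
    # should saturate, not overflow
    return float(np.exp(min(lo, 700.0))), float(np.exp(min(hi, 700.0)))


def edss_change_model(categories, quartiles, fu_time) -> dict:
    """Multinomial logit of EDSS change class on the ordinal quartile.

    ``stable`` is the reference category; quartile enters as a single
    ordinal (1-4) predictor together with follow-up time.  Returns one
    :class:`OddsResult` per non-reference category; separation or
    non-convergence is reported in the result, never silent.
    """
    c, q, t = _listwise(np.asarray(categories, dtype=object),
                        np.asarray(quartiles, dtype=float),
                        np.asarray(fu_time, dtype=float))
    levels = [lv for lv in ("stable", "improved", "worsened") if lv in set(c)]
    if len(levels) < 2:
        raise DegenerateInputError(
            f"need at least 2 observed EDSS-change categories, got {levels}"
        )
    if levels[0] != "stable":
        raise DegenerateInputError("no stable patients to anchor the reference")
    codes = np.array([levels.index(x) for x in c])
    X = sm.add_constant(np.column_stack([q, t]))
    diagnostics = {lv: int((c == lv).sum()) for lv in levels}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, X).fit(method="newton", maxiter=200, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, PerfectSeparationError) as err:
        return {"converged": False, "diagnostics": diagnostics,
                "error": str(err), "results": []}
    out = []
    params = np.asarray(res.params)    # (k_exog, n_cats - 1)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    for j, lv in enumerate(levels[1:]):
        beta, se = float(params[1, j]), float(bse[1, j])
        out.append(OddsResult(
            outcome=f"edss_{lv}", predictor="quartile",
            odds_ratio=float(np.exp(beta)), ci=_logit_ci(beta, se),
            p=float(pvals[1, j]), converged=converged,
            note=f"vs stable; n={diagnostics}"))
    return {"converged": converged, "diagnostics": diagnostics, "results": out}


def cognitive_decline_model(status, quartiles, fu_time,
                            outcome_name: str = "cognitive_decline") -> OddsResult:
    """Binary logistic model of cognitive decline on the ordinal quartile.

    ``status`` holds ``declined`` / ``stable`` labels (or booleans where
    True = declined); follow-up time is a covariate.
    """
    s = np.asarray(status)
    if s.dtype.kind in "bif":
        y = s.astype(float)
    else:
        y = (s == "declined").astype(float)
    y, q, t = _listwise(y, np.asarray(quartiles, dtype=float),
                        np.asarray(fu_time, dtype=float))
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("both cognitive statuses must be observed")
    if len(np.unique(q)) < 2:
        raise DegenerateInputError("constant quartile predictor")
    X = sm.add_constant(np.column_stack([q, t]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=200, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, PerfectSeparationError) as err:
        return OddsResult(outcome_name, "quartile", float("nan"),
                          (float("nan"), float("nan")), float("nan"),
                          converged=False, note=f"separation: {err}")
    beta, se = float(res.params[1]), float(res.bse[1])
    return OddsResult(outcome_name, "quartile", float(np.exp(beta)),
                      _logit_ci(beta, se), float(res.pvalues[1]),
                      converged=converged)


def dmt_quartile_test(quartiles, dmt_values, drop_levels=("unknown",)) -> ChiSquareResult:
    """Contingency chi-square between quartiles and a DMT field.

    Rows with missing or ``unknown`` DMT status are excluded listwise.  The
    plain (uncorrected) chi-square statistic is used; a flag is raised when
    any expected cell count falls below 1.
    """
    q, d = _listwise(np.asarray(quartiles), np.asarray(dmt_values, dtype=object))
    keep = ~np.isin(d.astype(str), list(drop_levels))
    q, d = q[keep], d[keep]
    if np.unique(q).size < 2 or np.unique(d.astype(str)).size < 2:
        raise DegenerateInputError("need >= 2 levels of quartile and DMT field")
    observed = pd.crosstab(pd.Series(q, name="quartile"),
                           pd.Series(d.astype(str), name="dmt"))
    chi2, p, dof, expected = stats.chi2_contingency(observed.to_numpy(),
                                                    correction=False)
    exp = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
    return ChiSquareResult(float(chi2), int(dof), float(p), observed, exp,
                           bool((expected < 1).any()))


def dunn_posthoc(values: np.ndarray, groups: np.ndarray,
                 p_adjust: str = "holm") -> list[dict]:
    """Dunn's rank-based pairwise test after Kruskal-Wallis (tie-corrected)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    N = len(v)
    ranks = stats.rankdata(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    levels = np.unique(g)
    pairs, zs = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            ra, rb = ranks[g == a], ranks[g == b]
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / len(ra) + 1.0 / len(rb)))
            zs.append((ra.mean() - rb.mean()) / se)
            pairs.append((a, b))
    praw = 2.0 * stats.norm.sf(np.abs(zs))
    padj = multipletests(praw, method=p_adjust)[1]
    return [{"pair": (str(a), str(b)), "z": float(z),
             "p": float(pr), "p_adjusted": float(pa)}
            for (a, b), z, pr, pa in zip(pairs, zs, praw, padj)]


def pooled_mean(counts, means) -> float:
    """Exact count-weighted pooled mean of group means."""
    c = np.asarray(counts, dtype=float)
    m = np.asarray(means, dtype=float)
    if c.sum() == 0:
        raise ValueError("zero total count")
    return float(np.sum(c * m) / c.sum())


_NUMERIC_VARS = ("age", "disease_duration", "edss", "nbv", "sdmt", "nhpt", "t25fw")
_CATEGORICAL_VARS = ("sex", "dmt_ever", "dmt_efficacy")


def demographics_table(cohort: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Group descriptives with distribution-aware omnibus tests.

    For each numeric variable: per-group mean, SD, range and n; a
    Lilliefors-corrected Kolmogorov-Smirnov normality flag (on within-group
    centred values) and a Levene equal-variance flag choose between ANOVA
    with Tukey HSD and Kruskal-Wallis with Holm-adjusted Dunn post hocs.
    Categorical variables get chi-square tests.  Groups with fewer than two
    rows are excluded from testing and flagged.
    """
    groups = [g for g in cohort["phenotype"].dropna().unique()]
    if len(groups) < 2:
        note = "single group: descriptives only"
    else:
        note = ""
    out: dict = {"groups": {g: int((cohort["phenotype"] == g).sum()) for g in groups},
                 "variables": {}, "note": note}
    for var in _NUMERIC_VARS:
        if var not in cohort.columns:
            continue
        desc, samples, labels = {}, [], []
        for g in groups:
            v = cohort.loc[cohort["phenotype"] == g, var].dropna().to_numpy(float)
            if len(v) == 0:
                continue
            desc[g] = {"n": int(len(v)), "mean": float(v.mean()),
                       "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
                       "min": float(v.min()), "max": float(v.max())}
            if len(v) >= 2:
                samples.append(v)
                labels.append(g)
        entry: dict = {"descriptives": desc}
        if len(samples) >= 2 and not note:
            centred = np.concatenate([s - s.mean() for s in samples])
            try:
                _, p_norm = lilliefors(centred, dist="norm")
            except Exception:
                p_norm = 0.0
            _, p_lev = stats.levene(*samples)
            normal = p_norm > alpha
            entry["normality_p"] = float(p_norm)
            entry["levene_p"] = float(p_lev)
            vals = np.concatenate(samples)
            labs = np.concatenate([[g] * len(s) for g, s in zip(labels, samples)])
            if normal and p_lev > alpha:
                comp = quartile_anova(vals, labs, outcome=var, grouping="phenotype",
                                      alpha=alpha)
                entry["test"] = "anova"
                entry["p"] = comp.p
                entry["statistic"] = comp.F
                entry["posthoc"] = comp.posthoc
            else:
                H, p_kw = stats.kruskal(*samples)
                entry["test"] = "kruskal-wallis"
                entry["p"] = float(p_kw)
                entry["statistic"] = float(H)
                entry["posthoc"] = (dunn_posthoc(vals, labs)
                                    if p_kw < alpha else [])
        out["variables"][var] = entry
    for var in _CATEGORICAL_VARS:
        if var not in cohort.columns:
            continue
        sub = cohort[["phenotype", var]].dropna()
        sub = sub[sub[var].astype(str) != "unknown"]
        if sub.empty or not note == "" or sub["phenotype"].nunique() < 2 \
                or sub[var].nunique() < 2:
            out["variables"][var] = {"counts": cohort.groupby("phenotype")[var]
                                     .value_counts().to_dict()}
            continue
        tab = pd.crosstab(sub["phenotype"], sub[var])
        chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        out["variables"][var] = {
            "counts": {f"{i}/{c}": int(tab.loc[i, c])
                       for i in tab.index for c in tab.columns},
            "test": "chi-square", "statistic": float(chi2),
            "df": int(dof), "p": float(p),
        }
    return out
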