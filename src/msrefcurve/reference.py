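"""Normative reference models for normalized brain volume.

Two references are supported:

* an **MS-specific** model fitted on the whole cohort (healthy controls and
  patients), regressing NBV on age, sex, disease duration and phenotype
  contrasts versus HC.  Patients are scored against it with leave-one-out
  (LOO) predictions so that a subject never influences their own expected
  value;
* an **HC-based** model fitted on the healthy-control arm only, with age and
  sex, emulating the commercial normative-curve tools.  Patients are
  out-of-sample for this fit by construction, so no LOO is needed.

A subject's deviation (observed minus predicted NBV) is mapped to a
percentile either parametrically (Gaussian: ``100 * Phi(residual / sigma)``)
or by the midrank empirical CDF, and percentiles are cut at 25/50/75 into
quartiles (quartile 1 = most atrophy relative to peers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy.special import expit, ndtr
from scipy.stats import rankdata


class RankDeficientDesignError(ValueError):
    """The design matrix is collinear; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


PHENO_LEVELS = ("RRMS", "SPMS", "PPMS")  # contrasts versus HC
QUARTILE_CUTOFFS = (25.0, 50.0, 75.0)


@dataclass(frozen=True)
class CovariateSpec:
    """Response plus ordered covariate terms of a reference model.

    ``sex`` expands to a male-vs-female indicator and ``phenotype`` to three
    contrasts versus HC; any other term is used as a continuous column.
    """

    response: str = "nbv"
    terms: tuple[str, ...] = ("age", "sex", "disease_duration", "phenotype")

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate covariate terms")
        if self.response in self.terms:
            raise ValueError("response appears among the covariates")


FULL_SPEC = CovariateSpec()
HC_SPEC = CovariateSpec(terms=("age", "sex"))


def build_design(df: pd.DataFrame, spec: CovariateSpec):
    """Expand a cohort table into (X, column_names) with a leading intercept."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in spec.terms:
        if term == "sex":
            cols.append((df["sex"].to_numpy() == "M").astype(float))
            names.append("sex[M]")
        elif term == "phenotype":
            ph = df["phenotype"].to_numpy()
            for level in PHENO_LEVELS:
                cols.append((ph == level).astype(float))
                names.append(f"phenotype[{level}]")
        else:
            if term not in df.columns:
                raise KeyError(f"missing covariate column {term!r}")
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [names[j] for j in np.flatnonzero(diag <= tol)]
        raise RankDeficientDesignError(bad or names)


@dataclass
class ReferenceModelFit:
    """A fitted reference curve for NBV."""

    family: str                      # "linear" | "beta"
    spec: CovariateSpec
    intercept: float                 # %ICV (linear) or logit scale (beta)
    coefficients: dict[str, float]   # named effects, same scale as intercept
    residual_scale: float            # %ICV
    r_squared: float
    aic: float
    n: int
    name: str = "ms-specific"
    phi: float | None = None         # beta-family precision
    extra: dict = field(default_factory=dict)

    def design(self, df: pd.DataFrame):
        X, names = build_design(df, self.spec)
        beta = np.array([self.intercept] + [self.coefficients[c] for c in names[1:]])
        return X, beta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted NBV on the %ICV scale."""
        X, beta = self.design(df)
        eta = X @ beta
        if self.family == "beta":
            return expit(eta) * 100.0
        return eta

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "name": self.name,
            "response": self.spec.response,
            "terms": list(self.spec.terms),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "residual_scale": self.residual_scale,
            "r_squared": self.r_squared,
            "aic": self.aic,
            "n": self.n,
            "phi": self.phi,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModelFit":
        return cls(
            family=d["family"],
            spec=CovariateSpec(d["response"], tuple(d["terms"])),
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            residual_scale=d["residual_scale"],
            r_squared=d["r_squared"],
            aic=d["aic"],
            n=d["n"],
            name=d.get("name", "ms-specific"),
            phi=d.get("phi"),
            extra=d.get("extra", {}),
        )


def _prepare(cohort: pd.DataFrame, spec: CovariateSpec):
    y = cohort[spec.response].to_numpy(dtype=float)
    X, names = build_design(cohort, spec)
    if len(y) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} rows to fit {X.shape[1]} parameters"
        )
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    _check_rank(X, names)
    return y, X, names


def fit_linear(cohort: pd.DataFrame, spec: CovariateSpec = FULL_SPEC,
               name: str = "ms-specific") -> ReferenceModelFit:
    """Ordinary least-squares reference model."""
    y, X, names = _prepare(cohort, spec)
    res = sm.OLS(y, X).fit()
    scale = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return ReferenceModelFit(
        family="linear",
        spec=spec,
        intercept=float(res.params[0]),
        coefficients={c: float(b) for c, b in zip(names[1:], res.params[1:])},
        residual_scale=scale,
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n=len(y),
        name=name,
        extra={
            "adj_r_squared": float(res.rsquared_adj),
            "f_statistic": float(res.fvalue),
            "df_model": int(res.df_model),
            "df_resid": int(res.df_resid),
        },
    )


def fit_beta(cohort: pd.DataFrame, spec: CovariateSpec = FULL_SPEC,
             name: str = "ms-specific") -> ReferenceModelFit:
    """Beta-regression reference model (logit mean link, constant precision).

    The response, a percentage, is rescaled to (0, 1) internally; values at
    exactly 0 or 100 are rejected rather than nudged.
    """
    from statsmodels.othermod.betareg import BetaModel

    y, X, names = _prepare(cohort, spec)
    if np.any(y <= 0.0) or np.any(y >= 100.0):
        raise ValueError("beta family requires responses strictly inside (0, 100)")
    res = BetaModel(y / 100.0, X).fit(disp=0)
    k = X.shape[1] + 1  # mean coefficients + precision
    aic = 2 * k - 2 * float(res.llf)
    mean_params = np.asarray(res.params[: X.shape[1]], dtype=float)
    phi = float(np.exp(res.params[-1]))  # precision is fitted on a log link
    fitted = expit(X @ mean_params) * 100.0
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return ReferenceModelFit(
        family="beta",
        spec=spec,
        intercept=float(mean_params[0]),
        coefficients={c: float(b) for c, b in zip(names[1:], mean_params[1:])},
        residual_scale=float(np.std(resid, ddof=X.shape[1])),
        r_squared=float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0,
        aic=aic,
        n=len(y),
        name=name,
        phi=phi,
        extra={"loglik": float(res.llf)},
    )


@dataclass
class SplineCheck:
    """AIC comparison of the linear fit against a spline-augmented refit."""

    aic_linear: float
    aic_spline: float
    spline_terms: tuple[str, ...]
    df: int

    @property
    def delta(self) -> float:
        """aic_spline - aic_linear; negative favours the spline model."""
        return self.aic_spline - self.aic_linear

    @property
    def preferred(self) -> str:
        return "spline" if self.delta < 0 else "linear"


def fit_spline_check(cohort: pd.DataFrame, spec: CovariateSpec = FULL_SPEC,
                     df_spline: int = 4) -> SplineCheck:
    """Nonlinearity check: natural cubic splines on the continuous terms.

    Each continuous covariate among age and disease duration is replaced by a
    natural cubic spline basis (``df_spline`` degrees of freedom); the AICs of
    the linear and spline-augmented least-squares fits are compared.
    """
    y, X, names = _prepare(cohort, spec)
    aic_linear = float(sm.OLS(y, X).fit().aic)
    spline_terms = tuple(t for t in spec.terms if t in ("age", "disease_duration"))
    cols, keep_names = [], []
    for j, nm in enumerate(names):
        if nm not in spline_terms:
            cols.append(X[:, j])
            keep_names.append(nm)
    for t in spline_terms:
        x = cohort[t].to_numpy(dtype=float)
        basis = np.asarray(dmatrix(f"cr(x, df={df_spline}) - 1", {"x": x}))
        cols.append(basis)
        keep_names.extend([f"cr({t}){k}" for k in range(basis.shape[1])])
    Xs = np.column_stack(cols)
    aic_spline = float(sm.OLS(y, Xs).fit().aic)
    return SplineCheck(aic_linear, aic_spline, spline_terms, df_spline)


def stepwise_select(cohort: pd.DataFrame, candidate_spec: CovariateSpec = FULL_SPEC,
                    criterion: str = "aic",
                    p_enter: float = 0.05, p_remove: float = 0.10) -> CovariateSpec:
    """Bidirectional covariate selection starting from the full model.

    Terms (``phenotype`` counts as one block of three contrasts) are dropped
    or re-added greedily.  The default criterion is AIC; ``criterion="pvalue"``
    uses block partial-F p-values (enter < ``p_enter``, remove > ``p_remove``)
    as a sensitivity mode.  Deterministic: ties break on candidate order.
    """
    if not candidate_spec.terms:
        raise ValueError("need at least one candidate covariate")
    all_terms = list(candidate_spec.terms)
    current = list(all_terms)

    def aic_of(terms):
        sub = CovariateSpec(candidate_spec.response, tuple(terms))
        y, X, _ = _prepare(cohort, sub)
        return float(sm.OLS(y, X).fit().aic)

    if criterion == "aic":
        best = aic_of(current) if current else np.inf
        while True:
            moves = []
            for t in current:
                trial = [u for u in current if u != t]
                if trial:
                    moves.append((aic_of(trial), "drop", t))
            for t in all_terms:
                if t not in current:
                    trial = current + [t]
                    moves.append((aic_of([u for u in all_terms if u in trial]),
                                  "add", t))
            if not moves:
                break
            moves.sort(key=lambda m: m[0])
            cand_aic, action, term = moves[0]
            if cand_aic >= best - 1e-9:
                break
            best = cand_aic
            if action == "drop":
                current.remove(term)
            else:
                current = [u for u in all_terms if u in current or u == term]
        return CovariateSpec(candidate_spec.response,
                             tuple(t for t in all_terms if t in current))

    if criterion != "pvalue":
        raise ValueError("criterion must be 'aic' or 'pvalue'")

    def block_pvalues(terms):
        full = CovariateSpec(candidate_spec.response, tuple(terms))
        y, X, _ = _prepare(cohort, full)
        res_full = sm.OLS(y, X).fit()
        out = {}
        for t in terms:
            reduced = [u for u in terms if u != t]
            if reduced:
                yr, Xr, _ = _prepare(cohort, CovariateSpec(full.response, tuple(reduced)))
                res_r = sm.OLS(yr, Xr).fit()
            else:
                res_r = sm.OLS(y, np.ones((len(y), 1))).fit()
            out[t] = float(res_full.compare_f_test(res_r)[1])
        return out

    changed = True
    while changed and current:
        changed = False
        pv = block_pvalues(current)
        worst = max(current, key=lambda t: pv[t])
        if pv[worst] > p_remove:
            current.remove(worst)
            changed = True
            continue
        for t in all_terms:
            if t in current:
                continue
            trial = [u for u in all_terms if u in current or u == t]
            if block_pvalues(trial)[t] < p_enter:
                current = trial
                changed = True
                break
    return CovariateSpec(candidate_spec.response,
                         tuple(t for t in all_terms if t in current))


def predict_nbv(fit: ReferenceModelFit, covariates) -> np.ndarray:
    """Predict NBV (%ICV) for covariates given as a dict or DataFrame."""
    if isinstance(covariates, dict):
        covariates = pd.DataFrame([covariates])
    needed = set()
    for t in fit.spec.terms:
        needed.add(t)
    missing = needed - set(covariates.columns)
    if missing:
        raise KeyError(f"missing covariates: {sorted(missing)}")
    return fit.predict(covariates)


def loo_predictions(cohort: pd.DataFrame, spec: CovariateSpec = FULL_SPEC) -> pd.DataFrame:
    """Leave-one-out predictions: coefficients refit without each row.

    The covariate spec is held fixed across folds; only the coefficients are
    re-estimated.  Returns a frame with ``id`` (if present), ``predicted``
    and ``residual`` (observed - LOO prediction).
    """
    y, X, names = _prepare(cohort, spec)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few rows for leave-one-out fitting")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        if rank < p:
            _check_rank(Xi, names)  # raises with column names
        preds[i] = X[i] @ beta
        mask[i] = True
    out = pd.DataFrame({"predicted": preds, "residual": y - preds})
    if "id" in cohort.columns:
        out.insert(0, "id", cohort["id"].to_numpy())
    return out


def residual_percentile(residuals, sigma: float | None = None,
                        mode: str = "gaussian") -> np.ndarray:
    """Map deviations to percentiles in [0, 100].

    Gaussian mode: ``100 * Phi(residual / sigma)`` with a fixed residual
    scale.  Empirical mode: midrank ECDF percentile within the scored set.
    """
    r = np.atleast_1d(np.asarray(residuals, dtype=float))
    if mode == "gaussian":
        if sigma is None or sigma <= 0:
            raise ValueError("gaussian mode needs a positive residual scale")
        return 100.0 * ndtr(r / sigma)
    if mode == "ecdf":
        return 100.0 * (rankdata(r, method="average") - 0.5) / len(r)
    raise ValueError("mode must be 'gaussian' or 'ecdf'")


def assign_quartile(percentile) -> np.ndarray:
    """Cut percentiles at 25/50/75 into quartiles 1-4 (half-open bins).

    A percentile exactly at a cutoff falls in the upper bin; 100 is in
    quartile 4.  Quartile 1 holds the strongest atrophy relative to peers.
    """
    p = np.atleast_1d(np.asarray(percentile, dtype=float))
    if np.any((p < 0) | (p > 100)) or np.any(np.isnan(p)):
        raise ValueError("percentiles must lie in [0, 100]")
    q = np.ones(p.shape, dtype=int)
    for cut in QUARTILE_CUTOFFS:
        q += (p >= cut).astype(int)
    return q


def hc_reference(cohort: pd.DataFrame) -> ReferenceModelFit:
    """Fit the HC-based reference (age + sex) on the healthy-control rows."""
    hc = cohort[cohort["phenotype"] == "HC"]
    if len(hc) == 0:
        raise ValueError("no healthy-control rows in the cohort")
    return fit_linear(hc, HC_SPEC, name="hc-based")


def score_deviations(cohort: pd.DataFrame, reference: str = "ms",
                     mode: str = "gaussian",
                     spec: CovariateSpec = FULL_SPEC) -> pd.DataFrame:
    """Deviation scores (predicted, residual, percentile, quartile) for pwMS.

    ``reference="ms"``: the disease-specific model is fitted on the whole
    cohort and each subject is scored with leave-one-out predictions; the
    percentile scale is the full-sample residual scale.  ``reference="hc"``:
    the HC-arm model predicts patients out-of-sample.  Only patient rows are
    returned; in ECDF mode percentiles are midranks among the scored rows.
    """
    is_ms = cohort["phenotype"] != "HC"
    if reference == "ms":
        fit = fit_linear(cohort, spec)
        loo = loo_predictions(cohort, spec)
        sub = loo[is_ms.to_numpy()]
        predicted = sub["predicted"].to_numpy()
        residual = sub["residual"].to_numpy()
        sigma = fit.residual_scale
        ref_name = "ms-specific"
    elif reference == "hc":
        fit = hc_reference(cohort)
        ms = cohort[is_ms]
        predicted = fit.predict(ms)
        residual = ms["nbv"].to_numpy(dtype=float) - predicted
        sigma = fit.residual_scale
        ref_name = "hc-based"
    else:
        raise ValueError("reference must be 'ms' or 'hc'")
    pct = residual_percentile(residual, sigma=sigma, mode=mode)
    out = pd.DataFrame({
        "id": cohort.loc[is_ms, "id"].to_numpy(),
        "reference": ref_name,
        "predicted": predicted,
        "residual": residual,
        "percentile": pct,
        "quartile": assign_quartile(pct),
    })
    return out


@dataclass
class BootstrapResult:
    """Percentile bootstrap confidence intervals for the model coefficients."""

    estimates: dict[str, tuple[float, float, float]]  # name -> (point, lo, hi)
    replicates: pd.DataFrame                          # one column per coefficient
    n_replicates: int

    def ci(self, name: str) -> tuple[float, float]:
        _, lo, hi = self.estimates[name]
        return lo, hi


def bootstrap_cis(cohort: pd.DataFrame, spec: CovariateSpec = FULL_SPEC,
                  B: int = 2500, seed: int = 0, alpha: float = 0.05,
                  max_retries: int = 100) -> BootstrapResult:
    """Nonparametric case-resampling bootstrap of the linear reference model.

    Rank-deficient resamples are redrawn (up to ``max_retries`` consecutive
    times).  Percentile-method two-sided ``1 - alpha`` intervals.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    y, X, names = _prepare(cohort, spec)
    n, p = X.shape
    res = sm.OLS(y, X).fit()
    point = np.asarray(res.params, dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty((B, p))
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, n)
            beta, _, rank, _ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            if rank == p:
                boots[b] = beta
                break
        else:
            raise RuntimeError("bootstrap resamples persistently rank-deficient")
    lo = np.percentile(boots, 100 * alpha / 2, axis=0)
    hi = np.percentile(boots, 100 * (1 - alpha / 2), axis=0)
    est = {nm: (float(point[j]), float(lo[j]), float(hi[j]))
           for j, nm in enumerate(names)}
    return BootstrapResult(est, pd.DataFrame(boots, columns=names), B)


def interaction_screen(cohort: pd.DataFrame,
                       spec: CovariateSpec = FULL_SPEC) -> dict:
    """AIC screen of all two-way covariate interactions added jointly.

    Products of the expanded covariate columns are appended to the
    main-effects design (zero and collinear products are dropped) and the
    AICs compared.  Reported for diagnostics only; quartile scoring always
    uses the main-effects model.
    """
    y, X, names = _prepare(cohort, spec)
    cols = [X]
    int_names = list(names)
    for a in range(1, X.shape[1]):
        for b in range(a + 1, X.shape[1]):
            prod = X[:, a] * X[:, b]
            if np.ptp(prod) == 0:
                continue
            trial = np.column_stack(cols + [prod])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols = [trial]
                int_names.append(f"{names[a]}:{names[b]}")
    Xi = cols[0]
    aic_main = float(sm.OLS(y, X).fit().aic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic_int = float(sm.OLS(y, Xi).fit().aic)
    return {
        "aic_main": aic_main,
        "aic_interactions": aic_int,
        "delta": aic_int - aic_main,
        "n_interaction_terms": Xi.shape[1] - X.shape[1],
        "preferred": "interactions" if aic_int < aic_main else "main-effects",
    }
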