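"""Synthetic MS cohort generator.

Emulates a cross-sectional MS-centre cohort (healthy controls plus the three
major MS phenotypes) with the covariate mixture, the linear generative model
for normalized brain volume (NBV, % of intracranial volume) and the
outcome-coupling structure the reference-curve analysis assumes:

* ages and disease durations are drawn from truncated normals per group;
* NBV is a linear function of age, sex, disease duration and phenotype plus
  Gaussian noise;
* clinical severity is driven by a latent variable proportional to the
  *negative standardized residual* of the NBV generative model -- i.e. by how
  far a patient's brain volume falls below the disease-specific expectation,
  not below a healthy-control expectation -- plus duration-linked drift and
  noise.  EDSS is obtained by quantile-mapping the latent onto the 0-8.5
  half-point grid within phenotype x duration strata, so that rank-based
  severity scores computed downstream inherit the intended coupling.

The default configuration encodes the published cohort composition
(259 HC / 503 RRMS / 134 SPMS / 76 PPMS) and the published generative
coefficients; see :func:`default_config`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, ndtri
from scipy.stats import rankdata, truncnorm

from .strata import pool_duration_bins

PHENOTYPES = ("HC", "RRMS", "SPMS", "PPMS")
MS_PHENOTYPES = ("RRMS", "SPMS", "PPMS")
EDSS_MAX = 8.5

COG_TESTS = ("cog1", "cog2", "cog3", "cog4", "cog5")


class GroupParams(BaseModel):
    """Covariate distribution of one phenotype group."""

    n: int = Field(ge=0)
    age_mean: float
    age_sd: float = Field(gt=0)
    age_range: tuple[float, float]
    pct_female: float = Field(ge=0.0, le=1.0)
    duration_mean: Optional[float] = None
    duration_sd: Optional[float] = Field(default=None, gt=0)
    duration_range: Optional[tuple[float, float]] = None


class GenerativeCoefficients(BaseModel):
    """Linear model for NBV (%ICV): intercept + effects of the covariates.

    Phenotype effects are contrasts versus healthy controls.
    """

    intercept: float
    age: float
    male: float
    duration: float
    ppms: float
    rrms: float
    spms: float


class OutcomeParams(BaseModel):
    """Coupling of clinical outcomes to the latent severity variable."""

    coupling: float = 0.6       # latent units per SD of negative NBV residual
    noise_sd: float = Field(default=1.0, ge=0)
    edss_base: float = 1.6      # expected EDSS at zero duration, RRMS
    edss_drift: float = 0.09    # expected EDSS increase per duration year
    edss_sd: float = 1.0
    pheno_offset: dict[str, float] = Field(
        default_factory=lambda: {"RRMS": 0.0, "SPMS": 1.55, "PPMS": 1.9}
    )
    sdmt_intercept: float = 62.0
    sdmt_slope: float = -3.0     # SDMT points per latent unit (lower = worse)
    sdmt_noise_sd: float = Field(default=9.0, ge=0)
    nhpt_intercept: float = 17.0
    nhpt_slope: float = 1.5      # seconds per latent unit (higher = worse)
    nhpt_noise_sd: float = Field(default=3.0, ge=0)
    t25fw_intercept: float = 4.5
    t25fw_slope: float = 0.0     # decoupled by default: no quartile effect
    t25fw_noise_sd: float = Field(default=1.5, ge=0)


class FollowupParams(BaseModel):
    """Five-year clinical-only follow-up of a patient subset."""

    n: int = Field(default=297, ge=0)
    time_mean: float = 4.93
    time_sd: float = Field(default=0.72, gt=0)
    n_rrms_to_spms: int = Field(default=23, ge=0)
    worsening_base_logodds: float = -0.85
    worsening_coupling: float = 0.3   # log-odds per SD of deviation below expectation
    improvement_prob: float = Field(default=0.08, ge=0, le=1)
    cog_practice_mean: float = 0.5
    cog_hc_sd: float = Field(default=3.0, gt=0)
    cog_ms_shift: float = -0.8
    cog_coupling: float = 0.3         # change-score units per residual SD


class SyntheticConfig(BaseModel):
    """Full parameterization of the synthetic cohort generator."""

    groups: dict[str, GroupParams]
    generative_coefficients: GenerativeCoefficients
    residual_sd: float = Field(default=2.8, gt=0)
    outcomes: OutcomeParams = Field(default_factory=OutcomeParams)
    followup: FollowupParams = Field(default_factory=FollowupParams)
    dmt_ever_freq: dict[str, tuple[float, float, float]]  # yes / no / unknown
    dmt_efficacy_freq: dict[str, tuple[float, float, float, float, float]]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name in PHENOTYPES:
            if name not in self.groups:
                raise ValueError(f"missing group parameters for {name!r}")
        for name in MS_PHENOTYPES:
            g = self.groups[name]
            if g.duration_mean is None or g.duration_sd is None:
                raise ValueError(f"group {name!r} needs duration parameters")
        if all(g.n == 0 for g in self.groups.values()):
            raise ValueError("all group counts are zero")
        return self

    @property
    def n_per_group(self) -> tuple[int, ...]:
        return tuple(self.groups[p].n for p in PHENOTYPES)

    @property
    def outcome_coupling(self) -> float:
        return self.outcomes.coupling

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        return cls.model_validate_json(text)


# ---------------------------------------------------------------------------
# Published cohort calibration
# ---------------------------------------------------------------------------

# Generative NBV coefficients (%ICV): effects of age (per year), male sex,
# disease duration (per year) and phenotype contrasts vs healthy controls.
GENERATIVE_BETAS = {
    "age": -0.077,
    "male": -0.758,
    "duration": -0.083,
    "ppms": -1.038,
    "rrms": -1.076,
    "spms": -1.787,
}

_GROUP_DEFAULTS = {
    "HC": dict(n=259, age_mean=48.3, age_sd=10.1, age_range=(18.9, 65.0),
               pct_female=174 / 259),
    "RRMS": dict(n=503, age_mean=46.7, age_sd=9.8, age_range=(21.0, 70.6),
                 pct_female=389 / 503, duration_mean=12.8, duration_sd=8.7,
                 duration_range=(0.69, 47.0)),
    "SPMS": dict(n=134, age_mean=54.5, age_sd=5.6, age_range=(34.0, 72.4),
                 pct_female=78 / 134, duration_mean=20.7, duration_sd=8.9,
                 duration_range=(3.5, 45.9)),
    "PPMS": dict(n=76, age_mean=55.8, age_sd=7.6, age_range=(35.0, 73.3),
                 pct_female=35 / 76, duration_mean=12.3, duration_sd=8.2,
                 duration_range=(0.7, 33.3)),
}

# DMT category frequencies per phenotype (drawn independently of deviation).
_DMT_EVER = {
    "RRMS": (261, 116, 126),
    "SPMS": (66, 29, 39),
    "PPMS": (15, 47, 15),
}
_DMT_EFFICACY = {
    "RRMS": (111, 10, 27, 229, 126),
    "SPMS": (18, 3, 6, 68, 39),
    "PPMS": (2, 0, 7, 53, 14),
}

_HC_TARGET_NBV = 82.7  # expected mean NBV of the HC arm, %ICV


def _truncated_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default generator configuration calibrated to the published cohort.

    The intercept of the NBV generative model is not a published quantity; it
    is set so that the *expected* mean NBV of the simulated healthy-control
    arm (truncated age distribution, 67.2% female) equals 82.7 %ICV.
    """
    hc = _GROUP_DEFAULTS["HC"]
    mean_age_hc = _truncated_mean(hc["age_mean"], hc["age_sd"], *hc["age_range"])
    frac_male_hc = 1.0 - hc["pct_female"]
    b = GENERATIVE_BETAS
    intercept = _HC_TARGET_NBV - b["age"] * mean_age_hc - b["male"] * frac_male_hc
    norm = lambda v: tuple(np.asarray(v, dtype=float) / np.sum(v))
    return SyntheticConfig(
        groups={k: GroupParams(**v) for k, v in _GROUP_DEFAULTS.items()},
        generative_coefficients=GenerativeCoefficients(intercept=intercept, **b),
        dmt_ever_freq={k: norm(v) for k, v in _DMT_EVER.items()},
        dmt_efficacy_freq={k: norm(v) for k, v in _DMT_EFFICACY.items()},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def linear_predictor(config: SyntheticConfig, df: pd.DataFrame) -> np.ndarray:
    """Expected NBV under the generative model for each row of ``df``."""
    c = config.generative_coefficients
    pred = (
        c.intercept
        + c.age * df["age"].to_numpy(float)
        + c.male * (df["sex"].to_numpy() == "M")
        + c.duration * df["disease_duration"].to_numpy(float)
        + c.rrms * (df["phenotype"].to_numpy() == "RRMS")
        + c.spms * (df["phenotype"].to_numpy() == "SPMS")
        + c.ppms * (df["phenotype"].to_numpy() == "PPMS")
    )
    return np.asarray(pred, dtype=float)


def _snap_edss(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 2.0) / 2.0, 0.0, EDSS_MAX)


def _draw_truncnorm(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a baseline cohort table, one row per participant.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    out = config.outcomes
    rows = []
    for ph in PHENOTYPES:
        g = config.groups[ph]
        if g.n == 0:
            continue
        age = _draw_truncnorm(rng, g.n, g.age_mean, g.age_sd, *g.age_range)
        sex = np.where(rng.random(g.n) < g.pct_female, "F", "M")
        if ph == "HC":
            duration = np.zeros(g.n)
        else:
            duration = _draw_truncnorm(
                rng, g.n, g.duration_mean, g.duration_sd, *g.duration_range
            )
        rows.append(pd.DataFrame({
            "id": [f"{ph}{i + 1:04d}" for i in range(g.n)],
            "phenotype": ph,
            "age": age,
            "sex": sex,
            "disease_duration": duration,
        }))
    df = pd.concat(rows, ignore_index=True)
    n = len(df)

    pred = linear_predictor(config, df)
    noise = rng.normal(0.0, config.residual_sd, n)
    df["nbv"] = pred + noise
    z = noise / config.residual_sd  # standardized generative residual

    is_ms = df["phenotype"].to_numpy() != "HC"
    latent = np.full(n, np.nan)
    latent[is_ms] = (
        out.coupling * (-z[is_ms])
        + out.edss_drift * df.loc[is_ms, "disease_duration"].to_numpy()
        + rng.normal(0.0, out.noise_sd, int(is_ms.sum()))
    )

    # EDSS: quantile-map the latent onto the half-point grid within
    # phenotype x duration strata, so within-stratum EDSS ranks equal
    # latent-severity ranks by construction.
    edss = np.full(n, np.nan)
    ms_idx = np.flatnonzero(is_ms)
    dur_ms = df.loc[ms_idx, "disease_duration"].to_numpy()
    pheno_ms = df.loc[ms_idx, "phenotype"].to_numpy()
    for ph in MS_PHENOTYPES:
        sel = ms_idx[pheno_ms == ph]
        if len(sel) == 0:
            continue
        strata = pool_duration_bins(df.loc[sel, "disease_duration"].to_numpy(),
                                    min_size=5)
        for s in np.unique(strata):
            members = sel[strata == s]
            lat = latent[members]
            p = (rankdata(lat, method="average") - 0.5) / len(members)
            mu = (out.edss_base + out.pheno_offset.get(ph, 0.0)
                  + out.edss_drift * df.loc[members, "disease_duration"].mean())
            edss[members] = _snap_edss(mu + out.edss_sd * ndtri(p))
    df["edss"] = edss

    sdmt = np.full(n, np.nan)
    nhpt = np.full(n, np.nan)
    t25fw = np.full(n, np.nan)
    lat_ms = latent[is_ms]
    sdmt[is_ms] = np.round(np.clip(
        out.sdmt_intercept + out.sdmt_slope * lat_ms
        + rng.normal(0.0, out.sdmt_noise_sd, len(lat_ms)), 5.0, 110.0))
    nhpt[is_ms] = np.clip(
        out.nhpt_intercept + out.nhpt_slope * lat_ms
        + rng.normal(0.0, out.nhpt_noise_sd, len(lat_ms)), 10.0, None)
    t25fw[is_ms] = np.clip(
        out.t25fw_intercept + out.t25fw_slope * lat_ms
        + rng.normal(0.0, out.t25fw_noise_sd, len(lat_ms)), 2.5, None)
    df["sdmt"], df["nhpt"], df["t25fw"] = sdmt, nhpt, t25fw

    dmt_ever = np.full(n, None, dtype=object)
    dmt_eff = np.full(n, None, dtype=object)
    for ph in MS_PHENOTYPES:
        sel = np.flatnonzero(df["phenotype"].to_numpy() == ph)
        if len(sel) == 0:
            continue
        dmt_ever[sel] = rng.choice(["yes", "no", "unknown"], size=len(sel),
                                   p=config.dmt_ever_freq[ph])
        dmt_eff[sel] = rng.choice(["low", "medium", "high", "none", "unknown"],
                                  size=len(sel), p=config.dmt_efficacy_freq[ph])
    df["dmt_ever"], df["dmt_efficacy"] = dmt_ever, dmt_eff
    return df


def generate_followup(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Attach 5-year clinical follow-up fields to a baseline cohort.

    A random patient subset of size ``config.followup.n`` receives a
    follow-up time, an evolved EDSS whose worsening probability increases as
    the baseline disease-specific NBV deviation decreases, and per-test
    cognitive change scores.  All healthy controls receive cognitive change
    scores as well; those define the reliable-change reference downstream.
    """
    fu = config.followup
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    df = cohort.copy()
    n = len(df)
    is_ms = df["phenotype"].to_numpy() != "HC"
    ms_idx = np.flatnonzero(is_ms)
    if fu.n > len(ms_idx):
        raise ValueError(
            f"follow-up size {fu.n} exceeds the {len(ms_idx)} patients in the cohort"
        )
    z = ((df["nbv"].to_numpy() - linear_predictor(config, df))
         / config.residual_sd)

    chosen = np.sort(rng.choice(ms_idx, size=fu.n, replace=False))
    fu_time = np.full(n, np.nan)
    a = (0.0 - fu.time_mean) / fu.time_sd
    fu_time[chosen] = truncnorm.rvs(a, np.inf, loc=fu.time_mean, scale=fu.time_sd,
                                    size=fu.n, random_state=rng)

    baseline = df["edss"].to_numpy()
    fu_edss = np.full(n, np.nan)
    for i in chosen:
        b = baseline[i]
        thr = 1.5 if b == 0.0 else (1.0 if b <= 4.5 else 0.5)
        p_w = expit(fu.worsening_base_logodds + fu.worsening_coupling * (-z[i]))
        u = rng.random()
        if u < p_w:
            extra = 0.5 if rng.random() < 0.25 else 0.0
            val = min(b + thr + extra, 10.0)
        elif u < p_w + fu.improvement_prob:
            val = max(b - thr, 0.0)
        else:
            delta = rng.choice([0.0, 0.5, -0.5], p=[0.6, 0.2, 0.2])
            if abs(delta) >= thr:
                delta = 0.0
            val = float(np.clip(b + delta, 0.0, 10.0))
        fu_edss[i] = val
    df["fu_time"], df["fu_edss"] = fu_time, fu_edss

    # Label-only RRMS -> SPMS conversions among the worst-deviating patients.
    fu_pheno = np.full(n, None, dtype=object)
    fu_pheno[chosen] = df.loc[chosen, "phenotype"].to_numpy()
    rr = chosen[df.loc[chosen, "phenotype"].to_numpy() == "RRMS"]
    n_conv = min(fu.n_rrms_to_spms, len(rr))
    if n_conv > 0:
        fu_pheno[rr[np.argsort(z[rr])[:n_conv]]] = "SPMS"
    df["fu_phenotype"] = fu_pheno

    is_hc = ~is_ms
    for t in COG_TESTS:
        change = np.full(n, np.nan)
        change[is_hc] = rng.normal(fu.cog_practice_mean, fu.cog_hc_sd,
                                   int(is_hc.sum()))
        change[chosen] = rng.normal(
            fu.cog_practice_mean + fu.cog_ms_shift + fu.cog_coupling * z[chosen],
            fu.cog_hc_sd, fu.n)
        df[f"{t}_change"] = change
    return df
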