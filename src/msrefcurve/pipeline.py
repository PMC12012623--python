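"""End-to-end pipeline: simulate -> fit -> deviations -> severity -> evaluate.

Every stage writes its intermediate to ``out_dir`` with seed, config hash and
package version embedded, and the same config + seed reproduce byte-identical
numeric outputs.  A stage failure aborts with the stage name attached.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import evaluate as ev
from . import io
from .cohort import SyntheticConfig, default_config, generate_cohort, generate_followup
from .reference import (FULL_SPEC, bootstrap_cis, fit_linear, hc_reference,
                        score_deviations)
from .severity import classify_edss_change, compute_msss, compute_rci


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


class PipelineConfig(BaseModel):
    """Paths and switches for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    percentile_mode: str = "gaussian"       # or "ecdf"
    bootstrap_B: int = Field(default=2500, ge=2)
    subset: Optional[str] = None            # phenotype filter for evaluation
    make_figures: bool = True
    synthetic: Optional[SyntheticConfig] = None

    def resolved_synthetic(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return default_config(seed=self.seed)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(name, err) from err
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a synthetic cohort; returns the results dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    syn = config.resolved_synthetic()
    cfg_hash = io.config_hash(syn)
    seed = config.seed

    cohort = _stage("simulate")(lambda: generate_followup(generate_cohort(syn), syn))()
    io.write_config_json(syn, out_dir / "config.json")
    io.write_cohort_csv(cohort, out_dir / "cohort.csv", seed, cfg_hash)

    def _fits():
        return fit_linear(cohort, FULL_SPEC), hc_reference(cohort)

    fit_ms, fit_hc = _stage("fit")(_fits)()
    io.write_fit_json(fit_ms, out_dir / "fit_ms.json", seed, cfg_hash)
    io.write_fit_json(fit_hc, out_dir / "fit_hc.json", seed, cfg_hash)
    boot = _stage("bootstrap")(
        lambda: bootstrap_cis(cohort, FULL_SPEC, B=config.bootstrap_B, seed=seed)
    )()

    def _devs():
        dms = score_deviations(cohort, "ms", mode=config.percentile_mode)
        dhc = score_deviations(cohort, "hc", mode=config.percentile_mode)
        return dms, dhc

    dev_ms, dev_hc = _stage("deviations")(_devs)()
    io.write_table(dev_ms, out_dir / "deviations_ms.csv",
                   io.make_metadata(seed, cfg_hash))
    io.write_table(dev_hc, out_dir / "deviations_hc.csv",
                   io.make_metadata(seed, cfg_hash))

    def _severity():
        ms = cohort[cohort["phenotype"] != "HC"].reset_index(drop=True)
        msss = compute_msss(ms["edss"], ms["disease_duration"])
        sev = pd.DataFrame({"id": ms["id"], "msss": msss["msss"].to_numpy()})
        fu = ms[ms["fu_time"].notna()]
        change = classify_edss_change(fu["edss"], fu["fu_edss"])
        sev = sev.merge(pd.DataFrame({"id": fu["id"], "edss_change": change}),
                        on="id", how="left")
        cog_cols = [c for c in cohort.columns if c.endswith("_change")
                    and c.startswith("cog")]
        if cog_cols:
            hc_tab = cohort.loc[cohort["phenotype"] == "HC", cog_cols].dropna()
            pat = fu[["id"] + cog_cols].dropna()
            if len(pat) and len(hc_tab) >= 2:
                rci = compute_rci(pat, hc_tab)
                sev = sev.merge(rci[["id", "n_declining_tests", "status"]]
                                .rename(columns={"status": "cog_status"}),
                                on="id", how="left")
        return sev

    severity = _stage("severity")(_severity)()
    io.write_table(severity, out_dir / "severity.csv",
                   io.make_metadata(seed, cfg_hash))

    results = _stage("evaluate")(
        lambda: evaluate_bundle(cohort, dev_ms, dev_hc, severity,
                                subset=config.subset)
    )()
    results["bootstrap"] = {
        name: {"point": pt, "ci": [lo, hi]}
        for name, (pt, lo, hi) in boot.estimates.items()
    }
    results["fits"] = {"ms": fit_ms.to_dict(), "hc": fit_hc.to_dict()}
    io.write_results_json(results, out_dir / "results.json", seed, cfg_hash)

    if config.make_figures:
        from .plots import plot_quartile_boxes, plot_reference_curves
        fig_dir = out_dir / "figures"
        _stage("report")(lambda: plot_reference_curves(
            fit_ms, "RRMS", "F", 10.0, cohort, fig_dir / "reference_curves.png"))()
        merged = severity.merge(dev_ms[["id", "quartile"]], on="id")
        _stage("report")(lambda: plot_quartile_boxes(
            merged["msss"], merged["quartile"], "MSSS",
            fig_dir / "msss_by_quartile.png"))()
    return results


def evaluate_bundle(cohort: pd.DataFrame, dev_ms: pd.DataFrame,
                    dev_hc: pd.DataFrame, severity: pd.DataFrame,
                    subset: str | None = None) -> dict:
    """The full statistical battery on scored deviation + severity tables."""
    ms = cohort[cohort["phenotype"] != "HC"].reset_index(drop=True)
    tab = (ms.merge(dev_ms[["id", "quartile"]].rename(columns={"quartile": "q_ms"}),
                    on="id")
             .merge(dev_hc[["id", "quartile"]].rename(columns={"quartile": "q_hc"}),
                    on="id")
             .merge(severity, on="id", how="left"))
    if subset is not None:
        tab = tab[tab["phenotype"] == subset].reset_index(drop=True)
    cov = tab[["age", "sex", "disease_duration", "phenotype"]]
    results: dict = {"n_patients": int(len(tab)), "subset": subset}

    results["demographics"] = ev.demographics_table(cohort)

    anova = {}
    for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc")):
        anova[ref] = ev.quartile_anova(tab["msss"], tab[qcol],
                                       outcome="msss",
                                       grouping=f"{ref}_quartile").to_dict()
    results["msss_anova"] = anova
    results["msss_added_value"] = ev.added_value_test(
        tab["msss"], tab["q_hc"], tab["q_ms"], outcome_name="msss").to_dict()

    ancova, added = {}, {}
    for outcome in ("sdmt", "nhpt", "t25fw"):
        ancova[outcome] = {
            ref: ev.ancova_quartiles(tab[outcome], tab[qcol], cov,
                                     outcome_name=outcome,
                                     grouping=f"{ref}_quartile").to_dict()
            for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc"))
        }
        added[outcome] = ev.added_value_test(
            tab[outcome], tab["q_hc"], tab["q_ms"], outcome_name=outcome).to_dict()
    results["functional_ancova"] = ancova
    results["functional_added_value"] = added

    results["dmt"] = {}
    for fld in ("dmt_ever", "dmt_efficacy"):
        per_ref = {}
        for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc")):
            try:
                per_ref[ref] = ev.dmt_quartile_test(
                    tab[qcol], tab[fld],
                    drop_levels=("unknown", "none"))
                per_ref[ref] = per_ref[ref].to_dict()
            except ev.DegenerateInputError as err:
                per_ref[ref] = {"error": str(err)}
        results["dmt"][fld] = per_ref

    fu = tab[tab["fu_time"].notna()].reset_index(drop=True)
    longitudinal: dict = {"n_followup": int(len(fu))}
    if len(fu) >= 20:
        fu_msss = compute_msss(fu["fu_edss"], fu["disease_duration"]
                               + fu["fu_time"])["msss"].to_numpy()
        longitudinal["fu_msss_anova"] = {
            ref: ev.longitudinal_quartiles(fu_msss, fu[qcol], fu["msss"],
                                           fu["fu_time"],
                                           outcome_name="fu_msss",
                                           grouping=f"{ref}_quartile").to_dict()
            for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc"))
        }
        longitudinal["fu_msss_added_value"] = ev.longitudinal_added_value(
            fu_msss, fu["q_hc"], fu["q_ms"], fu["msss"], fu["fu_time"],
            outcome_name="fu_msss").to_dict()
        if "edss_change" in fu.columns:
            longitudinal["edss_change"] = {}
            for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc")):
                try:
                    res = ev.edss_change_model(fu["edss_change"], fu[qcol],
                                               fu["fu_time"])
                    longitudinal["edss_change"][ref] = {
                        "converged": res["converged"],
                        "diagnostics": res["diagnostics"],
                        "results": [r.to_dict() for r in res["results"]],
                    }
                except ev.DegenerateInputError as err:
                    longitudinal["edss_change"][ref] = {"error": str(err)}
        if "cog_status" in fu.columns and fu["cog_status"].notna().any():
            longitudinal["cognitive_decline"] = {}
            for ref, qcol in (("ms", "q_ms"), ("hc", "q_hc")):
                sub = fu[fu["cog_status"].notna()]
                try:
                    longitudinal["cognitive_decline"][ref] = (
                        ev.cognitive_decline_model(sub["cog_status"], sub[qcol],
                                                   sub["fu_time"]).to_dict())
                except ev.DegenerateInputError as err:
                    longitudinal["cognitive_decline"][ref] = {"error": str(err)}
    results["longitudinal"] = longitudinal

    qsizes = np.unique(tab["q_ms"], return_counts=True)
    results["quartile_sizes_ms"] = {int(k): int(v) for k, v in zip(*qsizes)}
    return results
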