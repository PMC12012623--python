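"""Figures: reference curves with quartile bands, outcome-by-quartile boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.special import ndtri

from .reference import ReferenceModelFit

_BAND_COLORS = ("#d7301f", "#fdae61", "#a6d96a", "#1a9641")


def reference_curve_bands(fit: ReferenceModelFit, phenotype: str, sex: str,
                          duration: float, ages: np.ndarray,
                          sigma: float | None = None) -> dict:
    """Mean NBV curve and quartile band boundaries over an age grid.

    Boundaries are the predicted 25th/50th/75th percentile curves under the
    Gaussian residual model (``mean + sigma * z_{25/50/75}``).
    """
    sigma = fit.residual_scale if sigma is None else sigma
    if sigma <= 0:
        raise ValueError("positive residual scale required")
    grid = pd.DataFrame({
        "age": ages,
        "sex": sex,
        "disease_duration": duration,
        "phenotype": phenotype,
    })
    mean = fit.predict(grid)
    bounds = {f"p{int(p)}": mean + sigma * ndtri(p / 100.0) for p in (25, 50, 75)}
    return {"ages": np.asarray(ages, dtype=float), "mean": mean, **bounds}


def plot_reference_curves(fit: ReferenceModelFit, phenotype: str = "RRMS",
                          sex: str = "F", duration: float = 10.0,
                          cohort: pd.DataFrame | None = None,
                          path=None, sigma: float | None = None,
                          age_range: tuple[float, float] = (20.0, 70.0),
                          support: tuple[float, float] | None = None) -> dict:
    """Reference curves (NBV vs age) with shaded quartile bands.

    Curves are drawn for a fixed sex, phenotype and disease duration; subject
    points from ``cohort`` (same phenotype and sex, duration within +/- 2.5 y)
    are overlaid.  If the requested duration lies outside ``support`` (the
    fitted duration range, when given) the figure carries a warning
    annotation.  Returns the band data used for drawing.
    """
    ages = np.linspace(*age_range, 121)
    bands = reference_curve_bands(fit, phenotype, sex, duration, ages, sigma)
    fig, ax = plt.subplots(figsize=(7, 5))
    sig = fit.residual_scale if sigma is None else sigma
    lo = bands["mean"] - 4 * sig
    hi = bands["mean"] + 4 * sig
    edges = [lo, bands["p25"], bands["p50"], bands["p75"], hi]
    for k in range(4):
        ax.fill_between(ages, edges[k], edges[k + 1], color=_BAND_COLORS[k],
                        alpha=0.45, label=f"quartile {k + 1}")
    ax.plot(ages, bands["mean"], color="k", lw=1.2, label="expected NBV")
    if cohort is not None:
        sel = ((cohort["phenotype"] == phenotype) & (cohort["sex"] == sex)
               & (cohort["disease_duration"].sub(duration).abs() <= 2.5))
        ax.scatter(cohort.loc[sel, "age"], cohort.loc[sel, "nbv"], s=12,
                   color="k", zorder=3, label="subjects")
    if support is not None and not (support[0] <= duration <= support[1]):
        ax.annotate("requested duration outside fitted support",
                    xy=(0.02, 0.02), xycoords="axes fraction", color="crimson")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized brain volume (%ICV)")
    ax.set_title(f"{fit.name} reference, {sex}/{phenotype}, "
                 f"duration {duration:g} y")
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return bands


def plot_quartile_boxes(values, quartiles, outcome: str, path=None):
    """Boxplots of an outcome per deviation quartile."""
    v = np.asarray(values, dtype=float)
    q = np.asarray(quartiles)
    mask = ~np.isnan(v)
    v, q = v[mask], q[mask]
    levels = np.unique(q)
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [v[q == lv] for lv in levels]
    ax.boxplot(data, tick_labels=[str(lv) for lv in levels])
    ax.set_xlabel("deviation quartile (1 = most atrophy)")
    ax.set_ylabel(outcome)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return {str(lv): float(np.median(d)) for lv, d in zip(levels, data)}
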