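"""Clinical severity quantities: MSSS, EDSS change class, reliable change.

The MS severity score (MSSS) expresses a patient's EDSS as a rank among
patients with comparable disease duration, scaled to (0, 10): within a
duration stratum of size ``n`` the patient with midrank ``R`` gets
``10 * (R - 0.5) / n``.  By construction the stratum mean is exactly 5 and
the score depends on EDSS only through its within-stratum ranks.  The
published global MSSS lookup table is external data; this module computes a
cohort-local MSSS by the same ranking construction and can alternatively
apply a user-supplied lookup table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .strata import pool_duration_bins

EDSS_CHANGE_CATEGORIES = ("worsened", "stable", "improved")

#: tests whose change scores run the "wrong way" (higher = worse) and are
#: sign-flipped before the decline threshold is applied
HIGHER_IS_WORSE = frozenset({"nhpt", "t25fw"})

RCI_THRESHOLD = 1.645  # 90% one-sided confidence toward decline


def _validate_edss(values, name: str = "edss") -> np.ndarray:
    v = np.atleast_1d(np.asarray(values, dtype=float))
    ok = (v >= 0) & (v <= 10) & (np.mod(v * 2, 1) == 0)
    if not np.all(ok):
        bad = v[~ok]
        raise ValueError(f"{name} values off the 0-10 half-point grid: {bad[:5]}")
    return v


def compute_msss(edss, duration, min_stratum: int = 5,
                 lookup: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort-local MSSS per patient.

    Patients are binned by integer disease-duration year (sparse bins pooled
    with their neighbours until each stratum holds at least ``min_stratum``
    patients); within each stratum MSSS is the scaled EDSS midrank.  If a
    ``lookup`` table is given (columns ``duration_year``, ``edss``, ``msss``)
    scores are taken from it instead.

    Returns a frame with ``msss``, ``duration_stratum`` and ``stratum_size``.
    """
    # rank-based: any strictly monotone relabeling of EDSS gives the same
    # scores, so no half-point grid is enforced here
    e = np.atleast_1d(np.asarray(edss, dtype=float))
    d = np.atleast_1d(np.asarray(duration, dtype=float))
    if e.size == 0:
        raise ValueError("empty input")
    if np.any(~np.isfinite(e)):
        raise ValueError("non-finite EDSS values")
    if e.shape != d.shape:
        raise ValueError("edss and duration lengths differ")
    if np.any(d <= 0):
        raise ValueError("disease durations must be positive")

    if lookup is not None:
        return _lookup_msss(e, d, lookup)

    strata = pool_duration_bins(d, min_size=min_stratum)
    msss = np.empty_like(e)
    size = np.empty(e.shape, dtype=int)
    for s in np.unique(strata):
        sel = strata == s
        n_d = int(sel.sum())
        ranks = rankdata(e[sel], method="average")
        msss[sel] = 10.0 * (ranks - 0.5) / n_d
        size[sel] = n_d
    return pd.DataFrame({
        "msss": msss,
        "duration_stratum": strata,
        "stratum_size": size,
    })


def load_msss_lookup(path) -> pd.DataFrame:
    """Read an external MSSS lookup CSV (duration_year, edss, msss)."""
    table = pd.read_csv(path, comment="#")
    required = {"duration_year", "edss", "msss"}
    if not required.issubset(table.columns):
        raise ValueError(f"lookup table needs columns {sorted(required)}")
    return table


def _lookup_msss(edss: np.ndarray, duration: np.ndarray,
                 lookup: pd.DataFrame) -> pd.DataFrame:
    years = np.floor(duration).astype(int)
    lo, hi = int(lookup["duration_year"].min()), int(lookup["duration_year"].max())
    years = np.clip(years, lo, hi)
    key = lookup.set_index(["duration_year", "edss"])["msss"]
    try:
        msss = np.array([float(key.loc[(y, e)]) for y, e in zip(years, edss)])
    except KeyError as err:
        raise ValueError(f"lookup table has no entry for {err.args[0]}") from None
    return pd.DataFrame({
        "msss": msss,
        "duration_stratum": years,
        "stratum_size": np.zeros(len(msss), dtype=int),
    })


def edss_change_threshold(baseline) -> np.ndarray:
    """Minimal EDSS change that counts as worsening/improvement.

    1.5 points from a baseline of 0.0; 1.0 point for baselines up to 4.5;
    0.5 point above 4.5.
    """
    b = _validate_edss(baseline, "baseline_edss")
    return np.where(b == 0.0, 1.5, np.where(b <= 4.5, 1.0, 0.5))


def classify_edss_change(baseline_edss, fu_edss):
    """Classify EDSS evolution as worsened / stable / improved.

    A change of at least the baseline-dependent threshold in either
    direction leaves the stable band.  Scalar inputs give a scalar label.
    """
    scalar = np.isscalar(baseline_edss) and np.isscalar(fu_edss)
    b = _validate_edss(baseline_edss, "baseline_edss")
    f = _validate_edss(fu_edss, "fu_edss")
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up lengths differ")
    thr = edss_change_threshold(b)
    diff = f - b
    out = np.where(diff >= thr, "worsened",
                   np.where(diff <= -thr, "improved", "stable"))
    return out.item() if scalar else out


def compute_rci(patient_changes: pd.DataFrame, hc_changes: pd.DataFrame,
                higher_is_worse=HIGHER_IS_WORSE, threshold: float = RCI_THRESHOLD,
                min_declining: int = 2) -> pd.DataFrame:
    """Reliable change indices and cognitive-decline status.

    For each test ``t``: ``RCI_t = (change_patient - mean change_HC) / SD
    change_HC``; centering on the HC mean absorbs average practice effects.
    Tests named in ``higher_is_worse`` are sign-flipped so that a negative
    RCI always means decline.  A test declines when its RCI falls below
    ``-threshold``; a patient is ``declined`` when at least
    ``min_declining`` tests decline.
    """
    tests = [c for c in patient_changes.columns if c != "id"]
    if not tests:
        raise ValueError("no test columns in patient changes")
    missing = [t for t in tests if t not in hc_changes.columns]
    if missing:
        raise ValueError(f"HC change table lacks tests: {missing}")
    out = pd.DataFrame()
    if "id" in patient_changes.columns:
        out["id"] = patient_changes["id"].to_numpy()
    n_decl = np.zeros(len(patient_changes), dtype=int)
    for t in tests:
        hc = hc_changes[t].dropna().to_numpy(dtype=float)
        if len(hc) < 2:
            raise ValueError(f"need at least 2 HC change scores for {t!r}")
        sd = float(np.std(hc, ddof=1))
        if sd == 0:
            raise ValueError(f"zero HC change variance for {t!r}")
        rci = (patient_changes[t].to_numpy(dtype=float) - hc.mean()) / sd
        base = t.removesuffix("_change")
        if base in higher_is_worse or t in higher_is_worse:
            rci = -rci
        out[f"rci_{t}"] = rci
        n_decl += (rci < -threshold).astype(int)
    out["n_declining_tests"] = n_decl
    out["status"] = np.where(n_decl >= min_declining, "declined", "stable")
    return out
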