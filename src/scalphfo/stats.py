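"""Cohort-level statistics: medians, rank tests, correlations and the
linear model of HFO rate.

A reference cohort table of 30 paediatric epilepsy patients (whole-night
scalp EEG, per-patient HFO properties) ships with the package as
``data/table1.csv`` and drives the reproduction report.  Distributions are
described by median and interquartile range; group comparisons use Wilcoxon
rank-sum / signed-rank tests (normal approximation with continuity and tie
correction); correlations use Spearman's rank correlation; the HFO rate is
modelled by ordinary least squares on CSWS status, dichotomized age
(younger < 7 years), log10 seizure frequency, and ripple-band activity.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .types import InvalidConfigError

__all__ = [
    "load_table1",
    "median_iqr",
    "spearman",
    "wilcoxon_ranksum",
    "wilcoxon_signedrank",
    "LinearModelResult",
    "fit_rate_model",
    "simulate_cohort_table",
    "reproduce_paper_stats",
]

AGE_CUTOFF_YEARS = 7.0
MORPHOLOGY_MIN_EVENTS = 3  # morphology means require > 3 events


def load_table1() -> pd.DataFrame:
    """The packaged reference cohort table (one row per patient)."""
    with resources.files("scalphfo.data").joinpath("table1.csv").open() as f:
        return pd.read_csv(f)


def median_iqr(values) -> tuple[float, float]:
    """Median and Q3 - Q1 (linear interpolation), missing values dropped."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size == 0:
        raise InvalidConfigError("no finite values")
    q1, q3 = np.percentile(v, [25, 75])
    return float(np.median(v)), float(q3 - q1)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation on pairwise-complete pairs."""
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(df) < 4:
        raise InvalidConfigError("need at least 4 complete pairs")
    if df.x.nunique() < 2 or df.y.nunique() < 2:
        raise InvalidConfigError("correlation undefined for a constant vector")
    r, p = sstats.spearmanr(df.x, df.y)
    return float(r), float(p)


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided rank-sum p (normal approximation, continuity + ties)."""
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidConfigError("each group needs at least 3 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        raise InvalidConfigError("all values tied; test degenerate")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_signedrank(a, b) -> float:
    """Two-sided signed-rank p for paired samples (normal approximation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 5:
        raise InvalidConfigError("need at least 5 pairs")
    if np.all(a == b):
        raise InvalidConfigError("all pairs tied; test degenerate")
    res = sstats.wilcoxon(a, b, correction=True, method="approx")
    return float(res.pvalue)


@dataclass
class LinearModelResult:
    """Per-term OLS estimates with 95% CIs and p-values."""

    table: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


_MODEL_TERMS = ["intercept", "csws_yes", "age_group_older", "log_seizure_freq", "rba"]


def fit_rate_model(table: pd.DataFrame, log_base: float = 10.0) -> LinearModelResult:
    """OLS of HFO rate on CSWS, older-age indicator, log seizure frequency
    and RBA, with an intercept."""
    required = ["rate_per_min", "csws", "age_years", "seizures_per_month", "rba_uv"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InvalidConfigError(f"missing columns: {missing}")
    if (table.seizures_per_month <= 0).any():
        raise InvalidConfigError("seizure frequencies must be positive")
    X = pd.DataFrame(
        {
            "csws_yes": table.csws.astype(float),
            "age_group_older": (table.age_years >= AGE_CUTOFF_YEARS).astype(float),
            "log_seizure_freq": np.log(table.seizures_per_month) / np.log(log_base),
            "rba": table.rba_uv.astype(float),
        }
    )
    X = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise InvalidConfigError("rank-deficient design matrix")
    fit = sm.OLS(table.rate_per_min.astype(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "estimate": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    return LinearModelResult(out.loc[_MODEL_TERMS])


def simulate_cohort_table(
    n: int,
    coefs: dict[str, float],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cohort table generated from known model coefficients.

    ``coefs`` uses the model term names (intercept, csws_yes,
    age_group_older, log_seizure_freq, rba).  Used for parameter-recovery
    checks of :func:`fit_rate_model`.
    """
    rng = np.random.default_rng(seed)
    csws = rng.random(n) < 0.15
    older = rng.random(n) < 0.5
    log_seiz = rng.normal(1.0, 1.0, n)
    rba = rng.normal(1.4, 0.3, n)
    age = np.where(older, rng.uniform(7.0, 17.4, n), rng.uniform(0.7, 6.9, n))
    rate = (
        coefs.get("intercept", 0.0)
        + coefs.get("csws_yes", 0.0) * csws
        + coefs.get("age_group_older", 0.0) * older
        + coefs.get("log_seizure_freq", 0.0) * log_seiz
        + coefs.get("rba", 0.0) * rba
        + rng.normal(0.0, noise_sd, n)
    )
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age_years": age,
            "csws": csws.astype(int),
            "seizures_per_month": 10.0**log_seiz,
            "rba_uv": rba,
            "rate_per_min": rate,
        }
    )


def reproduce_paper_stats(table: pd.DataFrame) -> dict:
    """Recompute the cohort's headline statistics from a Table-1-style table.

    Age-trend correlations of event morphology and detectability (frequency,
    duration, amplitude, SNR, RBA vs age) are computed over the
    morphology-valid patients (> 3 events); the RBA-SNR correlation over all
    patients.  Returns a flat dict of named quantities, including a
    ``row_count_ok`` flag for the expected 30-patient cohort.
    """
    rep: dict = {"n_patients": int(len(table)), "row_count_ok": len(table) == 30}
    rep["total_minutes"] = float(5 * table.n_intervals.sum())
    young = table[table.age_years < AGE_CUTOFF_YEARS]
    old = table[table.age_years >= AGE_CUTOFF_YEARS]
    rep["n_younger"], rep["n_older"] = int(len(young)), int(len(old))
    rep["median_rate_all"], rep["iqr_rate_all"] = median_iqr(table.rate_per_min)
    rep["median_rate_younger"], rep["iqr_rate_younger"] = median_iqr(young.rate_per_min)
    rep["median_rate_older"], rep["iqr_rate_older"] = median_iqr(old.rate_per_min)
    rep["rate_young_vs_old_p"] = wilcoxon_ranksum(young.rate_per_min, old.rate_per_min)
    focal = table[table.classification == "focal"]
    gener = table[table.classification == "generalized"]
    rep["rate_focal_vs_generalized_p"] = wilcoxon_ranksum(
        focal.rate_per_min, gener.rate_per_min
    )
    rep["median_snr"], rep["iqr_snr"] = median_iqr(table.snr)
    rep["median_rba"], rep["iqr_rba"] = median_iqr(table.rba_uv)
    rep["median_frequency"], _ = median_iqr(table.frequency_hz)
    rep["median_duration"], _ = median_iqr(table.duration_ms)
    rep["median_amplitude"], _ = median_iqr(table.amplitude_uv)

    morph = table[table.n_events > MORPHOLOGY_MIN_EVENTS]
    rep["n_morphology_valid"] = int(len(morph))
    for col, name in [
        ("frequency_hz", "age_frequency"),
        ("duration_ms", "age_duration"),
        ("amplitude_uv", "age_amplitude"),
        ("snr", "age_snr"),
        ("rba_uv", "age_rba"),
    ]:
        r, p = spearman(morph.age_years, morph[col])
        rep[f"spearman_{name}_r"], rep[f"spearman_{name}_p"] = r, p
    r, p = spearman(table.rba_uv, table.snr)
    rep["spearman_rba_snr_r"], rep["spearman_rba_snr_p"] = r, p

    if "reliability_10min_pct" in table.columns:
        rel = table.reliability_10min_pct.dropna()
        rep["n_reliability"] = int(len(rel))
        rep["median_reliability_10min"], rep["iqr_reliability_10min"] = median_iqr(rel)
        rep["n_reliability_100"] = int((rel == 100).sum())

    model = fit_rate_model(table)
    for term in _MODEL_TERMS:
        rep[f"model_{term}"] = float(model[term].estimate)
        rep[f"model_{term}_p"] = float(model[term].p)
    return rep
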