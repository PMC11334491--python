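"""Survival-analysis battery for imaging-biomarker screening.

Implements the statistical workflow used to turn per-lesion morphological
features into recurrence biomarkers after stereotactic radiotherapy:

* volumetric progression events from longitudinal feature series;
* Kaplan-Meier curves and medians;
* two-group log-rank tests and the optimal-cutpoint *threshold sweep* with
  the non-isolated-significance selection rule;
* univariate Cox proportional-hazards screening and backward stepwise-Wald
  multivariate models;
* the TVN composite score (volume-ratio + necrosis-flag linear combination);
* auxiliary tests: Wilcoxon signed-rank, Spearman correlation with a
  strong-correlation flag, and Kolmogorov-Smirnov normality checking.

Kaplan-Meier, log-rank and Cox fitting are delegated to ``lifelines``; this
module owns the sweep/selection logic, the progression criterion and the
composite score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cohort import CohortRecord
from .morphometry import LesionTimepoint

__all__ = [
    "ProgressionCriterion",
    "progression_time",
    "KMCurve",
    "km_estimate",
    "logrank",
    "ThresholdSweepResult",
    "threshold_sweep",
    "median_difference",
    "CoxResult",
    "cox_univariate",
    "cox_multivariate",
    "cox_stepwise",
    "TVNCoefficients",
    "tvn_score",
    "wilcoxon_signed_rank",
    "spearman",
    "ks_normality",
]


# ---------------------------------------------------------------------------
# progression events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgressionCriterion:
    """Volumetric progression rule applied to a lesion's follow-up series.

    A follow-up scan counts as progression when its total volume exceeds the
    running post-treatment nadir by at least ``relative_increase`` (fraction)
    AND the absolute growth over the nadir is at least ``absolute_floor``
    (cm^3).  The nadir is initialized at the first post-treatment scan, so
    the earliest scan that can register an event is the second follow-up.
    """

    relative_increase: float = 0.20
    absolute_floor: float = 0.10  # cm^3

    def describe(self) -> str:
        return (
            f">= {self.relative_increase:.0%} over post-treatment nadir "
            f"and >= {self.absolute_floor} cm^3 absolute growth"
        )


def progression_time(
    series: list[LesionTimepoint],
    criterion: ProgressionCriterion = ProgressionCriterion(),
) -> tuple[float, bool]:
    """Time to volumetric progression (months) and event flag for one lesion.

    ``series`` must contain at least one pre-treatment timepoint (time < 0)
    and one follow-up (time >= 0).  Returns ``(time, True)`` at the first
    follow-up meeting the criterion, else ``(last follow-up time, False)``
    (censored).
    """
    ordered = sorted(series, key=lambda tp: tp.time)
    followups = [tp for tp in ordered if tp.time >= 0]
    pre = [tp for tp in ordered if tp.time < 0]
    if not pre:
        raise ValueError("series lacks a pre-treatment timepoint (time < 0)")
    if not followups:
        raise ValueError("series lacks post-treatment follow-ups")
    nadir = followups[0].features.total_volume
    for tp in followups[1:]:
        v = tp.features.total_volume
        if v >= nadir * (1.0 + criterion.relative_increase) and v - nadir >= criterion.absolute_floor:
            return tp.time, True
        nadir = min(nadir, v)
    return followups[-1].time, False


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve with right censoring."""

    times: np.ndarray  # event/censoring grid (months)
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray  # number at risk just before each time
    median: float | None  # first t with S(t) <= 0.5; None if never reached
    n: int
    n_events: int


def _times_events(records: list[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    if np.any(t < 0):
        raise ValueError("follow-up times must be non-negative")
    return t, e


def km_estimate(records: list[CohortRecord]) -> KMCurve:
    """Kaplan-Meier estimate of progression-free survival."""
    if not records:
        raise ValueError("need at least one record")
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    if table.index[0] == 0 and table.iloc[0]["removed"] == 0:  # entrance-only row
        table = table.iloc[1:]
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    med = float(kmf.median_survival_time_)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        median=None if math.isinf(med) else med,
        n=len(records),
        n_events=int(e.sum()),
    )


def logrank(group_a: list[CohortRecord], group_b: list[CohortRecord]) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2 with 1 df)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined without any event")
    res = multivariate_logrank_test(
        np.concatenate([ta, tb]),
        np.concatenate([np.zeros(len(ta)), np.ones(len(tb))]),
        np.concatenate([ea, eb]).astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def median_difference(curve_a: KMCurve, curve_b: KMCurve) -> float | None:
    """Absolute difference of KM medians (months); None if either is undefined."""
    if curve_a.median is None or curve_b.median is None:
        return None
    return abs(curve_a.median - curve_b.median)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSweepResult:
    """Outcome of the optimal-cutpoint log-rank sweep for one covariate.

    ``selected_threshold`` is the non-isolated significant candidate with the
    lowest log-rank p-value; it is None when no candidate qualifies (the full
    p-profile is retained either way, so multiplicity corrections can be
    applied downstream — the selected p itself is reported uncorrected, as is
    conventional for this optimistic procedure).
    """

    covariate: str
    candidates: np.ndarray
    p_values: np.ndarray
    group_sizes: np.ndarray  # (n_candidates, 2): n at-or-below / above threshold
    selected_threshold: float | None
    selected_p: float | None
    median_low: float | None = None
    median_high: float | None = None
    median_diff: float | None = None
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.selected_threshold is not None


def select_non_isolated(p_values, alpha: float = 0.05) -> int | None:
    """Index of the best *non-isolated* significant candidate, or None.

    A candidate is significant when its p-value is below ``alpha`` and
    non-isolated when at least one adjacent candidate in the profile is also
    significant — a literal reading of the selection rule that discards
    isolated significance spikes.  Among non-isolated significant candidates
    the one with the lowest p-value wins.
    """
    p = np.asarray(p_values, dtype=float)
    sig = p < alpha
    non_isolated = np.zeros_like(sig)
    for i in np.flatnonzero(sig):
        non_isolated[i] = (i > 0 and sig[i - 1]) or (i + 1 < len(sig) and sig[i + 1])
    if not non_isolated.any():
        return None
    cand = np.flatnonzero(non_isolated)
    return int(cand[np.argmin(p[cand])])


def threshold_sweep(
    records: list[CohortRecord],
    covariate: str,
    grid: int | str = "observed",
    min_group_fraction: float = 0.10,
    alpha: float = 0.05,
) -> ThresholdSweepResult:
    """Sweep a covariate's range for the best survival-splitting threshold.

    Each candidate threshold ``c`` splits the cohort into ``x <= c`` vs
    ``x > c`` and scores the split by the two-group log-rank p-value.
    Candidates are the unique observed values (``grid="observed"``) or an
    even grid of ``grid`` points between the observed minimum and maximum;
    splits leaving either group under ``min_group_fraction`` of the cohort
    are excluded.  A candidate is *significant* if p < ``alpha`` and
    *non-isolated* if at least one adjacent surviving candidate is also
    significant; the selected threshold is the non-isolated significant
    candidate with the lowest p.
    """
    x = np.array([r.covariates[covariate] for r in records], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError(f"covariate {covariate!r} needs >= 3 distinct values for a sweep")
    if isinstance(grid, str):
        if grid != "observed":
            raise ValueError("grid must be 'observed' or an integer count")
        candidates = np.unique(x)[:-1]  # splitting above the max is degenerate
    else:
        candidates = np.linspace(x.min(), x.max(), int(grid) + 2)[1:-1]
    n = len(records)
    min_n = max(1, math.ceil(min_group_fraction * n))
    kept, pvals, sizes = [], [], []
    for c in candidates:
        low = [r for r in records if r.covariates[covariate] <= c]
        high = [r for r in records if r.covariates[covariate] > c]
        if len(low) < min_n or len(high) < min_n:
            continue
        try:
            _, p = logrank(low, high)
        except ValueError:
            continue
        kept.append(c)
        pvals.append(p)
        sizes.append((len(low), len(high)))
    kept = np.array(kept)
    pvals = np.array(pvals)
    sizes = np.array(sizes).reshape(-1, 2)
    selected = selected_p = None
    idx = select_non_isolated(pvals, alpha) if len(kept) else None
    if idx is not None:
        selected = float(kept[idx])
        selected_p = float(pvals[idx])
    result = ThresholdSweepResult(
        covariate=covariate,
        candidates=kept,
        p_values=pvals,
        group_sizes=sizes,
        selected_threshold=selected,
        selected_p=selected_p,
        alpha=alpha,
    )
    if selected is not None:
        low = [r for r in records if r.covariates[covariate] <= selected]
        high = [r for r in records if r.covariates[covariate] > selected]
        km_low, km_high = km_estimate(low), km_estimate(high)
        result.median_low = km_low.median
        result.median_high = km_high.median
        result.median_diff = median_difference(km_low, km_high)
    return result


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary (Efron ties, Wald inference)."""

    covariates: list
    coef: dict
    hazard_ratio: dict
    ci_lower: dict
    ci_upper: dict
    p: dict
    eliminated: list = field(default_factory=list)  # stepwise drop order
    n: int = 0
    n_events: int = 0


def _cox_frame(records: list[CohortRecord], covariates: list[str]) -> pd.DataFrame:
    rows = {
        "time": [r.time for r in records],
        "event": [int(r.event) for r in records],
    }
    for c in covariates:
        rows[c] = [r.covariates[c] for r in records]
    return pd.DataFrame(rows)


def cox_multivariate(records: list[CohortRecord], covariates: list[str]) -> CoxResult:
    """Fit a Cox model on the given covariates (Efron tie handling)."""
    if not covariates:
        return CoxResult([], {}, {}, {}, {}, {}, n=len(records), n_events=sum(r.event for r in records))
    df = _cox_frame(records, covariates)
    if df["event"].sum() == 0:
        raise ValueError("Cox model undefined without any event")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise ValueError(f"Cox fit failed for {covariates}: {exc}") from exc
    s = cph.summary
    return CoxResult(
        covariates=list(covariates),
        coef={c: float(s.loc[c, "coef"]) for c in covariates},
        hazard_ratio={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        ci_lower={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_upper={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p={c: float(s.loc[c, "p"]) for c in covariates},
        n=len(records),
        n_events=int(df["event"].sum()),
    )


def cox_univariate(records: list[CohortRecord], covariate: str) -> CoxResult:
    """Single-covariate Cox screening fit."""
    return cox_multivariate(records, [covariate])


def cox_stepwise(
    records: list[CohortRecord],
    covariates: list[str],
    removal_alpha: float = 0.10,
) -> CoxResult:
    """Backward stepwise-Wald variable selection.

    Starting from the full model, repeatedly refit and drop the covariate
    with the largest Wald p-value until every remaining covariate has
    p <= ``removal_alpha``.  The elimination order is recorded; an empty
    model is a legitimate outcome when no covariate survives.
    """
    if len(covariates) < 2:
        raise ValueError("stepwise selection needs >= 2 candidate covariates")
    remaining = list(covariates)
    eliminated: list[str] = []
    result = cox_multivariate(records, remaining)
    while remaining:
        worst = max(remaining, key=lambda c: result.p[c])
        if result.p[worst] <= removal_alpha:
            break
        remaining.remove(worst)
        eliminated.append(worst)
        result = cox_multivariate(records, remaining)
    result.eliminated = eliminated
    return result


# ---------------------------------------------------------------------------
# TVN composite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TVNCoefficients:
    """Weights of the TVN composite recurrence score.

    Defaults are the published weights of the score combining the
    post/pre total-volume ratio with the necrosis flag at first follow-up:
    TVN = 0.084 * ratio + 0.339 * necrosis.
    """

    weight_volume_ratio: float = 0.084
    weight_necrosis: float = 0.339

    def __post_init__(self):
        if not (math.isfinite(self.weight_volume_ratio) and math.isfinite(self.weight_necrosis)):
            raise ValueError("TVN weights must be finite")


def tvn_score(
    volume_ratio: float,
    has_necrosis: bool,
    coefficients: TVNCoefficients = TVNCoefficients(),
) -> float:
    """TVN composite: weighted sum of volume-ratio and necrosis flag."""
    if volume_ratio < 0:
        raise ValueError("volume ratio must be non-negative")
    return (
        coefficients.weight_volume_ratio * volume_ratio
        + coefficients.weight_necrosis * (1.0 if has_necrosis else 0.0)
    )


# ---------------------------------------------------------------------------
# auxiliary tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(pre, post) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution when the non-zero differences number <= 25 and
    carry no ties; normal approximation with tie correction otherwise.
    Zero differences are dropped (Wilcoxon's original treatment).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
    res = stats.wilcoxon(d, method="exact" if exact else "approx", correction=not exact)
    return float(res.pvalue)


def spearman(x, y, strong: float = 0.7) -> tuple[float, bool]:
    """Spearman rank correlation and a strong-correlation flag (rho > 0.7)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, rho > strong


def ks_normality(x) -> tuple[float, float, str]:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    Because mean and SD are estimated from the sample, the plain KS null
    distribution is invalid; the Lilliefors-corrected p-value is returned
    and the correction is flagged in the third element.

    Returns ``(statistic, p_value, correction_note)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("KS normality check needs n >= 5")
    if np.unique(x).size < 2:
        raise ValueError("constant sample; normality test degenerate")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p), "lilliefors-corrected (parameters estimated from sample)"
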