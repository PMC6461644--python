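"""Survival-analysis primitives.

Kaplan-Meier estimation, two-sample log-rank / Gehan-Breslow tests, Cox
proportional-hazards fitting, Spearman correlation with a strong-correlation
flag, and Harrell's concordance index computed on the non-censored sample
(censored subjects are excluded entirely; over all event pairs with distinct
survival times the score must order survival correctly, score ties counting
one half).

Standard estimators are delegated to ``lifelines`` and ``scipy``; the
concordance index and the vectorized multi-threshold test statistics used by
the cutpoint search are implemented here because their conventions are
specific to this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "two_sample_test",
    "fit_cox",
    "spearman",
    "concordance_index",
]

STRONG_CORRELATION = 0.7  # |rho| above this flags a strong correlation


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival outcomes.

    times
        Follow-up in months, strictly positive.
    events
        True where death was observed, False where censored.
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be 1-D and equal length")
        if times.size and times.min() <= 0:
            raise ValueError("survival times must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, index: np.ndarray) -> "SurvivalSample":
        return SurvivalSample(self.times[index], self.events[index])


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray      # distinct times where the estimate changes
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # subjects at risk just before each time

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.shape else float(out)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, survival, at_risk) table suitable for replotting."""
        return pd.DataFrame(
            {"time": self.event_times, "survival": self.survival,
             "at_risk": self.at_risk}
        )


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimator, starting at S(0) = 1."""
    if len(sample) < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    # distinct observed times (event or censoring); keep event steps plus
    # censoring times so the at-risk column is complete
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    return KMCurve(times, surv, at_risk)


def two_sample_test(
    group_a: SurvivalSample,
    group_b: SurvivalSample,
    kind: Literal["logrank", "breslow"] = "logrank",
) -> tuple[float, float]:
    """Two-sample survival test; returns (chi-square statistic, p-value).

    ``logrank`` weights every event time equally; ``breslow`` is the
    Gehan-Breslow generalized Wilcoxon test, weighting by the at-risk count.
    Both are 1-df chi-square tests with two-tailed p-values.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.n_events + group_b.n_events == 0:
        return 0.0, 1.0
    if kind not in ("logrank", "breslow"):
        raise ValueError(f"unknown test kind: {kind!r}")
    weightings = None if kind == "logrank" else "wilcoxon"
    res = logrank_test(
        group_a.times, group_b.times,
        event_observed_A=group_a.events, event_observed_B=group_b.events,
        weightings=weightings,
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling)."""

    feature_names: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci95: np.ndarray            # (p, 2) Wald intervals on the HR scale
    p_values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_ci_low": self.ci95[:, 0],
                "HR_ci_high": self.ci95[:, 1],
                "p": self.p_values,
            },
            index=self.feature_names,
        )


def fit_cox(features: pd.DataFrame, sample: SurvivalSample) -> CoxResult:
    """Fit a Cox PH model of the survival sample on the feature columns.

    Rejects constant covariates by name; raises on non-convergence (e.g.
    monotone likelihood under perfect separation).
    """
    if features.shape[0] != len(sample):
        raise ValueError("feature rows and survival sample differ in length")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {', '.join(constant)}")
    if sample.n_events < features.shape[1]:
        raise ValueError("fewer observed events than covariates")
    df = features.reset_index(drop=True).copy()
    df["_time"] = sample.times
    df["_event"] = sample.events.astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    summary = cph.summary.loc[list(features.columns)]
    coefs = summary["coef"].to_numpy(dtype=float)
    return CoxResult(
        feature_names=list(features.columns),
        coefficients=coefs,
        hazard_ratios=np.exp(coefs),
        ci95=np.exp(
            summary[["coef lower 95%", "coef upper 95%"]].to_numpy(dtype=float)
        ),
        p_values=summary["p"].to_numpy(dtype=float),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, bool]:
    """Spearman rank correlation with midrank ties.

    Returns (rho, strong) where ``strong`` flags |rho| > 0.7.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, abs(rho) > STRONG_CORRELATION


def concordance_index(
    scores: Sequence[float],
    sample: SurvivalSample,
    orientation: Literal["higher-is-worse", "higher-is-better"] = "higher-is-worse",
) -> float:
    """Harrell-style concordance restricted to the non-censored sample.

    Censored subjects are dropped entirely. Over all pairs of event subjects
    with distinct survival times, a pair is concordant when the
    worse-prognosis-oriented score belongs to the shorter survivor; score
    ties count 0.5. Raises if no usable pair exists.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(sample):
        raise ValueError("scores and sample differ in length")
    mask = sample.events
    if mask.sum() < 2:
        raise ValueError("need at least two subjects with observed events")
    s = scores[mask]
    t = sample.times[mask]
    if orientation == "higher-is-better":
        s = -s
    elif orientation != "higher-is-worse":
        raise ValueError(f"unknown orientation: {orientation!r}")
    # pair (i, j) usable iff t_i != t_j; concordant iff the higher score has
    # the shorter time
    dt = t[:, None] - t[None, :]
    ds = s[:, None] - s[None, :]
    usable = dt != 0
    n_usable = int(np.count_nonzero(usable)) // 2
    if n_usable == 0:
        raise ValueError("no usable pairs (all survival times tied)")
    # count each unordered pair once via the upper triangle
    iu = np.triu_indices(t.size, k=1)
    dt_u, ds_u = dt[iu], ds[iu]
    ok = dt_u != 0
    concordant = np.sign(ds_u[ok]) == -np.sign(dt_u[ok])
    tied = ds_u[ok] == 0
    return float((concordant.sum() + 0.5 * tied.sum()) / ok.sum())


# ---------------------------------------------------------------------------
# Vectorized multi-threshold test statistics (used by the cutpoint search).
# ---------------------------------------------------------------------------

def sweep_survival_tests(
    feature: np.ndarray,
    sample: SurvivalSample,
    kind: Literal["logrank", "breslow"] = "logrank",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted O-E chi-square for every split of a sorted feature.

    Returns ``(thresholds, statistics, p_values)`` where threshold k is the
    midpoint between the k-th and (k+1)-th distinct sorted feature values and
    the low group is everything at or below it. Computed for all candidate
    splits at once; equals the per-split two-sample test exactly.
    """
    feature = np.asarray(feature, dtype=float)
    times, events = sample.times, sample.events
    n = times.size
    order = np.argsort(feature, kind="stable")
    f_sorted = feature[order]
    t_sorted = times[order]
    e_sorted = events[order]

    event_times = np.unique(times[events])
    if event_times.size == 0:
        raise ValueError("no observed events")
    # membership matrices over (event time, subject-in-feature-order)
    at_risk = t_sorted[None, :] >= event_times[:, None]
    died = (t_sorted[None, :] == event_times[:, None]) & e_sorted[None, :]
    n_total = at_risk.sum(axis=1).astype(float)
    d_total = died.sum(axis=1).astype(float)

    # prefix counts: low group = first k subjects in feature order
    n1 = np.cumsum(at_risk, axis=1).astype(float)   # (T, n) at-risk in low
    d1 = np.cumsum(died, axis=1).astype(float)

    w = np.ones_like(n_total) if kind == "logrank" else n_total
    if kind not in ("logrank", "breslow"):
        raise ValueError(f"unknown test kind: {kind!r}")

    expected = d_total[:, None] * n1 / n_total[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_total[:, None]
            * (n1 / n_total[:, None])
            * (1.0 - n1 / n_total[:, None])
            * (n_total[:, None] - d_total[:, None])
            / np.maximum(n_total[:, None] - 1.0, 1.0)
        )
    u = (w[:, None] * (d1 - expected)).sum(axis=0)        # (n,)
    v = (w[:, None] ** 2 * var).sum(axis=0)

    # candidate split after each distinct value except the last
    distinct_last = np.nonzero(np.diff(f_sorted) != 0)[0]
    thresholds = 0.5 * (f_sorted[distinct_last] + f_sorted[distinct_last + 1])
    u_k, v_k = u[distinct_last], v[distinct_last]
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v_k > 0, u_k**2 / np.maximum(v_k, 1e-300), 0.0)
    p = np.where(v_k > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return thresholds, chi2, p
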