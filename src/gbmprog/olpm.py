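"""Optimized linear prognostic model (OLPM).

Two searches drive the pipeline:

* ``best_threshold_split`` — exhaustive Kaplan-Meier cutpoint search for a
  single feature: every candidate threshold (midpoints of consecutive sorted
  values, subject to a minimum group size) is tested with the log-rank test,
  and the best *non-isolated* significant threshold (its neighbouring
  candidates are also significant) with the lowest p-value wins.

* ``fit_olpm`` — coefficient grid search seeded by a multivariate Cox fit:
  each coefficient B_i is perturbed over [B_i - f*B_i, B_i + f*B_i]
  (default f = 0.25) discretized into ``subintervals`` points, the full
  Cartesian grid of candidate linear models is enumerated (30^p in the full
  configuration), and for each candidate the prognostic score
  PS = sum(coef * feature) is dichotomized at the threshold maximizing the
  concordance index on event subjects. The globally best candidate, with its
  threshold frozen, is the OLPM.

The dichotomized-concordance sweep is O(n^2) per candidate via a 2-D prefix
sum over the event-subject pair matrix, which keeps the full 30^4 grid
tractable on one CPU.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .survstats import (
    CoxResult,
    SurvivalSample,
    concordance_index,
    fit_cox,
    sweep_survival_tests,
    two_sample_test,
)

__all__ = [
    "LinearModel",
    "GridSearchConfig",
    "SplitResult",
    "best_threshold_split",
    "fit_olpm",
    "evaluate_model",
    "dichotomized_cindex_sweep",
]

# Cartesian grids above this size are refused unless force=True
DEFAULT_GRID_CAP = 1_000_000


@dataclass(frozen=True)
class LinearModel:
    """Linear prognostic score with a frozen dichotomizing threshold.

    ``PS = sum_i coefficients[i] * feature_i``; subjects with PS above the
    threshold form the poor-prognosis group (higher PS is worse).
    """

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    threshold: float
    training_cindex: float | None = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("feature_names and coefficients length mismatch")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def score(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {', '.join(missing)}")
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        return X @ np.asarray(self.coefficients, dtype=float)

    def groups(self, features: pd.DataFrame) -> np.ndarray:
        """Boolean poor-prognosis indicator (PS > threshold)."""
        return self.score(features) > self.threshold

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            coefficients=tuple(d["coefficients"]),
            threshold=float(d["threshold"]),
            training_cindex=d.get("training_cindex"),
            provenance=d.get("provenance", {}),
        )


@dataclass(frozen=True)
class GridSearchConfig:
    """Knobs for the cutpoint and coefficient searches.

    fraction
        Half-width of the per-coefficient perturbation range as a fraction
        of the seed coefficient (0.25 = +/-25%).
    subintervals
        Grid points per coefficient (inclusive endpoints; 30 in the full
        configuration, 30^p candidate models for p features).
    min_group_fraction
        Smallest admissible arm as a fraction of the cohort; guards against
        1-vs-(n-1) splits.
    isolation_window
        A significant threshold counts as non-isolated when all candidate
        thresholds within this many positions on each side are significant
        too.
    """

    fraction: float = 0.25
    subintervals: int = 30
    min_group_fraction: float = 0.10
    isolation_window: int = 1
    significance: float = 0.05
    grid_cap: int = DEFAULT_GRID_CAP

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        if self.subintervals < 1:
            raise ValueError("subintervals must be >= 1")
        if not 0 <= self.min_group_fraction < 0.5:
            raise ValueError("min_group_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class SplitResult:
    """Outcome of dichotomizing a cohort at a threshold."""

    threshold: float
    p_logrank: float
    p_breslow: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    c_index: float
    group_sizes: tuple[int, int]      # (n low, n high)
    significant: bool = True          # False when no non-isolated p < 0.05

    def as_dict(self) -> dict:
        return asdict(self)


def _admissible_positions(
    n_low_at: np.ndarray, n: int, min_fraction: float
) -> np.ndarray:
    """Boolean mask over candidate thresholds meeting the group-size floor."""
    min_n = max(1, int(np.ceil(min_fraction * n)))
    return (n_low_at >= min_n) & (n - n_low_at >= min_n)


def _split_summary(
    feature: np.ndarray,
    sample: SurvivalSample,
    threshold: float,
    p_logrank: float,
    significant: bool,
) -> SplitResult:
    """Attach Breslow p, Cox HR/CI on the binary indicator and the c-index."""
    high = np.asarray(feature, dtype=float) > threshold
    low_s = sample.subset(~high)
    high_s = sample.subset(high)
    _, p_breslow = two_sample_test(low_s, high_s, kind="breslow")
    cox = fit_cox(
        pd.DataFrame({"high_group": high.astype(float)}), sample
    )
    c = concordance_index(high.astype(float), sample, orientation="higher-is-worse")
    return SplitResult(
        threshold=float(threshold),
        p_logrank=float(p_logrank),
        p_breslow=float(p_breslow),
        hazard_ratio=float(cox.hazard_ratios[0]),
        hr_ci95=(float(cox.ci95[0, 0]), float(cox.ci95[0, 1])),
        c_index=float(c),
        group_sizes=(int((~high).sum()), int(high.sum())),
        significant=significant,
    )


def best_threshold_split(
    feature: Sequence[float],
    sample: SurvivalSample,
    config: GridSearchConfig | None = None,
) -> SplitResult:
    """Exhaustive cutpoint search ranked by log-rank p-value.

    Among admissible candidate thresholds (midpoints of consecutive distinct
    sorted feature values whose arms both hold at least
    ``min_group_fraction`` of the cohort), thresholds significant at
    ``significance`` whose neighbours within ``isolation_window`` candidate
    positions are also significant are retained; the retained threshold with
    the lowest p-value is returned with Breslow p, hazard ratio with Wald
    95% CI (Cox on the binary indicator), and the dichotomized concordance
    index attached. If no retained threshold exists, the overall best-p
    split is returned flagged ``significant=False``.
    """
    config = config or GridSearchConfig()
    feature = np.asarray(feature, dtype=float)
    if feature.shape[0] != len(sample):
        raise ValueError("feature and sample differ in length")
    if np.unique(feature).size < 2:
        raise ValueError("constant feature: no candidate thresholds")
    thresholds, _, pvals = sweep_survival_tests(feature, sample, kind="logrank")
    n = feature.size
    n_low = np.searchsorted(np.sort(feature), thresholds, side="right")
    ok = _admissible_positions(n_low, n, config.min_group_fraction)
    if not ok.any():
        raise ValueError("no admissible threshold satisfies the group-size floor")
    thresholds, pvals = thresholds[ok], pvals[ok]

    sig = pvals < config.significance
    w = config.isolation_window
    non_isolated = sig.copy()
    for offset in range(1, w + 1):
        left = np.roll(sig, offset)
        right = np.roll(sig, -offset)
        # candidates at the edge have fewer neighbours; only existing ones count
        left[:offset] = True
        right[-offset:] = True
        non_isolated &= left & right
    if non_isolated.any():
        idx = int(np.flatnonzero(non_isolated)[np.argmin(pvals[non_isolated])])
        return _split_summary(feature, sample, thresholds[idx], pvals[idx], True)
    idx = int(np.argmin(pvals))
    return _split_summary(feature, sample, thresholds[idx], pvals[idx], False)


# ---------------------------------------------------------------------------
# Dichotomized-concordance threshold sweep
# ---------------------------------------------------------------------------

class _CindexSweeper:
    """Best dichotomizing threshold of a score by event-pair concordance.

    For event subjects only, with binary groups (high PS = worse prognosis):
    same-group pairs are score ties (0.5), cross-group pairs are concordant
    when the high-group member died earlier. With the pair-concordance
    matrix M over event subjects in PS order, the concordant cross-pair
    count for any split is a 2-D prefix-sum lookup, so the whole sweep is
    O(n^2) per candidate score vector.
    """

    def __init__(self, sample: SurvivalSample):
        self.events = sample.events
        t = sample.times[self.events]
        if t.size < 2:
            raise ValueError("need at least two subjects with observed events")
        self.t = t
        dt = t[:, None] - t[None, :]
        self.usable_pair = dt != 0
        self.total_pairs = int(self.usable_pair.sum()) // 2
        if self.total_pairs == 0:
            raise ValueError("no usable pairs (all event times tied)")
        # worse[j, k] = 1 if subject k died strictly before subject j
        self.worse = (dt > 0).astype(np.float64)

    def best_threshold(
        self, scores: np.ndarray, min_group_fraction: float = 0.0
    ) -> tuple[float, float]:
        """Return (threshold, c-index) maximizing the dichotomized c-index.

        Candidate thresholds are midpoints between consecutive distinct
        sorted score values over the full cohort; the group-size floor is
        applied on the full cohort. Ties in c-index break toward the lowest
        threshold.
        """
        scores = np.asarray(scores, dtype=float)
        n = scores.size
        order_all = np.argsort(scores, kind="stable")
        s_all = scores[order_all]
        distinct = np.nonzero(np.diff(s_all) != 0)[0]
        if distinct.size == 0:
            raise ValueError("constant score: no candidate thresholds")
        cand_thr = 0.5 * (s_all[distinct] + s_all[distinct + 1])
        n_low_all = distinct + 1
        ok = _admissible_positions(n_low_all, n, min_group_fraction)
        if not ok.any():
            raise ValueError("no admissible threshold satisfies the group-size floor")
        cand_thr, n_low_all = cand_thr[ok], n_low_all[ok]

        # event subjects sorted by score; M reordered accordingly
        s_ev = scores[self.events]
        order = np.argsort(s_ev, kind="stable")
        M = self.worse[np.ix_(order, order)]
        ties = ~self.usable_pair[np.ix_(order, order)]
        P = M.cumsum(axis=0).cumsum(axis=1)
        Pt = ties.cumsum(axis=0).cumsum(axis=1)
        m = s_ev.size

        # k event subjects below each candidate threshold
        s_ev_sorted = s_ev[order]
        k_ev = np.searchsorted(s_ev_sorted, cand_thr, side="right")

        # rows = low group (first k event subjects), cols = high group
        inside = (k_ev > 0) & (k_ev < m)
        kk = np.clip(k_ev, 1, m - 1)
        cross_conc = np.where(
            inside, P[kk - 1, m - 1] - P[kk - 1, kk - 1], 0.0
        )  # pairs where the high-group member died first
        tie_cross = np.where(inside, Pt[kk - 1, m - 1] - Pt[kk - 1, kk - 1], 0.0)
        cross_pairs = np.where(inside, k_ev * (m - k_ev) - tie_cross, 0.0)
        same_pairs = self.total_pairs - cross_pairs
        c_vals = (cross_conc + 0.5 * same_pairs) / self.total_pairs
        best = int(np.argmax(c_vals))
        return float(cand_thr[best]), float(c_vals[best])


def dichotomized_cindex_sweep(
    scores: Sequence[float],
    sample: SurvivalSample,
    min_group_fraction: float = 0.0,
) -> tuple[float, float]:
    """Best dichotomizing threshold of a prognostic score by c-index.

    Convenience wrapper over the incremental sweeper; equivalent to
    evaluating ``concordance_index(scores > thr)`` at every candidate
    threshold and keeping the maximum.
    """
    sweeper = _CindexSweeper(sample)
    return sweeper.best_threshold(np.asarray(scores, dtype=float), min_group_fraction)


def _coefficient_grid(seed: np.ndarray, config: GridSearchConfig) -> list[np.ndarray]:
    """Per-coefficient inclusive linspace over [B - f*B, B + f*B].

    A zero seed coefficient collapses its grid to {0}. With subintervals = 1
    the grid is the seed itself (identity limit).
    """
    grids = []
    for b in seed:
        if config.subintervals == 1 or config.fraction == 0 or b == 0:
            grids.append(np.array([b], dtype=float))
        else:
            half = config.fraction * abs(b)
            grids.append(np.linspace(b - half, b + half, config.subintervals))
    return grids


def fit_olpm(
    seed_model: CoxResult | LinearModel,
    features: pd.DataFrame,
    sample: SurvivalSample,
    config: GridSearchConfig | None = None,
    force: bool = False,
) -> LinearModel:
    """Coefficient grid search around a Cox seed, maximizing dichotomized c-index.

    Enumerates the full Cartesian grid of ``subintervals**p`` coefficient
    vectors; for each, finds the best dichotomizing threshold of the
    prognostic score on the discovery cohort. Returns the globally best
    model with its threshold frozen. Ties break toward the first candidate
    in lexicographic grid order.
    """
    config = config or GridSearchConfig()
    if isinstance(seed_model, CoxResult):
        names = tuple(seed_model.feature_names)
        seed = np.asarray(seed_model.coefficients, dtype=float)
    else:
        names = tuple(seed_model.feature_names)
        seed = np.asarray(seed_model.coefficients, dtype=float)
    if seed.size < 1:
        raise ValueError("need at least one seed coefficient")
    if not np.all(np.isfinite(seed)):
        raise ValueError("seed coefficients must be finite")
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")

    grids = _coefficient_grid(seed, config)
    n_candidates = int(np.prod([g.size for g in grids]))
    if n_candidates > config.grid_cap and not force:
        raise ValueError(
            f"grid of {n_candidates} candidates exceeds cap {config.grid_cap}; "
            "pass force=True to run anyway"
        )

    X = features[list(names)].to_numpy(dtype=float)
    sweeper = _CindexSweeper(sample)

    best_c = -np.inf
    best_coefs: tuple[float, ...] | None = None
    best_thr = np.nan
    for combo in itertools.product(*grids):
        coefs = np.asarray(combo, dtype=float)
        ps = X @ coefs
        if np.ptp(ps) == 0:
            continue
        try:
            thr, c = sweeper.best_threshold(ps, config.min_group_fraction)
        except ValueError:
            continue
        if c > best_c:  # strict: first-in-grid-order wins ties
            best_c, best_coefs, best_thr = c, tuple(float(v) for v in coefs), thr
    if best_coefs is None:
        raise ValueError("no candidate model produced an admissible split")
    return LinearModel(
        feature_names=names,
        coefficients=best_coefs,
        threshold=best_thr,
        training_cindex=best_c,
        provenance={
            "seed_coefficients": [float(b) for b in seed],
            "fraction": config.fraction,
            "subintervals": config.subintervals,
            "n_candidates": n_candidates,
            "n_train": len(sample),
        },
    )


def evaluate_model(
    model: LinearModel,
    features: pd.DataFrame,
    sample: SurvivalSample,
) -> SplitResult:
    """Apply a frozen model + threshold to a cohort; never re-optimizes.

    Returns the dichotomized concordance index, log-rank and Breslow p-values
    of the Kaplan-Meier split, and the hazard ratio with 95% CI.
    """
    ps = model.score(features)
    high = ps > model.threshold
    if high.all() or not high.any():
        raise ValueError("all subjects fall on one side of the frozen threshold")
    _, p_logrank = two_sample_test(sample.subset(~high), sample.subset(high),
                                   kind="logrank")
    return _split_summary(ps, sample, model.threshold, p_logrank, True)
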