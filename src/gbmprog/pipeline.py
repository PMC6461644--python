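"""End-to-end synthetic prognostic-modelling study.

``run_study`` executes the whole design on generated cohorts: discovery and
validation generation; univariate Kaplan-Meier cutpoint screening at
marginal significance (p < 0.1); Spearman deduplication of strongly
correlated feature pairs (|rho| > 0.7, keeping the lower-p member); a
multivariate Cox seed fit; the coefficient grid search for the optimized
linear model; the four ML comparators trained on the screened feature set
and on the full table; cross-validated attribute selection for the neural
network; and frozen-model evaluation on the validation cohort. The result
is a study report with one row per (model, feature-set) combination giving
discovery and validation concordance indices — the design of the published
comparison table.

Every stage draws its randomness from seeds derived deterministically from
the study seed, so a rerun from the persisted configuration reproduces the
report bit-exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mlsuite, olpm, survstats, synth

logger = logging.getLogger("gbmprog")

__all__ = ["StudyConfig", "StudyReport", "run_study", "screen_features"]

MARGINAL_P = 0.1


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one synthetic study run.

    ``subintervals`` controls the coefficient grid density (30 reproduces
    the full 30^p search; the default 7 keeps a complete run in the
    minutes range). ``rf_iterations`` scales the forest-based attribute
    pre-filter the same way (10000 in the full design).
    """

    seed: int = 0
    n_discovery: int = 311
    n_validation: int = 93
    subintervals: int = 7
    grid_fraction: float = 0.25
    rf_iterations: int = 300
    cv_folds: int = 20
    cv_holdout: int = 50
    cv_top_features: int = 5
    cv_max_subset_size: int = 4
    run_cv_ann: bool = True
    n_noise_features: int = 36

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        return cls(**json.loads(text))


@dataclass
class StudyReport:
    """Per-model performance plus the screening and correlation audits."""

    config: StudyConfig
    model_rows: pd.DataFrame          # model, n_features, c_discovery, c_validation
    screening: pd.DataFrame           # per-feature best split
    correlations: pd.DataFrame        # feature pairs with |rho| > 0.7
    kept_features: tuple[str, ...]
    olpm_model: olpm.LinearModel
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = [
            "# Synthetic prognostic-modelling study",
            "",
            f"Discovery n = {self.config.n_discovery}, "
            f"validation n = {self.config.n_validation}, "
            f"seed = {self.config.seed}",
            "",
            "## Model performance",
            "",
            self.model_rows.to_markdown(index=False, floatfmt=".3f"),
            "",
            "## Screened features",
            "",
            f"Kept after marginal-significance and correlation screening: "
            f"{', '.join(self.kept_features)}",
            "",
            "## Optimized linear model",
            "",
            "PS = " + " + ".join(
                f"({c:.4f} * {n})"
                for n, c in zip(self.olpm_model.feature_names,
                                self.olpm_model.coefficients)
            ),
            f"threshold = {self.olpm_model.threshold:.4f}",
        ]
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model_rows.to_csv(outdir / "report.csv", index=False)
        (outdir / "report.md").write_text(self.to_markdown())
        self.screening.to_csv(outdir / "screening.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        (outdir / "study_config.json").write_text(self.config.to_json())
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        (models_dir / "olpm.json").write_text(self.olpm_model.to_json())
        if self.km_curves:
            km_dir = outdir / "km_curves"
            km_dir.mkdir(exist_ok=True)
            for name, frame in self.km_curves.items():
                frame.to_csv(km_dir / f"{name}.csv", index=False)


def screen_features(
    X: pd.DataFrame,
    sample: survstats.SurvivalSample,
    config: olpm.GridSearchConfig | None = None,
    marginal_p: float = MARGINAL_P,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Univariate cutpoint screening + strong-correlation deduplication.

    A feature passes when its best non-isolated Kaplan-Meier split has
    log-rank p < ``marginal_p``. Among pairs of passing features with
    |Spearman rho| > 0.7, the higher-p member is dropped (tie: the later
    listed one). Returns (kept feature names, full audit table, dropped
    pairs table).
    """
    config = config or olpm.GridSearchConfig()
    rows = []
    for name in X.columns:
        feat = X[name].to_numpy(dtype=float)
        if np.ptp(feat) == 0:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        try:
            res = olpm.best_threshold_split(feat, sample, config)
        except ValueError:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rows.append(
            (name, res.threshold, res.p_logrank, res.hazard_ratio,
             res.c_index, res.p_logrank < marginal_p)
        )
    table = pd.DataFrame(
        rows,
        columns=["feature", "threshold", "p_logrank", "hazard_ratio",
                 "c_index", "passes"],
    )

    passing = [r[0] for r in rows if r[5]]
    p_of = {r[0]: r[2] for r in rows}
    # greedy dedup, best p first: a feature is dropped only in favour of a
    # feature that is itself kept (ties break toward the earlier-listed)
    order = sorted(passing, key=lambda f: (p_of[f], passing.index(f)))
    kept_greedy: list[str] = []
    corr_rows = []
    for f in order:
        clash = None
        for k in kept_greedy:
            rho, strong = survstats.spearman(X[f], X[k])
            if strong:
                clash = (k, rho)
                break
        if clash is None:
            kept_greedy.append(f)
        else:
            corr_rows.append((clash[0], f, clash[1], f))
    kept = [f for f in passing if f in kept_greedy]
    correlations = pd.DataFrame(
        corr_rows, columns=["feature_a", "feature_b", "rho", "dropped"]
    )
    if not kept:
        logger.warning("no feature passed the marginal-significance screen")
    return kept, table, correlations


def _cohorts(config: StudyConfig):
    disc_cfg = synth.CohortConfig(
        n_patients=config.n_discovery,
        seed=config.seed * 2 + 1,
        n_noise_features=config.n_noise_features,
        cohort_label="discovery",
    )
    val_cfg = synth.CohortConfig(
        n_patients=config.n_validation,
        seed=config.seed * 2 + 2,
        n_noise_features=config.n_noise_features,
        cohort_label="validation",
    )
    Xd, rd = synth.generate_cohort(disc_cfg)
    Xv, rv = synth.generate_cohort(val_cfg)
    return (Xd, synth.cohort_to_sample(rd)), (Xv, synth.cohort_to_sample(rv))


def _ml_row(
    kind: str,
    features: list[str],
    Xd, sd, Xv, sv,
    seed: int,
) -> tuple[str, int, float, float]:
    cfg = mlsuite.MLConfig(kind=kind, seed=seed)
    model = mlsuite.train_model(cfg, Xd[features], sd)
    c_disc = survstats.concordance_index(
        model.predict(Xd[features]), sd, orientation="higher-is-better"
    )
    c_val = survstats.concordance_index(
        model.predict(Xv[features]), sv, orientation="higher-is-better"
    )
    return kind, len(features), float(c_disc), float(c_val)


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the full synthetic study; optionally persist all artifacts."""
    t0 = time.time()
    stage = "generate"
    try:
        (Xd, sd), (Xv, sv) = _cohorts(config)
        if outdir is not None:
            # persist inputs immediately so a later stage failure still
            # leaves the completed artifacts behind
            cohort_dir = Path(outdir) / "cohorts"
            cohort_dir.mkdir(parents=True, exist_ok=True)
            Xd.to_csv(cohort_dir / "discovery_features.csv")
            Xv.to_csv(cohort_dir / "validation_features.csv")
            for label, smp, X in (("discovery", sd, Xd), ("validation", sv, Xv)):
                pd.DataFrame({
                    "patient_id": X.index,
                    "os_months": smp.times,
                    "event": smp.events,
                }).to_csv(cohort_dir / f"{label}_clinical.csv", index=False)

        stage = "screen"
        grid_cfg = olpm.GridSearchConfig(
            fraction=config.grid_fraction, subintervals=config.subintervals
        )
        # only clinical + morphological parameters feed the linear-model
        # screen (the noise columns stand in for textural attributes, which
        # enter the ML comparators only)
        screenable = [c for c in Xd.columns if not c.startswith("noise_")]
        kept, screening, correlations = screen_features(
            Xd[screenable], sd, grid_cfg
        )
        logger.info("screening kept %s (%.1fs)", kept, time.time() - t0)
        if not kept:
            raise RuntimeError("screening kept no features; stopping before "
                               "the linear-model stage")

        stage = "cox"
        cox = survstats.fit_cox(Xd[kept], sd)
        cox_c_disc = survstats.concordance_index(
            Xd[kept].to_numpy() @ cox.coefficients, sd)
        cox_c_val = survstats.concordance_index(
            Xv[kept].to_numpy() @ cox.coefficients, sv)

        stage = "olpm"
        model = olpm.fit_olpm(cox, Xd[kept], sd, grid_cfg)
        disc_eval = olpm.evaluate_model(model, Xd, sd)
        val_eval = olpm.evaluate_model(model, Xv, sv)

        stage = "ml"
        all_features = list(Xd.columns)
        rows = [
            ("cox", len(kept), float(cox_c_disc), float(cox_c_val)),
            ("olpm", len(kept), disc_eval.c_index, val_eval.c_index),
        ]
        for kind in ("ann", "svr_rff", "svr_rbf", "regression_tree"):
            rows.append(_ml_row(kind, kept, Xd, sd, Xv, sv, config.seed))
            rows.append(_ml_row(kind, all_features, Xd, sd, Xv, sv, config.seed))

        if config.run_cv_ann:
            stage = "cv_ann"
            scores, _ = mlsuite.rf_feature_scores(
                Xd[kept] if len(kept) >= 2 else Xd,
                sd, n_iterations=config.rf_iterations, seed=config.seed,
            )
            ranked = list(scores.sort_values(ascending=False).index)
            top = ranked[: config.cv_top_features]
            subsets = [
                combo
                for size in range(2, min(config.cv_max_subset_size, len(top)) + 1)
                for combo in itertools.combinations(top, size)
            ] or [tuple(top)]
            cv_res = mlsuite.cv_attribute_search(
                subsets, Xd, sd,
                n_folds=config.cv_folds, holdout_size=config.cv_holdout,
                seed=config.seed,
            )
            final = mlsuite.train_model(
                mlsuite.MLConfig(kind="ann", seed=config.seed),
                Xd[list(cv_res.best_subset)], sd,
            )
            c_val = survstats.concordance_index(
                final.predict(Xv[list(cv_res.best_subset)]), sv,
                orientation="higher-is-better",
            )
            rows.insert(2, ("ann_cv", len(cv_res.best_subset),
                            cv_res.mean_cindex, float(c_val)))

        stage = "report"
        model_rows = pd.DataFrame(
            rows, columns=["model", "n_features", "c_discovery", "c_validation"]
        )
        km_curves = {}
        for label, X, s in (("discovery", Xd, sd), ("validation", Xv, sv)):
            groups = model.groups(X)
            for arm, arm_mask in (("low", ~groups), ("high", groups)):
                if arm_mask.any():
                    km_curves[f"olpm_{label}_{arm}"] = survstats.km_estimate(
                        s.subset(arm_mask)
                    ).to_frame()
        report = StudyReport(
            config=config,
            model_rows=model_rows,
            screening=screening,
            correlations=correlations,
            kept_features=tuple(kept),
            olpm_model=model,
            km_curves=km_curves,
        )
        if outdir is not None:
            report.write(outdir)
        logger.info("study complete in %.1fs", time.time() - t0)
        return report
    except Exception:
        logger.exception("study failed at stage %r", stage)
        raise
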