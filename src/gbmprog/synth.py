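"""Synthetic glioblastoma cohorts and tumor masks.

Emulates the statistical structure of a pretreatment-GBM imaging cohort:
age around 63 years truncated to (19, 86); contrast-enhancing (CE) volume
log-normal with mean ~20 cm^3; CE rim width log-normal with mean ~0.57 cm;
surface regularity a scaled Beta on (0.24, 0.99) with mean ~0.62; maximum
diameter derived from CE volume through multiplicative noise calibrated to a
target Spearman correlation (default 0.916); necrotic volume log-normal with
mean ~13.5 cm^3 and total volume = CE + necrotic by construction. Survival
follows Weibull-baseline proportional hazards with a log-linear prognostic
score in the informative features (defaults are the published linear-model
weights), median overall survival ~12.8 months at the mean score, and
independent administrative censoring calibrated by bisection to ~9%
censored. Noise columns are independent standard normals padding the table
to 44 features.

``generate_tumor_mask`` rasterizes a radially perturbed sphere with a
concentric necrotic core for exercising the geometry module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import ndimage

from .survstats import SurvivalSample

__all__ = [
    "CohortConfig",
    "ClinicalRecord",
    "generate_cohort",
    "generate_tumor_mask",
    "cohort_to_sample",
    "write_cohort",
]

#: hazard log-linear weights of the informative features (per-unit, on the
#: natural scale of each feature): the published optimized linear model
DEFAULT_TRUE_COEFFICIENTS = {
    "age": 0.030,
    "ce_rim_width": -0.340,
    "surface_regularity": -1.100,
    "ce_volume": 0.012,
}

INFORMATIVE_FEATURES = tuple(DEFAULT_TRUE_COEFFICIENTS)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of one synthetic cohort.

    Defaults reproduce the discovery-cohort summary characteristics: median
    age 63 (range 19-86), median OS 12.8 months, ~9% censoring (27 of 311),
    CE volume mean ~20 cm^3, rim width mean ~0.57 cm, surface regularity
    mean ~0.62, Spearman(CE volume, max diameter) ~0.916.
    """

    n_patients: int = 311
    seed: int = 0
    age_center: float = 63.0          # years
    age_spread: float = 12.0          # years (SD before truncation)
    age_range: tuple[float, float] = (19.0, 86.0)
    median_os: float = 12.8           # months at the mean prognostic score
    weibull_shape: float = 1.2
    censor_fraction: float = 0.087    # 27/311
    true_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    n_noise_features: int = 36        # pads the table to 44 columns
    include_derived_morphology: bool = True
    diameter_volume_rho_target: float = 0.916
    # log-normal parameters (meanlog chosen so E[X] matches the table means)
    ce_volume_sigma: float = 0.9      # E = 19.64 cm^3
    rim_width_sigma: float = 0.45     # E = 0.57 cm
    necrotic_volume_sigma: float = 1.2  # E = 13.50 cm^3
    cohort_label: str = "discovery"
    #: collapse the survival noise (every subject at the median quantile of
    #: its own survival law) so OS is a deterministic monotone function of
    #: the prognostic score; for calibration checks
    deterministic_survival: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0 <= self.censor_fraction <= 1:
            raise ValueError("censor_fraction must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.median_os <= 0:
            raise ValueError("median_os must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age: float
    os_months: float
    event: bool
    cohort: str = "discovery"

    def __post_init__(self) -> None:
        if self.os_months <= 0:
            raise ValueError("os_months must be positive")


def _truncated_normal(rng, center, spread, lo, hi, size):
    """Rejection-sampled truncated normal; deterministic given the rng state."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(center, spread, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _lognormal_with_mean(rng, mean, sigma, size):
    """Log-normal draws with E[X] = mean and log-scale SD sigma."""
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=size)


def _calibrate_censoring(times: np.ndarray, u: np.ndarray, target: float):
    """Administrative censoring C = c_max * U calibrated by bisection.

    Finds c_max such that the realized fraction of subjects with T > C is as
    close as possible to the target; monotone in c_max, so plain bisection
    on the empirical fraction suffices.
    """
    if target <= 0:
        return np.full_like(times, np.inf)

    def frac(c_max):
        return float(np.mean(times > c_max * u))

    lo, hi = 1e-6, float(times.max()) / max(u.min(), 1e-12) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * u


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[ClinicalRecord]]:
    """Draw one cohort: a feature table and matching clinical records.

    The returned DataFrame has ``patient_id`` as its index and one named
    column per feature; records carry (age, OS months, event flag). All
    randomness derives from ``config.seed``.
    """
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(), []
    # independent streams so the noise-column count never perturbs the
    # informative features or the survival draws
    s_feat, s_surv, s_noise = np.random.SeedSequence(config.seed).spawn(3)
    rng = np.random.default_rng(s_feat)
    rng_surv = np.random.default_rng(s_surv)
    rng_noise = np.random.default_rng(s_noise)

    age = _truncated_normal(
        rng, config.age_center, config.age_spread,
        config.age_range[0], config.age_range[1], n,
    )
    ce_volume = _lognormal_with_mean(rng, 19.64, config.ce_volume_sigma, n)
    rim_width = _lognormal_with_mean(rng, 0.57, config.rim_width_sigma, n)
    # scaled Beta(4, 3.9) on (0.24, 0.99): mean 0.24 + 0.506*0.75 ~ 0.62
    regularity = 0.24 + 0.75 * rng.beta(4.0, 3.9, size=n)
    necrotic_volume = _lognormal_with_mean(
        rng, 13.50, config.necrotic_volume_sigma, n
    )

    # max diameter = equivalent spherical diameter of CE volume times
    # multiplicative log-normal noise; the noise SD is set analytically from
    # the Spearman target: on log scale corr = s/sqrt(s^2 + 9*eps^2) with
    # s = SD(log V)
    rho = config.diameter_volume_rho_target
    s = config.ce_volume_sigma
    eps_sd = (
        (s / 3.0) * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0)) if rho != 0 else 10.0
    )
    eq_diameter = 2.0 * (3.0 * ce_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    # 1.52x the CE equivalent-sphere diameter reproduces the ~5.1 cm mean
    # (the measured diameter spans the whole irregular tumor, not just CE)
    max_diameter = 1.52 * eq_diameter * np.exp(rng.normal(0.0, eps_sd, size=n))
    if rho < 0:
        max_diameter = float(np.median(max_diameter)) ** 2 / max_diameter

    columns: dict[str, np.ndarray] = {
        "age": age,
        "ce_volume": ce_volume,
        "ce_rim_width": rim_width,
        "surface_regularity": regularity,
    }
    if config.include_derived_morphology:
        total_volume = ce_volume + necrotic_volume
        # surface from the sphericity relation, blurred by independent
        # multiplicative noise: real surface measurements are not a
        # deterministic function of volume and regularity
        total_surface = (
            (36.0 * np.pi * total_volume**2) ** (1.0 / 3.0) / regularity
            * np.exp(rng.normal(0.0, 0.35, size=n))
        )
        columns.update(
            max_diameter=max_diameter,
            necrotic_volume=necrotic_volume,
            total_volume=total_volume,
            total_surface=total_surface,
        )
    for i in range(config.n_noise_features):
        columns[f"noise_{i + 1:02d}"] = rng_noise.standard_normal(n)

    features = pd.DataFrame(
        columns, index=[f"P{i + 1:04d}" for i in range(n)]
    )
    features.index.name = "patient_id"

    # Weibull-baseline proportional hazards on the centered prognostic score
    missing = [f for f in config.true_coefficients if f not in features.columns]
    if missing:
        raise ValueError(f"true_coefficients name unknown feature(s): {missing}")
    ps = np.zeros(n)
    for name, beta in config.true_coefficients.items():
        ps += beta * features[name].to_numpy()
    ps_centered = ps - ps.mean()
    k = config.weibull_shape
    lam = config.median_os / np.log(2.0) ** (1.0 / k)
    u_surv = (np.full(n, 0.5) if config.deterministic_survival
              else rng_surv.uniform(size=n))
    t_death = lam * (-np.log(u_surv) / np.exp(ps_centered)) ** (1.0 / k)
    t_death = np.maximum(t_death, 0.03)  # months; floor at ~1 day

    u_cens = rng_surv.uniform(size=n)
    c_times = _calibrate_censoring(t_death, u_cens, config.censor_fraction)
    os_months = np.minimum(t_death, c_times)
    event = t_death <= c_times
    os_months = np.maximum(os_months, 0.01)

    records = [
        ClinicalRecord(
            patient_id=str(pid),
            age=float(a),
            os_months=float(t),
            event=bool(e),
            cohort=config.cohort_label,
        )
        for pid, a, t, e in zip(features.index, age, os_months, event)
    ]
    return features, records


def cohort_to_sample(records: list[ClinicalRecord]) -> SurvivalSample:
    """Survival outcomes of a record list in table order."""
    return SurvivalSample(
        np.array([r.os_months for r in records]),
        np.array([r.event for r in records]),
    )


def write_cohort(
    features: pd.DataFrame,
    records: list[ClinicalRecord],
    outdir: str | Path,
    config: CohortConfig | None = None,
) -> None:
    """CSV export: features.csv, clinical.csv, and the config for provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.to_csv(outdir / "features.csv")
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        outdir / "clinical.csv", index=False
    )
    if config is not None:
        (outdir / "cohort_config.json").write_text(config.to_json())


# ---------------------------------------------------------------------------
# Voxel masks
# ---------------------------------------------------------------------------

def _angular_field(rng, smooth_sigma: float = 6.0, grid: int = 64) -> np.ndarray:
    """Smooth zero-mean random field on a (latitude, longitude) grid.

    Wrap-smoothed so the perturbation is continuous across the longitude
    seam; normalized to unit maximum absolute value.
    """
    raw = rng.standard_normal((grid, grid))
    smooth = ndimage.gaussian_filter(raw, smooth_sigma, mode="wrap")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    return smooth / peak if peak > 0 else smooth


def generate_tumor_mask(
    ce_volume_target: float,
    necrosis_fraction: float = 0.4,
    irregularity: float = 0.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
):
    """Rasterize a radially perturbed sphere with a concentric necrotic core.

    The tumor boundary is r(direction) = R * (1 + irregularity * f), with f
    a smooth random angular field; the necrotic core is the same shape
    scaled by necrosis_fraction**(1/3), so core volume is that fraction of
    the total and necrotic voxels are strictly interior. R is found by
    bisection so the CE (shell) voxel volume matches the target within the
    rasterization error (<2% at <=1 mm isotropic spacing).

    Returns a :class:`gbmprog.geometry.VoxelMask` (labels 1 = CE shell,
    2 = necrotic core).
    """
    from .geometry import VoxelMask  # local import to avoid a cycle

    if ce_volume_target <= 0:
        raise ValueError("ce_volume_target must be positive")
    if not 0 <= necrosis_fraction < 1:
        raise ValueError("necrosis_fraction must be in [0, 1)")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    spacing = tuple(float(v) for v in spacing)
    if min(spacing) <= 0:
        raise ValueError("spacing components must be positive")
    voxel_volume_cm3 = np.prod(spacing) / 1000.0
    if ce_volume_target < voxel_volume_cm3:
        raise ValueError("target CE volume is smaller than one voxel")

    total_target_mm3 = 1000.0 * ce_volume_target / (1.0 - necrosis_fraction)
    r_nominal = (3.0 * total_target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_max = r_nominal * (1.0 + irregularity) * 1.2 + 2.0 * max(spacing)

    shape = tuple(int(2 * np.ceil(r_max / sp) + 3) for sp in spacing)
    center = [(sh - 1) / 2.0 * sp for sh, sp in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(
        *(np.arange(sh) * sp - c for sh, sp, c in zip(shape, spacing, center)),
        indexing="ij",
    )
    radius = np.sqrt(zz**2 + yy**2 + xx**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(radius > 0, zz / radius, 1.0), -1, 1))
        phi = np.arctan2(yy, xx)  # (-pi, pi]

    rng = np.random.default_rng(seed)
    if irregularity > 0:
        fld = _angular_field(rng)
        g = fld.shape[0]
        ti = theta / np.pi * (g - 1)
        pi_ = (phi + np.pi) / (2.0 * np.pi) * (g - 1)
        pert = ndimage.map_coordinates(
            fld, [ti.ravel(), pi_.ravel()], order=1, mode="wrap"
        ).reshape(radius.shape)
        direction_radius = 1.0 + irregularity * pert
    else:
        direction_radius = np.ones_like(radius)
    direction_radius = np.maximum(direction_radius, 0.05)
    # normalized radius: u <= R means inside the perturbed sphere of scale R
    u = radius / direction_radius

    core_scale = necrosis_fraction ** (1.0 / 3.0)
    target_ce_voxels = 1000.0 * ce_volume_target / (1000.0 * voxel_volume_cm3)

    def ce_count(R):
        total = u <= R
        core = u <= R * core_scale
        return int(total.sum() - core.sum())

    lo, hi = 0.5 * max(spacing), r_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ce_count(mid) < target_ce_voxels:
            lo = mid
        else:
            hi = mid
    best_r = min((lo, hi), key=lambda R: abs(ce_count(R) - target_ce_voxels))

    labels = np.zeros(shape, dtype=np.int16)
    labels[u <= best_r] = 1
    if necrosis_fraction > 0:
        labels[u <= best_r * core_scale] = 2
    if not (labels == 1).any():
        raise ValueError("degenerate mask: no CE voxels at the target volume")
    return VoxelMask(labels=labels, spacing=spacing)
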