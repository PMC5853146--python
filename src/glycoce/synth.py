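"""Synthetic cohorts and electropherograms with known ground truth.

The generator realizes the statistical structure the analysis assumes, so
every downstream stage can be tested against known truth without any data
download:

* :func:`generate_cohort` draws subjects from a :class:`CohortPreset`:
  covariates first (age, sex, CRP, serostatus, treatment, disease duration),
  then ``log(G0/G1)`` as a linear predictor plus Gaussian residual.  The
  preset's ratio median and IQR are population targets: the intercept and the
  residual SD are solved numerically at preset-calibration time (fixed
  internal seed) so the population median and IQR of the ratio equal the
  preset values even though CRP and serostatus enter asymmetrically.
* :func:`compose_profile` inverts the trait formulas: it tilts a base
  relative-area vector so its G0/G1 ratio and G0% hit given targets exactly,
  rescaling the remaining peaks to preserve normalization.
* :func:`render_electropherogram` draws the vector as Gaussian CE-LIF peaks
  (width growing linearly with migration time) at the times implied by the
  true migration model, together with the APTS-maltose internal standard and
  the DP 2-15 dextran ladder channel, plus white noise and a smooth baseline
  drift.

Ratio distributions are modeled log-normally given covariates (published
medians/IQRs are right-skewed).  The default presets transcribe the RA,
axSpA and healthy-control baseline characteristics (n, age, sex, CRP,
serostatus prevalences, G0/G1 medians and IQRs) of the study population the
package emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .egram import CalibrationModel, Electropherogram, REFERENCE_MALTOSE_TIME
from .reference import ReferenceTable, build_reference_table
from .traits import GlycoProfile, compute_traits

__all__ = [
    "CohortPreset",
    "CompositionModel",
    "MigrationModel",
    "FeasibilityError",
    "PresetError",
    "HEALTHY_BASE_COMPOSITION",
    "TABLE1_PRESETS",
    "get_preset",
    "save_preset",
    "load_preset",
    "generate_cohort",
    "generate_study",
    "compose_profile",
    "render_electropherogram",
    "generate_expression_table",
]


class FeasibilityError(ValueError):
    """Raised when a (ratio, G0%) target cannot be realized on a base vector."""


class PresetError(ValueError):
    """Raised when a cohort preset is internally inconsistent or infeasible."""


# ------------------------------------------------------------- composition

# Default healthy relative-area vector over the 22 reference peaks.  G0 and
# G1 together carry ~72% of the total area, the G0/G1 ratio is ~0.95 and G0%
# ~35, matching a healthy adult IgG-Fc profile.
HEALTHY_BASE_COMPOSITION: dict[int, float] = {
    1: 0.010,
    2: 0.020,
    3: 0.020,
    4: 0.035,
    5: 0.010,
    6: 0.015,
    7: 0.005,
    8: 0.010,
    9: 0.003,
    10: 0.004,
    11: 0.040,
    12: 0.220,
    13: 0.020,
    14: 0.070,
    15: 0.015,
    16: 0.008,
    17: 0.130,
    18: 0.110,
    19: 0.035,
    20: 0.030,
    21: 0.060,
    22: 0.130,
}


@dataclass(frozen=True)
class CompositionModel:
    """A base relative-area vector plus the reference table used to tilt it."""

    base: tuple[tuple[int, float], ...] = tuple(sorted(HEALTHY_BASE_COMPOSITION.items()))
    gu_tolerance: float = 0.1

    def __post_init__(self) -> None:
        vals = [v for _, v in self.base]
        if any(v < 0 for v in vals):
            raise PresetError("base composition must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise PresetError(f"base composition must sum to 1, got {sum(vals)}")

    @property
    def reference(self) -> ReferenceTable:
        return build_reference_table(gu_tolerance=self.gu_tolerance)

    def base_dict(self) -> dict[int, float]:
        return dict(self.base)


def compose_profile(
    target_ratio: float,
    target_g0_percent: float,
    model: Optional[CompositionModel] = None,
) -> dict[int, float]:
    """Reweight the base vector to hit a (G0/G1 ratio, G0%) target exactly.

    G0-class peaks are scaled to sum to ``g0 = target_g0_percent / 100``,
    G1-class peaks to ``g1 = g0 / target_ratio``, and all remaining peaks are
    rescaled to carry the leftover mass ``1 - g0 - g1``.  Raises
    :class:`FeasibilityError` (stating the attainable range) for infeasible
    target pairs.
    """
    if model is None:
        model = CompositionModel()
    ref = model.reference
    base = model.base_dict()
    if not np.isfinite(target_ratio) or target_ratio <= 0:
        raise FeasibilityError(f"target ratio must be positive, got {target_ratio}")
    g0 = target_g0_percent / 100.0
    if not 0.0 < g0 < 1.0:
        raise FeasibilityError(f"target G0% must be in (0, 100), got {target_g0_percent}")
    g1 = g0 / target_ratio
    rest = 1.0 - g0 - g1
    if rest < -1e-12:
        min_ratio = g0 / (1.0 - g0)
        raise FeasibilityError(
            f"targets G0%={target_g0_percent}, ratio={target_ratio} need G0+G1>1; "
            f"for this G0% the ratio must be >= {min_ratio:.4f}"
        )
    rest = max(rest, 0.0)

    ids = {c: ref.peak_ids_by_class(c) for c in ("G0", "G1")}
    other_ids = [p.peak_id for p in ref.peaks if p.trait_class not in ("G0", "G1")]
    b0 = sum(base[i] for i in ids["G0"])
    b1 = sum(base[i] for i in ids["G1"])
    br = sum(base[i] for i in other_ids)
    if b0 <= 0 or b1 <= 0:
        raise FeasibilityError("base vector has no support on G0 or G1 peaks")
    if rest > 0 and br <= 0:
        raise FeasibilityError(
            "base vector has no support outside G0/G1; only targets with "
            "G0+G1=1 are attainable"
        )
    out: dict[int, float] = {}
    for i in ids["G0"]:
        out[i] = base[i] * g0 / b0
    for i in ids["G1"]:
        out[i] = base[i] * g1 / b1
    for i in other_ids:
        out[i] = base[i] * rest / br if br > 0 else 0.0
    return out


# --------------------------------------------------------------- migration


@dataclass(frozen=True)
class MigrationModel:
    """True migration time (minutes) as a gently nonlinear function of GU."""

    t0: float = 8.0
    k: float = 1.15
    c: float = 0.02

    def __call__(self, gu):
        g = np.asarray(gu, dtype=float)
        t = self.t0 + self.k * g + self.c * g * g
        return float(t) if np.isscalar(gu) else t

    @property
    def maltose_time(self) -> float:
        return self(2.0)  # maltose is the DP-2 oligomer

    def as_calibration_model(self, dp_range: tuple[int, int] = (2, 15)) -> CalibrationModel:
        """Ground-truth calibration: exact ladder knots of this migration model."""
        dps = list(range(dp_range[0], dp_range[1] + 1))
        return CalibrationModel(
            maltose_time=self.maltose_time,
            ladder_points=tuple((self(float(dp)), float(dp)) for dp in dps),
        )


# ------------------------------------------------------------------ presets


@dataclass(frozen=True)
class CohortPreset:
    """Generative model of one cohort.

    Effects act on ``log(G0/G1)``; slopes are per unit of the covariate.
    ``residual_sd=None`` means: solve the residual SD so the population IQR
    of the ratio matches ``ratio_iqr`` (raising :class:`PresetError` if the
    systematic spread alone already exceeds it).
    """

    name: str
    cohort: str  # RA | axSpA | HC
    n: int
    age_mean: float
    age_sd: float
    female_fraction: float
    ratio_median: float
    ratio_iqr: tuple[float, float]
    g0g1_sum: float
    g0g1_sum_sd: float = 0.02
    crp_mean: Optional[float] = None
    crp_sd: Optional[float] = None
    das28_mean: Optional[float] = None
    das28_sd: Optional[float] = None
    n_missing_activity: int = 0
    acpa_prevalence: Optional[float] = None
    rf_prevalence: Optional[float] = None
    se_prevalence: Optional[float] = None
    hla_b27_prevalence: Optional[float] = None
    therapy_fraction: Optional[float] = None
    sulfasalazine_fraction: Optional[float] = None
    subtype_as_fraction: Optional[float] = None  # axSpA: AS vs nr-axSpA
    duration_anchors: Optional[tuple[tuple[float, float], ...]] = None
    duration_lognormal: Optional[tuple[float, float]] = None
    age_slope: float = 0.0
    crp_slope: float = 0.0
    crp_slope_se: float = 0.0  # added to crp_slope for SE carriers
    crp_slope_rf: float = 0.0  # added to crp_slope for RF positives
    acpa_effect: float = 0.0
    rf_effect: float = 0.0
    se_effect: float = 0.0
    hla_b27_effect: float = 0.0
    sex_effect: float = 0.0  # male minus female
    sulfasalazine_effect: float = 0.0
    subtype_effect: float = 0.0  # AS minus nr-axSpA, half each side
    residual_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PresetError(f"n must be >= 1, got {self.n}")
        for nm in (
            "female_fraction",
            "acpa_prevalence",
            "rf_prevalence",
            "se_prevalence",
            "hla_b27_prevalence",
            "therapy_fraction",
            "sulfasalazine_fraction",
            "subtype_as_fraction",
        ):
            v = getattr(self, nm)
            if v is not None and not 0.0 <= v <= 1.0:
                raise PresetError(f"{nm} must be a probability, got {v}")
        for nm in ("age_sd", "g0g1_sum_sd"):
            if not getattr(self, nm) > 0:
                raise PresetError(f"{nm} must be > 0")
        if self.residual_sd is not None and self.residual_sd < 0:
            raise PresetError(f"residual_sd must be >= 0, got {self.residual_sd}")
        q1, q3 = self.ratio_iqr
        if not 0 < q1 <= self.ratio_median <= q3:
            raise PresetError(f"ratio_iqr {self.ratio_iqr} inconsistent with median")


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def _draw_covariates(preset: CohortPreset, rng: np.random.Generator, n: int) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n))
    df["age"] = np.clip(rng.normal(preset.age_mean, preset.age_sd, n), 18.0, 92.0)
    df["sex"] = np.where(rng.random(n) < preset.female_fraction, "F", "M")
    if preset.crp_mean is not None:
        shape, scale = _gamma_params(preset.crp_mean, preset.crp_sd)
        df["crp"] = rng.gamma(shape, scale, n)
    else:
        df["crp"] = np.nan
    for col, prev in (
        ("acpa", preset.acpa_prevalence),
        ("rf", preset.rf_prevalence),
        ("se", preset.se_prevalence),
        ("hla_b27", preset.hla_b27_prevalence),
        ("therapy", preset.therapy_fraction),
        ("sulfasalazine", preset.sulfasalazine_fraction),
    ):
        df[col] = (rng.random(n) < prev).astype(float) if prev is not None else np.nan
    if preset.subtype_as_fraction is not None:
        df["subtype"] = np.where(
            rng.random(n) < preset.subtype_as_fraction, "AS", "nr-axSpA"
        )
    else:
        df["subtype"] = None
    if preset.duration_anchors is not None:
        probs = np.array([p for p, _ in preset.duration_anchors])
        years = np.array([y for _, y in preset.duration_anchors])
        df["disease_duration"] = np.interp(rng.random(n), probs, years)
    elif preset.duration_lognormal is not None:
        mu, sigma = preset.duration_lognormal
        df["disease_duration"] = rng.lognormal(mu, sigma, n)
    else:
        df["disease_duration"] = np.nan
    if preset.das28_mean is not None:
        # couple DAS28 to CRP through a Gaussian copula so activity markers
        # agree qualitatively (rho = 0.5)
        shape, scale = _gamma_params(preset.crp_mean, preset.crp_sd)
        u = sps.gamma.cdf(df["crp"].to_numpy(), shape, scale=scale)
        z_crp = sps.norm.ppf(np.clip(u, 1e-9, 1 - 1e-9))
        eps = rng.normal(size=n)
        z = 0.5 * z_crp + math.sqrt(1 - 0.25) * eps
        df["das28"] = np.clip(preset.das28_mean + preset.das28_sd * z, 0.5, 9.4)
        df["esr"] = np.clip(
            2.0 + 1.8 * np.power(df["crp"], 0.66) + rng.normal(0, 4, n), 1.0, 140.0
        )
    else:
        df["das28"] = np.nan
        df["esr"] = np.nan
    return df


def _systematic(preset: CohortPreset, df: pd.DataFrame) -> np.ndarray:
    """Linear predictor of log(G0/G1), before intercept and residual."""
    eta = preset.age_slope * (df["age"].to_numpy(dtype=float) - 55.0)
    eta = eta + preset.sex_effect * (df["sex"].to_numpy() == "M").astype(float)
    crp = np.nan_to_num(df["crp"].to_numpy(dtype=float))
    slope = np.full(len(df), preset.crp_slope)
    if preset.crp_slope_se:
        slope = slope + preset.crp_slope_se * np.nan_to_num(df["se"].to_numpy(dtype=float))
    if preset.crp_slope_rf:
        slope = slope + preset.crp_slope_rf * np.nan_to_num(df["rf"].to_numpy(dtype=float))
    eta = eta + slope * crp
    for col, eff in (
        ("acpa", preset.acpa_effect),
        ("rf", preset.rf_effect),
        ("se", preset.se_effect),
        ("hla_b27", preset.hla_b27_effect),
        ("sulfasalazine", preset.sulfasalazine_effect),
    ):
        if eff:
            eta = eta + eff * np.nan_to_num(df[col].to_numpy(dtype=float))
    if preset.subtype_effect and preset.subtype_as_fraction is not None:
        is_as = (df["subtype"].to_numpy() == "AS").astype(float)
        eta = eta + preset.subtype_effect * (is_as - 0.5)
    return np.asarray(eta, dtype=float)


_CAL_N = 40_000
_CAL_SEED = 987_654_321  # internal, fixed: preset calibration is not user randomness


@lru_cache(maxsize=32)
def _calibrate(preset: CohortPreset) -> tuple[float, float]:
    """Solve (intercept, residual_sd) so the population median and IQR of the
    ratio equal the preset targets.  Deterministic given the preset."""
    rng = np.random.default_rng(_CAL_SEED)
    big = replace(preset, n=_CAL_N)
    cov = _draw_covariates(big, rng, _CAL_N)
    eta = _systematic(big, cov)
    eps = rng.normal(size=_CAL_N)
    q1, q3 = preset.ratio_iqr
    target_iqr = math.log(q3) - math.log(q1)

    if preset.residual_sd is not None:
        sigma = preset.residual_sd
    else:
        def iqr_at(s: float) -> float:
            x = eta + s * eps
            return float(np.percentile(x, 75) - np.percentile(x, 25))

        if iqr_at(0.0) > target_iqr:
            raise PresetError(
                f"preset {preset.name!r}: systematic spread (IQR {iqr_at(0.0):.3f} on the "
                f"log scale) already exceeds the target IQR {target_iqr:.3f}; "
                "the implied residual variance is negative"
            )
        lo, hi = 0.0, 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if iqr_at(mid) < target_iqr:
                lo = mid
            else:
                hi = mid
        sigma = 0.5 * (lo + hi)

    med = float(np.median(eta + sigma * eps))
    intercept = math.log(preset.ratio_median) - med
    return intercept, sigma


def generate_cohort(preset: CohortPreset, seed: int) -> pd.DataFrame:
    """Draw a cohort table from a preset; deterministic given the seed.

    Columns: subject_id, cohort, subtype, age, sex, crp, das28, esr, acpa,
    rf, se, hla_b27, disease_duration, therapy, sulfasalazine, g0_g1_ratio,
    g0_percent, g0g1_sum (the last three are the generator's ground truth).
    """
    intercept, sigma = _calibrate(preset)
    rng = np.random.default_rng(seed)
    df = _draw_covariates(preset, rng, preset.n)
    eta = _systematic(preset, df)
    log_ratio = intercept + eta + sigma * rng.normal(size=preset.n)
    ratio = np.exp(log_ratio)
    s = np.clip(
        rng.normal(preset.g0g1_sum, preset.g0g1_sum_sd, preset.n), 0.55, 0.90
    )
    g0 = s * ratio / (1.0 + ratio)
    df.insert(0, "subject_id", [f"{preset.cohort}-{i:04d}" for i in range(preset.n)])
    df.insert(1, "cohort", preset.cohort)
    df["g0_g1_ratio"] = ratio
    df["g0_percent"] = 100.0 * g0
    df["g0g1_sum"] = s
    if preset.n_missing_activity:
        k = min(preset.n_missing_activity, preset.n)
        miss = rng.choice(preset.n, size=k, replace=False)
        df.loc[df.index[miss], ["crp", "das28", "esr"]] = np.nan
    return df


TABLE1_PRESETS: dict[str, CohortPreset] = {
    "table1-RA": CohortPreset(
        name="table1-RA",
        cohort="RA",
        n=178,
        age_mean=55.0,
        age_sd=12.4,
        female_fraction=0.783,
        ratio_median=1.25,
        ratio_iqr=(1.09, 1.56),
        g0g1_sum=0.747,
        crp_mean=19.4,
        crp_sd=30.6,
        das28_mean=5.1,
        das28_sd=1.4,
        n_missing_activity=5,
        acpa_prevalence=0.539,
        rf_prevalence=0.764,
        se_prevalence=0.539,
        therapy_fraction=0.71,
        sulfasalazine_fraction=47.0 / 178.0,
        duration_anchors=(
            (0.0, 0.02),
            (0.125, 0.5),
            (0.375, 2.6),
            (0.625, 7.6),
            (0.875, 16.6),
            (1.0, 60.8),
        ),
        age_slope=0.006,
        crp_slope=0.006,
        crp_slope_se=0.002,
        crp_slope_rf=-0.002,
        acpa_effect=0.07,
        se_effect=0.03,
        sulfasalazine_effect=-0.11,
    ),
    "table1-axSpA": CohortPreset(
        name="table1-axSpA",
        cohort="axSpA",
        n=126,
        age_mean=44.3,
        age_sd=8.4,
        female_fraction=0.651,
        ratio_median=0.89,
        ratio_iqr=(0.79, 1.09),
        g0g1_sum=0.690,
        crp_mean=5.8,
        crp_sd=10.3,
        hla_b27_prevalence=0.698,
        subtype_as_fraction=64.0 / 126.0,
        duration_lognormal=(math.log(4.5), 0.7137),
        age_slope=0.006,
        crp_slope=0.001,
        hla_b27_effect=-0.05,
        subtype_effect=0.09,
    ),
    "table1-HC": CohortPreset(
        name="table1-HC",
        cohort="HC",
        n=119,
        age_mean=55.2,
        age_sd=13.5,
        female_fraction=0.782,
        ratio_median=0.95,
        ratio_iqr=(0.77, 1.13),
        g0g1_sum=0.727,
        age_slope=0.006,
    ),
}


def get_preset(name: str) -> CohortPreset:
    try:
        return TABLE1_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(TABLE1_PRESETS)}"
        ) from None


def save_preset(preset: CohortPreset, path) -> None:
    """Write a preset as a YAML config file."""
    import dataclasses

    import yaml

    data = dataclasses.asdict(preset)
    # tuples -> lists for clean YAML
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = [list(v) if isinstance(v, tuple) else v for v in val]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_preset(path) -> CohortPreset:
    """Read a preset from a YAML config file (validates on construction)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("ratio_iqr", "duration_lognormal"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    if data.get("duration_anchors") is not None:
        data["duration_anchors"] = tuple(tuple(a) for a in data["duration_anchors"])
    return CohortPreset(**data)


def generate_study(seed: int, presets: Optional[Sequence[CohortPreset]] = None) -> pd.DataFrame:
    """Generate all cohorts of the study design into one table."""
    if presets is None:
        presets = [TABLE1_PRESETS[k] for k in ("table1-RA", "table1-axSpA", "table1-HC")]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(presets))
    frames = [
        generate_cohort(p, int(c.generate_state(1)[0] % (2**31)))
        for p, c in zip(presets, children)
    ]
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------- renderer


def _add_gaussians(
    t: np.ndarray,
    y: np.ndarray,
    centers: np.ndarray,
    sigmas: np.ndarray,
    areas: np.ndarray,
) -> None:
    for mu, sg, a in zip(centers, sigmas, areas):
        if a <= 0:
            continue
        lo = np.searchsorted(t, mu - 6 * sg)
        hi = np.searchsorted(t, mu + 6 * sg)
        if hi <= lo:
            continue
        tt = t[lo:hi]
        y[lo:hi] += a / (sg * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((tt - mu) / sg) ** 2)


def _peak_sigma(time: np.ndarray | float) -> np.ndarray | float:
    # CE peaks broaden with migration time (diffusion-dominated)
    return 0.015 + 0.0015 * np.asarray(time, dtype=float)


MALTOSE_AREA_FRACTION = 0.25  # internal-standard area relative to total glycan area


def render_electropherogram(
    areas: Mapping[int, float],
    migration: Optional[MigrationModel] = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    target_min_snr: Optional[float] = None,
    drift_factor_sd: float = 0.0,
    baseline_drift: bool = True,
    total_area: float = 100.0,
    dt: float = 0.008,
    position_jitter_sd: float = 0.002,
    ref: Optional[ReferenceTable] = None,
    dp_range: tuple[int, int] = (2, 15),
) -> tuple[Electropherogram, Electropherogram]:
    """Render a relative-area vector as (sample, ladder) CE-LIF traces.

    Peaks are Gaussians at the times the migration model implies for the
    reference GU positions, with areas proportional to the input vector; the
    maltose internal standard and the DP 2-15 dextran ladder are rendered
    alongside.  ``target_min_snr`` sets the white-noise SD so the smallest
    rendered peak has that SNR (overriding ``noise_sd``).  A multiplicative
    migration drift (SD ``drift_factor_sd``) applies to both channels, as a
    shared-run effect the maltose normalization must undo.  Deterministic
    given the seed.
    """
    if migration is None:
        migration = MigrationModel()
    if ref is None:
        ref = build_reference_table()
    if any(v < 0 for v in areas.values()):
        raise ValueError("areas must be non-negative")
    rng = np.random.default_rng(seed)
    drift = 1.0 + (rng.normal(0, drift_factor_sd) if drift_factor_sd > 0 else 0.0)
    drift = float(np.clip(drift, 0.9, 1.1))

    gu_by_id = {p.peak_id: p.gu_position for p in ref.peaks}
    glyc_gu = np.array([gu_by_id[i] for i in sorted(areas)])
    glyc_area = np.array([areas[i] for i in sorted(areas)]) * total_area
    glyc_t = migration(glyc_gu) * drift
    glyc_t = glyc_t + rng.normal(0, position_jitter_sd, glyc_t.size)
    maltose_t = migration.maltose_time * drift + rng.normal(0, position_jitter_sd)
    maltose_area = MALTOSE_AREA_FRACTION * total_area

    centers = np.concatenate([[maltose_t], glyc_t])
    areas_all = np.concatenate([[maltose_area], glyc_area])
    sigmas = _peak_sigma(centers)
    heights = areas_all / (sigmas * math.sqrt(2 * math.pi))
    pos_heights = heights[areas_all > 0]

    if target_min_snr is not None and pos_heights.size:
        noise_sd = float(np.min(pos_heights)) / target_min_snr
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    # sample channel
    t_lo = min(centers.min(), migration.maltose_time) - 0.8
    t_hi = centers.max() + 0.8
    t = np.arange(t_lo, t_hi, dt)
    y = np.zeros_like(t)
    _add_gaussians(t, y, centers, sigmas, areas_all)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, t.size)
        if baseline_drift:
            y = y + (
                10 * noise_sd
                + 0.5 * noise_sd * (t - t[0])
                + 3 * noise_sd * np.sin(2 * math.pi * (t - t[0]) / 8.0)
            )
    sample = Electropherogram(t, y, channel_label="sample")

    # ladder channel: DP 2..15, areas tapering gently with DP
    dps = np.arange(dp_range[0], dp_range[1] + 1, dtype=float)
    lad_t = migration(dps) * drift + rng.normal(0, position_jitter_sd, dps.size)
    lad_area = 0.12 * total_area * 0.95 ** (dps - dps[0])
    lt_grid = np.arange(lad_t.min() - 0.8, lad_t.max() + 0.8, dt)
    ly = np.zeros_like(lt_grid)
    _add_gaussians(lt_grid, ly, lad_t, _peak_sigma(lad_t), lad_area)
    if noise_sd > 0:
        ly = ly + rng.normal(0, noise_sd, lt_grid.size)
        if baseline_drift:
            ly = ly + 10 * noise_sd + 0.3 * noise_sd * (lt_grid - lt_grid[0])
    ladder = Electropherogram(lt_grid, ly, channel_label="ladder")
    return sample, ladder


# --------------------------------------------------------------- expression

_EXPRESSION_GENES = {
    # gene: (naive-B level, plasma-cell fold change)
    "B4GALT3": (100.0, 3.0),
    "B4GALT1": (150.0, 2.0),
    "MGAT3": (80.0, 1.5),
    "FUT8": (120.0, 1.8),
    "ST6GAL1": (200.0, 2.5),
}

_B_CELL_STAGES = ("pro_B", "pre_B", "immature_B", "naive_B", "plasma_cell")


def generate_expression_table(
    seed: int = 0,
    b4galt3_fold: float = 3.0,
    noise_cv: float = 0.05,
    n_pools: int = 2,
) -> pd.DataFrame:
    """Synthetic normalized transcript intensities across B-cell stages.

    Emulates a normalized microarray summary (two independent pools per
    differentiation stage) in which glycosyltransferase transcripts --
    B4GALT3 in particular, at ``b4galt3_fold`` (default threefold) -- are
    higher in plasma cells than in naive B cells.  Tidy columns: gene,
    population, pool, intensity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, (base, fold) in _EXPRESSION_GENES.items():
        fold = b4galt3_fold if gene == "B4GALT3" else fold
        for stage in _B_CELL_STAGES:
            level = base * (fold if stage == "plasma_cell" else 1.0)
            # early stages express slightly below the naive level
            if stage in ("pro_B", "pre_B"):
                level *= 0.8
            for pool in range(1, n_pools + 1):
                rows.append(
                    {
                        "gene": gene,
                        "population": stage,
                        "pool": pool,
                        "intensity": level * (1.0 + noise_cv * rng.normal()),
                    }
                )
    return pd.DataFrame(rows)
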