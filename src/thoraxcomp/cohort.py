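"""Simulated PET/CT referral cohorts with known statistical ground truth.

Generates per-subject covariates, body-composition metrics with a
configurable volume-density correlation structure, and event times from
cause-specific proportional-hazards models with myocardial infarction
and death as competing events plus independent uniform censoring.  The
true per-SD log-hazards and the target correlation matrix are returned
alongside the table, so the downstream survival models have a
parameter-recovery oracle.

Composition metrics are drawn as a multivariate normal on the z-score
scale and mapped linearly to plausible units, which preserves the
target Pearson correlations exactly in the population.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TissueDistribution",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "impute_missing_bmi",
    "CAC_CATEGORIES",
]

#: ordinal coronary-calcium categories with a point mass at zero
CAC_CATEGORIES = ("0", "1-99", "100-399", ">=400")


@dataclass(frozen=True)
class TissueDistribution:
    """Marginal scales and the volume-density correlation for one tissue."""

    vol_mean: float
    vol_sd: float
    dens_mean: float
    dens_sd: float
    vol_dens_corr: float


def _default_tissues() -> dict[str, TissueDistribution]:
    # volume index in cm^3/m^2, density in HU; correlations from the
    # cohort the simulator emulates (SM +0.46, SAT -0.68, EAT -0.46,
    # VAT -0.23, IMAT -0.52; bone unreported, set to 0)
    return {
        "sm": TissueDistribution(350.0, 80.0, 35.0, 8.0, 0.46),
        "bone": TissueDistribution(250.0, 60.0, 220.0, 40.0, 0.0),
        "sat": TissueDistribution(450.0, 180.0, -95.0, 10.0, -0.68),
        "eat": TissueDistribution(60.0, 25.0, -75.0, 8.0, -0.46),
        "vat": TissueDistribution(250.0, 120.0, -85.0, 12.0, -0.23),
        "imat": TissueDistribution(40.0, 20.0, -65.0, 12.0, -0.52),
    }


def _default_comorbidities() -> dict[str, float]:
    return {
        "hypertension": 0.790,
        "diabetes": 0.388,
        "dyslipidaemia": 0.690,
        "family_history_cad": 0.208,
        "smoking": 0.081,
        "heart_failure": 0.195,
        "cancer": 0.192,
        "prior_mi": 0.206,
        "prior_revascularization": 0.289,
        "early_revascularization": 0.08,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, covariate distributions, and true hazard structure.

    Continuous entries of ``beta_death`` / ``beta_mi`` are log-hazard
    ratios per (true) SD of the named column; binary covariates enter on
    the 0/1 scale.  Weibull baselines are per cause; ``mi_scale=None``
    or ``death_scale=None`` switches a cause off, ``censor_high=None``
    disables censoring.
    """

    n: int = 10085
    male_fraction: float = 0.572
    age_mean: float = 67.5
    age_sd: float = 12.6
    bmi_mean: float = 30.3
    bmi_sd: float = 7.0
    bmi_missing_p: float = 0.003
    comorbidity_prevalence: dict[str, float] = field(default_factory=_default_comorbidities)
    tissues: dict[str, TissueDistribution] = field(default_factory=_default_tissues)

    # PET markers (log-scale parameters for the log-normal ones)
    log_tpd_mean: float = 1.72
    log_tpd_sd: float = 1.40
    lvef_mean: float = 63.0
    lvef_sd: float = 14.0
    delta_lvef_mean: float = 2.1
    delta_lvef_sd: float = 4.7
    log_mfr_mean: float = 0.784
    log_mfr_sd: float = 0.369
    cac_probs: tuple[float, ...] = (0.30, 0.15, 0.20, 0.35)

    beta_death: dict[str, float] = field(
        default_factory=lambda: {"age": 0.45, "vat_density_hu": 0.336, "sm_vol_idx": -0.128}
    )
    beta_mi: dict[str, float] = field(
        default_factory=lambda: {"vat_density_hu": 0.18, "prior_mi": 0.50}
    )
    death_shape: float = 1.1
    death_scale: float | None = 11.0
    mi_shape: float = 1.0
    mi_scale: float | None = 40.0
    censor_low: float = 1.0
    censor_high: float | None = 11.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        probs = {"male_fraction": self.male_fraction, "bmi_missing_p": self.bmi_missing_p}
        probs.update(self.comorbidity_prevalence)
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.cac_probs) - 1.0) > 1e-9:
            raise ValueError("CAC category probabilities must sum to 1")
        for t, dist in self.tissues.items():
            if not -1.0 < dist.vol_dens_corr < 1.0:
                raise ValueError(
                    f"correlation matrix not positive definite: pair "
                    f"({t}_vol_idx, {t}_density_hu) has r={dist.vol_dens_corr}"
                )


@dataclass
class SimulatedCohort:
    """A simulated cohort table plus the ground truth that generated it."""

    table: pd.DataFrame
    truth: dict

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    def truth_to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.truth, indent=2, default=float))
        return path


def _weibull_times(rng, shape: float, scale: float | None, eta: np.ndarray) -> np.ndarray:
    """Latent event times under a Weibull proportional-hazards model."""
    n = len(eta)
    if scale is None:
        return np.full(n, np.inf)
    u = rng.uniform(size=n)
    return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> SimulatedCohort:
    """Draw one cohort; same seed gives an identical table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    df = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    df["male"] = (rng.uniform(size=n) < spec.male_fraction).astype(int)
    df["sex"] = np.where(df["male"] == 1, "male", "female")
    age_z = rng.standard_normal(n)
    df["age"] = spec.age_mean + spec.age_sd * age_z
    df["bmi"] = spec.bmi_mean + spec.bmi_sd * rng.standard_normal(n)
    for name, p in spec.comorbidity_prevalence.items():
        df[name] = (rng.uniform(size=n) < p).astype(int)

    # PET markers
    df["stress_tpd"] = np.exp(spec.log_tpd_mean + spec.log_tpd_sd * rng.standard_normal(n))
    df["stress_lvef"] = np.clip(
        spec.lvef_mean + spec.lvef_sd * rng.standard_normal(n), 15.0, 90.0
    )
    df["delta_lvef"] = spec.delta_lvef_mean + spec.delta_lvef_sd * rng.standard_normal(n)
    df["mfr"] = np.exp(spec.log_mfr_mean + spec.log_mfr_sd * rng.standard_normal(n))
    df["cac_category"] = rng.choice(CAC_CATEGORIES, size=n, p=spec.cac_probs)

    # body composition on the z-scale, then linear maps to units
    z_cols: dict[str, np.ndarray] = {"age": age_z}
    for t, dist in spec.tissues.items():
        cov = np.array([[1.0, dist.vol_dens_corr], [dist.vol_dens_corr, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        df[f"{t}_vol_idx"] = dist.vol_mean + dist.vol_sd * z[:, 0]
        df[f"{t}_density_hu"] = dist.dens_mean + dist.dens_sd * z[:, 1]
        z_cols[f"{t}_vol_idx"] = z[:, 0]
        z_cols[f"{t}_density_hu"] = z[:, 1]

    def _linear_predictor(betas: dict[str, float]) -> np.ndarray:
        eta = np.zeros(n)
        for col, beta in betas.items():
            if col in z_cols:
                eta += beta * z_cols[col]
            elif col in df.columns:
                eta += beta * df[col].to_numpy(dtype=float)
            else:
                raise ValueError(f"hazard covariate {col!r} is not a simulated column")
        return eta

    t_death = _weibull_times(rng, spec.death_shape, spec.death_scale, _linear_predictor(spec.beta_death))
    t_mi = _weibull_times(rng, spec.mi_shape, spec.mi_scale, _linear_predictor(spec.beta_mi))
    if spec.censor_high is None:
        t_cens = np.full(n, np.inf)
    else:
        t_cens = rng.uniform(spec.censor_low, spec.censor_high, size=n)
    times = np.minimum.reduce([t_death, t_mi, t_cens])
    if not np.all(np.isfinite(times)):
        raise ValueError("event generation produced infinite follow-up; enable at least one cause or censoring")
    event = np.zeros(n, dtype=int)
    event[(t_mi <= t_death) & (t_mi <= t_cens)] = 1
    event[(t_death < t_mi) & (t_death <= t_cens)] = 2
    df["time_years"] = times
    df["event"] = event  # 0 censored, 1 MI, 2 death
    df["death_or_mi"] = (event > 0).astype(int)

    if spec.bmi_missing_p > 0:
        df.loc[rng.uniform(size=n) < spec.bmi_missing_p, "bmi"] = np.nan

    truth = {
        "beta_death": dict(spec.beta_death),
        "beta_mi": dict(spec.beta_mi),
        "vol_density_corr": {t: d.vol_dens_corr for t, d in spec.tissues.items()},
        "death_weibull": {"shape": spec.death_shape, "scale": spec.death_scale},
        "mi_weibull": {"shape": spec.mi_shape, "scale": spec.mi_scale},
        "censoring": {"low": spec.censor_low, "high": spec.censor_high},
        "seed": spec.seed,
        "n": n,
    }
    return SimulatedCohort(table=df, truth=truth)


def impute_missing_bmi(table: pd.DataFrame, column: str = "bmi") -> tuple[pd.DataFrame, int]:
    """Replace missing BMI with the population median; returns (table, n imputed)."""
    if column not in table.columns:
        raise ValueError(f"column {column!r} not present")
    missing = table[column].isna()
    n_missing = int(missing.sum())
    if n_missing == len(table):
        raise ValueError("all BMI values missing; median imputation impossible")
    out = table.copy()
    if n_missing:
        out.loc[missing, column] = table[column].median(skipna=True)
    return out, n_missing


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    if "tissues" in d:
        d["tissues"] = {t: TissueDistribution(**v) for t, v in d["tissues"].items()}
    for key in ("cac_probs",):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortSpec(**d)


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
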