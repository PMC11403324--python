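"""Simulation configuration for synthetic pregnancy saliva cohorts.

Defaults reproduce the study conditions of a three-stage antenatal
protocol: seven samples per day (awakening, +15 min, +30 min, 10:30,
12:00, 17:00, bedtime), attendance in one to three pregnancy stages,
covariate prevalences of a Finnish pregnancy cohort, log-scale variance
components of the final diurnal mixed model, and planted protocol
violations at the observed quality-control rates.

Violation-rate semantics (per key of ``violation_rates``):

* ``rise_before_S1``, ``illness``, ``s2s3_late``, ``s4_early`` —
  probability per sampling day (at most one day-level violation per day);
* ``missing_time``, ``high_cv`` — probability per sample, planted only on
  violation-free days so each planted event triggers exactly one QC rule;
* ``duplicate_day`` — probability per subject-stage of a second, less
  complete sampling day;
* ``missing_date`` — probability per subject of all date records missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

#: protocol clock times; None marks awakening-anchored or bedtime samples
PROTOCOL_TIMES = {"S4": 10.5, "S5": 12.0, "S6": 17.0}
#: offsets from awakening for the morning samples, hours
MORNING_OFFSETS = {"S1": 0.0, "S2": 0.25, "S3": 0.5}


def _default_fixed_effects() -> dict:
    # final diurnal-model coefficients on the ln(ug/L + 1) scale
    return {
        "intercept": 1.297,
        "time": -0.165,
        "time2": 0.006,
        "stage[mid]": 0.096,
        "stage[late]": 0.146,
        "awakening": -0.059,
        "season[winter]": 0.02,
        "time:stage[mid]": -0.0005,
        "time:stage[late]": 0.006,
        "time:awakening": 0.005,
        "stage[mid]:season[winter]": -0.01,
        "stage[late]:season[winter]": 0.072,
        "stage[mid]:awakening": -0.003,
        "stage[late]:awakening": 0.014,
        "time:stage[mid]:awakening": 0.0001,
        "time:stage[late]:awakening": -0.004,
    }


def _default_attendance() -> dict:
    # chosen to match the observed stage sizes (~60% early, ~79% mid, ~73%
    # late) and the 1/2/3-stage participation split of the cohort
    return {
        "early,mid,late": 0.384,
        "early,mid": 0.117,
        "early,late": 0.049,
        "mid,late": 0.189,
        "early": 0.053,
        "mid": 0.100,
        "late": 0.108,
    }


def _default_covariate_model() -> dict:
    return {
        "bmi_mean": 23.82,
        "bmi_sd": 3.93,
        "age_mean": 34.63,
        "age_sd": 4.82,
        "p_hypertensive": 0.052,
        "p_gdm": 0.208,
        "p_smoking": 0.06,
        "p_primiparous": 0.51,
        "p_education": {"secondary": 0.19, "lower tertiary": 0.27, "upper tertiary": 0.54},
        "p_chromosomal_testing": 0.44,
        "p_mental_disorder": 0.12,
        "p_corticosteroid": 0.022,
    }


def _default_violation_rates() -> dict:
    # per-day / per-sample / per-subject rates reproducing the study's
    # published per-sample QC removal fractions
    return {
        "rise_before_S1": 0.076,
        "illness": 0.009,
        "s2s3_late": 0.007,
        "s4_early": 0.012,
        "missing_time": 0.002,
        "high_cv": 0.016,
        "duplicate_day": 0.017,
        "missing_date": 0.009,
    }


@dataclass
class SimConfig:
    """Generative configuration; all variances are on the ln(ug/L + 1) scale."""

    n_subjects: int = 600
    seed: int = 0
    stage_attendance: dict = field(default_factory=_default_attendance)
    awakening_mean: float = 7.3
    awakening_sd: float = 1.15
    bedtime_mean: float = 23.1
    bedtime_sd: float = 1.1
    fixed_effects: dict = field(default_factory=_default_fixed_effects)
    var_plate: float = 0.001
    var_person: float = 0.048
    var_slope: float = 0.008
    # intercept-slope correlation -0.75 expressed as a covariance
    cov_int_slope: float = -0.75 * float(np.sqrt(0.048 * 0.008))
    var_stage: float = 0.019
    var_residual: float = 0.189
    ar_phi: float = 0.4
    occasion_sd_multipliers: tuple = (1.0,) * 7
    car_amplitude: float = 0.25
    car_absent_frac: float = 0.64
    covariate_model: dict = field(default_factory=_default_covariate_model)
    violation_rates: dict = field(default_factory=_default_violation_rates)
    n_plates: int | None = None  # None: 96-well plates in accession order
    duplicate_cv: float = 0.05

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("var_plate", "var_person", "var_slope", "var_stage", "var_residual"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative variance, got {v}")
        if not (0.0 < self.ar_phi < 1.0):
            raise ValueError(f"ar_phi must lie strictly in (0, 1), got {self.ar_phi}")
        if self.var_person > 0 and self.var_slope > 0:
            r = self.cov_int_slope / np.sqrt(self.var_person * self.var_slope)
            if abs(r) > 1:
                raise ValueError("cov_int_slope implies |correlation| > 1")
        elif self.cov_int_slope != 0:
            raise ValueError("cov_int_slope requires positive intercept and slope variances")
        if len(self.occasion_sd_multipliers) != 7 or any(
            m <= 0 for m in self.occasion_sd_multipliers
        ):
            raise ValueError("occasion_sd_multipliers must be 7 positive scalars")
        for key, p in self.violation_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"violation rate {key} outside [0, 1]")
        if not (0.0 <= self.car_absent_frac <= 1.0):
            raise ValueError("car_absent_frac must be a probability")
        tot = sum(self.stage_attendance.values())
        if tot <= 0:
            raise ValueError("stage attendance probabilities must sum to > 0")
        if any(p < 0 for p in self.stage_attendance.values()):
            raise ValueError("stage attendance probabilities must be non-negative")
        if any(not pat for pat in self.stage_attendance):
            raise ValueError("every attendance pattern needs at least one stage")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occasion_sd_multipliers"] = list(self.occasion_sd_multipliers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "occasion_sd_multipliers" in d:
            d["occasion_sd_multipliers"] = tuple(d["occasion_sd_multipliers"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **kw) -> "SimConfig":
        d = self.to_dict()
        d.update(kw)
        return SimConfig.from_dict(d)
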