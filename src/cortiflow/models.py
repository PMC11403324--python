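"""Morning (CAR) and diurnal-slope model construction, structure selection,
timing-covariate pruning, variance-decomposition ICCs and effect sizes.

The morning model uses the awakening samples S1-S3 from every pregnancy
stage; the diurnal model runs from the morning peak (the maximum of S1-S3)
to bedtime.  Both share the random-effects skeleton (assay-plate, person
and person-by-stage intercepts) and are refined along a fixed ladder:
random slope for time, then continuous AR(1) residuals, then heterogeneous
continuous AR(1).  A rung is kept only when it lowers the AIC and the
nested likelihood-ratio test rejects at P < .05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cortiflow.indices import MORNING
from cortiflow.lmm import MixedLMM, ModelSpec, compare

MORNING_TERMS = ["time", "time2", "stage", "awakening", "season", "time:stage"]
DIURNAL_TERMS = [
    "time", "time2", "stage", "awakening", "season", "time:stage",
    "time:awakening", "stage:season", "stage:awakening", "time:stage:awakening",
]

#: timing-covariate families, pruned highest-order first
TIMING_FAMILIES = [
    "time:stage:awakening",
    "stage:awakening",
    "stage:season",
    "time:awakening",
    "season",
    "awakening",
]


def make_morning_spec() -> ModelSpec:
    """Morning (CAR) model: S1-S3 rows, full timing-covariate candidate set."""
    return ModelSpec(
        response="log_conc",
        fixed_terms=list(MORNING_TERMS),
        random_plate=True,
        random_person=True,
        random_slope=False,
        random_stage=True,
        residual="independent",
    )


def make_diurnal_spec() -> ModelSpec:
    """Diurnal-slope model: morning peak to S7, Table-style fixed effects."""
    return ModelSpec(
        response="log_conc",
        fixed_terms=list(DIURNAL_TERMS),
        random_plate=True,
        random_person=True,
        random_slope=False,
        random_stage=True,
        residual="independent",
    )


def morning_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the morning model: occasions S1-S3."""
    return table[table["occasion"].isin(MORNING)].copy()


def diurnal_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows from the morning peak (max of S1-S3) to bedtime, per person-stage."""
    keep = []
    for (_, _), grp in table.groupby(["subject_id", "stage"], sort=False):
        grp = grp.sort_values("time")
        m = grp[grp["occasion"].isin(MORNING)]
        if len(m):
            peak_time = m.loc[m["log_conc"].idxmax(), "time"]
        else:
            peak_time = grp["time"].iloc[0]
        keep.append(grp[grp["time"] >= peak_time - 1e-12])
    return pd.concat(keep, ignore_index=True)


# -- covariance-structure ladder ---------------------------------------------

LADDER = (
    ("random intercepts", {"random_slope": False, "residual": "independent"}),
    ("+ random slope", {"random_slope": True, "residual": "independent"}),
    ("+ continuous AR(1)", {"random_slope": True, "residual": "car1"}),
    ("+ heterogeneous AR(1)", {"random_slope": True, "residual": "heterogeneous_car1"}),
)


def select_structure(spec: ModelSpec, table: pd.DataFrame, alpha: float = 0.05):
    """Climb the covariance ladder by REML AIC + nested LRT at P < alpha.

    Returns (best fitted results, trace).  The trace records the AIC of
    every attempted rung and why each was kept or rejected.
    """
    trace = []
    best_fit = None
    best_name = None
    for name, overrides in LADDER:
        rung_spec = spec.replace(estimation="REML", **overrides)
        entry = {"rung": name, "spec": overrides}
        try:
            fit = MixedLMM.from_dataframe(table, rung_spec).fit()
        except Exception as exc:  # non-convergent rung: skip with warning
            entry["status"] = f"skipped: {exc}"
            trace.append(entry)
            continue
        entry["aic"] = fit.aic
        entry["loglik"] = fit.llf
        if best_fit is None:
            entry["status"] = "baseline"
            best_fit, best_name = fit, name
        else:
            cmp = compare(best_fit, fit, nested=True)
            entry["delta_aic"] = cmp["delta_aic"]
            entry["lr_pvalue"] = cmp["lr_pvalue"]
            if cmp["delta_aic"] < 0 and cmp["lr_pvalue"] < alpha:
                entry["status"] = "kept"
                best_fit, best_name = fit, name
            else:
                entry["status"] = "rejected"
        trace.append(entry)
    return best_fit, {"selected": best_name, "rungs": trace}


def prune_timing_covariates(
    spec: ModelSpec, table: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelSpec, list]:
    """Drop timing-covariate families not supported by an ML chi-square test.

    Families are tested highest-order first; a family is retained if it is
    part of a retained higher-order interaction (marginality) or if removing
    it significantly worsens the ML likelihood (LRT P < alpha).
    """
    terms = list(spec.fixed_terms)
    trace = []
    for fam in TIMING_FAMILIES:
        if fam not in terms:
            continue
        fam_set = set(fam.split(":"))
        protected = any(
            fam_set < set(t.split(":")) for t in terms if t != fam
        )
        if protected:
            trace.append({"family": fam, "status": "kept (marginality)"})
            continue
        full = spec.replace(fixed_terms=terms, estimation="ML")
        reduced = spec.replace(
            fixed_terms=[t for t in terms if t != fam], estimation="ML"
        )
        fit_full = MixedLMM.from_dataframe(table, full).fit()
        fit_red = MixedLMM.from_dataframe(table, reduced).fit()
        cmp = compare(fit_red, fit_full, nested=True)
        if cmp["lr_pvalue"] < alpha:
            trace.append({"family": fam, "status": "kept", "p": cmp["lr_pvalue"]})
        else:
            terms.remove(fam)
            trace.append({"family": fam, "status": "dropped", "p": cmp["lr_pvalue"]})
    return spec.replace(fixed_terms=terms), trace


# -- ICC and effect sizes ------------------------------------------------------


@dataclass
class ICCResult:
    icc_throughout: float
    icc_within_stage: float
    formula_id: str = "person_over_person_slope_stage_residual"

    def __post_init__(self):
        if not (0 <= self.icc_throughout <= self.icc_within_stage <= 1):
            raise ValueError("ICC ordering violated")


def icc_from_components(vc: dict, scope: str = "both") -> ICCResult:
    """Stability ICCs from the mixed-model variance decomposition.

    icc_throughout = var_person / (var_person + var_slope + var_stage +
    var_residual); icc_within_stage additionally credits the slope and
    person-stage components to the person.  The assay-plate variance is a
    batch artefact and excluded from both.
    """
    vp = float(vc.get("var_person", 0.0))
    vs = float(vc.get("var_slope", 0.0))
    vd = float(vc.get("var_stage", 0.0))
    ve = float(vc.get("var_residual", 0.0))
    denom = vp + vs + vd + ve
    if denom <= 0:
        raise ValueError("ICC undefined: zero total variance")
    return ICCResult(
        icc_throughout=vp / denom,
        icc_within_stage=(vp + vs + vd) / denom,
    )


@dataclass
class EffectSize:
    """A log-scale coefficient and its interpretation as a percent change."""

    coefficient: float
    percent_change: float

    def __post_init__(self):
        if self.percent_change <= -100:
            raise ValueError("percent change must exceed -100")


def _round_half_away(x: float, ndigits: int = 1) -> float:
    q = 10.0**ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def percent_change(b: float) -> EffectSize:
    """(exp(b) - 1) * 100, rounded half-away-from-zero to one decimal."""
    if not np.isfinite(b):
        raise ValueError("coefficient must be finite")
    pc = (math.exp(b) - 1.0) * 100.0
    return EffectSize(coefficient=b, percent_change=_round_half_away(pc, 1))
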