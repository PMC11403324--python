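"""Cardiometabolic-complication testing on the cortisol mixed models.

Each exposure (prepregnancy BMI, hypertensive pregnancy disorders, GDM) is
tested in a separate model via three nested augmentations of the final
morning or diurnal model: (1) a between-person main effect, (2) its
interaction with the within-person time slope (the CAR or diurnal slope),
and (3) the 3-way interaction with time and pregnancy stage.  Lower-order
terms implied by an interaction are always included.  The procedure can be
repeated with the full covariate adjustment set, and followed up by
stratifying on BMI >= 25 vs < 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cortiflow.design import _BINARY, _CENTERED
from cortiflow.lmm import MixedLMM, ModelSpec
from cortiflow.models import (
    MORNING_TERMS,
    DIURNAL_TERMS,
    morning_rows,
    diurnal_rows,
    percent_change,
)

EXPOSURES = ("bmi", "hypertensive", "gdm")
ADJUSTMENT_SET = [
    "chromosomal_testing", "age", "parity", "smoking", "mental_disorder", "education",
]

#: final covariance structures of the two models
FINAL_STRUCTURE = {
    "morning": {"random_slope": True, "residual": "car1"},
    "diurnal": {"random_slope": True, "residual": "heterogeneous_car1"},
}

_STEPS = (
    ("main", ["{e}"]),
    ("x_time", ["{e}", "{e}:time"]),
    ("x_time_x_stage", ["{e}", "{e}:time", "{e}:stage", "{e}:time:stage"]),
)


def _exposure_label(exposure: str) -> str:
    if exposure == "bmi":
        return _CENTERED["bmi"][1]
    return _BINARY[exposure][1]


@dataclass
class ComplicationResult:
    exposure: str
    model: str
    adjusted: bool
    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)


def _base_terms(model: str, adjusted: bool) -> list[str]:
    terms = list(MORNING_TERMS if model == "morning" else DIURNAL_TERMS)
    if adjusted:
        terms += ADJUSTMENT_SET
    return terms


def _model_rows(model: str, table: pd.DataFrame) -> pd.DataFrame:
    return morning_rows(table) if model == "morning" else diurnal_rows(table)


def test_complication(
    exposure: str,
    model: str,
    table: pd.DataFrame,
    adjusted: bool = False,
    structure: dict | None = None,
    alpha: float = 0.05,
) -> ComplicationResult:
    """Run the 3-step testing procedure for one exposure on one model.

    ``table`` is the full analysis table; rows are restricted to the
    morning (S1-S3) or diurnal (peak-S7) window here.  ``structure``
    overrides the final covariance structure (e.g. for small studies).
    """
    if exposure not in EXPOSURES:
        raise ValueError(f"exposure must be one of {EXPOSURES}")
    if model not in ("morning", "diurnal"):
        raise ValueError("model must be 'morning' or 'diurnal'")
    col = "bmi" if exposure == "bmi" else _BINARY[exposure][0]
    if table[col].nunique() <= 1:
        raise ValueError(f"exposure {exposure} has no variation in the data")

    rows = _model_rows(model, table)
    struct = structure if structure is not None else FINAL_STRUCTURE[model]
    base = _base_terms(model, adjusted)
    label = _exposure_label(exposure)

    out_rows = []
    fits = {}
    for step, extra in _STEPS:
        terms = base + [t.format(e=exposure) for t in extra]
        spec = ModelSpec(fixed_terms=terms, estimation="REML", **struct)
        res = MixedLMM.from_dataframe(rows, spec).fit()
        fits[step] = res
        new = [t.format(e=exposure) for t in extra]
        highest = new[-1]
        fe = res.fe_table()
        mask = fe["Predictor"].str.startswith(label) if highest == exposure else (
            fe["Predictor"].str.startswith(label)
            & (fe["Predictor"].str.count("×") == highest.count(":"))
        )
        for _, r in fe[mask].iterrows():
            rec = dict(r)
            rec["step"] = step
            rec["percent_change"] = (
                percent_change(r["b"]).percent_change if r["P"] < alpha else None
            )
            out_rows.append(rec)
    tab = pd.DataFrame(out_rows)[["step", "Predictor", "b", "SE", "t", "P", "percent_change"]]
    return ComplicationResult(
        exposure=exposure, model=model, adjusted=adjusted, table=tab, fits=fits
    )


def stratify_bmi(
    rows: pd.DataFrame,
    spec: ModelSpec,
    cutoff: float = 25.0,
) -> dict:
    """Refit one model within the BMI >= cutoff and BMI < cutoff strata.

    ``rows`` must already be restricted to the model window (morning or
    diurnal).  BMI exactly at the cutoff falls in the high stratum.
    """
    out = {}
    for name, mask in (
        ("high", rows["bmi"] >= cutoff),
        ("low", rows["bmi"] < cutoff),
    ):
        sub = rows[mask]
        if sub["subject_id"].nunique() < 2:
            raise ValueError(f"BMI stratum '{name}' has fewer than 2 subjects")
        out[name] = MixedLMM.from_dataframe(sub, spec).fit()
    return out
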