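"""Per-person-stage cortisol summary indices and stage descriptives.

AUCg is the trapezoidal area under the log-concentration curve with respect
to ground over the sampled day; AUCi is the morning (S1-S3) area with
respect to the increase from the awakening sample, so AUCi <= 0 marks an
absent (declining) cortisol awakening response.  Both use the actual
per-day sampling times in hours; bedtimes past midnight are stored as
clock hours > 24 so times stay monotone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MORNING = ["S1", "S2", "S3"]
OCCASIONS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]


def auc_ground(times, values) -> float:
    """Trapezoidal area under the curve with respect to ground."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if len(t) < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            "times must be strictly increasing (bedtime past midnight should "
            "be coded as clock hours > 24)"
        )
    return float(np.trapezoid(v, t))


def auc_increase(times, values) -> float:
    """Morning area relative to the first (awakening) sample."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if len(t) < 2:
        raise ValueError("AUCi needs S1 plus at least one later morning sample")
    return auc_ground(t, v) - float(v[0]) * float(t[-1] - t[0])


def morning_peak(occasions, times, values) -> tuple[float, float]:
    """Maximum log value among available S1-S3 and its time; ties -> earliest."""
    rows = [
        (t, v) for o, t, v in zip(occasions, times, values) if o in MORNING
    ]
    if not rows:
        raise ValueError("no morning samples available")
    rows.sort(key=lambda r: r[0])
    best = max(rows, key=lambda r: r[1])  # max is stable: earliest tie wins
    return best[1], best[0]


def compute_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Per person-stage AUCg, AUCi, CAR-presence and morning peak.

    AUCg is reported for complete 7-occasion days, AUCi for complete
    S1-S3 mornings ("complete cases"); partially observed quantities are
    still computed when the defining samples are available but flagged
    incomplete.
    """
    out = []
    for (sid, stage), grp in table.groupby(["subject_id", "stage"], sort=False):
        grp = grp.sort_values("time")
        occ = list(grp["occasion"])
        t = grp["time"].to_numpy(float)
        v = grp["log_conc"].to_numpy(float)
        rec = {
            "subject_id": sid,
            "stage": stage,
            "n_samples": len(grp),
            "auc_g": np.nan,
            "auc_i": np.nan,
            "car_present": np.nan,
            "complete_g": len(grp) == 7,
            "complete_i": all(o in occ for o in MORNING),
            "morning_peak_value": np.nan,
            "morning_peak_time": np.nan,
        }
        if len(grp) >= 2:
            rec["auc_g"] = auc_ground(t, v)
        m = grp[grp["occasion"].isin(MORNING)]
        if "S1" in occ and len(m) >= 2:
            rec["auc_i"] = auc_increase(m["time"].to_numpy(), m["log_conc"].to_numpy())
            rec["car_present"] = bool(rec["auc_i"] > 0)
        if len(m) >= 1:
            rec["morning_peak_value"], rec["morning_peak_time"] = morning_peak(
                m["occasion"], m["time"], m["log_conc"]
            )
        out.append(rec)
    return pd.DataFrame(out)


def _cross_stage_icc(values: pd.DataFrame) -> float:
    """Two-way consistency, single-rater ICC across the three stages.

    values: rows = subjects with all stages, columns = stages.
    """
    if len(values) < 2 or values.shape[1] < 2:
        return np.nan
    import pingouin as pg

    long = values.reset_index().melt(
        id_vars="subject_id", var_name="stage", value_name="v"
    )
    icc = pg.intraclass_corr(
        data=long, targets="subject_id", raters="stage", ratings="v"
    )
    # consistency, single rater: labelled ICC3 or ICC(C,1) depending on version
    sel = icc["Type"].isin(["ICC3", "ICC(C,1)"])
    return float(icc.loc[sel, "ICC"].iloc[0])


def stage_descriptives(table: pd.DataFrame, indices: pd.DataFrame) -> dict:
    """Occasion-level and index-level descriptive tables by pregnancy stage."""
    occ_rows = []
    for (stage, occ), grp in table.groupby(["stage", "occasion"]):
        occ_rows.append(
            {
                "stage": stage,
                "occasion": occ,
                "n": len(grp),
                "raw_mean": float(grp["value"].mean()) if "value" in grp else np.nan,
                "raw_sd": float(grp["value"].std()) if "value" in grp else np.nan,
                "log_mean": float(grp["log_conc"].mean()),
                "log_sd": float(grp["log_conc"].std()),
                "clock_mean": float(grp["clock_time"].mean()),
                "clock_sd": float(grp["clock_time"].std()),
            }
        )
    occasion_table = pd.DataFrame(occ_rows)

    idx_rows = []
    for stage, grp in indices.groupby("stage"):
        gi = grp[grp["complete_i"] & grp["auc_i"].notna()]
        gg = grp[grp["complete_g"] & grp["auc_g"].notna()]
        idx_rows.append(
            {
                "stage": stage,
                "n_person_stages": len(grp),
                "auc_i_mean": float(gi["auc_i"].mean()) if len(gi) else np.nan,
                "auc_i_sd": float(gi["auc_i"].std()) if len(gi) else np.nan,
                "auc_g_mean": float(gg["auc_g"].mean()) if len(gg) else np.nan,
                "auc_g_sd": float(gg["auc_g"].std()) if len(gg) else np.nan,
                "n_car_absent": int((gi["auc_i"] <= 0).sum()),
                "frac_car_absent": float((gi["auc_i"] <= 0).mean()) if len(gi) else np.nan,
            }
        )
    index_table = pd.DataFrame(idx_rows)

    stages_per_subject = indices.groupby("subject_id")["stage"].nunique()
    participation = stages_per_subject.value_counts().sort_index().to_dict()

    iccs = {}
    n_stages = indices["stage"].nunique()
    for col in ("auc_i", "auc_g"):
        wide = indices.pivot_table(
            index="subject_id", columns="stage", values=col
        ).dropna()
        iccs[col] = _cross_stage_icc(wide) if n_stages > 1 and len(wide) >= 2 else np.nan

    return {
        "occasions": occasion_table,
        "indices": index_table,
        "participation": participation,
        "cross_stage_icc": iccs,
    }
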