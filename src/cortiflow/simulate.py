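"""Synthetic three-stage pregnancy saliva cohorts with planted QC violations.

The generator draws, on the ln(ug/L + 1) scale,

    y = fixed-effect mean + CAR bump + b0_person + b1_person * t
        + d_person_stage + plate effect + eps_day(t)

with day residual vectors eps correlated as phi ** |dt hours| (optionally
rescaled per occasion), then inverts the transform to raw ug/L and measures
every sample in duplicate with multiplicative lognormal assay error.
Protocol violations (rising before S1, illness days, late S2/S3, early S4,
missing times, discordant duplicates, duplicate assessment days, missing
dates, corticosteroid use) are planted at configured rates and recorded in
an exact truth ledger so the QC pipeline can be audited sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cortiflow.config import SimConfig, MORNING_OFFSETS, PROTOCOL_TIMES

OCCASIONS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]
STAGES = ["early", "mid", "late"]

#: samples removed by each QC rule when it fires on one planted event
_RULE_SCOPE = {
    "rise_before_S1": "one_sample",
    "s2s3_late": "one_sample",
    "s4_early": "one_sample",
    "high_cv": "one_sample",
    "illness": "whole_day",
    "duplicate_day": "whole_day",
    "missing_date": "whole_subject",
    "corticosteroid": "whole_subject",
}


@dataclass
class SyntheticCohort:
    """samples/subjects in the long-format CSV schema plus an exact truth ledger."""

    samples: pd.DataFrame
    subjects: pd.DataFrame
    truth: dict

    def planted_counts(self) -> dict:
        """Planted sample-removal counts per QC rule."""
        return dict(self.truth["violation_sample_counts"])


def day_residual_cov(times_since_awakening, config: SimConfig, occasions=None) -> np.ndarray:
    """Residual covariance of one sampling day: sigma^2 m_i m_j phi^|dt|."""
    t = np.asarray(times_since_awakening, float)
    dt = np.abs(t[:, None] - t[None, :])
    cov = config.var_residual * np.power(config.ar_phi, dt)
    mult = np.asarray(config.occasion_sd_multipliers)
    if occasions is None:
        occasions = OCCASIONS[: len(t)]
    idx = np.array([OCCASIONS.index(o) for o in occasions])
    mm = mult[idx]
    return cov * mm[:, None] * mm[None, :]


def _mean_log(config: SimConfig, t, stage, awake_c, winter, subj=None):
    """Evaluate the generative fixed-effect mean at one sample."""
    vals = {
        "intercept": 1.0,
        "time": t,
        "time2": t * t,
        "stage[mid]": 1.0 if stage == "mid" else 0.0,
        "stage[late]": 1.0 if stage == "late" else 0.0,
        "awakening": awake_c,
        "season[winter]": 1.0 if winter else 0.0,
    }
    if subj is not None:  # optional between-person exposure effects
        vals["bmi"] = float(subj["bmi"]) - config.covariate_model["bmi_mean"]
        vals["gdm"] = float(subj["gdm"])
        vals["hypertensive"] = float(subj["hypertensive"])
    total = 0.0
    for term, coef in config.fixed_effects.items():
        prod = 1.0
        for f in term.split(":"):
            prod *= vals[f]
        total += coef * prod
    return total


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Normal truncated to [lo, hi] by resampling (bounds are generous)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size), x)
        bad = (x < lo) | (x > hi)
    return x


def _draw_subjects(config: SimConfig, rng) -> pd.DataFrame:
    cm = config.covariate_model
    n = config.n_subjects
    edu_levels = list(cm["p_education"])
    edu_p = np.array([cm["p_education"][k] for k in edu_levels], float)
    edu_p = edu_p / edu_p.sum()
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:05d}" for i in range(n)],
            "bmi": np.maximum(rng.normal(cm["bmi_mean"], cm["bmi_sd"], n), 15.0),
            "age": np.clip(rng.normal(cm["age_mean"], cm["age_sd"], n), 18, 50),
            "hypertensive": (rng.random(n) < cm["p_hypertensive"]).astype(int),
            "gdm": (rng.random(n) < cm["p_gdm"]).astype(int),
            "smoking": (rng.random(n) < cm["p_smoking"]).astype(int),
            "parity_primiparous": (rng.random(n) < cm["p_primiparous"]).astype(int),
            "education": rng.choice(edu_levels, n, p=edu_p),
            "chromosomal_testing": (rng.random(n) < cm["p_chromosomal_testing"]).astype(int),
            "mental_disorder": (rng.random(n) < cm["p_mental_disorder"]).astype(int),
            "corticosteroid": (rng.random(n) < cm["p_corticosteroid"]).astype(int),
        }
    )


def _day_times(config: SimConfig, rng, occasions):
    """Clock times for one day; monotone-repaired, protocol compliant."""
    awake = float(_truncnorm(rng, config.awakening_mean, config.awakening_sd, 4.0, 12.0))
    bed = float(_truncnorm(rng, config.bedtime_mean, config.bedtime_sd, 20.0, 27.0))
    times = {}
    for occ in occasions:
        if occ in MORNING_OFFSETS:
            times[occ] = awake + MORNING_OFFSETS[occ]
        elif occ in PROTOCOL_TIMES:
            times[occ] = PROTOCOL_TIMES[occ] + float(rng.normal(0.0, 0.15))
        else:  # S7 bedtime
            times[occ] = bed
    # repair: strictly increasing and S4 at least 1h03 after awakening
    if "S4" in times:
        times["S4"] = max(times["S4"], awake + 1.05)
    prev = None
    for occ in occasions:
        if prev is not None and times[occ] <= prev + 0.1:
            times[occ] = prev + 0.1
        prev = times[occ]
    return awake, bed, times


_DAY_RULES = ["rise_before_S1", "illness", "s2s3_late", "s4_early"]


def _generate(config: SimConfig, rng, plant: bool):
    """Core generator; returns (samples df, subjects df, truth dict)."""
    subjects = _draw_subjects(config, rng)
    vr = dict(config.violation_rates) if plant else {}
    n = config.n_subjects

    patterns = list(config.stage_attendance)
    pprob = np.array([config.stage_attendance[k] for k in patterns], float)
    pprob = pprob / pprob.sum()
    sub_patterns = rng.choice(patterns, n, p=pprob)

    cov_is = config.cov_int_slope
    G = np.array([[config.var_person, cov_is], [cov_is, config.var_slope]])
    if np.all(G == 0):
        b_person = np.zeros((n, 2))
    else:
        bL = np.linalg.cholesky(G + 1e-14 * np.eye(2))
        b_person = (bL @ rng.standard_normal((2, n))).T  # (n, 2)

    missing_date_subj = set()
    if vr.get("missing_date", 0) > 0:
        mask = rng.random(n) < vr["missing_date"]
        missing_date_subj = set(np.flatnonzero(mask))

    ledger: dict[str, list] = {r: [] for r in _RULE_SCOPE}
    ledger["missing_time"] = []
    for i in np.flatnonzero(subjects["corticosteroid"].to_numpy()):
        ledger["corticosteroid"].append({"subject_id": subjects["subject_id"][i]})
    for i in sorted(missing_date_subj):
        ledger["missing_date"].append({"subject_id": subjects["subject_id"][i]})

    day_rule_probs = np.array([vr.get(r, 0.0) for r in _DAY_RULES])

    records = []  # one per sample
    truth_rows = []
    d_effects = []  # per person-stage intercepts
    base_date = pd.Timestamp("2016-01-01")

    for i in range(n):
        sid = subjects["subject_id"][i]
        stages = sub_patterns[i].split(",")
        exempt = subjects["corticosteroid"][i] == 1 or i in missing_date_subj
        for stage in STAGES:
            if stage not in stages:
                continue
            d_stage = float(rng.normal(0.0, np.sqrt(config.var_stage)))
            d_effects.append({"subject_id": sid, "stage": stage, "d": d_stage})
            car_absent = bool(rng.random() < config.car_absent_frac)
            bump = (-1.0 if car_absent else 1.0) * config.car_amplitude

            extra_day = plant and not exempt and (
                rng.random() < vr.get("duplicate_day", 0.0)
            )
            day_defs = [(OCCASIONS, 0)]
            if extra_day:
                day_defs.append((OCCASIONS[:5], 3))  # less complete second day
                ledger["duplicate_day"].append(
                    {"subject_id": sid, "stage": stage, "n_samples": 5}
                )

            for day_no, (occasions, date_shift) in enumerate(day_defs):
                awake, bed, times = _day_times(config, rng, occasions)
                date = base_date + pd.Timedelta(days=int(rng.integers(0, 365)) + date_shift)
                winter = date.month >= 10 or date.month <= 3

                rose, ill = False, False
                day_rule = None
                if plant and not exempt and day_no == 0 and day_rule_probs.sum() > 0:
                    u = rng.random()
                    cum = np.cumsum(day_rule_probs)
                    k = int(np.searchsorted(cum, u))
                    if k < len(_DAY_RULES):
                        day_rule = _DAY_RULES[k]
                if day_rule == "rise_before_S1":
                    rose = True
                    ledger["rise_before_S1"].append({"subject_id": sid, "stage": stage})
                elif day_rule == "illness":
                    ill = True
                    ledger["illness"].append(
                        {"subject_id": sid, "stage": stage, "n_samples": len(occasions)}
                    )
                elif day_rule == "s2s3_late":
                    occ = "S2" if rng.random() < 0.5 else "S3"
                    times[occ] = awake + 65.0 / 60.0 + float(rng.random()) * 0.4
                    ledger["s2s3_late"].append(
                        {"subject_id": sid, "stage": stage, "occasion": occ}
                    )
                elif day_rule == "s4_early":
                    times["S4"] = awake + 50.0 / 60.0
                    ledger["s4_early"].append(
                        {"subject_id": sid, "stage": stage, "occasion": "S4"}
                    )
                # re-sort after planted time edits is NOT done: QC drops these rows

                tvec = np.array([times[o] - awake for o in occasions])
                if config.var_residual > 0:
                    cov = day_residual_cov(tvec, config, occasions)
                    eps = np.linalg.cholesky(
                        cov + 1e-12 * np.eye(len(tvec))
                    ) @ rng.standard_normal(len(tvec))
                else:
                    eps = np.zeros(len(tvec))

                clean_day = day_rule is None and day_no == 0 and plant and not exempt

                for j, occ in enumerate(occasions):
                    t = tvec[j]
                    mu = _mean_log(
                        config, t, stage, awake - config.awakening_mean, winter,
                        subj=subjects.iloc[i],
                    )
                    car = bump if occ in ("S2", "S3") else 0.0
                    log_true = (
                        mu
                        + car
                        + b_person[i, 0]
                        + b_person[i, 1] * t
                        + d_stage
                        + eps[j]
                    )
                    raw_true = max(np.expm1(log_true), 0.0)
                    records.append(
                        {
                            "subject_id": sid,
                            "stage": stage,
                            "occasion": occ,
                            "clock_time": times[occ],
                            "date": None if i in missing_date_subj else str(date.date()),
                            "awakening_time": awake,
                            "rose_before_S1": rose,
                            "ill_on_day": ill,
                            "raw_true": raw_true,
                            "_clean_day": clean_day,
                            "_subj_idx": i,
                        }
                    )
                    truth_rows.append(
                        {
                            "subject_id": sid,
                            "stage": stage,
                            "occasion": occ,
                            "day_no": day_no,
                            "log_true": log_true,
                            "mean_log": mu,
                            "car_bump": car,
                            "resid": eps[j],
                            "d_stage": d_stage,
                            "time": t,
                        }
                    )

    samples = pd.DataFrame(records)
    truth_samples = pd.DataFrame(truth_rows)

    # plates in accession order; plate effects enter the measured values
    n_samp = len(samples)
    if config.n_plates:
        per = int(np.ceil(n_samp / config.n_plates))
    else:
        per = 96
    plate_id = np.arange(n_samp) // per
    samples["plate_id"] = plate_id
    n_plates = int(plate_id.max()) + 1
    plate_eff = rng.normal(0.0, np.sqrt(config.var_plate), n_plates)
    log_meas = truth_samples["log_true"].to_numpy() + plate_eff[plate_id]
    raw_meas = np.maximum(np.expm1(log_meas), 0.0)
    truth_samples["log_measured"] = log_meas
    truth_samples["plate_effect"] = plate_eff[plate_id]

    # duplicate aliquots with multiplicative lognormal assay error
    s_dup = config.duplicate_cv * np.sqrt(np.pi / 2.0)
    dup_err = rng.normal(0.0, s_dup, (n_samp, 2))
    samples["raw_dup1"] = raw_meas * np.exp(dup_err[:, 0])
    samples["raw_dup2"] = raw_meas * np.exp(dup_err[:, 1])

    # sample-level plants, restricted to violation-free days
    if plant:
        clean = samples["_clean_day"].to_numpy()
        awake_ok = samples["awakening_time"].to_numpy() <= 9.0
        if vr.get("missing_time", 0) > 0:
            cand = clean & awake_ok & (rng.random(n_samp) < vr["missing_time"])
            for k in np.flatnonzero(cand):
                samples.loc[k, "clock_time"] = np.nan
                ledger["missing_time"].append(
                    {
                        "subject_id": samples["subject_id"][k],
                        "stage": samples["stage"][k],
                        "occasion": samples["occasion"][k],
                    }
                )
        if vr.get("high_cv", 0) > 0:
            taken = samples["clock_time"].isna().to_numpy()
            # stay above the assay truncation floor so the discordance survives
            above_floor = samples["raw_dup1"].to_numpy() >= 0.06
            cand = clean & ~taken & above_floor & (rng.random(n_samp) < vr["high_cv"])
            for k in np.flatnonzero(cand):
                samples.loc[k, "raw_dup2"] = samples.loc[k, "raw_dup1"] * 2.2
                ledger["high_cv"].append(
                    {
                        "subject_id": samples["subject_id"][k],
                        "stage": samples["stage"][k],
                        "occasion": samples["occasion"][k],
                    }
                )

    samples = samples.drop(columns=["raw_true", "_clean_day", "_subj_idx"])

    # expected sample removals per rule, for exact ledger audits
    day_sizes = samples.groupby(["subject_id", "stage"]).size()
    counts = {}
    for rule, events in ledger.items():
        if rule == "missing_time":
            counts[rule] = len(events)
        elif _RULE_SCOPE.get(rule) == "one_sample":
            counts[rule] = len(events)
        elif rule in ("illness", "duplicate_day"):
            counts[rule] = int(sum(e["n_samples"] for e in events))
        else:  # whole_subject
            counts[rule] = int(
                sum(
                    (samples["subject_id"] == e["subject_id"]).sum() for e in events
                )
            )

    truth = {
        "config": config.to_dict(),
        "violations": ledger,
        "violation_sample_counts": counts,
        "random_effects": {
            "person": pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"],
                    "b_intercept": b_person[:, 0],
                    "b_slope": b_person[:, 1],
                }
            ),
            "person_stage": pd.DataFrame(d_effects),
            "plate": pd.DataFrame(
                {"plate_id": np.arange(n_plates), "effect": plate_eff}
            ),
        },
        "samples": truth_samples,
    }
    return samples, subjects, truth


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a raw cohort (duplicate aliquots, planted violations)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples, subjects, truth = _generate(config, rng, plant=True)
    return SyntheticCohort(samples=samples, subjects=subjects, truth=truth)


def simulate_analysis_table(config: SimConfig, seed: int | None = None):
    """Generate a QC-clean, log-scale analysis table directly.

    Bypasses the raw-concentration inverse transform and assay duplication,
    so the response is exactly Gaussian under the generative mixed model —
    the right input for estimator-recovery studies.  Returns (table, truth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples, subjects, truth = _generate(config, rng, plant=False)
    tab = samples.copy()
    tab["log_conc"] = truth["samples"]["log_measured"].to_numpy()
    tab["time"] = truth["samples"]["time"].to_numpy()
    month = pd.to_datetime(tab["date"]).dt.month
    tab["season"] = np.where((month >= 10) | (month <= 3), "winter", "summer")
    tab = tab.merge(subjects.drop(columns=["corticosteroid"]), on="subject_id")
    return tab, truth
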