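"""Multi-level quality control for serial salivary-cortisol protocols.

Rules run in a pinned order: corticosteroid and missing-date subject
exclusions, truncation of sub-assay-range values at 0.05 ug/L,
duplicate-assessment-day resolution, illness days, timing rules (rising
before S1; S2/S3 later than 60 min after awakening; S4 within the first
60 min), the duplicate-aliquot CV > 0.25 filter with averaging, missing-time
imputation (protocol times for S2-S6, stage-specific occasion medians for
S1/S7), the ln(x + 1) transform, per-stage +/-4 SD winsorization, and the
minimum-sample rules (>= 2 samples per pregnancy stage, >= 3 per subject).
Every removal is logged in a :class:`QCReport` whose counts must conserve
the sample total.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from cortiflow.config import MORNING_OFFSETS, PROTOCOL_TIMES

log = logging.getLogger(__name__)

TRUNCATION_LIMIT = 0.05  # ug/L, assay functional sensitivity
CV_LIMIT = 0.25
WINSOR_SD = 4.0
MORNING_WINDOW_H = 1.0  # S2/S3 must fall within, S4 outside, this window


class QCError(ValueError):
    pass


class QCReport:
    """Ordered per-rule accounting of removals and modifications."""

    def __init__(self, n_samples_in: int):
        self.n_samples_in = n_samples_in
        self.n_samples_out: int | None = None
        self.entries: list[dict] = []
        self.modifications: dict[str, int] = {}

    def add(self, rule: str, samples: int = 0, days: int = 0, subjects: int = 0):
        self.entries.append(
            {"rule": rule, "samples": int(samples), "days": int(days),
             "subjects": int(subjects)}
        )
        if samples or days or subjects:
            log.info("QC rule %s removed %d samples (%d days, %d subjects)",
                     rule, samples, days, subjects)

    def modify(self, what: str, count: int):
        self.modifications[what] = self.modifications.get(what, 0) + int(count)
        if count:
            log.info("QC modified %d samples (%s)", count, what)

    @property
    def removed_samples(self) -> dict:
        return {e["rule"]: e["samples"] for e in self.entries}

    def check_conservation(self) -> bool:
        removed = sum(e["samples"] for e in self.entries)
        return self.n_samples_in - removed == self.n_samples_out

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "rules": self.entries,
            "modifications": self.modifications,
            "conserved": self.check_conservation(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)

    def to_text(self) -> str:
        lines = [f"samples in: {self.n_samples_in}"]
        for e in self.entries:
            lines.append(
                f"  {e['rule']:<24} -{e['samples']:>5} samples"
                f" ({e['days']} days, {e['subjects']} subjects)"
            )
        for k, v in self.modifications.items():
            lines.append(f"  {k:<24} {v:>6} samples modified")
        lines.append(f"samples out: {self.n_samples_out}")
        return "\n".join(lines)


# -- elementary operations --------------------------------------------------


def truncate_low(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Floor raw concentrations at the assay limit; returns (values, n changed)."""
    v = np.asarray(values, float)
    if np.nanmin(v) < 0 if v.size else False:
        raise QCError("negative raw concentration")
    low = v < TRUNCATION_LIMIT
    low &= ~np.isnan(v)
    out = np.where(low, TRUNCATION_LIMIT, v)
    return out, int(low.sum())


def average_duplicates(dup1, dup2):
    """Vectorised duplicate handling: (value, cv, keep).

    cv is the two-point sample SD over the mean; samples with cv > 0.25 are
    flagged keep=False; singletons keep their lone aliquot with cv = NaN;
    samples with no aliquot get keep=False and value NaN.
    """
    d1 = np.asarray(dup1, float)
    d2 = np.asarray(dup2, float)
    both = ~np.isnan(d1) & ~np.isnan(d2)
    mean2 = (d1 + d2) / 2.0
    sd = np.abs(d1 - d2) / np.sqrt(2.0)
    cv = np.where(both & (mean2 > 0), sd / np.where(mean2 > 0, mean2, 1.0), np.nan)
    value = np.where(both, mean2, np.where(np.isnan(d1), d2, d1))
    keep = ~np.isnan(value) & ~(cv > CV_LIMIT)
    return value, cv, keep


def _day_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["subject_id"].astype(str)
        + "|" + df["stage"].astype(str)
        + "|" + df["date"].astype(str)
    )


def _protocol_time(row) -> float:
    occ = row["occasion"]
    if occ in MORNING_OFFSETS:
        return row["awakening_time"] + MORNING_OFFSETS[occ]
    if occ in PROTOCOL_TIMES:
        return PROTOCOL_TIMES[occ]
    return np.nan


def _timing_violations(day: pd.DataFrame) -> int:
    """Count protocol-adherence violations on one day (for day ranking)."""
    n = 0
    if day["rose_before_S1"].any():
        n += 1
    if day["ill_on_day"].any():
        n += 1
    rel = day["clock_time"] - day["awakening_time"]
    late = day["occasion"].isin(["S2", "S3"]) & (rel > MORNING_WINDOW_H)
    early = (day["occasion"] == "S4") & (rel < MORNING_WINDOW_H)
    n += int((late | early).fillna(False).sum())
    return n


def _day_outliers(day: pd.DataFrame) -> int:
    """Samples beyond 2 SD of the day-specific mean, on the log scale."""
    v = np.log1p(np.nanmean(day[["raw_dup1", "raw_dup2"]].to_numpy(), axis=1))
    v = v[~np.isnan(v)]
    if len(v) < 3:
        return 0
    sd = v.std(ddof=1)
    if sd == 0:
        return 0
    return int((np.abs(v - v.mean()) > 2 * sd).sum())


# -- pipeline stages ---------------------------------------------------------


def exclude_subjects(samples: pd.DataFrame, subjects: pd.DataFrame, report: QCReport):
    """Corticosteroid treatment and fully missing date records."""
    cort = set(subjects.loc[subjects.get("corticosteroid", 0) == 1, "subject_id"])
    drop = samples["subject_id"].isin(cort)
    report.add("corticosteroid", samples=drop.sum(),
               days=_day_key(samples[drop]).nunique(), subjects=len(cort & set(samples["subject_id"])))
    samples = samples[~drop]

    all_missing = samples.groupby("subject_id")["date"].apply(lambda s: s.isna().all())
    bad = set(all_missing[all_missing].index)
    drop = samples["subject_id"].isin(bad)
    report.add("missing_date", samples=drop.sum(),
               days=_day_key(samples[drop]).nunique(), subjects=len(bad))
    return samples[~drop]


def resolve_duplicate_days(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Keep one sampling day per subject-stage.

    Ranking: most non-missing samples, then fewest protocol violations, then
    fewest day-specific >2 SD outliers, then the earlier date.
    """
    samples = samples.reset_index(drop=True)  # tolerate duplicated indexes
    keep_idx = []
    removed = 0
    days_removed = 0
    for (_, _), grp in samples.groupby(["subject_id", "stage"], sort=False):
        dates = grp["date"].dropna().unique()
        if len(dates) <= 1:
            keep_idx.append(grp.index)
            continue
        scored = []
        for d in dates:
            day = grp[grp["date"] == d]
            n_ok = int(day[["raw_dup1", "raw_dup2"]].notna().any(axis=1).sum())
            scored.append((-n_ok, _timing_violations(day), _day_outliers(day), d))
        best = min(scored)[3]
        keep = grp["date"] == best
        keep_idx.append(grp.index[keep])
        removed += int((~keep).sum())
        days_removed += len(dates) - 1
    report.add("duplicate_day", samples=removed, days=days_removed)
    return samples.loc[np.concatenate([np.asarray(ix) for ix in keep_idx])]


def apply_day_and_sample_rules(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Illness days, rising before S1, late S2/S3, early S4."""
    samples = samples.copy()
    ill = samples["ill_on_day"].fillna(False).astype(bool)
    report.add("illness", samples=ill.sum(), days=_day_key(samples[ill]).nunique())
    samples = samples[~ill]

    rose = (samples["occasion"] == "S1") & samples["rose_before_S1"].fillna(False).astype(bool)
    report.add("rise_before_S1", samples=rose.sum())
    samples = samples[~rose]

    # rule-relevant samples missing a clock time are imputed per protocol
    # first and the rule applied to the imputed time
    needs = samples["occasion"].isin(["S2", "S3", "S4"]) & samples["clock_time"].isna()
    if needs.any():
        imput = samples[needs].apply(_protocol_time, axis=1)
        samples.loc[needs, "clock_time"] = imput
        samples.loc[needs, "_time_imputed"] = True
        report.modify("times_imputed", int(needs.sum()))

    rel = samples["clock_time"] - samples["awakening_time"]
    late = samples["occasion"].isin(["S2", "S3"]) & (rel > MORNING_WINDOW_H)
    late = late.fillna(False)
    report.add("s2s3_late", samples=late.sum())
    samples = samples[~late]

    rel = samples["clock_time"] - samples["awakening_time"]
    early = ((samples["occasion"] == "S4") & (rel < MORNING_WINDOW_H)).fillna(False)
    report.add("s4_early", samples=early.sum())
    return samples[~early]


def filter_cv_and_average(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Drop discordant duplicates (CV > 0.25), average the rest."""
    samples = samples.copy()
    value, cv, keep = average_duplicates(samples["raw_dup1"], samples["raw_dup2"])
    samples["value"] = value
    samples["cv"] = cv
    missing = np.isnan(value)
    report.add("missing_concentration", samples=missing.sum())
    high = ~keep & ~missing
    report.add("high_cv", samples=high.sum())
    return samples[keep]


def impute_times(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Protocol times for S2-S6; stage-specific occasion medians for S1/S7."""
    samples = samples.copy()
    miss = samples["clock_time"].isna()
    n_imputed = 0
    dropped_days = []
    for idx in samples.index[miss]:
        row = samples.loc[idx]
        occ = row["occasion"]
        if occ in ("S1", "S7"):
            pool = samples[
                (samples["stage"] == row["stage"])
                & (samples["occasion"] == occ)
                & samples["clock_time"].notna()
            ]["clock_time"]
            if len(pool) == 0:
                if occ == "S1":
                    dropped_days.append(_day_key(samples.loc[[idx]]).iloc[0])
                    continue
                raise QCError(f"no cohort median computable for {occ}")
            samples.loc[idx, "clock_time"] = float(pool.median())
        else:
            samples.loc[idx, "clock_time"] = _protocol_time(row)
        samples.loc[idx, "_time_imputed"] = True
        n_imputed += 1
    report.modify("times_imputed", n_imputed)
    if dropped_days:
        bad = _day_key(samples).isin(dropped_days)
        report.add("unimputable_day", samples=bad.sum(), days=len(dropped_days))
        samples = samples[~bad]
    else:
        report.add("unimputable_day")
    return samples


def transform_and_winsorize(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """ln(x + 1) transform then per-stage winsorization at +/-4 SD."""
    samples = samples.copy()
    samples["log_conc"] = np.log1p(samples["value"])
    n_wins = 0
    for stage, grp in samples.groupby("stage"):
        v = grp["log_conc"].to_numpy()
        if len(v) < 2:
            warnings.warn(f"stage {stage} has <2 values; winsorization skipped")
            continue
        mu, sd = v.mean(), v.std(ddof=1)
        lo, hi = mu - WINSOR_SD * sd, mu + WINSOR_SD * sd
        clipped = np.clip(v, lo, hi)
        n_wins += int((clipped != v).sum())
        samples.loc[grp.index, "log_conc"] = clipped
    report.modify("winsorized", n_wins)
    return samples


def enforce_minimums(samples: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """>= 2 samples per retained subject-stage, >= 3 per retained subject."""
    per_stage = samples.groupby(["subject_id", "stage"]).transform("size")
    thin = per_stage < 2
    report.add(
        "min_two_per_stage",
        samples=thin.sum(),
        days=_day_key(samples[thin]).nunique(),
    )
    samples = samples[~thin]
    per_subj = samples.groupby("subject_id")["subject_id"].transform("size")
    small = per_subj < 3
    report.add(
        "min_three_per_subject",
        samples=small.sum(),
        days=_day_key(samples[small]).nunique(),
        subjects=samples.loc[small, "subject_id"].nunique(),
    )
    return samples[~small]


def run_qc(
    samples: pd.DataFrame, subjects: pd.DataFrame
) -> tuple[pd.DataFrame, QCReport]:
    """Full pipeline: raw long table -> analysis table + QC report."""
    df = samples.copy()
    if "sample_uid" not in df.columns:
        df["sample_uid"] = np.arange(len(df))
    report = QCReport(len(df))

    df = exclude_subjects(df, subjects, report)

    for col in ("raw_dup1", "raw_dup2"):
        vals, _n = truncate_low(df[col].to_numpy())
        df[col] = vals
        report.modify("truncated_aliquots", _n)

    df = resolve_duplicate_days(df, report)
    df = apply_day_and_sample_rules(df, report)
    df = filter_cv_and_average(df, report)
    df = impute_times(df, report)
    df = transform_and_winsorize(df, report)
    df = enforce_minimums(df, report)

    out = _build_analysis_table(df, subjects)
    report.n_samples_out = len(out)
    if not report.check_conservation():
        raise QCError("QC ledger does not conserve the sample count")
    return out, report


def _build_analysis_table(df: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["time"] = out["clock_time"] - out["awakening_time"]
    # median-imputed S1 times may precede the diary awakening time; they are
    # floored at awakening, which a recorded time is not allowed to do
    imputed = out.get("_time_imputed")
    imputed = (
        imputed.eq(True) if imputed is not None else pd.Series(False, index=out.index)
    )
    if ((out["time"] < -1e-9) & ~imputed).any():
        raise QCError("negative time since awakening after QC")
    out["time"] = out["time"].clip(lower=0.0)
    month = pd.to_datetime(out["date"]).dt.month
    out["season"] = np.where((month >= 10) | (month <= 3), "winter", "summer")
    cov_cols = [c for c in subjects.columns if c != "corticosteroid"]
    out = out.merge(subjects[cov_cols], on="subject_id", how="left")
    keep = [
        "sample_uid", "subject_id", "stage", "occasion", "log_conc", "value",
        "time", "clock_time", "awakening_time", "date", "season", "plate_id",
    ] + [c for c in cov_cols if c != "subject_id"]
    out = out[keep].sort_values(["subject_id", "stage", "time"]).reset_index(drop=True)
    return out
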