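"""Quality-control rules: elementary operations, rule composition, ledger
conservation, exact agreement with the generator's planted-violation truth."""

import numpy as np
import pandas as pd
import pytest

from cortiflow import SimConfig, simulate_cohort, run_qc
from cortiflow.qc import (
    QCReport,
    apply_day_and_sample_rules,
    average_duplicates,
    enforce_minimums,
    exclude_subjects,
    impute_times,
    resolve_duplicate_days,
    transform_and_winsorize,
    truncate_low,
    QCError,
)

OCC = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]
CLOCK = [7.0, 7.25, 7.5, 10.5, 12.0, 17.0, 23.0]


def make_day(sid="A", stage="early", date="2016-05-01", occasions=None,
             awake=7.0, value=1.0, **overrides):
    occasions = occasions or OCC
    rows = []
    for o in occasions:
        c = CLOCK[OCC.index(o)] + (awake - 7.0 if o in ("S1", "S2", "S3") else 0.0)
        rows.append(
            dict(subject_id=sid, stage=stage, occasion=o, raw_dup1=value,
                 raw_dup2=value, clock_time=c, date=date, awakening_time=awake,
                 rose_before_S1=False, ill_on_day=False, plate_id=0)
        )
    df = pd.DataFrame(rows)
    for k, v in overrides.items():
        df[k] = v
    return df


def subjects_frame(ids, corticosteroid=()):
    return pd.DataFrame(
        {
            "subject_id": list(ids),
            "corticosteroid": [1 if s in corticosteroid else 0 for s in ids],
            "bmi": 24.0, "age": 33.0, "hypertensive": 0, "gdm": 0, "smoking": 0,
            "parity_primiparous": 0, "education": "secondary",
            "chromosomal_testing": 0, "mental_disorder": 0,
        }
    )


# -- elementary ops -----------------------------------------------------------


@pytest.mark.parametrize("raw,expected", [(0.03, 0.05), (0.05, 0.05), (1.20, 1.20)])
def test_truncation_at_assay_limit(raw, expected):
    vals, n = truncate_low(np.array([raw]))
    assert vals[0] == expected
    assert n == (1 if raw < 0.05 else 0)


def test_truncation_rejects_negative_concentration():
    with pytest.raises(QCError):
        truncate_low(np.array([-0.1]))


def test_duplicate_averaging_and_cv_filter():
    d1 = np.array([1.0, 1.0, 1.0, np.nan, np.nan])
    d2 = np.array([1.0, 2.0, 1.1, 2.0, np.nan])
    value, cv, keep = average_duplicates(d1, d2)
    assert value[0] == 1.0 and cv[0] == 0.0 and keep[0]
    assert cv[1] == pytest.approx(np.sqrt(0.5) / 1.5, abs=1e-4) and not keep[1]
    assert cv[2] == pytest.approx(0.0673, abs=1e-3) and keep[2]
    assert value[2] == pytest.approx(1.05)
    assert value[3] == 2.0 and np.isnan(cv[3]) and keep[3]  # singleton kept
    assert not keep[4]  # both aliquots absent -> dropped


# -- duplicate-day resolution -------------------------------------------------


def test_duplicate_day_keeps_most_complete():
    df = pd.concat(
        [
            make_day(date="2016-05-01"),
            make_day(date="2016-05-04", occasions=OCC[:5]),
        ]
    )
    rep = QCReport(len(df))
    out = resolve_duplicate_days(df, rep)
    assert set(out["date"]) == {"2016-05-01"}
    assert rep.removed_samples["duplicate_day"] == 5


def test_single_day_untouched():
    df = make_day()
    rep = QCReport(len(df))
    out = resolve_duplicate_days(df, rep)
    pd.testing.assert_frame_equal(out, df)


def test_duplicate_day_tie_breaks_to_earlier_date_total_order():
    # four equally complete days; one has a timing violation, one an outlier
    d1 = make_day(date="2016-05-09")                      # clean, earliest kept
    d2 = make_day(date="2016-05-11")                      # clean, later
    d3 = make_day(date="2016-05-03")                      # violation (ill)
    d3["ill_on_day"] = True
    d4 = make_day(date="2016-05-05")                      # day-specific outlier
    d4.loc[d4["occasion"] == "S5", ["raw_dup1", "raw_dup2"]] = 60.0
    days = [d1, d2, d3, d4]
    # the winner must not depend on input order (ranking is a total order)
    import itertools

    for perm in itertools.permutations(range(4)):
        df = pd.concat([days[k] for k in perm]).reset_index(drop=True)
        out = resolve_duplicate_days(df, QCReport(len(df)))
        assert set(out["date"]) == {"2016-05-09"}


# -- subject exclusions and timing rules -------------------------------------


def test_corticosteroid_and_missing_date_subjects_excluded():
    df = pd.concat(
        [make_day("A"), make_day("B"), make_day("C", date=np.nan)]
    ).reset_index(drop=True)
    subs = subjects_frame(["A", "B", "C"], corticosteroid={"B"})
    rep = QCReport(len(df))
    out = exclude_subjects(df, subs, rep)
    assert set(out["subject_id"]) == {"A"}
    assert rep.removed_samples["corticosteroid"] == 7
    assert rep.removed_samples["missing_date"] == 7


def test_timing_rules_remove_late_s2s3_and_early_s4():
    df = make_day()
    df.loc[df["occasion"] == "S3", "clock_time"] = 7.0 + 65 / 60  # 65 min late
    rep = QCReport(len(df))
    out = apply_day_and_sample_rules(df, rep)
    assert "S3" not in set(out["occasion"])
    assert rep.removed_samples["s2s3_late"] == 1

    df = make_day()
    df.loc[df["occasion"] == "S4", "clock_time"] = 7.0 + 50 / 60  # 50 min early
    rep = QCReport(len(df))
    out = apply_day_and_sample_rules(df, rep)
    assert "S4" not in set(out["occasion"])
    assert rep.removed_samples["s4_early"] == 1


def test_timing_rules_keep_exact_60_minute_boundary():
    df = make_day()
    df.loc[df["occasion"] == "S3", "clock_time"] = 8.0  # exactly +60 min
    df.loc[df["occasion"] == "S4", "clock_time"] = 8.0 + 1e-9
    rep = QCReport(len(df))
    out = apply_day_and_sample_rules(df, rep)
    assert len(out) == 7
    assert sum(rep.removed_samples.values()) == 0


def test_compliant_day_passes_unchanged_and_flags_remove():
    df = make_day()
    rep = QCReport(len(df))
    assert len(apply_day_and_sample_rules(df, rep)) == 7

    df = make_day(rose_before_S1=True)
    rep = QCReport(len(df))
    out = apply_day_and_sample_rules(df, rep)
    assert "S1" not in set(out["occasion"]) and len(out) == 6

    df = make_day(ill_on_day=True)
    rep = QCReport(len(df))
    assert len(apply_day_and_sample_rules(df, rep)) == 0


# -- time imputation ----------------------------------------------------------


def test_time_imputation_protocol_and_median():
    # three reference days establish stage medians for S1/S7
    ref = pd.concat(
        [make_day("R1"), make_day("R2"), make_day("R3")]
    )
    ref.loc[ref["occasion"] == "S7", "clock_time"] = [22.0, 23.0, 24.0]
    day = make_day("X")
    day.loc[day["occasion"].isin(["S2", "S4", "S7"]), "clock_time"] = np.nan
    df = pd.concat([ref, day]).reset_index(drop=True)
    rep = QCReport(len(df))
    out = impute_times(df, rep)
    x = out[out["subject_id"] == "X"].set_index("occasion")["clock_time"]
    assert x["S2"] == pytest.approx(7.25)   # awakening + 15 min
    assert x["S4"] == pytest.approx(10.5)   # protocol 10:30
    assert x["S7"] == pytest.approx(23.0)   # stage median
    assert rep.modifications["times_imputed"] == 3


# -- transform and winsorization ----------------------------------------------


def test_log_transform_and_winsorization_fence():
    rng = np.random.default_rng(0)
    vals = np.exp(rng.normal(0.8, 0.2, 40)) - 1  # log-scale sd ~ 0.2
    rows = []
    for i, v in enumerate(vals):
        rows.append(dict(subject_id=f"S{i}", stage="early", occasion="S1",
                         value=max(v, 0.0), clock_time=7.0, date="2016-05-01",
                         awakening_time=7.0, raw_dup1=v, raw_dup2=v,
                         rose_before_S1=False, ill_on_day=False, plate_id=0))
    df = pd.DataFrame(rows)
    logv = np.log1p(df["value"])
    mu, sd = logv.mean(), logv.std(ddof=1)
    outlier_log = mu + 6 * sd
    df.loc[0, "value"] = np.expm1(outlier_log)
    # fence must come from the pre-replacement distribution
    logv2 = np.log1p(df["value"])
    fence = logv2.mean() + 4 * logv2.std(ddof=1)
    rep = QCReport(len(df))
    out = transform_and_winsorize(df, rep)
    assert out.loc[0, "log_conc"] == pytest.approx(fence, abs=1e-12)
    assert rep.modifications["winsorized"] == 1
    # raw zero maps to log zero, values at the mean are untouched
    assert np.log1p(0.0) == 0.0
    untouched = out.loc[1:, "log_conc"].to_numpy()
    assert np.allclose(untouched, logv2[1:], atol=1e-12)


# -- minimum-sample rules ------------------------------------------------------


def test_minimum_sample_rules_compose():
    a = make_day("A")                                     # 7 samples, fine
    b = pd.concat([
        make_day("B", stage="early", occasions=["S1", "S2"]),
        make_day("B", stage="mid", occasions=["S1"]),     # stage dropped
    ])
    df = pd.concat([a, b]).reset_index(drop=True)
    df["value"] = 1.0
    rep = QCReport(len(df))
    out = enforce_minimums(df, rep)
    # B keeps one 2-sample stage -> 2 total < 3 -> subject dropped
    assert set(out["subject_id"]) == {"A"}
    assert rep.removed_samples["min_two_per_stage"] == 1
    assert rep.removed_samples["min_three_per_subject"] == 2

    rep = QCReport(len(a))
    a2 = a.copy()
    a2["value"] = 1.0
    assert len(enforce_minimums(a2, rep)) == 7  # compliant cohort: identity


# -- full pipeline -------------------------------------------------------------


def test_qc_ledger_matches_planted_truth_exactly(small_cohort):
    table, report = run_qc(small_cohort.samples, small_cohort.subjects)
    removed = report.removed_samples
    for rule, planted in small_cohort.planted_counts().items():
        if rule == "missing_time":
            assert report.modifications["times_imputed"] >= planted
        else:
            assert removed[rule] == planted, rule
    assert report.check_conservation()


def test_qc_is_idempotent(small_cohort):
    table1, report1 = run_qc(small_cohort.samples, small_cohort.subjects)
    surviving = small_cohort.samples.loc[table1["sample_uid"]].copy()
    surviving["sample_uid"] = table1["sample_uid"].to_numpy()
    table2, report2 = run_qc(surviving, small_cohort.subjects)
    assert sum(report2.removed_samples.values()) == 0
    t1 = table1.sort_values("sample_uid").reset_index(drop=True)
    t2 = table2.sort_values("sample_uid").reset_index(drop=True)
    pd.testing.assert_frame_equal(t1, t2)
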