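"""Mixed-model engine: closed-form reductions, dense brute-force oracle,
basis invariance, GLS profiling, optimizer diagnostics and model comparison."""

import numpy as np
import pandas as pd
import pytest

from cortiflow import SimConfig
from cortiflow.lmm import MixedLMM, ModelSpec, compare
from cortiflow.simulate import simulate_analysis_table
from cortiflow.models import make_morning_spec, morning_rows

LOG2PI = np.log(2 * np.pi)


def dense_reml_oracle(m: MixedLMM, vc: dict) -> float:
    """Brute-force -l_REML: assemble V entrywise, use explicit determinants."""
    n = m.n
    t, V = m.time, np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            v = 0.0
            if m.subject[i] == m.subject[j]:
                v += vc.get("var_person", 0.0)
                v += vc.get("cov_int_slope", 0.0) * (t[i] + t[j])
                v += vc.get("var_slope", 0.0) * t[i] * t[j]
                if m.stage_series[i] == m.stage_series[j]:
                    v += vc.get("var_stage", 0.0)
            if m.series[i] == m.series[j]:
                if m.spec.residual == "independent":
                    v += vc["var_residual"] * (i == j)
                else:
                    mm = 1.0
                    if m.spec.residual == "heterogeneous_car1":
                        mults = np.asarray(vc.get("occ_mult", np.ones(7)))
                        mm = mults[m.occ[i]] * mults[m.occ[j]]
                    v += vc["var_residual"] * mm * vc["ar_phi"] ** abs(t[i] - t[j])
            if m.spec.random_plate and m.plate[i] == m.plate[j]:
                v += vc.get("var_plate", 0.0)
            V[i, j] = v
    X, y = m.X, m.y
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    n_, p = X.shape
    return 0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(A)[1]
        - np.linalg.slogdet(X.T @ X)[1]
        + r @ Vi @ r
        + (n_ - p) * LOG2PI
    )


@pytest.fixture()
def messy_table():
    """<=50-row unbalanced fixture exercising every random component."""
    rng = np.random.default_rng(0)
    rows = []
    for s in range(5):
        for stg in ["early", "mid", "late"][: 2 + s % 2]:
            for i, occ in enumerate(["S1", "S2", "S3", "S4", "S5"][: 3 + s % 3]):
                tt = [0.0, 0.25, 0.5, 3.3, 4.9][i]
                rows.append(
                    dict(subject_id=s, stage=stg, occasion=occ, time=tt,
                         plate_id=(len(rows) // 9) % 3, date="d",
                         log_conc=rng.normal(1.2 - 0.1 * tt, 0.6),
                         awakening_time=7.0, season="summer")
                )
    return pd.DataFrame(rows)


FULL_VC = dict(
    var_plate=0.01, var_person=0.06, var_slope=0.02, cov_int_slope=-0.01,
    var_stage=0.05, var_residual=0.13, ar_phi=0.4,
    occ_mult=np.array([1, 1.1, 0.9, 1.2, 0.8, 1.05, 1.3]),
)


def test_reml_criterion_matches_dense_oracle(messy_table):
    for residual in ("independent", "car1", "heterogeneous_car1"):
        spec = ModelSpec(fixed_terms=["time", "time2", "stage"], random_plate=True,
                         random_person=True, random_slope=True, random_stage=True,
                         residual=residual)
        m = MixedLMM.from_dataframe(messy_table, spec)
        got = m.neg_restricted_loglik(FULL_VC)
        want = dense_reml_oracle(m, FULL_VC)
        assert got == pytest.approx(want, abs=1e-8)


def test_marginal_covariance_matches_dense_assembly(messy_table):
    spec = ModelSpec(fixed_terms=["time"], random_plate=True, random_person=True,
                     random_slope=True, random_stage=True,
                     residual="heterogeneous_car1")
    m = MixedLMM.from_dataframe(messy_table, spec)
    V = m.marginal_covariance(FULL_VC)
    t = m.time
    # spot-check entries independently of the engine's assembly
    for i, j in [(0, 0), (0, 1), (3, 9), (10, 30), (5, 5)]:
        v = 0.0
        if m.subject[i] == m.subject[j]:
            v += FULL_VC["var_person"]
            v += FULL_VC["cov_int_slope"] * (t[i] + t[j])
            v += FULL_VC["var_slope"] * t[i] * t[j]
            if m.stage_series[i] == m.stage_series[j]:
                v += FULL_VC["var_stage"]
        if m.series[i] == m.series[j]:
            mm = FULL_VC["occ_mult"][m.occ[i]] * FULL_VC["occ_mult"][m.occ[j]]
            v += FULL_VC["var_residual"] * mm * FULL_VC["ar_phi"] ** abs(t[i] - t[j])
        if m.plate[i] == m.plate[j]:
            v += FULL_VC["var_plate"]
        assert V[i, j] == pytest.approx(v, abs=1e-12)


def test_single_group_independent_reduces_to_gls_density():
    rng = np.random.default_rng(1)
    n = 12
    tab = pd.DataFrame(
        dict(subject_id=0, stage="early", occasion=["S1"] * n,
             time=np.linspace(0, 2, n), plate_id=0, date="d",
             log_conc=rng.normal(1.0, 0.5, n), awakening_time=7.0,
             season="summer")
    )
    spec = ModelSpec(fixed_terms=["time"], random_plate=False, random_person=False,
                     random_slope=False, random_stage=False, residual="independent")
    m = MixedLMM.from_dataframe(tab, spec)
    s2 = 0.3
    got = m.neg_restricted_loglik({"var_residual": s2})
    X, y = m.X, m.y
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(((y - X @ beta) ** 2).sum())
    p = X.shape[1]
    want = 0.5 * ((n - p) * (LOG2PI + np.log(s2)) + rss / s2)
    assert got == pytest.approx(want, abs=1e-10)


def test_car1_at_negligible_phi_equals_independent():
    rng = np.random.default_rng(2)
    rows = []
    for s in range(4):
        for i, tt in enumerate([0.0, 1.5, 3.0, 5.0]):  # gaps >= 1 h
            rows.append(dict(subject_id=s, stage="early", occasion=f"S{i+1}",
                             time=tt, plate_id=0, date="d",
                             log_conc=rng.normal(1.0, 0.4), awakening_time=7.0,
                             season="summer"))
    tab = pd.DataFrame(rows)
    base = dict(fixed_terms=["time"], random_plate=False, random_person=True,
                random_slope=False, random_stage=False)
    vc = {"var_person": 0.05, "var_residual": 0.2}
    m_ind = MixedLMM.from_dataframe(tab, ModelSpec(residual="independent", **base))
    m_ar = MixedLMM.from_dataframe(tab, ModelSpec(residual="car1", **base))
    got_ind = m_ind.neg_restricted_loglik(vc)
    got_ar = m_ar.neg_restricted_loglik({**vc, "ar_phi": 1e-10})
    assert got_ar == pytest.approx(got_ind, abs=1e-8)


def test_balanced_one_way_reml_equals_anova_closed_form():
    rng = np.random.default_rng(3)
    g, r = 6, 4
    y = rng.normal(2.0, 1.0, g * r) + np.repeat(rng.normal(0, 0.8, g), r)
    tab = pd.DataFrame(
        dict(subject_id=np.repeat(np.arange(g), r), stage="early",
             occasion="S1", log_conc=y, time=np.tile(np.arange(r) * 1.0, g),
             plate_id=0, date="d", awakening_time=7.0, season="summer")
    )
    spec = ModelSpec(fixed_terms=[], random_plate=False, random_person=True,
                     random_slope=False, random_stage=False,
                     residual="independent")
    res = MixedLMM.from_dataframe(tab, spec).fit()
    ybar = y.reshape(g, r).mean(axis=1)
    msb = r * ybar.var(ddof=1)
    msw = ((y.reshape(g, r) - ybar[:, None]) ** 2).sum() / (g * (r - 1))
    assert res.vc["var_residual"] == pytest.approx(msw, rel=1e-4)
    assert res.vc["var_person"] == pytest.approx((msb - msw) / r, rel=1e-4)


def test_zero_random_variance_matches_ols():
    rng = np.random.default_rng(4)
    n = 60
    tab = pd.DataFrame(
        dict(subject_id=np.arange(n), stage="early", occasion="S1",
             time=rng.uniform(0, 2, n), plate_id=0, date="d",
             awakening_time=7.0, season="summer")
    )
    tab["log_conc"] = 1.0 + 0.5 * tab["time"] + rng.normal(0, 0.3, n)
    spec = ModelSpec(fixed_terms=["time"], random_plate=False, random_person=True,
                     random_slope=False, random_stage=False,
                     residual="independent")
    res = MixedLMM.from_dataframe(tab, spec).fit()
    X = np.column_stack([np.ones(n), tab["time"]])
    beta = np.linalg.lstsq(X, tab["log_conc"], rcond=None)[0]
    s2 = float(((tab["log_conc"] - X @ beta) ** 2).sum()) / (n - 2)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    # each subject has one row, so the person variance is unidentified and the
    # GLS fit must collapse to OLS (design order: Intercept, Time)
    assert np.allclose(res.params.values, beta, atol=1e-3)
    assert np.allclose(res.bse.values, se, rtol=0.05)


def test_restricted_loglik_invariant_to_fixed_effect_basis(messy_table):
    spec = ModelSpec(fixed_terms=["time", "stage"], random_plate=False,
                     random_person=True, random_slope=False, random_stage=True,
                     residual="car1")
    m1 = MixedLMM.from_dataframe(messy_table, spec)
    T = np.array([[1, 0, 0, 0], [1, 1, 0, 0], [0, 2, 1, 0], [0, -1, 3, 1.0]])
    m2 = MixedLMM(
        m1.y, m1.X @ T, [f"c{i}" for i in range(4)], m1.subject, m1.series,
        m1.stage_series, m1.plate, m1.occ, m1.time, spec
    )
    vc = {"var_person": 0.05, "var_stage": 0.02, "var_residual": 0.2, "ar_phi": 0.4}
    assert m1.neg_restricted_loglik(vc) == pytest.approx(
        m2.neg_restricted_loglik(vc), abs=1e-8
    )


def test_profiled_beta_equals_gls_and_gradient_vanishes():
    tab, _ = simulate_analysis_table(SimConfig(n_subjects=40, seed=6, car_amplitude=0.0))
    rows = morning_rows(tab)
    spec = make_morning_spec().replace(random_slope=True, residual="car1")
    m = MixedLMM.from_dataframe(rows, spec)
    res = m.fit()
    assert res.grad_norm < 1e-4
    V = m.marginal_covariance(res.vc)
    Vi = np.linalg.inv(V)
    A = m.X.T @ Vi @ m.X
    beta = np.linalg.solve(A, m.X.T @ Vi @ m.y)
    assert np.allclose(res.params.values, beta, atol=1e-6)
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    assert np.allclose(res.bse.values, se, rtol=1e-4)


def test_compare_identical_models_keeps_simpler():
    tab, _ = simulate_analysis_table(SimConfig(n_subjects=25, seed=8))
    spec = ModelSpec(fixed_terms=["time"], random_plate=False, random_person=True,
                     random_slope=False, random_stage=False,
                     residual="independent")
    a = MixedLMM.from_dataframe(tab, spec).fit()
    b = MixedLMM.from_dataframe(tab, spec).fit()
    out = compare(a, b)
    assert out["delta_aic"] == pytest.approx(0.0, abs=1e-6)
    assert out["verdict"] == "keep simpler"


def test_lrt_detects_strong_autocorrelation():
    base = dict(fixed_terms=["time", "time2", "stage"], random_plate=False,
                random_person=True, random_slope=False, random_stage=True)
    hits = 0
    for seed in range(10):
        tab, _ = simulate_analysis_table(
            SimConfig(n_subjects=40, seed=500 + seed, ar_phi=0.9,
                      var_slope=0.0, cov_int_slope=0.0, car_amplitude=0.0)
        )
        a = MixedLMM.from_dataframe(tab, ModelSpec(residual="independent", **base)).fit()
        b = MixedLMM.from_dataframe(tab, ModelSpec(residual="car1", **base)).fit()
        hits += compare(a, b)["lr_pvalue"] < 0.05
    assert hits >= 9


def test_lrt_type_i_for_autocorrelation_is_controlled():
    base = dict(fixed_terms=["time", "stage"], random_plate=False,
                random_person=True, random_slope=False, random_stage=True)
    hits = 0
    n_seeds = 30
    for seed in range(n_seeds):
        tab, _ = simulate_analysis_table(
            SimConfig(n_subjects=25, seed=700 + seed, ar_phi=1e-12,
                      var_slope=0.0, cov_int_slope=0.0, car_amplitude=0.0)
        )
        a = MixedLMM.from_dataframe(tab, ModelSpec(residual="independent", **base)).fit()
        b = MixedLMM.from_dataframe(tab, ModelSpec(residual="car1", **base)).fit()
        hits += compare(a, b)["lr_pvalue"] < 0.05
    # 99% binomial envelope around the nominal 5% (boundary LRT is conservative)
    assert hits <= 7


def test_compare_rejects_mismatched_fits(messy_table):
    spec = ModelSpec(fixed_terms=["time"], random_plate=False, random_person=True,
                     random_slope=False, random_stage=False, residual="independent")
    a = MixedLMM.from_dataframe(messy_table, spec).fit()
    b = MixedLMM.from_dataframe(messy_table.iloc[:30], spec).fit()
    with pytest.raises(ValueError):
        compare(a, b)


def test_spec_validation_and_yaml_round_trip():
    with pytest.raises(ValueError):
        ModelSpec(random_slope=True, random_person=False)
    with pytest.raises(ValueError):
        ModelSpec(residual="toeplitz")
    spec = ModelSpec(fixed_terms=["time", "stage"], residual="car1")
    assert ModelSpec.from_yaml(spec.to_yaml()) == spec
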