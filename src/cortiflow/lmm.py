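"""Restricted-maximum-likelihood linear mixed models for serial saliva data.

The marginal model is

    y = X beta + Z_plate b + Z_person c0 + Z_person*t c1 + Z_stage d + eps

with a crossed assay-plate intercept, a person intercept, an optional
person-level random slope for time since awakening (with intercept-slope
covariance), a person-by-pregnancy-stage intercept, and residuals that are
independent, continuous AR(1), or heterogeneous continuous AR(1) within each
person-stage sampling day: corr(eps_i, eps_j) = phi ** |t_i - t_j| in hours,
optionally rescaled by occasion-specific SD multipliers (S1 fixed at 1).

Estimation profiles the residual variance and the fixed effects out of the
(restricted) likelihood and optimises the remaining variance parameters on a
log/atanh/logit scale with bounded quasi-Newton (L-BFGS-B).  The person-level
random effects and residual blocks make the marginal covariance block
diagonal by subject once the plate intercept is handled by a Woodbury
correction, so one likelihood evaluation costs O(sum_i k_i^3) with k_i <= 21
plus a plate-by-plate solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from cortiflow.design import build_design

OCCASIONS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]
_STAGE_ORDER = {"early": 0, "mid": 1, "late": 2}

LOG2PI = float(np.log(2.0 * np.pi))

_VAR_FLOOR = 1e-10  # boundary variance estimates are pinned here


class BoundaryWarning(UserWarning):
    """A variance component was estimated at the zero boundary."""


class ConvergenceError(RuntimeError):
    """Optimisation failed after all restarts; carries the best iterate."""

    def __init__(self, msg, best=None, grad_norm=None):
        super().__init__(msg)
        self.best = best
        self.grad_norm = grad_norm


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    fixed_terms are colon-product term strings (see cortiflow.design); an
    intercept is always included.  residual is one of "independent", "car1",
    "heterogeneous_car1".
    """

    response: str = "log_conc"
    fixed_terms: list[str] = field(default_factory=list)
    random_plate: bool = True
    random_person: bool = True
    random_slope: bool = False
    random_stage: bool = True
    residual: str = "independent"
    estimation: str = "REML"

    def __post_init__(self):
        if self.residual not in ("independent", "car1", "heterogeneous_car1"):
            raise ValueError(f"unknown residual structure {self.residual!r}")
        if self.random_slope and not self.random_person:
            raise ValueError("a person random slope requires the person intercept")
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be REML or ML")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **kw) -> "ModelSpec":
        d = self.to_dict()
        d.update(kw)
        return ModelSpec.from_dict(d)


class MixedLMM:
    """Linear mixed model for a long-format cortisol analysis table.

    Build with :meth:`from_dataframe`; call :meth:`fit` to obtain a
    :class:`MixedLMMResults`.
    """

    def __init__(self, y, X, names, subject, series, stage_series, plate, occ, time, spec):
        order = np.lexsort((time, stage_series, subject))
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        self.names = list(names)
        self.subject = np.asarray(subject)[order]
        self.series = np.asarray(series)[order]
        self.stage_series = np.asarray(stage_series)[order]
        self.plate = np.asarray(plate)[order]
        self.occ = np.asarray(occ)[order]
        self.time = np.asarray(time, float)[order]
        self.spec = spec
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError("need more observations than fixed-effect parameters")
        # the -log|X'X| term makes the restricted likelihood invariant to the
        # fixed-effects basis (Harville's formulation)
        self._logdet_xtx = float(np.linalg.slogdet(self.X.T @ self.X)[1])
        self._prepare_blocks()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec) -> "MixedLMM":
        X, names = build_design(table, spec.fixed_terms)
        y = table[spec.response].to_numpy(float)
        subject = pd.factorize(table["subject_id"])[0]
        stage_key = table["subject_id"].astype(str) + "|" + table["stage"].astype(str)
        stage_series = pd.factorize(stage_key)[0]
        if "date" in table.columns:
            ser_key = stage_key + "|" + table["date"].astype(str)
        else:
            ser_key = stage_key
        series = pd.factorize(ser_key)[0]
        if spec.random_plate:
            plate = pd.factorize(table["plate_id"])[0]
        else:
            plate = np.zeros(len(table), int)
        occ = table["occasion"].map({o: i for i, o in enumerate(OCCASIONS)}).to_numpy()
        if spec.residual == "heterogeneous_car1" and np.any(pd.isna(occ)):
            raise ValueError("heterogeneous_car1 requires S1..S7 occasion labels")
        occ = np.where(pd.isna(occ), 0, occ).astype(int)
        time = table["time"].to_numpy(float)
        return cls(y, X, names, subject, series, stage_series, plate, occ, time, spec)

    def _prepare_blocks(self):
        """Group rows by subject and batch subjects with equal block size."""
        self.n_subjects = int(self.subject.max()) + 1
        self.n_plates = int(self.plate.max()) + 1
        # rows are sorted by subject; find boundaries
        idx_split = np.flatnonzero(np.diff(self.subject)) + 1
        blocks = np.split(np.arange(self.n), idx_split)
        by_size: dict[int, list[np.ndarray]] = {}
        for b in blocks:
            by_size.setdefault(len(b), []).append(b)
        self.batches = []
        U = np.column_stack([self.X, self.y])
        for k, rows_list in sorted(by_size.items()):
            rows = np.array(rows_list)  # (m, k)
            t = self.time[rows]
            dt = np.abs(t[:, :, None] - t[:, None, :])
            ser = self.series[rows]
            same_series = ser[:, :, None] == ser[:, None, :]
            stg = self.stage_series[rows]
            same_stage = stg[:, :, None] == stg[:, None, :]
            self.batches.append(
                dict(
                    rows=rows,
                    t=t,
                    dt=dt,
                    same_series=same_series.astype(float),
                    same_stage=same_stage.astype(float),
                    occ=self.occ[rows],
                    plate=self.plate[rows],
                    U=U[rows],
                )
            )

    # -- variance parameter packing ---------------------------------------

    def _param_layout(self):
        """Names of the optimised (transformed) variance parameters."""
        spec = self.spec
        layout = []
        if spec.random_plate:
            layout.append("log_lam_plate")
        if spec.random_person:
            layout.append("log_lam_person")
        if spec.random_slope:
            layout += ["log_lam_slope", "z_corr"]
        if spec.random_stage:
            layout.append("log_lam_stage")
        if spec.residual in ("car1", "heterogeneous_car1"):
            layout.append("logit_phi")
        if spec.residual == "heterogeneous_car1":
            layout += [f"log_mult_{o}" for o in OCCASIONS[1:]]
        return layout

    def _unpack(self, theta):
        layout = self._param_layout()
        d = dict(zip(layout, theta))
        lam_plate = np.exp(d["log_lam_plate"]) if "log_lam_plate" in d else 0.0
        lam_person = np.exp(d["log_lam_person"]) if "log_lam_person" in d else 0.0
        lam_slope = np.exp(d["log_lam_slope"]) if "log_lam_slope" in d else 0.0
        corr = np.tanh(d["z_corr"]) if "z_corr" in d else 0.0
        lam_stage = np.exp(d["log_lam_stage"]) if "log_lam_stage" in d else 0.0
        phi = 1.0 / (1.0 + np.exp(-d["logit_phi"])) if "logit_phi" in d else 0.0
        mult = np.ones(7)
        if self.spec.residual == "heterogeneous_car1":
            for i, o in enumerate(OCCASIONS[1:], start=1):
                mult[i] = np.exp(d[f"log_mult_{o}"])
        return lam_plate, lam_person, lam_slope, corr, lam_stage, phi, mult

    # -- likelihood --------------------------------------------------------

    def _block_cov(self, batch, lam_person, lam_slope, corr, lam_stage, phi, mult):
        """Per-subject covariance blocks on the residual-variance ratio scale."""
        t, dt = batch["t"], batch["dt"]
        if self.spec.residual == "independent":
            m, k = t.shape
            W = np.zeros((m, k, k))
            W[:, np.arange(k), np.arange(k)] = 1.0
        else:
            W = batch["same_series"] * np.power(phi, dt) if phi > 0 else (
                batch["same_series"] * (dt == 0)
            )
            if self.spec.residual == "heterogeneous_car1":
                mm = mult[batch["occ"]]
                W = W * mm[:, :, None] * mm[:, None, :]
        if self.spec.random_person:
            W = W + lam_person
        if self.spec.random_slope:
            cov = corr * np.sqrt(lam_person * lam_slope)
            W = W + cov * (t[:, :, None] + t[:, None, :]) + lam_slope * (
                t[:, :, None] * t[:, None, :]
            )
        if self.spec.random_stage:
            W = W + lam_stage * batch["same_stage"]
        return W

    def _core(self, theta):
        """logdet V0, F = U' V0^-1 U for U = [X y]; None on failure."""
        lam_plate, lam_person, lam_slope, corr, lam_stage, phi, mult = self._unpack(theta)
        p1 = self.p + 1
        logdet = 0.0
        F = np.zeros((p1, p1))
        use_plate = self.spec.random_plate and lam_plate > 0
        if use_plate:
            S = np.zeros((self.n_plates, self.n_plates))
            M = np.zeros((self.n_plates, p1))
        for batch in self.batches:
            W = self._block_cov(batch, lam_person, lam_slope, corr, lam_stage, phi, mult)
            m, k, _ = W.shape
            try:
                L = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * np.log(np.einsum("mii->mi", L)).sum()
            Ub = batch["U"]
            if use_plate:
                eye = np.broadcast_to(np.eye(k), (m, k, k))
                aug = np.concatenate([Ub, eye], axis=2)
                sol = np.linalg.solve(W, aug)
                WinvU, Winv = sol[:, :, :p1], sol[:, :, p1:]
                pl = batch["plate"]
                np.add.at(M, pl.ravel(), WinvU.reshape(-1, p1))
                pi = np.broadcast_to(pl[:, :, None], (m, k, k)).ravel()
                pj = np.broadcast_to(pl[:, None, :], (m, k, k)).ravel()
                np.add.at(S, (pi, pj), Winv.ravel())
            else:
                WinvU = np.linalg.solve(W, Ub)
            F += np.einsum("mki,mkj->ij", Ub, WinvU)
        if use_plate:
            C = S + np.eye(self.n_plates) / lam_plate
            try:
                cf = cho_factor(C, lower=True)
            except np.linalg.LinAlgError:
                return None
            logdet += 2.0 * np.log(np.diag(cf[0])).sum() + self.n_plates * np.log(lam_plate)
            F = F - M.T @ cho_solve(cf, M)
        return logdet, F

    def _crit(self, theta, method=None, sigma2=None):
        """-2 * (restricted) log likelihood, residual variance profiled unless given."""
        method = method or self.spec.estimation
        core = self._core(theta)
        if core is None:
            return 1e12
        logdetV0, F = core
        A = F[: self.p, : self.p]
        bvec = F[: self.p, self.p]
        yy = F[self.p, self.p]
        try:
            cfA = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        beta = cho_solve(cfA, bvec)
        rss = float(yy - bvec @ beta)
        if rss <= 0:
            return 1e12
        logdetA = 2.0 * np.log(np.diag(cfA[0])).sum()
        n, p = self.n, self.p
        if method == "REML":
            if sigma2 is None:
                s2 = rss / (n - p)
                return (
                    logdetV0 + logdetA - self._logdet_xtx
                    + (n - p) * (np.log(s2) + 1.0 + LOG2PI)
                )
            return (
                logdetV0
                + (n - p) * np.log(sigma2)
                + logdetA
                - self._logdet_xtx
                + rss / sigma2
                + (n - p) * LOG2PI
            )
        if sigma2 is None:
            s2 = rss / n
            return logdetV0 + n * (np.log(s2) + 1.0 + LOG2PI)
        return logdetV0 + n * np.log(sigma2) + rss / sigma2 + n * LOG2PI

    def neg_restricted_loglik(self, vc: dict) -> float:
        """-l_REML at explicit natural-scale variance parameters.

        vc keys (as applicable): var_plate, var_person, var_slope,
        cov_int_slope, var_stage, var_residual, ar_phi, occ_mult.
        """
        theta = self._pack_natural(vc)
        s2 = float(vc["var_residual"])
        return 0.5 * self._crit(theta, method="REML", sigma2=s2)

    def _pack_natural(self, vc: dict):
        s2 = float(vc["var_residual"])
        theta = []
        for name in self._param_layout():
            if name == "log_lam_plate":
                theta.append(np.log(max(vc.get("var_plate", 0.0), 1e-300) / s2))
            elif name == "log_lam_person":
                theta.append(np.log(max(vc.get("var_person", 0.0), 1e-300) / s2))
            elif name == "log_lam_slope":
                theta.append(np.log(max(vc.get("var_slope", 0.0), 1e-300) / s2))
            elif name == "z_corr":
                vp, vs = vc.get("var_person", 0.0), vc.get("var_slope", 0.0)
                c = vc.get("cov_int_slope", 0.0)
                r = c / np.sqrt(vp * vs) if vp > 0 and vs > 0 else 0.0
                theta.append(np.arctanh(np.clip(r, -0.999, 0.999)))
            elif name == "log_lam_stage":
                theta.append(np.log(max(vc.get("var_stage", 0.0), 1e-300) / s2))
            elif name == "logit_phi":
                phi = float(vc.get("ar_phi", 0.5))
                phi = np.clip(phi, 1e-8, 1 - 1e-8)
                theta.append(np.log(phi / (1 - phi)))
            elif name.startswith("log_mult_"):
                occ = name.split("_")[-1]
                mult = vc.get("occ_mult", np.ones(7))
                theta.append(np.log(mult[OCCASIONS.index(occ)]))
        return np.array(theta)

    # -- fitting -----------------------------------------------------------

    def _initial_points(self):
        mt2 = max(float(np.mean(self.time**2)), 1e-6)
        base = {
            "log_lam_plate": np.log(0.02),
            "log_lam_person": np.log(0.5),
            "log_lam_slope": np.log(0.5 / mt2),
            "z_corr": 0.0,
            "log_lam_stage": np.log(0.3),
            "logit_phi": 0.0,
        }
        layout = self._param_layout()
        x0 = np.array([base.get(name, 0.0) for name in layout])
        # documented restarts: scaled-up and scaled-down variance ratios
        shift = np.array(
            [1.5 if name.startswith("log_lam") else 0.5 for name in layout]
        )
        return [x0, x0 + shift, x0 - shift]

    def _bounds(self):
        out = []
        for name in self._param_layout():
            if name.startswith("log_lam"):
                out.append((np.log(1e-7), np.log(1e4)))
            elif name == "z_corr":
                out.append((-3.0, 3.0))
            elif name == "logit_phi":
                out.append((-9.0, 9.0))
            else:  # log occasion multiplier
                out.append((-2.5, 2.5))
        return out

    def fit(self, method: str | None = None, maxiter: int = 300) -> "MixedLMMResults":
        """Optimise the (restricted) likelihood and return results."""
        method = method or self.spec.estimation
        layout = self._param_layout()
        best = None
        if not layout:
            best = optimize.OptimizeResult(
                x=np.zeros(0), fun=self._crit(np.zeros(0), method), success=True
            )
        else:
            bounds = self._bounds()
            for x0 in self._initial_points():
                res = optimize.minimize(
                    self._crit,
                    x0,
                    args=(method,),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
                )
                if best is None or res.fun < best.fun:
                    best = res
                if best.success and best.fun < 1e11:
                    break
            if best.fun >= 1e11:
                raise ConvergenceError(
                    "likelihood evaluation failed at every restart", best=best
                )
        return self._results_at(best, method)

    def _results_at(self, opt, method):
        theta = opt.x
        lam_plate, lam_person, lam_slope, corr, lam_stage, phi, mult = self._unpack(theta)
        core = self._core(theta)
        logdetV0, F = core
        A = F[: self.p, : self.p]
        bvec = F[: self.p, self.p]
        yy = F[self.p, self.p]
        cfA = cho_factor(A, lower=True)
        beta = cho_solve(cfA, bvec)
        rss = float(yy - bvec @ beta)
        dof = self.n - self.p if method == "REML" else self.n
        s2 = rss / dof
        cov_beta = s2 * cho_solve(cfA, np.eye(self.p))
        se = np.sqrt(np.diag(cov_beta))

        def nat(lam):
            v = lam * s2
            if lam <= 2e-7:
                warnings.warn(
                    "variance component at boundary; pinned at 1e-10", BoundaryWarning
                )
                return _VAR_FLOOR
            return v

        vc = {"var_residual": s2}
        if self.spec.random_plate:
            vc["var_plate"] = nat(lam_plate)
        if self.spec.random_person:
            vc["var_person"] = nat(lam_person)
        if self.spec.random_slope:
            vc["var_slope"] = nat(lam_slope)
            vc["cov_int_slope"] = corr * np.sqrt(vc["var_person"] * vc["var_slope"])
            vc["corr_int_slope"] = corr
        if self.spec.random_stage:
            vc["var_stage"] = nat(lam_stage)
        if self.spec.residual in ("car1", "heterogeneous_car1"):
            vc["ar_phi"] = phi
        if self.spec.residual == "heterogeneous_car1":
            vc["occ_mult"] = mult
        crit = self._crit(theta, method)
        k = self.p + len(theta) + 1  # fixed effects + variance parameters + sigma^2
        grad_norm = self._grad_norm(theta, method, crit)
        if not opt.success and grad_norm > 1e-2:
            raise ConvergenceError(
                f"optimizer did not converge (grad norm {grad_norm:.3g})",
                best=opt,
                grad_norm=grad_norm,
            )
        return MixedLMMResults(
            model=self,
            method=method,
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            cov_params=cov_beta,
            vc=vc,
            theta=theta,
            llf=-0.5 * crit,
            aic=crit + 2 * k,
            k_params=k,
            nobs=self.n,
            converged=bool(opt.success),
            grad_norm=grad_norm,
        )

    def _grad_norm(self, theta, method, f0):
        if len(theta) == 0:
            return 0.0
        h = 1e-5
        g = np.zeros_like(theta)
        for i in range(len(theta)):
            tp = theta.copy()
            tp[i] += h
            g[i] = (self._crit(tp, method) - f0) / h
        return float(np.linalg.norm(g) / max(1.0, abs(f0)))

    # -- diagnostics -------------------------------------------------------

    def marginal_covariance(self, vc: dict) -> np.ndarray:
        """Dense marginal covariance V at natural-scale components (small n only)."""
        if self.n > 3000:
            raise ValueError("dense covariance restricted to small problems")
        s2 = float(vc["var_residual"])
        t = self.time
        V = np.zeros((self.n, self.n))
        same_series = self.series[:, None] == self.series[None, :]
        if self.spec.residual == "independent":
            V += s2 * np.eye(self.n)
        else:
            phi = float(vc["ar_phi"])
            dt = np.abs(t[:, None] - t[None, :])
            R = s2 * same_series * np.power(phi, dt)
            if self.spec.residual == "heterogeneous_car1":
                mm = np.asarray(vc.get("occ_mult", np.ones(7)))[self.occ]
                R = R * mm[:, None] * mm[None, :]
            V += R
        same_subj = self.subject[:, None] == self.subject[None, :]
        if self.spec.random_person:
            V += vc.get("var_person", 0.0) * same_subj
        if self.spec.random_slope:
            c = vc.get("cov_int_slope", 0.0)
            V += same_subj * (
                c * (t[:, None] + t[None, :])
                + vc.get("var_slope", 0.0) * t[:, None] * t[None, :]
            )
        if self.spec.random_stage:
            same_stage = self.stage_series[:, None] == self.stage_series[None, :]
            V += vc.get("var_stage", 0.0) * same_stage
        if self.spec.random_plate:
            same_plate = self.plate[:, None] == self.plate[None, :]
            V += vc.get("var_plate", 0.0) * same_plate
        return V


class MixedLMMResults:
    """Fitted mixed model: estimates, uncertainties and diagnostics."""

    def __init__(self, model, method, params, bse, cov_params, vc, theta, llf, aic,
                 k_params, nobs, converged, grad_norm):
        self.model = model
        self.method = method
        self.params = params
        self.bse = bse
        self.cov_params = cov_params
        self.vc = vc
        self.theta = theta
        self.llf = llf
        self.aic = aic
        self.k_params = k_params
        self.nobs = nobs
        self.converged = converged
        self.grad_norm = grad_norm
        self._infer()

    def _infer(self):
        m = self.model
        # containment-style denominator df: within-subject columns test against
        # the residual stratum, between-subject columns against subjects
        within = np.zeros(m.p, bool)
        for j in range(m.p):
            col = m.X[:, j]
            df_grp = pd.Series(col).groupby(m.subject).nunique()
            within[j] = bool((df_grp > 1).any())
        p_b = int((~within).sum())
        df_between = max(m.n_subjects - p_b, 1)
        df_within = max(m.n - m.n_subjects - int(within.sum()), 1)
        self.df_resid = pd.Series(
            np.where(within, df_within, df_between), index=m.names
        )
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=m.names
        )

    # -- presentation ------------------------------------------------------

    def fe_table(self) -> pd.DataFrame:
        """Fixed-effect rows in the Predictor / b / SE / t / P layout."""
        return pd.DataFrame(
            {
                "Predictor": self.params.index,
                "b": self.params.values,
                "SE": self.bse.values,
                "t": self.tvalues.values,
                "P": self.pvalues.values,
            }
        )

    def vc_table(self) -> pd.DataFrame:
        rows = []
        labels = {
            "var_plate": "Var(b_i) (ELISA plate)",
            "var_person": "Var(c_i0j) (person-level)",
            "cov_int_slope": "Covariance (intercept, slope)",
            "var_slope": "Var(c_i1j) (slopes)",
            "var_stage": "Var(d_ijk) (pregstage-level)",
            "var_residual": "var(eps_ijk) (residual)",
            "ar_phi": "AR(1) phi (per hour)",
        }
        for key, label in labels.items():
            if key in self.vc:
                rows.append({"Random component": label, "Variance component": self.vc[key]})
        if "occ_mult" in self.vc:
            for o, mval in zip(OCCASIONS, self.vc["occ_mult"]):
                rows.append(
                    {"Random component": f"SD multiplier {o}", "Variance component": mval}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Mixed model ({self.method}), residual={self.model.spec.residual}",
            f"n obs {self.nobs}, subjects {self.model.n_subjects}, "
            f"logLik {self.llf:.3f}, AIC {self.aic:.3f}, converged={self.converged}",
            "",
            self.fe_table().to_string(index=False, float_format=lambda v: f"{v: .4g}"),
            "",
            self.vc_table().to_string(index=False, float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<MixedLMMResults n={self.nobs} method={self.method} "
            f"llf={self.llf:.2f} aic={self.aic:.2f}>"
        )


def compare(fit_a: MixedLMMResults, fit_b: MixedLMMResults, nested: bool = True) -> dict:
    """Compare two fits on the same rows: delta AIC and, if nested, an LRT.

    fit_a is the simpler model.  For fixed-effect comparisons both fits must
    be ML; REML comparisons are valid only when the fixed effects agree.
    """
    if fit_a.nobs != fit_b.nobs:
        raise ValueError("fits use different numbers of rows")
    if fit_a.method != fit_b.method:
        raise ValueError("fits use different estimation methods")
    if fit_a.method == "REML" and list(fit_a.params.index) != list(fit_b.params.index):
        raise ValueError("REML comparisons require identical fixed effects")
    out = {
        "aic_a": fit_a.aic,
        "aic_b": fit_b.aic,
        "delta_aic": fit_b.aic - fit_a.aic,
    }
    if nested:
        df = fit_b.k_params - fit_a.k_params
        lr = 2.0 * (fit_b.llf - fit_a.llf)
        lr = max(lr, 0.0)
        out["lr_stat"] = lr
        out["lr_df"] = df
        out["lr_pvalue"] = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
        out["verdict"] = (
            "keep larger"
            if (out["delta_aic"] < 0 and df > 0 and out["lr_pvalue"] < 0.05)
            else "keep simpler"
        )
    return out
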