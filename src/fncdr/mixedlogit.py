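"""Mixed logistic regression with nested random intercepts.

Fits the three-level model used throughout the pipeline: binary outcome,
fixed effects for the episode characteristics, and Gaussian random
intercepts per patient nested within centers,

    logit P(y_ij = 1) = x_ij' beta + u_center(i) + v_patient(i),
    u ~ N(0, sigma_c^2),  v ~ N(0, sigma_p^2).

The marginal likelihood is maximized under the Laplace approximation (the
glmer default, nAGQ = 1): for each variance pair the fixed effects and the
random-effect modes are found by a joint penalized Newton iteration, and the
two log-standard-deviations are profiled with L-BFGS-B.  The nested design
makes the random-effects Hessian block-diagonal by center with arrow
structure (one center intercept coupled to its patients), so every inner
solve is linear in the number of patients.

If the three-level optimization fails (non-convergence, non-finite
likelihood, or a gradient norm above tolerance at the returned point), the
model is refitted with a patient-only random intercept, and failing that as
a plain logistic regression; ``levels_used`` records the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .characteristics import get_characteristic

_GRAD_TOL = 1e-3  # "model failure" threshold on the profiled gradient norm
_SEPARATION_BOUND = 15.0  # |beta| beyond this flags complete separation
_LOG_SIGMA_BOUNDS = (-6.0, 3.0)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, fixed-effect terms and grouping of one mixed-logit model."""

    outcome: str
    terms: tuple[str, ...] = ()
    interaction: str | None = None  # characteristic x randomized_fever_limit
    grouping: str = "patient_in_center"  # | "patient" | "none"

    def __post_init__(self) -> None:
        if self.outcome not in ("bacteremia", "smc", "sre"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("model terms must be unique")
        if self.grouping not in ("patient_in_center", "patient", "none"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class FitResult:
    """Fixed effects, variance components and diagnostics of one fit."""

    spec: ModelSpec
    labels: list[str]  # per-column labels, first is 'intercept'
    coefficients: np.ndarray
    standard_errors: np.ndarray
    sigma_center: float
    sigma_patient: float
    loglik: float
    levels_used: int
    converged: bool
    separation: bool = False
    term_columns: dict = field(default_factory=dict)  # term -> design column idx
    n_obs: int = 0

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def or_ci(self, z: float = 1.959963984540054) -> np.ndarray:
        lo = np.exp(self.coefficients - z * self.standard_errors)
        hi = np.exp(self.coefficients + z * self.standard_errors)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        z = np.abs(self.coefficients) / self.standard_errors
        return 2.0 * norm.sf(z)

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.labels.index(label)])

    def summary(self) -> pd.DataFrame:
        ci = self.or_ci()
        return pd.DataFrame({
            "coefficient": self.coefficients,
            "se": self.standard_errors,
            "odds_ratio": self.odds_ratios,
            "or_low": ci[:, 0], "or_high": ci[:, 1],
            "p_value": self.p_values,
        }, index=self.labels)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "terms": list(self.spec.terms),
            "labels": self.labels,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "sigma_center": self.sigma_center,
            "sigma_patient": self.sigma_patient,
            "loglik": self.loglik,
            "levels_used": self.levels_used,
            "converged": self.converged,
            "separation": self.separation,
        }


# --------------------------------------------------------------------------
# design construction

def build_design(spec: ModelSpec, table: pd.DataFrame):
    """(y, X, labels, term_columns, center_codes, patient_codes)."""
    y = np.asarray(table[spec.outcome], dtype=float)
    cols = [np.ones(len(table))]
    labels = ["intercept"]
    term_columns: dict[str, list[int]] = {}
    for term in spec.terms:
        x, lab = get_characteristic(term).design(table)
        term_columns[term] = list(range(len(labels), len(labels) + x.shape[1]))
        cols.append(x)
        labels.extend(lab)
    if spec.interaction is not None:
        limit_high = (np.asarray(table["randomized_fever_limit"], dtype=float)
                      == 39.0).astype(float)
        cols.append(limit_high.reshape(-1, 1))
        labels.append("fever_limit_39")
        term_columns["fever_limit_39"] = [len(labels) - 1]
        x, lab = get_characteristic(spec.interaction).design(table)
        inter = x * limit_high[:, None]
        term_columns["interaction"] = list(range(len(labels), len(labels) + inter.shape[1]))
        cols.append(inter)
        labels.extend([f"{l}:fever_limit_39" for l in lab])
    X = np.column_stack(cols)
    centers, center_codes = np.unique(table["center_id"].to_numpy(), return_inverse=True)
    patients, patient_codes = np.unique(table["patient_id"].to_numpy(), return_inverse=True)
    return y, X, labels, term_columns, center_codes, patient_codes


# --------------------------------------------------------------------------
# Laplace machinery

def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bernoulli_ll(y, eta):
    # y*eta - log(1+exp(eta)), stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _NestedLaplace:
    """Laplace objective for patient-in-center (3-level) or patient-only
    (2-level, ``center_codes=None``) random intercepts."""

    def __init__(self, y, X, center_codes, patient_codes):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.cc = center_codes
        self.pc = patient_codes
        self.n_center = 0 if center_codes is None else int(center_codes.max()) + 1
        self.n_patient = int(patient_codes.max()) + 1
        # patient -> center map (nested design)
        if center_codes is not None:
            self.patient_center = np.zeros(self.n_patient, dtype=int)
            self.patient_center[patient_codes] = center_codes
            self.center_patients = [np.flatnonzero(self.patient_center == c)
                                    for c in range(self.n_center)]
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.n_center)
        self.v = np.zeros(self.n_patient)

    # -- arrow-structured solve of (Z'WZ + P) x = rhs ----------------------
    def _prepare_blocks(self, w, inv_sc2, inv_sp2):
        wp = np.bincount(self.pc, weights=w, minlength=self.n_patient)
        d = wp + inv_sp2
        if self.cc is None:
            return wp, d, None, None
        wc = np.bincount(self.cc, weights=w, minlength=self.n_center)
        a = wc + inv_sc2
        return wp, d, wc, a

    def _solve_C(self, rhs_u, rhs_v, wp, d, a):
        """Solve the random-effects block; rhs_v is (Q,) or (Q,k)."""
        if self.cc is None:
            if rhs_v.ndim == 1:
                return None, rhs_v / d
            return None, rhs_v / d[:, None]
        single = rhs_v.ndim == 1
        if single:
            rhs_u = rhs_u[:, None]
            rhs_v = rhs_v[:, None]
        xu = np.zeros_like(rhs_u, dtype=float)
        xv = np.zeros_like(rhs_v, dtype=float)
        for c in range(self.n_center):
            pats = self.center_patients[c]
            r = wp[pats]                      # coupling u_c <-> v_j
            dj = d[pats]
            schur = a[c] - np.sum(r * r / dj)
            t = rhs_u[c] - (r / dj) @ rhs_v[pats]
            xu[c] = t / schur
            xv[pats] = (rhs_v[pats] - np.outer(r, xu[c])) / dj[:, None]
        if single:
            return xu[:, 0], xv[:, 0]
        return xu, xv

    def _logdet_C(self, wp, d, a):
        if self.cc is None:
            return float(np.sum(np.log(d)))
        total = float(np.sum(np.log(d)))
        for c in range(self.n_center):
            pats = self.center_patients[c]
            total += math.log(a[c] - np.sum(wp[pats] ** 2 / d[pats]))
        return total

    # -- inner joint Newton ------------------------------------------------
    def _penalized(self, beta, u, v, inv_sc2, inv_sp2):
        eta = self.X @ beta + v[self.pc]
        if self.cc is not None:
            eta = eta + u[self.cc]
        ll = _bernoulli_ll(self.y, eta)
        pen = 0.5 * inv_sp2 * float(v @ v)
        if self.cc is not None:
            pen += 0.5 * inv_sc2 * float(u @ u)
        return ll - pen, eta

    def inner(self, log_sc, log_sp, max_iter=80, tol=1e-9):
        """Maximize the penalized joint log-likelihood over (beta, u, v)."""
        inv_sc2 = math.exp(-2.0 * log_sc) if self.cc is not None else 0.0
        inv_sp2 = math.exp(-2.0 * log_sp)
        beta, u, v = self.beta.copy(), self.u.copy(), self.v.copy()
        obj, eta = self._penalized(beta, u, v, inv_sc2, inv_sp2)
        converged = False
        for _ in range(max_iter):
            mu = _sigmoid(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.y - mu
            g_beta = self.X.T @ resid
            g_v = np.bincount(self.pc, weights=resid, minlength=self.n_patient) - inv_sp2 * v
            g_u = (np.bincount(self.cc, weights=resid, minlength=self.n_center) - inv_sc2 * u
                   if self.cc is not None else np.zeros(0))
            gnorm = max(np.abs(g_beta).max(initial=0.0),
                        np.abs(g_v).max(initial=0.0),
                        np.abs(g_u).max(initial=0.0))
            if gnorm < tol:
                converged = True
                break
            wp, d, wc, a = self._prepare_blocks(w, inv_sc2, inv_sp2)
            # B = X' W Z, assembled as per-group weighted column sums
            Xw = self.X * w[:, None]
            Bv = np.zeros((self.p, self.n_patient))
            np.add.at(Bv.T, self.pc, Xw)   # (Q, p) scatter-add
            if self.cc is not None:
                Bu = np.zeros((self.p, self.n_center))
                np.add.at(Bu.T, self.cc, Xw)
            A = self.X.T @ Xw
            # Schur complement on the random effects
            s_u, s_v = self._solve_C(g_u, g_v, wp, d, a)
            CB_u, CB_v = self._solve_C(
                Bu.T if self.cc is not None else None, Bv.T, wp, d, a)
            BCBt = Bv @ CB_v
            Bs = Bv @ s_v
            if self.cc is not None:
                BCBt += Bu @ CB_u
                Bs += Bu @ s_u
            S = A - BCBt
            try:
                d_beta = np.linalg.solve(S, g_beta - Bs)
            except np.linalg.LinAlgError:
                raise FitError("singular fixed-effects system")
            rhs_v = g_v - Bv.T @ d_beta
            rhs_u = g_u - Bu.T @ d_beta if self.cc is not None else None
            d_u, d_v = self._solve_C(rhs_u, rhs_v, wp, d, a)
            # damped Newton: halve until the penalized objective improves
            step = 1.0
            for _ in range(30):
                nb = beta + step * d_beta
                nv = v + step * d_v
                nu = u + step * d_u if self.cc is not None else u
                new_obj, new_eta = self._penalized(nb, nu, nv, inv_sc2, inv_sp2)
                if new_obj >= obj - 1e-12:
                    break
                step *= 0.5
            else:
                break
            beta, u, v, obj, eta = nb, nu, nv, new_obj, new_eta
        self.beta, self.u, self.v = beta, u, v
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        wp, d, wc, a = self._prepare_blocks(w, inv_sc2, inv_sp2)
        logdet = self._logdet_C(wp, d, a)
        q_terms = self.n_patient * 2.0 * log_sp
        if self.cc is not None:
            q_terms += self.n_center * 2.0 * log_sc
        laplace = obj - 0.5 * q_terms - 0.5 * logdet
        return laplace, converged, (w, wp, d, a)

    def inner_b(self, beta, log_sc, log_sp, max_iter=60, tol=1e-9):
        """Maximize the penalized log-likelihood over (u, v) at fixed beta;
        return the Laplace log-marginal-likelihood."""
        inv_sc2 = math.exp(-2.0 * log_sc) if self.cc is not None else 0.0
        inv_sp2 = math.exp(-2.0 * log_sp)
        u, v = self.u.copy(), self.v.copy()
        obj, eta = self._penalized(beta, u, v, inv_sc2, inv_sp2)
        for _ in range(max_iter):
            mu = _sigmoid(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            resid = self.y - mu
            g_v = np.bincount(self.pc, weights=resid, minlength=self.n_patient) - inv_sp2 * v
            g_u = (np.bincount(self.cc, weights=resid, minlength=self.n_center) - inv_sc2 * u
                   if self.cc is not None else np.zeros(0))
            if max(np.abs(g_v).max(initial=0.0), np.abs(g_u).max(initial=0.0)) < tol:
                break
            wp, d, wc, a = self._prepare_blocks(w, inv_sc2, inv_sp2)
            d_u, d_v = self._solve_C(g_u if self.cc is not None else None, g_v, wp, d, a)
            step = 1.0
            for _ in range(30):
                nv = v + step * d_v
                nu = u + step * d_u if self.cc is not None else u
                new_obj, new_eta = self._penalized(beta, nu, nv, inv_sc2, inv_sp2)
                if new_obj >= obj - 1e-12:
                    break
                step *= 0.5
            u, v, obj, eta = nu, nv, new_obj, new_eta
        self.u, self.v = u, v
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        wp, d, wc, a = self._prepare_blocks(w, inv_sc2, inv_sp2)
        q_terms = self.n_patient * 2.0 * log_sp
        if self.cc is not None:
            q_terms += self.n_center * 2.0 * log_sc
        return obj - 0.5 * q_terms - 0.5 * self._logdet_C(wp, d, a)

    def fit(self, start_log_sigmas):
        """Laplace ML: stage 1 profiles beta inside the penalized Newton
        (fast, glmer nAGQ=0 flavor); stage 2 refines (beta, log sigmas)
        jointly over the full Laplace objective, whose log-determinant also
        depends on beta (glmer nAGQ=1 flavor)."""
        two_level = self.cc is None

        def negloglik(phi):
            log_sc = 0.0 if two_level else phi[0]
            log_sp = phi[-1]
            ll, conv, _ = self.inner(log_sc, log_sp)
            if not np.isfinite(ll):
                return 1e10
            return -ll

        best = None
        best_state = None
        for start in start_log_sigmas:
            x0 = np.asarray(start[-1:] if two_level else start, dtype=float)
            self.beta[:] = 0.0
            self.u[:] = 0.0
            self.v[:] = 0.0
            res = minimize(negloglik, x0, method="L-BFGS-B",
                           bounds=[_LOG_SIGMA_BOUNDS] * x0.size,
                           options={"maxiter": 60, "ftol": 1e-9})
            negloglik(res.x)  # restore the state at the optimum
            if best is None or res.fun < best.fun:
                best = res
                best_state = (self.beta.copy(), self.u.copy(), self.v.copy())

        # stage 2: beta joins the outer optimization
        self.beta, self.u, self.v = best_state
        n_theta = 1 if two_level else 2

        def negloglik_full(params):
            theta = params[:n_theta]
            beta = params[n_theta:]
            log_sc = 0.0 if two_level else theta[0]
            log_sp = theta[n_theta - 1]
            ll = self.inner_b(beta, log_sc, log_sp)
            return -ll if np.isfinite(ll) else 1e10

        x0 = np.concatenate([best.x, self.beta])
        bounds = [_LOG_SIGMA_BOUNDS] * n_theta + [(None, None)] * self.p
        res2 = minimize(negloglik_full, x0, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": 200, "ftol": 1e-10})
        if np.isfinite(res2.fun) and res2.fun <= best.fun + 1e-9:
            phi = res2.x[:n_theta]
            self.beta = res2.x[n_theta:]
            outer_success = bool(res2.success or res2.status == 1)
        else:  # keep the profiled solution
            phi = best.x
            self.beta = best_state[0]
            outer_success = bool(best.success or best.status == 1)
        log_sc = 0.0 if two_level else phi[0]
        log_sp = phi[-1]
        ll = self.inner_b(self.beta, log_sc, log_sp)
        inv_sc2 = 0.0 if two_level else math.exp(-2.0 * log_sc)
        inv_sp2 = math.exp(-2.0 * log_sp)
        eta = self.X @ self.beta + self.v[self.pc]
        if not two_level:
            eta = eta + self.u[self.cc]
        mu = _sigmoid(eta)
        # mode convergence check (the "model failure" gradient criterion)
        resid = self.y - mu
        g_v = np.bincount(self.pc, weights=resid, minlength=self.n_patient) - inv_sp2 * self.v
        gnorm = np.abs(g_v).max(initial=0.0)
        if not two_level:
            g_u = np.bincount(self.cc, weights=resid, minlength=self.n_center) - inv_sc2 * self.u
            gnorm = max(gnorm, np.abs(g_u).max(initial=0.0))
        inner_conv = bool(gnorm < _GRAD_TOL)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        wp, d, wc, a = self._prepare_blocks(w, inv_sc2, inv_sp2)
        # conditional covariance of beta: Schur complement of the joint Hessian
        Xw = self.X * w[:, None]
        A = self.X.T @ Xw
        Bv = np.zeros((self.p, self.n_patient))
        np.add.at(Bv.T, self.pc, Xw)
        if not two_level:
            Bu = np.zeros((self.p, self.n_center))
            np.add.at(Bu.T, self.cc, Xw)
            CB_u, CB_v = self._solve_C(Bu.T, Bv.T, wp, d, a)
            S = A - Bv @ CB_v - Bu @ CB_u
        else:
            _, CB_v = self._solve_C(None, Bv.T, wp, d, a)
            S = A - Bv @ CB_v
        cov = np.linalg.inv(S)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        sigma_c = 0.0 if two_level else math.exp(log_sc)
        sigma_p = math.exp(log_sp)
        converged = outer_success and inner_conv
        return self.beta.copy(), se, sigma_c, sigma_p, ll, converged


def _plain_logistic(y, X, max_iter=100, tol=1e-10):
    """Logistic regression by damped Newton (IRLS); returns beta, se, ll, conv."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    obj = _bernoulli_ll(y, eta)
    converged = False
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        g = X.T @ (y - mu)
        if np.abs(g).max() < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            step_dir = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):
            nb = beta + step * step_dir
            new_eta = X @ nb
            new_obj = _bernoulli_ll(y, new_eta)
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        beta, eta, obj = nb, new_eta, new_obj
    mu = _sigmoid(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return beta, se, obj, converged


# --------------------------------------------------------------------------
# public fitting interface

_STARTS = ((math.log(0.3), math.log(0.8)), (-2.0, -2.0))


def fit(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit the model with the fallback ladder 3-level -> 2-level -> plain.

    Deterministic given the data: the variance profile is started from fixed
    initial values and the best optimum is kept.
    """
    y, X, labels, term_columns, cc, pc = build_design(spec, table)
    if y.min() == y.max():
        raise FitError(f"outcome {spec.outcome!r} has a single class")

    ladder = {"patient_in_center": (3, 2, 1), "patient": (2, 1), "none": (1,)}[spec.grouping]
    last_error: Exception | None = None
    for level in ladder:
        try:
            if level == 1:
                beta, se, ll, conv = _plain_logistic(y, X)
                sc = sp = 0.0
            else:
                model = _NestedLaplace(y, X, cc if level == 3 else None, pc)
                beta, se, sc, sp, ll, conv = model.fit(_STARTS)
            if not np.all(np.isfinite(beta)) or not np.isfinite(ll):
                raise FitError("non-finite estimate")
            separation = bool(np.abs(beta).max() > _SEPARATION_BOUND)
            if not conv and not separation and level > 1:
                raise FitError("optimizer did not converge")
            return FitResult(
                spec=spec, labels=labels, coefficients=beta, standard_errors=se,
                sigma_center=sc, sigma_patient=sp, loglik=ll,
                levels_used=level, converged=conv and not separation,
                separation=separation, term_columns=term_columns, n_obs=len(y),
            )
        except (FitError, np.linalg.LinAlgError) as err:  # fall down the ladder
            last_error = err
            continue
    raise FitError(f"all fallback levels failed: {last_error}")


def predict_linear(fit_result: FitResult, table: pd.DataFrame) -> np.ndarray:
    """Fixed-effects linear predictor (random effects set to 0)."""
    y, X, labels, _, _, _ = build_design(fit_result.spec, _with_outcome(table, fit_result.spec))
    if labels != fit_result.labels:
        raise ValueError(f"design mismatch: expected {fit_result.labels}, got {labels}")
    return X @ fit_result.coefficients


def _with_outcome(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    # prediction tables need not carry the outcome column
    if spec.outcome in table.columns:
        return table
    t = table.copy()
    t[spec.outcome] = 0.0
    return t


# --------------------------------------------------------------------------
# screens

@dataclass
class ScreenResult:
    characteristic: str
    p_value: float | None
    significant: bool
    fit: FitResult | None
    error: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.error is None


def _term_p_value(spec_terms: tuple[str, ...], term: str, table: pd.DataFrame,
                  outcome: str, grouping: str) -> tuple[float, FitResult]:
    """p-value of ``term`` in the model with terms ``spec_terms``.

    Single-column terms use the Wald z-test; multi-column (categorical) terms
    use the likelihood-ratio test against the model without the term, at the
    same number of random-effect levels.
    """
    full = fit(ModelSpec(outcome, spec_terms, grouping=grouping), table)
    cols = full.term_columns[term]
    if len(cols) == 1:
        return float(full.p_values[cols[0]]), full
    reduced_terms = tuple(t for t in spec_terms if t != term)
    reduced = fit(ModelSpec(outcome, reduced_terms, grouping=grouping), table)
    if reduced.levels_used != full.levels_used:
        # refit the reduced model at the full model's ladder level for a
        # comparable likelihood
        grp = {3: "patient_in_center", 2: "patient", 1: "none"}[full.levels_used]
        reduced = fit(ModelSpec(outcome, reduced_terms, grouping=grp), table)
    lr = 2.0 * (full.loglik - reduced.loglik)
    p = float(chi2.sf(max(lr, 0.0), df=len(cols)))
    return p, full


def univariable_screen(table: pd.DataFrame, outcome: str,
                       characteristics: tuple[str, ...],
                       alpha: float = 0.05,
                       grouping: str = "patient_in_center") -> list[ScreenResult]:
    """One mixed-model fit per characteristic; significant if p < alpha.

    Failed fits are reported as not-evaluable rather than aborting the
    screen.  Results are ordered by ascending p-value (not-evaluable last).
    """
    results = []
    for char in characteristics:
        try:
            p, f = _term_p_value((char,), char, table, outcome, grouping)
            results.append(ScreenResult(char, p, p < alpha, f))
        except (FitError, ValueError, KeyError) as err:
            results.append(ScreenResult(char, None, False, None, error=str(err)))
    results.sort(key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 1.0))
    return results


def significant_set(results: list[ScreenResult]) -> tuple[str, ...]:
    return tuple(r.characteristic for r in results if r.significant)


@dataclass
class InteractionResult:
    characteristic: str
    p_value: float
    significant: bool
    fit: FitResult


def interaction_screen(table: pd.DataFrame, outcome: str, characteristic: str,
                       alpha: float = 0.01,
                       grouping: str = "patient_in_center") -> InteractionResult:
    """Test characteristic x randomized-fever-limit interaction at alpha."""
    limits = np.unique(table["randomized_fever_limit"])
    if limits.size < 2:
        raise ValueError("interaction screen requires both fever-limit levels present")
    spec = ModelSpec(outcome, (characteristic,), interaction=characteristic,
                     grouping=grouping)
    full = fit(spec, table)
    cols = full.term_columns["interaction"]
    if len(cols) == 1:
        p = float(full.p_values[cols[0]])
    else:
        lr = 2.0 * (full.loglik - _main_effects_loglik(spec, table, grouping, full.levels_used))
        p = float(chi2.sf(max(lr, 0.0), df=len(cols)))
    return InteractionResult(characteristic, p, p < alpha, full)


def _main_effects_loglik(spec: ModelSpec, table: pd.DataFrame, grouping: str,
                         levels_used: int) -> float:
    """Log-likelihood of the main-effects model (characteristic + limit)."""
    t = table.copy()
    t["fever_limit_39_main"] = (t["randomized_fever_limit"] == 39.0).astype(int)
    from .characteristics import CHARACTERISTICS, Characteristic
    if "fever_limit_39_main" not in CHARACTERISTICS:
        CHARACTERISTICS["fever_limit_39_main"] = Characteristic(
            "fever_limit_39_main", "binary")
    grp = {3: "patient_in_center", 2: "patient", 1: "none"}[levels_used]
    reduced = fit(ModelSpec(spec.outcome, (spec.interaction, "fever_limit_39_main"),
                            grouping=grp), t)
    return reduced.loglik
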