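"""Longitudinal latent-disability progression with interval-censored dropout.

The latent trajectory of subject *i* is linear in time,

    D_i(t) = D_i0 + a_i * t,      D_i0 = theta1 + eta_i1,
                                  a_i  = (1 - beta_drug * x_grp) * (theta2 + eta_i2),

with correlated bivariate-normal random effects (SDs ``omega1``/``omega2``,
correlation ``rho``), item parameters fixed to previously estimated baseline
values, and time measured in months at the interface but years internally
(progression and hazard rates are per year).  Dropout is modeled as an
interval-censored time-to-event with a log-linear hazard in one of four
subject-level covariates (none, current disability, progression rate,
baseline disability).

Fitting maximizes the marginal likelihood, integrating the two random
effects per subject by a vectorized Laplace approximation (default, the
classical pharmacometric choice for this model family) or adaptive
Gauss-Hermite quadrature.  For speed the per-visit item log-likelihood of
every subject is pre-tabulated on a dense latent grid once per dataset --
it does not depend on the population parameters -- and interpolated with
cubic Hermite polynomials during optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .items import ItemBank, dlogpmf_table, logpmf_table

__all__ = [
    "VisitSchedule",
    "ProgressionParams",
    "SubjectEffects",
    "HazardSpec",
    "LEADE_SCHEDULE",
    "CTS_SCHEDULE",
    "trajectory",
    "survival",
    "dropout_interval_loglik",
    "joint_subject_loglik",
    "LongitudinalIRT",
    "LongitudinalIRTResults",
    "fit_longitudinal",
    "select_hazard",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
HAZARD_KINDS = ("constant", "disability", "progression_rate", "baseline_disability")


@dataclass(frozen=True)
class VisitSchedule:
    """Scheduled assessment times in months since baseline."""

    times: tuple[float, ...]

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        if len(t) < 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("visit times must start at 0 and strictly increase")
        object.__setattr__(self, "times", t)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.times) / 12.0

    @property
    def end(self) -> float:
        return self.times[-1]


#: 18-month trial with an 8-week withdrawal phase: 8 visits to month 20
LEADE_SCHEDULE = VisitSchedule((0, 3, 6, 9, 12, 15, 18, 20))
#: trial-simulation design: 7 assessments to month 18
CTS_SCHEDULE = VisitSchedule((0, 3, 6, 9, 12, 15, 18))


@dataclass(frozen=True)
class ProgressionParams:
    """Population parameters of the linear latent progression model."""

    theta1: float  # typical baseline disability
    theta2: float  # typical progression slope, latent units / year
    omega1: float  # SD of the baseline random effect
    omega2: float  # SD of the slope random effect
    rho: float  # correlation of (eta1, eta2)
    beta_drug: float = 0.0  # fractional slope reduction in the treated arm

    def __post_init__(self):
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("omega1, omega2 must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| <= 1 required")
        if not -1 < self.beta_drug < 1:
            raise ValueError("beta_drug must lie in (-1, 1)")

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * self.omega1 * self.omega2
        return np.array([[self.omega1**2, c], [c, self.omega2**2]])


@dataclass(frozen=True)
class SubjectEffects:
    """One subject's random-effect deviations and arm indicator."""

    eta1: float
    eta2: float
    x_grp: int = 0

    def d0(self, params: ProgressionParams) -> float:
        return params.theta1 + self.eta1

    def slope(self, params: ProgressionParams) -> float:
        return (1.0 - params.beta_drug * self.x_grp) * (params.theta2 + self.eta2)


@dataclass(frozen=True)
class HazardSpec:
    """Log-linear dropout hazard: log h = theta3 [+ theta4 * covariate]."""

    kind: str
    theta3: float
    theta4: float | None = None

    def __post_init__(self):
        if self.kind not in HAZARD_KINDS:
            raise ValueError(f"unknown hazard kind {self.kind!r}")
        if self.kind == "constant" and self.theta4 is not None:
            raise ValueError("constant hazard takes no theta4")
        if self.kind != "constant" and self.theta4 is None:
            raise ValueError(f"hazard kind {self.kind!r} requires theta4")


def trajectory(t_months, effects: SubjectEffects, params: ProgressionParams):
    """Latent disability at time ``t_months`` (slope is per year)."""
    t = np.asarray(t_months, dtype=float) / 12.0
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    return effects.d0(params) + effects.slope(params) * t


def _cum_hazard(t_years, d0, slope, hazard: HazardSpec):
    """Integrated hazard over (0, t); vectorized over subjects and/or t."""
    t = np.asarray(t_years, dtype=float)
    if hazard.kind == "constant":
        return np.exp(hazard.theta3) * t
    if hazard.kind == "progression_rate":
        return np.exp(hazard.theta3 + hazard.theta4 * slope) * t
    if hazard.kind == "baseline_disability":
        return np.exp(hazard.theta3 + hazard.theta4 * d0) * t
    # current-disability hazard: exp(th3 + th4 (d0 + a u)) integrates in
    # closed form as an exponential of a linear function of u
    base = np.exp(hazard.theta3 + hazard.theta4 * d0)
    r = np.asarray(hazard.theta4 * slope, dtype=float)
    small = np.abs(r) < 1e-12
    rr = np.where(small, 1.0, r)
    return base * np.where(small, t, np.expm1(rr * t) / rr)


def survival(t_months, effects: SubjectEffects, params: ProgressionParams,
             hazard: HazardSpec):
    """Probability of remaining in the study beyond ``t_months``."""
    t = np.asarray(t_months, dtype=float) / 12.0
    if np.any(t < 0):
        raise ValueError("t_months must be >= 0")
    return np.exp(-_cum_hazard(t, effects.d0(params), effects.slope(params), hazard))


def dropout_interval_loglik(
    last_seen_months: float,
    first_missed_months: float | None,
    effects: SubjectEffects,
    params: ProgressionParams,
    hazard: HazardSpec,
    end_of_study_months: float | None = None,
) -> float:
    """Interval-censored dropout log-probability for one subject.

    A subject who dropped out did so between the last attended and first
    missed visit: ``log(S(last) - S(missed))``.  A completer contributes
    ``log S(end of study)`` (``end_of_study_months`` defaults to
    ``last_seen_months``).
    """
    s_last = float(survival(last_seen_months, effects, params, hazard))
    if first_missed_months is None:
        end = last_seen_months if end_of_study_months is None else end_of_study_months
        return float(np.log(survival(end, effects, params, hazard)))
    if not first_missed_months > last_seen_months:
        raise ValueError("first_missed must be later than last_seen")
    s_miss = float(survival(first_missed_months, effects, params, hazard))
    p = s_last - s_miss
    if p <= 0:
        warnings.warn("interval dropout probability underflow; floored", stacklevel=2)
        return float(np.log(1e-300))
    return float(np.log(p))


def _dropout_loglik_vec(eta1, eta2, theta1, theta2, mult, last_y, miss_y, end_y,
                        hazard: HazardSpec):
    """Vectorized interval-censored dropout log-likelihood.

    ``miss_y`` is NaN for completers (who contribute log S(end)).
    """
    d0 = theta1 + eta1
    slope = mult * (theta2 + eta2)
    s_last = np.exp(-_cum_hazard(last_y, d0, slope, hazard))
    out = np.empty_like(s_last)
    comp = np.isnan(miss_y)
    s_end = np.exp(-_cum_hazard(np.where(comp, end_y, 0.0), d0, slope, hazard))
    out[comp] = np.log(s_end[comp])
    if (~comp).any():
        s_miss = np.exp(-_cum_hazard(np.where(comp, 0.0, miss_y), d0, slope, hazard))
        p = np.clip(s_last - s_miss, 1e-300, None)
        out[~comp] = np.log(p[~comp])
    return out


# ---------------------------------------------------------------------------
# exact single-subject joint likelihood (reference implementation)


def joint_subject_loglik(
    records: pd.DataFrame,
    bank: ItemBank,
    params: ProgressionParams,
    hazard: HazardSpec | None = None,
    dropout: tuple[float, float | None] | None = None,
    x_grp: int = 0,
    end_of_study_months: float | None = None,
    method: str = "laplace",
    n_nodes: int = 9,
) -> float:
    """Log marginal likelihood of one subject's longitudinal responses.

    Integrates the two correlated random effects by Laplace approximation or
    ``n_nodes`` x ``n_nodes`` adaptive Gauss-Hermite quadrature, evaluating
    every item likelihood exactly (no grid interpolation) -- this is the
    reference path; dataset-level fitting uses the vectorized engine.
    """
    times = np.sort(records["time_months"].unique())
    t_years = times / 12.0
    mult = 1.0 - params.beta_drug * x_grp
    per_visit: list[list[tuple]] = [[] for _ in times]
    tindex = {t: i for i, t in enumerate(times)}
    for _, r in records.iterrows():
        per_visit[tindex[r["time_months"]]].append((bank[r["item_id"]], int(r["value"])))

    def data_loglik(eta1: float, eta2: float) -> float:
        total = 0.0
        for tv, obs in zip(t_years, per_visit):
            D = (params.theta1 + eta1) + mult * (params.theta2 + eta2) * tv
            for item, y in obs:
                table = logpmf_table(item, np.asarray(D))
                if not np.isfinite(table[y]):
                    raise FloatingPointError(
                        f"non-finite likelihood at t={tv * 12:g} months, "
                        f"item {item.item_id!r}"
                    )
                total += float(table[y])
        return total

    def drop_loglik(eta1: float, eta2: float) -> float:
        if hazard is None or dropout is None:
            return 0.0
        eff = SubjectEffects(eta1, eta2, x_grp)
        return dropout_interval_loglik(
            dropout[0], dropout[1], eff, params, hazard, end_of_study_months
        )

    if params.omega1 == 0.0 and params.omega2 == 0.0:
        return data_loglik(0.0, 0.0) + drop_loglik(0.0, 0.0)

    Om = params.cov
    if np.linalg.det(Om) <= 0:
        Om = Om + 1e-10 * np.eye(2)
    Oinv = np.linalg.inv(Om)
    logdetOm = float(np.log(np.linalg.det(Om)))

    def g(eta: np.ndarray) -> float:
        q = float(eta @ Oinv @ eta)
        return (
            data_loglik(eta[0], eta[1])
            + drop_loglik(eta[0], eta[1])
            - _LOG_2PI
            - 0.5 * logdetOm
            - 0.5 * q
        )

    res = minimize(lambda e: -g(e), np.zeros(2), method="BFGS")
    mode = res.x
    h = 1e-4
    H = np.empty((2, 2))
    g0 = g(mode)
    for i in range(2):
        ei = np.eye(2)[i] * h
        H[i, i] = (g(mode + ei) - 2 * g0 + g(mode - ei)) / h**2
    e0 = np.array([h, 0.0])
    e1 = np.array([0.0, h])
    H[0, 1] = H[1, 0] = (
        g(mode + e0 + e1) - g(mode + e0 - e1) - g(mode - e0 + e1) + g(mode - e0 - e1)
    ) / (4 * h**2)
    P = -H
    detP = float(np.linalg.det(P))
    if method == "laplace":
        return g0 + _LOG_2PI - 0.5 * np.log(detP)
    if method in ("agh", "adaptive_gauss_hermite"):
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        C = np.linalg.inv(P)
        Lc = np.linalg.cholesky(C)
        terms = []
        for i in range(n_nodes):
            for j in range(n_nodes):
                xq = np.array([x[i], x[j]])
                eq = mode + np.sqrt(2.0) * Lc @ xq
                terms.append(np.log(w[i] * w[j]) + xq @ xq + g(eq))
        return float(logsumexp(terms) + np.log(2.0) - 0.5 * np.log(detP))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# vectorized dataset engine


class _LongData:
    """Long-format trial data rearranged into (subject, visit) tensors."""

    def __init__(self, data: pd.DataFrame, bank: ItemBank):
        if len(data) == 0:
            raise ValueError("no response records")
        self.subjects = np.asarray(pd.unique(data["subject_id"]))
        sub_idx = pd.Series(np.arange(len(self.subjects)), index=self.subjects)
        self.times = np.sort(np.asarray(pd.unique(data["time_months"]), dtype=float))
        t_idx = pd.Series(np.arange(len(self.times)), index=self.times)
        rows = sub_idx[data["subject_id"]].to_numpy()
        cols = t_idx[data["time_months"].astype(float)].to_numpy()
        vals = data["value"].to_numpy(dtype=int)
        icodes = data["item_id"].to_numpy()
        if "arm" in data.columns:
            arm = data.groupby("subject_id", sort=False)["arm"].first()
            self.x = arm.loc[self.subjects].to_numpy(dtype=float)
        else:
            self.x = np.zeros(len(self.subjects))
        self.items = []
        self.obs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for it in bank.items:
            m = icodes == it.item_id
            if not m.any():
                continue
            key = rows[m] * len(self.times) + cols[m]
            if len(np.unique(key)) != len(key):
                raise ValueError(
                    f"duplicate responses for item {it.item_id!r} at a visit"
                )
            self.items.append(it)
            self.obs.append((rows[m], cols[m], vals[m]))
        self.n_subjects = len(self.subjects)
        self.n_visits = len(self.times)
        self.attended = np.zeros((self.n_subjects, self.n_visits), dtype=bool)
        self.attended[rows, cols] = True
        self.n_observations = len(vals)


def _hermite_eval(y0, y1, d0, d1, t, h):
    t2 = t * t
    t3 = t2 * t
    val = (
        (2 * t3 - 3 * t2 + 1) * y0
        + (t3 - 2 * t2 + t) * h * d0
        + (-2 * t3 + 3 * t2) * y1
        + (t3 - t2) * h * d1
    )
    dval = (
        (6 * t2 - 6 * t) * y0
        + (3 * t2 - 4 * t + 1) * h * d0
        + (-6 * t2 + 6 * t) * y1
        + (3 * t2 - 2 * t) * h * d1
    ) / h
    return val, dval


class _Engine:
    """Pre-tabulated per-(subject, visit) data log-likelihood on a latent grid."""

    def __init__(
        self,
        ld: _LongData,
        grid_lo: float = -8.0,
        grid_hi: float = 8.0,
        grid_step: float = 0.05,
    ):
        self.ld = ld
        self.grid = np.arange(grid_lo, grid_hi + 1e-9, grid_step)
        self.h = grid_step
        G = self.grid.size
        S, V = ld.n_subjects, ld.n_visits
        self.L = np.zeros((S, V, G))
        self.dL = np.zeros((S, V, G))
        for it, (rs, cs, ys) in zip(ld.items, ld.obs):
            table = logpmf_table(it, self.grid)
            dtable = dlogpmf_table(it, self.grid)
            self.L[rs, cs] += table[ys]
            self.dL[rs, cs] += dtable[ys]
        # second derivative at the nodes from the analytic first derivative
        self.d2L = np.gradient(self.dL, self.h, axis=2, edge_order=2)
        self._eta = np.zeros((S, 2))

    def _interp(self, D):
        """Interpolated (L, L', L'') at latent values D, shape (S, V)."""
        u = (D - self.grid[0]) / self.h
        i = np.clip(u.astype(int), 0, self.grid.size - 2)
        t = u - i
        idx = i[..., None]
        take = lambda A, k: np.take_along_axis(A, idx + k, axis=2)[..., 0]
        L0, L1 = take(self.L, 0), take(self.L, 1)
        d0, d1 = take(self.dL, 0), take(self.dL, 1)
        s0, s1 = take(self.d2L, 0), take(self.d2L, 1)
        val, _ = _hermite_eval(L0, L1, d0, d1, t, self.h)
        dval, d2val = _hermite_eval(d0, d1, s0, s1, t, self.h)
        return val, dval, d2val

    def marginal_loglik(
        self,
        theta1: float,
        theta2: float,
        Om: np.ndarray,
        beta: float,
        hazard: HazardSpec | None,
        dropout: tuple[np.ndarray, np.ndarray, float] | None,
        method: str = "laplace",
        n_nodes: int = 5,
        per_subject: bool = False,
    ):
        """Marginal log-likelihood, integrating (eta1, eta2) per subject."""
        ld = self.ld
        t_y = ld.times / 12.0
        mult = 1.0 - beta * ld.x  # (S,)
        base = theta1 + np.outer(mult * theta2, t_y)  # (S, V)
        cvec = np.outer(mult, t_y)  # (S, V)
        Oinv = np.linalg.inv(Om)
        logdetOm = float(np.log(np.linalg.det(Om)))

        use_drop = hazard is not None and dropout is not None
        if use_drop:
            last_y, miss_y, end_y = dropout

        def drop_val(e1, e2):
            if not use_drop:
                return 0.0
            return _dropout_loglik_vec(
                e1, e2, theta1, theta2, mult, last_y, miss_y, end_y, hazard
            )

        def g_parts(eta):
            D = base + eta[:, :1] + cvec * eta[:, 1:]
            L, dL, d2L = self._interp(D)
            return D, L, dL, d2L

        def g_value(eta):
            """Joint log-density up to eta-free constants, per subject."""
            D = base + eta[:, :1] + cvec * eta[:, 1:]
            L, _, _ = self._interp(D)
            q = np.einsum("si,ij,sj->s", eta, Oinv, eta)
            out = L.sum(1) - 0.5 * q
            if use_drop:
                out = out + drop_val(eta[:, 0], eta[:, 1])
            return out

        fd = 1e-5

        def grad_hess(eta):
            _, L, dL, d2L = g_parts(eta)
            g1 = np.stack([dL.sum(1), (cvec * dL).sum(1)], axis=1) - eta @ Oinv
            H11 = d2L.sum(1) - Oinv[0, 0]
            H12 = (cvec * d2L).sum(1) - Oinv[0, 1]
            H22 = (cvec**2 * d2L).sum(1) - Oinv[1, 1]
            if use_drop:
                f0 = drop_val(eta[:, 0], eta[:, 1])
                fp1 = drop_val(eta[:, 0] + fd, eta[:, 1])
                fm1 = drop_val(eta[:, 0] - fd, eta[:, 1])
                fp2 = drop_val(eta[:, 0], eta[:, 1] + fd)
                fm2 = drop_val(eta[:, 0], eta[:, 1] - fd)
                fpp = drop_val(eta[:, 0] + fd, eta[:, 1] + fd)
                fpm = drop_val(eta[:, 0] + fd, eta[:, 1] - fd)
                fmp = drop_val(eta[:, 0] - fd, eta[:, 1] + fd)
                fmm = drop_val(eta[:, 0] - fd, eta[:, 1] - fd)
                g1[:, 0] += (fp1 - fm1) / (2 * fd)
                g1[:, 1] += (fp2 - fm2) / (2 * fd)
                H11 += (fp1 - 2 * f0 + fm1) / fd**2
                H22 += (fp2 - 2 * f0 + fm2) / fd**2
                H12 += (fpp - fpm - fmp + fmm) / (4 * fd**2)
            return g1, H11, H12, H22

        def newton(eta, maxiter):
            """Monotone (backtracking) Newton ascent to tight gradient norm.

            Tight convergence makes the Laplace value insensitive to the
            warm start (error is quadratic in the residual gradient), which
            the outer finite-difference gradients rely on.
            """
            gv = None
            for _ in range(maxiter):
                g1, H11, H12, H22 = grad_hess(eta)
                if np.abs(g1).max() < 1e-8:
                    break
                det = H11 * H22 - H12**2
                bad = (det <= 1e-12) | (H11 >= 0)
                det = np.where(bad, 1.0, det)
                s1 = -(H22 * g1[:, 0] - H12 * g1[:, 1]) / det
                s2 = -(-H12 * g1[:, 0] + H11 * g1[:, 1]) / det
                step = np.stack([s1, s2], axis=1)
                step[bad] = 0.05 * g1[bad]
                nrm = np.sqrt((step**2).sum(1, keepdims=True))
                step = step * np.minimum(1.0, 2.0 / np.maximum(nrm, 1e-300))
                if np.abs(step).max() <= 1e-3 and not bad.any():
                    # pure Newton region: accept without a line search
                    eta = eta + step
                    continue
                if gv is None:
                    gv = g_value(eta)
                cand = eta + step
                gv_new = g_value(cand)
                for _bt in range(15):
                    worse = gv_new < gv - 1e-12
                    if not worse.any():
                        break
                    step[worse] *= 0.5
                    cand = eta + step
                    gv_new = g_value(cand)
                accept = gv_new >= gv - 1e-12
                eta = np.where(accept[:, None], cand, eta)
                gv = np.where(accept, gv_new, gv)
            return eta

        eta = newton(self._eta.copy(), 100)
        g1, *_ = grad_hess(eta)
        stuck = np.abs(g1).max(axis=1) > 1e-6
        if stuck.any():
            # deterministic restart for the few non-converged subjects
            eta2 = newton(np.zeros_like(eta), 200)
            eta[stuck] = eta2[stuck]
        self._eta = eta.copy()

        D, L, dL, d2L = g_parts(eta)
        H11 = d2L.sum(1) - Oinv[0, 0]
        H12 = (cvec * d2L).sum(1) - Oinv[0, 1]
        H22 = (cvec**2 * d2L).sum(1) - Oinv[1, 1]
        dval = drop_val(eta[:, 0], eta[:, 1]) if use_drop else 0.0
        if use_drop:
            f0 = dval
            H11 = H11 + (
                drop_val(eta[:, 0] + fd, eta[:, 1])
                - 2 * f0
                + drop_val(eta[:, 0] - fd, eta[:, 1])
            ) / fd**2
            H22 = H22 + (
                drop_val(eta[:, 0], eta[:, 1] + fd)
                - 2 * f0
                + drop_val(eta[:, 0], eta[:, 1] - fd)
            ) / fd**2
            H12 = H12 + (
                drop_val(eta[:, 0] + fd, eta[:, 1] + fd)
                - drop_val(eta[:, 0] + fd, eta[:, 1] - fd)
                - drop_val(eta[:, 0] - fd, eta[:, 1] + fd)
                + drop_val(eta[:, 0] - fd, eta[:, 1] - fd)
            ) / (4 * fd**2)
        detP = np.clip(H11 * H22 - H12**2, 1e-300, None)
        q = np.einsum("si,ij,sj->s", eta, Oinv, eta)
        gmode = (
            L.sum(1) + dval - _LOG_2PI - 0.5 * logdetOm - 0.5 * q
        )
        if method == "laplace":
            ll = gmode + _LOG_2PI - 0.5 * np.log(detP)
        elif method in ("agh", "adaptive_gauss_hermite"):
            x, w = np.polynomial.hermite.hermgauss(n_nodes)
            # per-subject Cholesky of (-H)^-1
            C11 = H22 / detP
            C12 = -H12 / detP
            C22 = H11 / detP
            l11 = np.sqrt(np.clip(C11, 1e-300, None))
            l21 = C12 / l11
            l22 = np.sqrt(np.clip(C22 - l21**2, 1e-300, None))
            terms = np.empty((self.ld.n_subjects, n_nodes * n_nodes))
            k = 0
            for i2 in range(n_nodes):
                for j2 in range(n_nodes):
                    e1 = eta[:, 0] + np.sqrt(2.0) * l11 * x[i2]
                    e2 = eta[:, 1] + np.sqrt(2.0) * (l21 * x[i2] + l22 * x[j2])
                    eq = np.stack([e1, e2], axis=1)
                    Dq = base + eq[:, :1] + cvec * eq[:, 1:]
                    Lq, _, _ = self._interp(Dq)
                    qq = np.einsum("si,ij,sj->s", eq, Oinv, eq)
                    gq = (
                        Lq.sum(1)
                        + (drop_val(e1, e2) if use_drop else 0.0)
                        - _LOG_2PI
                        - 0.5 * logdetOm
                        - 0.5 * qq
                    )
                    terms[:, k] = np.log(w[i2] * w[j2]) + x[i2] ** 2 + x[j2] ** 2 + gq
                    k += 1
            ll = logsumexp(terms, axis=1) + np.log(2.0) - 0.5 * np.log(detP)
        else:
            raise ValueError(f"unknown method {method!r}")
        if per_subject:
            return ll
        return float(ll.sum())

    def posterior_modes(self) -> np.ndarray:
        return self._eta.copy()


# ---------------------------------------------------------------------------
# model / results


def _derive_dropout_table(ld: _LongData, schedule: VisitSchedule) -> pd.DataFrame:
    """Interval-censored dropout data from attendance vs the schedule."""
    sched = np.asarray(schedule.times, dtype=float)
    col_of = {t: np.searchsorted(sched, t) for t in ld.times}
    last_seen = np.zeros(ld.n_subjects)
    first_missed = np.full(ld.n_subjects, np.nan)
    for s in range(ld.n_subjects):
        att = [int(col_of[t]) for v, t in enumerate(ld.times) if ld.attended[s, v]]
        last = max(att)
        last_seen[s] = sched[last]
        if last < len(sched) - 1:
            first_missed[s] = sched[last + 1]
    return pd.DataFrame(
        {
            "subject_id": ld.subjects,
            "last_seen_months": last_seen,
            "first_missed_months": first_missed,
        }
    )


_PACK_NAMES = ("theta1", "theta2", "omega1", "omega2", "rho")


class LongitudinalIRT:
    """Longitudinal IRT progression model for one trial dataset.

    Item (ICC) parameters are fixed to the supplied bank -- typically
    previously estimated baseline values -- and only the population
    progression parameters (plus optional drug effect and dropout hazard)
    are estimated.

    Parameters
    ----------
    data : long-format response table (``subject_id``, ``time_months``,
        ``item_id``, ``value``; optional ``arm`` with 0 = placebo).
    bank : item bank with fixed parameters.
    hazard_kind : one of ``constant | disability | progression_rate |
        baseline_disability``, or None for no dropout model.
    drug_effect : estimate the fractional slope reduction ``beta_drug``
        (default: automatically on when both arms are present).
    schedule : scheduled visits; needed to interval-censor dropout and to
        mark completers.  Defaults to the observed visit times.
    dropout : optional table (``subject_id``, ``last_seen_months``,
        ``first_missed_months`` with NaN for completers); derived from
        attendance against the schedule when omitted.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        bank: ItemBank,
        hazard_kind: str | None = None,
        drug_effect: bool | None = None,
        schedule: VisitSchedule | None = None,
        dropout: pd.DataFrame | None = None,
        grid_step: float = 0.05,
    ):
        self.bank = bank
        self._ld = _LongData(data, bank)
        self.schedule = schedule
        if schedule is None and hazard_kind is not None:
            self.schedule = VisitSchedule(tuple(self._ld.times))
        self.hazard_kind = hazard_kind
        if hazard_kind is not None and hazard_kind not in HAZARD_KINDS:
            raise ValueError(f"unknown hazard kind {hazard_kind!r}")
        self.drug_effect = (
            bool(self._ld.x.any()) if drug_effect is None else drug_effect
        )
        self._engine = _Engine(self._ld, grid_step=grid_step)
        if hazard_kind is not None:
            if dropout is None:
                dropout = _derive_dropout_table(self._ld, self.schedule)
            dd = dropout.set_index("subject_id").loc[self._ld.subjects]
            self._dropout = (
                dd["last_seen_months"].to_numpy(dtype=float) / 12.0,
                dd["first_missed_months"].to_numpy(dtype=float) / 12.0,
                self.schedule.end / 12.0,
            )
        else:
            self._dropout = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, bank: ItemBank, **kw):
        return cls(data, bank, **kw)

    # -- parameter packing ---------------------------------------------------

    def _names(self) -> list[str]:
        names = list(_PACK_NAMES)
        if self.drug_effect:
            names.append("beta_drug")
        if self.hazard_kind is not None:
            names.append("theta3")
            if self.hazard_kind != "constant":
                names.append("theta4")
        return names

    def _pack(self, natural: dict) -> np.ndarray:
        u = [
            natural["theta1"],
            natural["theta2"],
            np.log(max(natural["omega1"], 1e-4)),
            np.log(max(natural["omega2"], 1e-4)),
            np.arctanh(np.clip(natural["rho"], -0.99, 0.99)),
        ]
        if self.drug_effect:
            u.append(natural.get("beta_drug", 0.0))
        if self.hazard_kind is not None:
            u.append(natural.get("theta3", 0.0))
            if self.hazard_kind != "constant":
                u.append(natural.get("theta4", 0.0))
        return np.asarray(u, dtype=float)

    def _unpack(self, u: np.ndarray) -> dict:
        out = dict(
            theta1=float(u[0]),
            theta2=float(u[1]),
            omega1=float(np.exp(u[2])),
            omega2=float(np.exp(u[3])),
            rho=float(np.tanh(u[4])),
        )
        k = 5
        if self.drug_effect:
            out["beta_drug"] = float(u[k])
            k += 1
        if self.hazard_kind is not None:
            out["theta3"] = float(u[k])
            k += 1
            if self.hazard_kind != "constant":
                out["theta4"] = float(u[k])
        return out

    def _start(self) -> dict:
        """Crude per-visit latent estimates seed the population parameters."""
        eng, ld = self._engine, self._ld
        prior = -0.5 * (eng.grid / 3.0) ** 2
        d_first = eng.grid[np.argmax(eng.L[:, 0, :] + prior, axis=1)]
        last_v = np.array(
            [np.max(np.nonzero(ld.attended[s])[0]) for s in range(ld.n_subjects)]
        )
        d_last = eng.grid[
            np.argmax(eng.L[np.arange(ld.n_subjects), last_v, :] + prior, axis=1)
        ]
        t_last = np.maximum(ld.times[last_v] / 12.0, 1e-6)
        slopes = (d_last - d_first) / t_last
        ok = ld.times[last_v] > 0
        start = dict(
            theta1=float(np.mean(d_first)),
            theta2=float(np.mean(slopes[ok])) if ok.any() else 0.0,
            omega1=float(max(np.std(d_first) * 0.9, 0.05)),
            omega2=float(max(np.std(slopes[ok]) * 0.5, 0.05)) if ok.any() else 0.1,
            rho=0.0,
            beta_drug=0.0,
        )
        if self.hazard_kind is not None:
            n_drop = int(np.sum(~np.isnan(self._dropout[1])))
            py = float(np.sum(self._dropout[0])) + 1e-6
            start["theta3"] = float(np.log(max(n_drop, 0.5) / py))
            start["theta4"] = 0.0
        return start

    def _hazard_from(self, natural: dict) -> HazardSpec | None:
        if self.hazard_kind is None:
            return None
        return HazardSpec(
            self.hazard_kind,
            natural["theta3"],
            natural.get("theta4") if self.hazard_kind != "constant" else None,
        )

    def loglik(self, natural: dict, method: str = "laplace", n_nodes: int = 5) -> float:
        """Marginal log-likelihood at a natural-scale parameter dict."""
        p = ProgressionParams(
            natural["theta1"], natural["theta2"], natural["omega1"],
            natural["omega2"], natural["rho"], natural.get("beta_drug", 0.0),
        )
        return self._engine.marginal_loglik(
            p.theta1, p.theta2, p.cov, p.beta_drug,
            self._hazard_from(natural), self._dropout, method, n_nodes,
        )

    def fit(
        self,
        method: str = "laplace",
        n_nodes: int = 5,
        start: dict | None = None,
        se: bool = True,
        maxiter: int = 300,
    ) -> "LongitudinalIRTResults":
        names = self._names()
        u0 = self._pack({**self._start(), **(start or {})})

        def nll(u: np.ndarray) -> float:
            nat = self._unpack(u)
            try:
                ll = self.loglik(nat, method=method, n_nodes=n_nodes)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return 1e10
            return -ll if np.isfinite(ll) else 1e10

        res = minimize(
            nll, u0, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10**6},
        )
        natural = self._unpack(res.x)
        bse = pd.Series(np.nan, index=names)
        cov_nat = None
        if se:
            from .comparators import _robust_bse

            Hu = _numerical_hessian(nll, res.x)
            jac = self._natural_jacobian(res.x)
            try:
                cov_u = np.linalg.inv(Hu)
                cov_nat = jac @ cov_u @ jac.T
                d = np.diag(cov_nat)
                if not np.all(d > 0):
                    raise np.linalg.LinAlgError("information not PD")
                bse = pd.Series(np.sqrt(d), index=names)
            except np.linalg.LinAlgError:
                # boundary variance components: salvage the identified block
                bse = pd.Series(_robust_bse(Hu, np.diag(jac)), index=names)
                cov_nat = None
                if bse.isna().all():
                    warnings.warn(
                        "observed information not positive definite; "
                        "standard errors unavailable",
                        stacklevel=2,
                    )
        if abs(natural["rho"]) > 0.97:
            warnings.warn("random-effect correlation near its boundary", stacklevel=2)
        params = ProgressionParams(
            natural["theta1"], natural["theta2"], natural["omega1"],
            natural["omega2"], natural["rho"], natural.get("beta_drug", 0.0),
        )
        return LongitudinalIRTResults(
            model=self,
            progression=params,
            hazard=self._hazard_from(natural),
            estimates=pd.Series({n: natural[n] for n in names}),
            bse=bse,
            cov_params_natural=cov_nat,
            llf=-float(res.fun),
            converged=bool(res.success),
            n_subjects=self._ld.n_subjects,
            n_observations=self._ld.n_observations,
            settings=dict(method=method, n_nodes=n_nodes, maxiter=maxiter),
        )

    def _natural_jacobian(self, u: np.ndarray) -> np.ndarray:
        d = np.ones(len(u))
        d[2] = np.exp(u[2])
        d[3] = np.exp(u[3])
        d[4] = 1.0 - np.tanh(u[4]) ** 2
        return np.diag(d)


def _numerical_hessian(f, x: np.ndarray, h: float = 0.02) -> np.ndarray:
    """Central-difference Hessian.

    The step is deliberately large: the objective carries tiny evaluation
    noise from the interpolated likelihood and warm-started inner modes, and
    the curvature in the drug-effect direction is small, so a naive 1e-4
    step produces a noise-dominated (badly anti-conservative) Hessian.
    Truncation error at h = 0.02 is negligible against the parameter SEs.
    """
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.eye(n)[i] * h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.eye(n)[j] * h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


@dataclass
class LongitudinalIRTResults:
    """Fitted longitudinal IRT model."""

    model: LongitudinalIRT
    progression: ProgressionParams
    hazard: HazardSpec | None
    estimates: pd.Series
    bse: pd.Series
    cov_params_natural: np.ndarray | None
    llf: float
    converged: bool
    n_subjects: int
    n_observations: int
    settings: dict

    @property
    def params(self) -> pd.Series:
        return self.estimates

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        lo = self.estimates - z * self.bse
        hi = self.estimates + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def wald_test_drug(self, alpha: float = 0.05) -> dict:
        """Wald test of the fractional slope-reduction drug effect."""
        if "beta_drug" not in self.estimates.index:
            raise ValueError("model was fitted without a drug effect")
        est = float(self.estimates["beta_drug"])
        se = float(self.bse["beta_drug"])
        z = norm.ppf(1 - alpha / 2)
        lo, hi = est - z * se, est + z * se
        return dict(
            estimate=est, se=se, ci_low=lo, ci_high=hi,
            significant=bool(np.isfinite(se) and (lo > 0 or hi < 0)),
        )

    def random_effects(self) -> pd.DataFrame:
        """Posterior modes of (eta1, eta2) at the final estimates."""
        self.model.loglik(dict(self.estimates))
        eta = self.model._engine.posterior_modes()
        return pd.DataFrame(
            {
                "subject_id": self.model._ld.subjects,
                "eta1": eta[:, 0],
                "eta2": eta[:, 1],
            }
        )

    def summary(self) -> str:
        lines = [
            "Longitudinal IRT progression model (ICCs fixed)",
            f"  subjects: {self.n_subjects}   item observations: "
            f"{self.n_observations}",
            f"  log-likelihood: {self.llf:.2f}   method: "
            f"{self.settings['method']}   converged: {self.converged}",
        ]
        ci = self.conf_int()
        tab = pd.DataFrame(
            {"estimate": self.estimates, "std err": self.bse,
             "[0.025": ci["lower"], "0.975]": ci["upper"]}
        )
        lines.append(tab.to_string(float_format="%.4f"))
        return "\n".join(lines)


def fit_longitudinal(
    data: pd.DataFrame,
    bank: ItemBank,
    hazard_kind: str | None = None,
    **kwargs,
) -> LongitudinalIRTResults:
    """Convenience wrapper: build a :class:`LongitudinalIRT` and fit it."""
    fit_keys = {"method", "n_nodes", "start", "se", "maxiter"}
    fit_kw = {k: kwargs.pop(k) for k in list(kwargs) if k in fit_keys}
    return LongitudinalIRT(data, bank, hazard_kind=hazard_kind, **kwargs).fit(**fit_kw)


def select_hazard(
    data: pd.DataFrame,
    bank: ItemBank,
    alpha: float = 0.05,
    candidates: Sequence[str] = ("disability", "progression_rate", "baseline_disability"),
    **kwargs,
) -> tuple[HazardSpec, pd.DataFrame]:
    """Choose the dropout hazard by likelihood-ratio test against constant.

    Each one-covariate hazard is compared with the constant hazard (1 df);
    among the significant expansions the one with the largest drop in -2LL is
    returned, otherwise the constant hazard.
    """
    crit = chi2.ppf(1 - alpha, df=1)
    base = fit_longitudinal(data, bank, hazard_kind="constant", se=False, **kwargs)
    rows = [dict(kind="constant", llf=base.llf, delta_m2ll=0.0, significant=False)]
    best_kind, best_fit, best_delta = "constant", base, 0.0
    # each expansion starts from the nested constant-hazard optimum, so the
    # likelihood-ratio statistic cannot go negative beyond optimizer slop
    warm = {**dict(base.estimates), "theta4": 0.0}
    for kind in candidates:
        fit = fit_longitudinal(
            data, bank, hazard_kind=kind, se=False, start=warm, **kwargs
        )
        delta = 2.0 * (fit.llf - base.llf)
        sig = delta > crit
        rows.append(dict(kind=kind, llf=fit.llf, delta_m2ll=delta, significant=sig))
        if sig and delta > best_delta:
            best_kind, best_fit, best_delta = kind, fit, delta
    report = pd.DataFrame(rows)
    return best_fit.hazard, report
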