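"""Non-IRT analysis methods used in the power comparison.

Two comparators operate on the familiar total scale score rather than the
item level:

* :func:`ls_means_analysis` -- the classical least-squares-means
  repeated-measures analysis of change from baseline (treatment, visit,
  treatment-by-visit interaction, baseline score as covariate, subjects as
  grouping factor).  With a random subject intercept the within-subject
  covariance is compound-symmetric; without dropout this is the
  mixed-effect model repeated measures (MMRM) analysis.
* :class:`TotalScoreProgression` -- a longitudinal linear
  disease-progression model for the total score with correlated
  baseline/slope random effects, additive residual error and a fractional
  drug effect on the slope.  This is a reconstruction of the standard
  pharmacometric summary-score analysis (the Ito-style linear model); the
  total score is analyzed untransformed.

Both declare a drug effect significant when the 95% Wald confidence
interval of the effect excludes the null value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

import statsmodels.formula.api as smf

__all__ = [
    "AnalysisDecision",
    "ls_means_analysis",
    "TotalScoreProgression",
    "TotalScoreResults",
    "fit_total_score_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class AnalysisDecision:
    """Outcome of one drug-effect analysis of one trial."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    null_value: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            outside = self.null_value < self.ci_low or self.null_value > self.ci_high
            if bool(outside) != bool(self.significant):
                raise ValueError("significance flag inconsistent with the CI")


def _check_totals(totals: pd.DataFrame):
    need = {"subject_id", "time_months", "arm", "total"}
    missing = need - set(totals.columns)
    if missing:
        raise ValueError(f"totals table lacks columns {sorted(missing)}")


def ls_means_analysis(
    totals: pd.DataFrame,
    alpha: float = 0.05,
    covariance: str = "compound_symmetry",
) -> AnalysisDecision:
    """LS-means repeated-measures analysis of change from baseline.

    Fits change-from-baseline ~ treatment + visit + treatment:visit +
    baseline with subjects as random grouping factor and reads the treatment
    difference at the last scheduled visit off the fitted model.
    ``covariance`` is ``compound_symmetry`` (random subject intercept,
    default) or ``unstructured`` (adds a random visit slope -- a pragmatic
    relaxation; a fully unstructured fit is rarely stable at trial sizes).
    """
    _check_totals(totals)
    df = totals.copy()
    base = df[df["time_months"] == 0].set_index("subject_id")["total"]
    post = df[df["time_months"] > 0].copy()
    if post.empty or post["time_months"].nunique() < 2:
        raise ValueError("need >= 2 post-baseline visits")
    post["baseline"] = post["subject_id"].map(base)
    post = post.dropna(subset=["baseline"])
    last = post["time_months"].max()
    for arm in (0, 1):
        if not ((post["arm"] == arm) & (post["time_months"] == last)).any():
            raise ValueError(f"arm {arm} empty at the decision visit")
    post["cfb"] = post["total"] - post["baseline"]
    post["visit"] = post["time_months"].astype(float)

    if float(np.var(post["cfb"])) < 1e-12:
        # degenerate zero-noise data: no estimable variance, no effect
        return AnalysisDecision("ls_means", 0.0, 0.0, 0.0, 0.0, False)

    re_formula = "1" if covariance == "compound_symmetry" else "1 + visit"
    model = smf.mixedlm(
        "cfb ~ C(visit) * arm + baseline",
        post,
        groups=post["subject_id"],
        re_formula=re_formula,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs")
    names = list(res.fe_params.index)
    L = np.zeros(len(names))
    L[names.index("arm")] = 1.0
    inter = f"C(visit)[T.{last}]:arm"
    if inter in names:
        L[names.index(inter)] = 1.0
    est = float(L @ res.fe_params.to_numpy())
    cov = res.cov_params().loc[names, names].to_numpy()
    se = float(np.sqrt(L @ cov @ L))
    z = norm.ppf(1 - alpha / 2)
    lo, hi = est - z * se, est + z * se
    return AnalysisDecision(
        "ls_means", est, se, lo, hi, bool(lo > 0 or hi < 0),
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# pharmacometric total-score model


class TotalScoreProgression:
    """Linear mixed-effects progression model for the total score.

    Score_ij = (B + eta_Bi) + (1 - beta * x_i) (S + eta_Si) t_ij + eps_ij

    with correlated (eta_B, eta_S), additive residual error and time in
    years.  The marginal per-subject distribution is multivariate normal, so
    the likelihood is evaluated in closed form, grouped by arm and visit
    pattern.
    """

    _names_base = ("B", "S", "omega_B", "omega_S", "rho", "sigma")

    def __init__(self, totals: pd.DataFrame, drug_effect: bool | None = None):
        _check_totals(totals)
        df = totals.sort_values(["subject_id", "time_months"], kind="stable")
        self.drug_effect = (
            bool((df["arm"] != 0).any()) if drug_effect is None else drug_effect
        )
        self._groups: list[tuple[np.ndarray, float, np.ndarray]] = []
        pat = df.groupby("subject_id", sort=False).agg(
            x=("arm", "first"),
            times=("time_months", tuple),
        )
        pat["y"] = df.groupby("subject_id", sort=False)["total"].apply(
            lambda s: tuple(s)
        )
        for (x, times), sub in pat.groupby(["x", "times"], sort=False):
            t = np.asarray(times, dtype=float) / 12.0
            Y = np.array([list(y) for y in sub["y"]], dtype=float)
            self._groups.append((t, float(x), Y))
        self.n_subjects = len(pat)
        self.nobs = int(sum(g[2].size for g in self._groups))

    @property
    def _names(self) -> list[str]:
        return list(self._names_base) + (["beta_drug"] if self.drug_effect else [])

    def _nll(self, u: np.ndarray) -> float:
        B, S = u[0], u[1]
        wB, wS = np.exp(u[2]), np.exp(u[3])
        rho = np.tanh(u[4])
        sig = np.exp(u[5])
        beta = u[6] if self.drug_effect else 0.0
        Om = np.array(
            [[wB**2, rho * wB * wS], [rho * wB * wS, wS**2]]
        )
        total = 0.0
        for t, x, Y in self._groups:
            m = 1.0 - beta * x
            Z = np.stack([np.ones_like(t), m * t], axis=1)
            Sig = Z @ Om @ Z.T + sig**2 * np.eye(len(t))
            mu = B + m * S * t
            try:
                Lc = np.linalg.cholesky(Sig)
            except np.linalg.LinAlgError:
                return 1e10
            resid = (Y - mu).T  # (k, n)
            w = np.linalg.solve(Lc, resid)
            n = Y.shape[0]
            total += -0.5 * (
                n * len(t) * _LOG_2PI
                + 2.0 * n * np.log(np.diag(Lc)).sum()
                + np.sum(w**2)
            )
        return -total if np.isfinite(total) else 1e10

    def _start(self) -> np.ndarray:
        # crude per-subject least squares
        b0, sl = [], []
        for t, x, Y in self._groups:
            if len(t) >= 2:
                A = np.stack([np.ones_like(t), t], axis=1)
                coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
                b0.extend(coef[0])
                sl.extend(coef[1])
            else:
                b0.extend(Y[:, 0])
        b0 = np.asarray(b0)
        sl = np.asarray(sl) if sl else np.array([1.0])
        u = np.array(
            [
                float(np.mean(b0)),
                float(np.mean(sl)),
                np.log(max(np.std(b0), 0.5)),
                np.log(max(np.std(sl) * 0.7, 0.2)),
                0.0,
                np.log(2.0),
            ]
        )
        if self.drug_effect:
            u = np.append(u, 0.0)
        return u

    def fit(self, se: bool = True, maxiter: int = 300) -> "TotalScoreResults":
        res = minimize(
            self._nll, self._start(), method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10**6},
        )
        u = res.x
        est = {
            "B": float(u[0]),
            "S": float(u[1]),
            "omega_B": float(np.exp(u[2])),
            "omega_S": float(np.exp(u[3])),
            "rho": float(np.tanh(u[4])),
            "sigma": float(np.exp(u[5])),
        }
        if self.drug_effect:
            est["beta_drug"] = float(u[6])
        bse = pd.Series(np.nan, index=self._names)
        if se:
            H = _hess(self._nll, u)
            jac = np.ones(len(u))
            jac[2], jac[3], jac[5] = np.exp(u[2]), np.exp(u[3]), np.exp(u[5])
            jac[4] = 1.0 - np.tanh(u[4]) ** 2
            bse = pd.Series(
                _robust_bse(H, jac), index=self._names
            )
        return TotalScoreResults(
            model=self,
            estimates=pd.Series(est),
            bse=bse,
            llf=-float(res.fun),
            converged=bool(res.success),
        )


def _robust_bse(H: np.ndarray, jac: np.ndarray) -> np.ndarray:
    """Delta-method SEs, dropping boundary directions with no curvature.

    Variance components at their boundary (omega -> 0, |rho| -> 1) leave the
    observed information singular; the remaining parameters' SEs are taken
    from the non-degenerate submatrix and the boundary ones reported as NaN.
    """
    n = len(jac)
    bse = np.full(n, np.nan)
    d = np.diag(H)
    keep = np.nonzero(d > 1e-8 * max(d.max(), 1.0))[0]
    for attempt in range(len(keep)):
        sub = H[np.ix_(keep, keep)]
        try:
            cov = np.linalg.inv(sub)
            dg = np.diag(cov)
            if np.all(dg > 0):
                bse[keep] = np.sqrt(dg) * jac[keep]
                return bse
        except np.linalg.LinAlgError:
            pass
        # drop the weakest direction and retry
        if len(keep) <= 1:
            break
        keep = np.delete(keep, int(np.argmin(d[keep])))
    return bse


def _hess(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
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
class TotalScoreResults:
    """Fitted total-score progression model."""

    model: TotalScoreProgression
    estimates: pd.Series
    bse: pd.Series
    llf: float
    converged: bool

    @property
    def params(self) -> pd.Series:
        return self.estimates

    def decision(self, alpha: float = 0.05) -> AnalysisDecision:
        if "beta_drug" not in self.estimates.index:
            raise ValueError("model fitted without a drug effect")
        est = float(self.estimates["beta_drug"])
        se = float(self.bse["beta_drug"])
        z = norm.ppf(1 - alpha / 2)
        lo, hi = est - z * se, est + z * se
        sig = bool(np.isfinite(se) and (lo > 0 or hi < 0))
        if not np.isfinite(se):
            lo = hi = np.nan
        return AnalysisDecision(
            "total_score", est, se, lo, hi, sig, converged=self.converged
        )

    def summary(self) -> str:
        tab = pd.DataFrame({"estimate": self.estimates, "std err": self.bse})
        return (
            "Total-score linear progression model\n"
            f"  subjects: {self.model.n_subjects}   observations: "
            f"{self.model.nobs}   log-likelihood: {self.llf:.2f}\n"
            + tab.to_string(float_format="%.4f")
        )


def fit_total_score_model(
    totals: pd.DataFrame, alpha: float = 0.05
) -> AnalysisDecision:
    """Fit the total-score progression model and return its drug decision."""
    return TotalScoreProgression(totals).fit().decision(alpha)
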