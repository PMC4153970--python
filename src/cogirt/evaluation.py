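"""Power and type-I-error estimation across analysis methods.

Each replicate simulates one trial from the longitudinal IRT model and
analyzes it with one or more of the three methods (LS-means, total-score
mixed model, longitudinal IRT).  When several methods are requested they
analyze the *same* simulated trials (common random numbers), which sharpens
the between-method comparison.  Per-replicate seeds derive deterministically
from the master seed, so results are exactly reproducible and trials are
shared across calls with the same design and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .comparators import AnalysisDecision, fit_total_score_model, ls_means_analysis
from .longitudinal import LongitudinalIRT
from .simulate import TrialDesign, simulate_trial, total_score

__all__ = [
    "PowerResult",
    "estimate_power",
    "estimate_type1",
    "power_study",
    "subjects_for_power",
    "analyze_trial",
]

METHODS = ("ls_means", "total_score", "irt")


@dataclass(frozen=True)
class PowerResult:
    """Empirical rejection rate of one method at one sample size."""

    method: str
    n_total: int
    n_replicates: int
    n_significant: int
    n_failed: int
    power: float
    ci_low: float
    ci_high: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power outside [0, 1]")


def _replicate_seed(master: int, rep: int) -> int:
    return int(np.random.SeedSequence([master, rep]).generate_state(1)[0] % (2**31))


def analyze_trial(
    trial, method: str, alpha: float = 0.05
) -> AnalysisDecision:
    """Apply one analysis method to a simulated trial."""
    if method == "irt":
        res = LongitudinalIRT(
            trial.responses, trial.design.bank, drug_effect=True
        ).fit(se=True)
        w = res.wald_test_drug(alpha)
        return AnalysisDecision(
            "irt", w["estimate"], w["se"], w["ci_low"], w["ci_high"],
            w["significant"], converged=res.converged,
        )
    totals = total_score(trial.responses, trial.design.bank)
    if method == "total_score":
        return fit_total_score_model(totals, alpha)
    if method == "ls_means":
        return ls_means_analysis(totals, alpha)
    raise ValueError(f"unknown method {method!r}")


def power_study(
    methods: Sequence[str],
    design: TrialDesign,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    fail_policy: str = "nonsignificant",
    return_decisions: bool = False,
):
    """Rejection rates of several methods on the same simulated trials."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if fail_policy not in ("nonsignificant", "exclude"):
        raise ValueError("fail_policy must be 'nonsignificant' or 'exclude'")
    counts = {m: 0 for m in methods}
    fails = {m: 0 for m in methods}
    decisions: list[dict] = []
    for rep in range(n_replicates):
        trial = simulate_trial(replace(design, seed=_replicate_seed(seed, rep)))
        for m in methods:
            try:
                dec = analyze_trial(trial, m, alpha)
                ok = np.isfinite(dec.se) and dec.se > 0
            except (ValueError, np.linalg.LinAlgError):
                dec, ok = None, False
            if not ok:
                fails[m] += 1
                sig = False
            else:
                sig = dec.significant
            counts[m] += int(sig)
            if return_decisions:
                decisions.append(
                    dict(
                        replicate=rep,
                        method=m,
                        significant=sig,
                        estimate=dec.estimate if dec else np.nan,
                        failed=not ok,
                    )
                )
    out = []
    for m in methods:
        denom = n_replicates - (fails[m] if fail_policy == "exclude" else 0)
        denom = max(denom, 1)
        p = counts[m] / denom
        lo, hi = proportion_confint(counts[m], denom, alpha=0.05, method="wilson")
        out.append(
            PowerResult(
                m, design.n_total, denom, counts[m], fails[m],
                p, float(lo), float(hi), seed,
            )
        )
    if return_decisions:
        return out, pd.DataFrame(decisions)
    return out


def estimate_power(
    method: str,
    design: TrialDesign,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    fail_policy: str = "nonsignificant",
) -> PowerResult:
    """Empirical power of one analysis method under a trial design."""
    return power_study([method], design, n_replicates, seed, alpha, fail_policy)[0]


def estimate_type1(
    method: str,
    design: TrialDesign,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    fail_policy: str = "nonsignificant",
) -> PowerResult:
    """Empirical type-I error: the design is forced to a zero drug effect."""
    null_design = replace(design, params=replace(design.params, beta_drug=0.0))
    return power_study([method], null_design, n_replicates, seed, alpha, fail_policy)[0]


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit (non-decreasing, unit weights)."""
    y = np.asarray(y, dtype=float).copy()
    w = np.ones_like(y)
    # blocks as (value, weight) stacks
    vals: list[float] = []
    wts: list[float] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wt = wts[-2] + wts[-1]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [wt]
    out = []
    i = 0
    # expand blocks back to original length
    lengths = np.asarray(wts, dtype=int)
    for v, k in zip(vals, lengths):
        out.extend([v] * k)
    return np.asarray(out)


def subjects_for_power(
    power_curve, target: float = 0.8
) -> float:
    """Interpolate the number of subjects required for a target power.

    ``power_curve`` is a sequence of :class:`PowerResult` (or a frame with
    ``n_total`` and ``power`` columns).  Monte-Carlo jitter is removed by an
    isotonic (non-decreasing) fit before linear interpolation in ``n``.
    """
    if isinstance(power_curve, pd.DataFrame):
        df = power_curve[["n_total", "power"]].copy()
    else:
        df = pd.DataFrame(
            [(r.n_total, r.power) for r in power_curve], columns=["n_total", "power"]
        )
    if len(df) < 2:
        raise ValueError("need >= 2 grid points")
    df = df.sort_values("n_total")
    n = df["n_total"].to_numpy(dtype=float)
    p = _pava_nondecreasing(df["power"].to_numpy())
    if not (p.min() <= target <= p.max()):
        raise ValueError(
            f"target power {target} outside the observed range "
            f"[{p.min():.3f}, {p.max():.3f}]"
        )
    exact = np.nonzero(np.isclose(df["power"].to_numpy(), target))[0]
    if exact.size:
        return float(n[exact[0]])
    return float(np.interp(target, p, n))
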