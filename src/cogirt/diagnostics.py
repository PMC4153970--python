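"""Simulation-based model checking.

* :func:`icc_vs_smoother` contrasts a fitted item characteristic curve with
  a nonparametric generalized-additive-model smoother of the observed
  outcomes against the empirical Bayes disability estimates (penalized
  cubic B-spline, smoothness chosen by generalized cross-validation; logit
  link for binary outcomes).
* :func:`vpc` produces visual-predictive-check bands: observed statistics
  (item-outcome fractions, total-score percentiles, retention curve) are
  compared with percentile bands over many model-simulated replicate
  trials.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .items import ItemSpec, expected_score
from .simulate import TrialDesign, simulate_trial, total_score

__all__ = ["icc_vs_smoother", "vpc"]


def icc_vs_smoother(
    records: pd.DataFrame,
    ebes: pd.DataFrame,
    item: ItemSpec,
    grid: np.ndarray | None = None,
    df_spline: int = 6,
    by_study: bool = False,
) -> pd.DataFrame:
    """Model ICC vs a cross-validated spline smoother of observed outcomes.

    ``records`` holds this item's observed responses; ``ebes`` the subjects'
    disability estimates (``subject_id``, ``d_hat``).  Returns a tidy frame
    with the model's expected outcome and the smoother with a pointwise 95%
    band on a latent grid (optionally per study).
    """
    from statsmodels.gam.api import BSplines, GLMGam
    import statsmodels.api as sm

    obs = records[records["item_id"] == item.item_id]
    merged = obs.merge(ebes[["subject_id", "d_hat"]], on="subject_id")
    if len(merged) == 0:
        raise ValueError(f"no observations for item {item.item_id!r}")

    strata = (
        [(s, g) for s, g in merged.groupby("study_id")]
        if by_study
        else [("pooled", merged)]
    )
    frames = []
    for label, sub in strata:
        x = sub["d_hat"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        if grid is None:
            ggrid = np.linspace(x.min(), x.max(), 81)
        else:
            ggrid = np.asarray(grid, dtype=float)
        if len(sub) < 30:
            warnings.warn(
                f"only {len(sub)} observations for item {item.item_id!r} "
                f"({label}); smoother band will be wide",
                stacklevel=2,
            )
        if np.ptp(y) == 0.0:
            # constant outcome: the smoother is the flat observed proportion
            sm_mean = np.full_like(ggrid, y[0])
            frames.append(
                pd.DataFrame(
                    {
                        "stratum": label, "D": ggrid,
                        "icc": expected_score(item, ggrid),
                        "smoother": sm_mean, "lo": sm_mean, "hi": sm_mean,
                    }
                )
            )
            continue
        binary = item.family == "binary3pl"
        family = sm.families.Binomial() if binary else sm.families.Gaussian()
        nspl = min(df_spline, max(4, len(np.unique(x)) // 5))
        bs = BSplines(x[:, None], df=[nspl], degree=[3])
        gam = GLMGam(y, np.ones((len(y), 1)), smoother=bs, family=family)
        try:
            alpha = gam.select_penweight(criterion="gcv")[0]
        except Exception:
            alpha = [1.0]
        gam = GLMGam(
            y, np.ones((len(y), 1)), smoother=bs, family=family, alpha=alpha
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gam.fit()
        gx = np.clip(ggrid, x.min(), x.max())
        basis = bs.transform(gx[:, None])
        X = np.column_stack([np.ones(len(gx)), basis])
        eta = X @ res.params
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        if binary:
            inv = res.model.family.link.inverse
            mean, lo, hi = inv(eta), inv(eta - 1.96 * se), inv(eta + 1.96 * se)
        else:
            mean, lo, hi = eta, eta - 1.96 * se, eta + 1.96 * se
        frames.append(
            pd.DataFrame(
                {
                    "stratum": label, "D": ggrid,
                    "icc": expected_score(item, ggrid),
                    "smoother": mean, "lo": lo, "hi": hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _total_stats(totals: pd.DataFrame) -> pd.DataFrame:
    g = totals.groupby("time_months")["total"]
    return pd.DataFrame(
        {
            "median": g.median(),
            "p2.5": g.quantile(0.025),
            "p97.5": g.quantile(0.975),
        }
    )


def _retention(responses: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    att = responses.groupby("subject_id")["time_months"].max()
    n = len(att)
    return np.array([(att >= t).sum() / n for t in times])


def _item_fractions(
    responses: pd.DataFrame, items: list[ItemSpec], times: np.ndarray
) -> pd.DataFrame:
    rows = []
    for it in items:
        sub = responses[responses["item_id"] == it.item_id]
        for t in times:
            at_t = sub[sub["time_months"] == t]["value"]
            n = max(len(at_t), 1)
            for k in it.support:
                rows.append(
                    (it.item_id, int(k), float(t), (at_t == k).sum() / n)
                )
    return pd.DataFrame(rows, columns=["item_id", "outcome", "time_months", "frac"])


def vpc(
    observed: pd.DataFrame,
    design: TrialDesign,
    n_replicates: int = 200,
    level: str = "total",
    seed: int = 0,
    items: list[ItemSpec] | None = None,
) -> pd.DataFrame:
    """Visual predictive check of a fitted model against observed data.

    ``design`` carries the fitted model (progression parameters, hazard,
    bank) and the study design to resimulate; ``observed`` is the observed
    response table.  Returns a tidy band table (stratum, time, observed,
    lo, hi) at the requested ``level``:

    - ``"total"``: median / 2.5th / 97.5th percentile of the total score per
      visit vs their 95% simulation intervals;
    - ``"item"``: per item-outcome fraction of subjects per visit;
    - ``"dropout"``: retention curve.
    """
    if level not in ("item", "total", "dropout"):
        raise ValueError("level must be item, total or dropout")
    obs_times = np.sort(observed["time_months"].unique())
    sched = np.asarray(design.schedule.times, dtype=float)
    if not set(obs_times) <= set(sched):
        raise ValueError(
            f"observed visit times {obs_times.tolist()} not all in the "
            f"design schedule {sched.tolist()}"
        )
    seeds = [
        int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        for r in range(n_replicates)
    ]
    sims = [simulate_trial(replace(design, seed=s)) for s in seeds]

    if level == "total":
        obs_stats = _total_stats(total_score(observed, design.bank))
        reps = np.stack(
            [
                _total_stats(total_score(s.responses, design.bank))
                .loc[obs_stats.index]
                .to_numpy()
                for s in sims
            ]
        )  # (R, T, 3)
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        rows = []
        for j, stat in enumerate(obs_stats.columns):
            for i, t in enumerate(obs_stats.index):
                rows.append(
                    dict(
                        stratum=stat, time_months=float(t),
                        observed=float(obs_stats.iloc[i, j]),
                        lo=float(lo[i, j]), hi=float(hi[i, j]),
                        n_replicates=n_replicates,
                    )
                )
        return pd.DataFrame(rows)

    if level == "dropout":
        obs_ret = _retention(observed, sched)
        reps = np.stack([_retention(s.responses, sched) for s in sims])
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        return pd.DataFrame(
            dict(
                stratum="retention", time_months=sched, observed=obs_ret,
                lo=lo, hi=hi, n_replicates=n_replicates,
            )
        )

    if items is None:
        present = set(observed["item_id"])
        items = [it for it in design.bank.items if it.item_id in present]
    obs_frac = _item_fractions(observed, items, obs_times)
    reps = np.stack(
        [
            _item_fractions(s.responses, items, obs_times)["frac"].to_numpy()
            for s in sims
        ]
    )
    obs_frac["lo"] = np.percentile(reps, 2.5, axis=0)
    obs_frac["hi"] = np.percentile(reps, 97.5, axis=0)
    obs_frac["n_replicates"] = n_replicates
    obs_frac = obs_frac.rename(columns={"frac": "observed"})
    obs_frac["stratum"] = (
        obs_frac["item_id"] + "=" + obs_frac["outcome"].astype(str)
    )
    return obs_frac[
        ["stratum", "item_id", "outcome", "time_months", "observed", "lo", "hi",
         "n_replicates"]
    ]
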