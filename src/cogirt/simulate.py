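"""Clinical-trial and multi-study synthetic data generation.

Simulates item-level response datasets with exactly the statistical
structure the models assume: a standard-normal baseline disability for
cross-sectional multi-study data (with per-study assessment variants), and
correlated baseline/slope random effects, an optional multiplicative drug
effect on the progression rate, and hazard-based monotone dropout for
longitudinal trials.  Also maps item responses back to component scores and
the familiar total scale score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .items import ItemBank, ItemSpec, sample_item
from .longitudinal import (
    HazardSpec,
    ProgressionParams,
    VisitSchedule,
    _cum_hazard,
)

__all__ = [
    "TrialDesign",
    "SimulatedTrial",
    "simulate_trial",
    "simulate_baseline_studies",
    "total_score",
    "DEFAULT_BASELINE_STUDIES",
]

#: study sizes and assessment variants of the emulated pooled baseline
#: databases (subject counts per study; variants live in the default bank)
DEFAULT_BASELINE_STUDIES = (
    ("ADNI", 819),
    ("CAMD_1131", 57),
    ("CAMD_1132", 412),
    ("CAMD_1137", 216),
    ("CAMD_1138", 202),
    ("CAMD_1140", 137),
    ("CAMD_1141", 492),
    ("CAMD_1142", 409),
)

_COLUMNS = ["subject_id", "study_id", "time_months", "arm", "item_id", "value"]


@dataclass(frozen=True)
class TrialDesign:
    """Design of one simulated parallel-arm trial."""

    n_total: int
    params: ProgressionParams
    bank: ItemBank
    schedule: VisitSchedule
    allocation: float = 0.5
    hazard: HazardSpec | None = None
    variant: str | None = None  # study-variant item mask; None = whole bank
    study_id: str = "SIM"
    seed: int | None = None

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not 0.0 <= self.allocation <= 1.0:
            raise ValueError("allocation must lie in [0, 1]")
        if self.variant is not None and self.variant not in self.bank.study_variants:
            raise ValueError(f"unknown study variant {self.variant!r}")


@dataclass
class SimulatedTrial:
    """One simulated trial: responses, dropout intervals and the truth."""

    responses: pd.DataFrame
    dropout: pd.DataFrame
    truth: pd.DataFrame
    design: TrialDesign

    def totals(self) -> pd.DataFrame:
        return total_score(self.responses, self.design.bank)


def _chol2(params: ProgressionParams) -> np.ndarray:
    """Cholesky factor of the random-effect covariance; valid at zero SDs."""
    return np.array(
        [
            [params.omega1, 0.0],
            [params.rho * params.omega2,
             params.omega2 * np.sqrt(max(1.0 - params.rho**2, 0.0))],
        ]
    )


def _sample_dropout_years(rng, d0, slope, hazard: HazardSpec) -> np.ndarray:
    """Inverse-CDF dropout times; inf where the subject never drops out."""
    u = rng.random(d0.shape)
    target = -np.log(u)  # solve cumulative hazard H(t) = target
    if hazard.kind == "constant":
        rate = np.full_like(d0, np.exp(hazard.theta3))
        return target / rate
    if hazard.kind == "progression_rate":
        return target / np.exp(hazard.theta3 + hazard.theta4 * slope)
    if hazard.kind == "baseline_disability":
        return target / np.exp(hazard.theta3 + hazard.theta4 * d0)
    # time-varying hazard: H(t) = base (exp(r t) - 1) / r
    base = np.exp(hazard.theta3 + hazard.theta4 * d0)
    r = hazard.theta4 * slope
    small = np.abs(r) < 1e-12
    rr = np.where(small, 1.0, r)
    arg = 1.0 + target * rr / base
    t = np.where(
        small,
        target / base,
        np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / rr, np.inf),
    )
    return t


def simulate_trial(design: TrialDesign) -> SimulatedTrial:
    """Simulate one parallel-arm longitudinal trial at the item level.

    Random effects are drawn from the correlated bivariate normal, the
    treated arm's progression rate is scaled by ``1 - beta_drug``, items are
    sampled at every attended visit, and dropout times (when a hazard is
    given) come from the subject-specific survival function by inverse
    transform; records after the dropout interval opens are removed.
    """
    rng = np.random.default_rng(design.seed)
    p = design.params
    n = design.n_total
    subjects = np.array([f"S{i + 1:05d}" for i in range(n)])
    n_treat = int(round(n * design.allocation))
    x = np.zeros(n, dtype=int)
    x[rng.permutation(n)[:n_treat]] = 1
    eta = rng.standard_normal((n, 2)) @ _chol2(p).T
    d0 = p.theta1 + eta[:, 0]
    slope = (1.0 - p.beta_drug * x) * (p.theta2 + eta[:, 1])

    times = np.asarray(design.schedule.times, dtype=float)
    t_years = times / 12.0
    if design.hazard is not None:
        t_drop = _sample_dropout_years(rng, d0, slope, design.hazard)
    else:
        t_drop = np.full(n, np.inf)
    attended = t_years[None, :] < t_drop[:, None]
    attended[:, 0] = True  # everyone is assessed at baseline

    items = (
        design.bank.variant_items(design.variant)
        if design.variant is not None
        else list(design.bank.items)
    )
    D = d0[:, None] + slope[:, None] * t_years[None, :]
    frames = []
    for item in items:
        for v, tm in enumerate(times):
            rows = np.nonzero(attended[:, v])[0]
            vals = sample_item(D[rows, v], item, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects[rows],
                        "study_id": design.study_id,
                        "arm": x[rows],
                        "time_months": tm,
                        "item_id": item.item_id,
                        "value": vals,
                    }
                )
            )
    responses = pd.concat(frames, ignore_index=True)
    responses = responses.sort_values(
        ["subject_id", "time_months", "item_id"], kind="stable"
    ).reset_index(drop=True)[_COLUMNS]

    last_idx = attended.shape[1] - 1 - np.argmax(attended[:, ::-1], axis=1)
    last_seen = times[last_idx]
    first_missed = np.where(
        last_idx < len(times) - 1, times[np.minimum(last_idx + 1, len(times) - 1)],
        np.nan,
    )
    dropout = pd.DataFrame(
        {
            "subject_id": subjects,
            "last_seen_months": last_seen,
            "first_missed_months": first_missed,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": subjects,
            "arm": x,
            "eta1": eta[:, 0],
            "eta2": eta[:, 1],
            "d0": d0,
            "slope": slope,
            "dropout_months": np.where(np.isfinite(t_drop), t_drop * 12.0, np.nan),
        }
    )
    return SimulatedTrial(responses, dropout, truth, design)


def simulate_baseline_studies(
    bank: ItemBank,
    study_specs: Sequence[tuple[str, int]] | Sequence[tuple[str, int, str]] = DEFAULT_BASELINE_STUDIES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate pooled cross-sectional baseline data from several studies.

    ``study_specs`` lists ``(study_id, n_subjects)`` (the study id doubles as
    the bank's variant key) or ``(study_id, n_subjects, variant)``.  Each
    subject's disability is drawn from N(0, 1) and every administered item is
    sampled once.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for spec in study_specs:
        study, n = spec[0], int(spec[1])
        variant = spec[2] if len(spec) > 2 else study
        items = list(bank.items) if variant is None else bank.variant_items(variant)
        if n == 0:
            continue
        D = rng.standard_normal(n)
        subjects = np.array([f"{study}_S{i + 1:04d}" for i in range(n)])
        for item in items:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects,
                        "study_id": study,
                        "arm": 0,
                        "time_months": 0.0,
                        "item_id": item.item_id,
                        "value": sample_item(D, item, rng),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["study_id", "subject_id", "item_id"], kind="stable"
    ).reset_index(drop=True)[_COLUMNS]


def total_score(
    responses: pd.DataFrame,
    bank: ItemBank,
    per_component: bool = False,
) -> pd.DataFrame:
    """Map item responses to component scores and the total scale score.

    The total sums the components flagged ``in_total`` in the bank's score
    map (components a study variant did not administer are simply absent).
    Partially missing ``sum``-rule components are prorated to the subject's
    administered item count; ``mean_round`` components average their
    repetitions; ``binned`` components map a count through score bins.
    """
    if not bank.score_map:
        raise ValueError("bank has no score_map")
    comps = bank.score_map["components"]
    item_to_comp = {}
    for name, spec in comps.items():
        for iid in spec["items"]:
            item_to_comp[iid] = name
    df = responses.copy()
    unknown = set(df["item_id"]) - set(item_to_comp)
    if unknown:
        raise ValueError(f"items not covered by score_map: {sorted(unknown)}")
    df["component"] = df["item_id"].map(item_to_comp)

    keys = ["subject_id", "time_months"]
    has_arm = "arm" in df.columns
    g = df.groupby(keys + ["component"], sort=True)["value"]
    agg = g.agg(vsum="sum", vmean="mean", vcount="count", vfirst="first").reset_index()

    # per-subject administered item count per component (dropout-robust)
    n_admin = (
        df.groupby(["subject_id", "component"])["item_id"]
        .nunique()
        .rename("n_admin")
        .reset_index()
    )
    agg = agg.merge(n_admin, on=["subject_id", "component"], how="left")

    rule = agg["component"].map({c: s["rule"] for c, s in comps.items()})
    score = np.empty(len(agg))
    m = (rule == "sum").to_numpy()
    score[m] = np.rint(
        agg.loc[m, "vsum"] * agg.loc[m, "n_admin"] / agg.loc[m, "vcount"]
    )
    m = (rule == "mean_round").to_numpy()
    score[m] = np.rint(agg.loc[m, "vmean"])
    m = (rule == "binned").to_numpy()
    if m.any():
        for comp, spec in comps.items():
            if spec["rule"] != "binned":
                continue
            mm = m & (agg["component"] == comp).to_numpy()
            edges = np.asarray(spec["edges"], dtype=float)
            score[mm] = (
                agg.loc[mm, "vfirst"].to_numpy()[:, None] <= edges[None, :]
            ).sum(axis=1)
    agg["score"] = score
    agg["in_total"] = agg["component"].map(
        {c: bool(s.get("in_total", True)) for c, s in comps.items()}
    )

    total = (
        agg.loc[agg["in_total"]]
        .groupby(keys, sort=True)["score"]
        .sum()
        .rename("total")
        .reset_index()
    )
    if per_component:
        wide = agg.pivot_table(
            index=keys, columns="component", values="score", aggfunc="first"
        ).reset_index()
        total = wide.merge(total, on=keys, how="left")
    if has_arm:
        arms = df.groupby("subject_id", sort=False)["arm"].first().reset_index()
        total = total.merge(arms, on="subject_id", how="left")
        cols = [c for c in total.columns if c not in ("arm", "total")]
        total = total[cols + ["arm", "total"]]
    return total
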