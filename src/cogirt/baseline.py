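"""Marginal-likelihood estimation of the cross-sectional (baseline) IRT model.

The latent cognitive disability ``D`` is a subject-level random effect with a
fixed N(0, 1) distribution (this anchors the scale and location of the latent
axis).  Item parameters are estimated by maximizing the marginal likelihood

    L = prod_i  integral  prod_j P(y_ij | D)  phi(D)  dD

with the integral approximated by fixed-grid Gauss-Hermite quadrature
(Bock-Aitkin marginal maximum likelihood), per-subject adaptive Gauss-Hermite,
or the Laplace approximation.  Missing-by-design items (study variants) are
simply absent from a subject's likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .items import ItemBank, ItemSpec, dlogpmf_table, logpmf_table

__all__ = [
    "BaselineIRT",
    "BaselineIRTResults",
    "fit_baseline",
    "marginal_loglik_subject",
    "estimate_ebe",
    "gh_nodes",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/log-weights rescaled to a standard normal weight."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), np.log(w) - 0.5 * np.log(np.pi)


# ---------------------------------------------------------------------------
# long-format data -> per-item index arrays


class _ItemData:
    """Per-item (subject-row, value) arrays extracted from a long table."""

    def __init__(self, data: pd.DataFrame, bank: ItemBank):
        if len(data) == 0:
            raise ValueError("no response records")
        unknown = set(data["item_id"]) - set(bank.item_ids)
        if unknown:
            raise ValueError(f"unknown item ids in data: {sorted(unknown)}")
        self.subjects = np.asarray(pd.unique(data["subject_id"]))
        sub_idx = pd.Series(
            np.arange(len(self.subjects)), index=self.subjects
        )
        rows = sub_idx[data["subject_id"]].to_numpy()
        vals = data["value"].to_numpy(dtype=int)
        icodes = data["item_id"].to_numpy()
        self.items: list[ItemSpec] = []
        self.obs_rows: list[np.ndarray] = []
        self.obs_vals: list[np.ndarray] = []
        for it in bank.items:
            m = icodes == it.item_id
            if not m.any():
                continue
            v = vals[m]
            lo, hi = it.support[0], it.support[-1]
            if v.min() < lo or v.max() > hi:
                raise ValueError(
                    f"values outside support {lo}..{hi} for item {it.item_id!r}"
                )
            self.items.append(it)
            self.obs_rows.append(rows[m])
            self.obs_vals.append(v)
        self.n_subjects = len(self.subjects)
        self.n_observations = int(sum(len(v) for v in self.obs_vals))

    def loglik_grid(self, grid: np.ndarray) -> np.ndarray:
        """Sum of item log-likelihoods, shape (n_subjects, len(grid))."""
        L = np.zeros((self.n_subjects, grid.size))
        for it, rows, vals in zip(self.items, self.obs_rows, self.obs_vals):
            table = logpmf_table(it, grid)  # (K, Q)
            np.add.at(L, rows, table[vals])
        return L

    def dloglik_at(self, D: np.ndarray) -> np.ndarray:
        """Gradient of the data log-likelihood wrt each subject's own D."""
        g = np.zeros(self.n_subjects)
        for it, rows, vals in zip(self.items, self.obs_rows, self.obs_vals):
            table = dlogpmf_table(it, D[rows])  # (K, n_obs)
            np.add.at(g, rows, table[vals, np.arange(len(vals))])
        return g

    def loglik_at(self, D: np.ndarray) -> np.ndarray:
        f = np.zeros(self.n_subjects)
        for it, rows, vals in zip(self.items, self.obs_rows, self.obs_vals):
            table = logpmf_table(it, D[rows])
            np.add.at(f, rows, table[vals, np.arange(len(vals))])
        return f


def _posterior_modes(idx: _ItemData, tol: float = 1e-10, maxiter: int = 50):
    """Vectorized Newton search for per-subject posterior modes of D.

    Returns (mode, curvature) where curvature = -g''(mode) > 0 includes the
    N(0,1) prior term.
    """
    D = np.zeros(idx.n_subjects)
    h = 1e-5
    for _ in range(maxiter):
        g1 = idx.dloglik_at(D) - D
        g2 = (idx.dloglik_at(D + h) - idx.dloglik_at(D - h)) / (2 * h) - 1.0
        g2 = np.minimum(g2, -1e-8)
        step = np.clip(-g1 / g2, -1.0, 1.0)
        D = np.clip(D + step, -10.0, 10.0)
        if np.max(np.abs(step)) < tol:
            break
    curv = -((idx.dloglik_at(D + h) - idx.dloglik_at(D - h)) / (2 * h) - 1.0)
    return D, np.maximum(curv, 1e-8)


def _marginal_loglik_subjects(
    idx: _ItemData, method: str, n_nodes: int
) -> np.ndarray:
    """Per-subject log marginal likelihood under the N(0,1) latent prior."""
    if method in ("gauss_hermite", "gh"):
        z, logw = gh_nodes(n_nodes)
        L = idx.loglik_grid(z)
        return logsumexp(L + logw, axis=1)
    mode, curv = _posterior_modes(idx)
    log_prior = -0.5 * (_LOG_2PI + mode**2)
    if method == "laplace":
        g = idx.loglik_at(mode) + log_prior
        return g + 0.5 * _LOG_2PI - 0.5 * np.log(curv)
    if method in ("adaptive_gauss_hermite", "agh"):
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        sd = 1.0 / np.sqrt(curv)
        terms = np.empty((idx.n_subjects, n_nodes))
        for q in range(n_nodes):
            Dq = mode + np.sqrt(2.0) * sd * x[q]
            g = idx.loglik_at(Dq) - 0.5 * (_LOG_2PI + Dq**2)
            terms[:, q] = np.log(w[q]) + x[q] ** 2 + g
        return logsumexp(terms, axis=1) + 0.5 * np.log(2.0) + np.log(sd)
    raise ValueError(f"unknown method {method!r}")


def marginal_loglik_subject(
    records: pd.DataFrame,
    bank: ItemBank,
    method: str = "adaptive_gauss_hermite",
    n_nodes: int = 7,
) -> float:
    """Log marginal likelihood of one subject's responses.

    ``records`` is a long-format frame (``item_id``, ``value``; other columns
    ignored) for a single subject.
    """
    if len(records) == 0:
        raise ValueError("no response records for subject")
    if records["subject_id"].nunique() > 1 if "subject_id" in records else False:
        raise ValueError("records span multiple subjects")
    df = records.copy()
    df["subject_id"] = "s"
    idx = _ItemData(df, bank)
    if method != "laplace" and n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return float(_marginal_loglik_subjects(idx, method, n_nodes)[0])


def fit_baseline(data: pd.DataFrame, bank: ItemBank, **kwargs) -> "BaselineIRTResults":
    """Convenience wrapper: build a :class:`BaselineIRT` and fit it."""
    fit_keys = {"method", "n_nodes", "start_bank", "maxiter", "gtol"}
    fit_kw = {k: kwargs.pop(k) for k in list(kwargs) if k in fit_keys}
    return BaselineIRT(data, bank, **kwargs).fit(**fit_kw)


@dataclass
class EBE:
    """Empirical Bayes estimate of one subject's cognitive disability."""

    subject_id: object
    d_hat: float
    d_sd: float


def estimate_ebe(
    records: pd.DataFrame,
    bank: ItemBank,
    subjects: Sequence | None = None,
) -> pd.DataFrame:
    """Posterior modes and curvature SDs of D for every subject in ``records``.

    Subjects listed in ``subjects`` but absent from the data fall back to the
    prior (d_hat = 0, d_sd = 1) with a warning.
    """
    out_subjects: list = []
    d_hat: list[float] = []
    d_sd: list[float] = []
    if len(records):
        idx = _ItemData(records, bank)
        mode, curv = _posterior_modes(idx)
        out_subjects = list(idx.subjects)
        d_hat = list(mode)
        d_sd = list(1.0 / np.sqrt(curv))
    if subjects is not None:
        missing = [s for s in subjects if s not in set(out_subjects)]
        if missing:
            warnings.warn(
                f"{len(missing)} subject(s) without records: EBE set to the prior",
                stacklevel=2,
            )
            out_subjects += missing
            d_hat += [0.0] * len(missing)
            d_sd += [1.0] * len(missing)
    return pd.DataFrame({"subject_id": out_subjects, "d_hat": d_hat, "d_sd": d_sd})


# ---------------------------------------------------------------------------
# parameter packing (natural scale <-> unconstrained optimizer scale)


def _free_param_names(item: ItemSpec) -> list[str]:
    fam = item.family
    if fam in ("binary3pl", "binomial_words"):
        return ["a", "b", "c"]
    if fam == "word_recognition":
        return ["a", "b", "c", "d"]
    if fam == "gen_poisson_count":
        return ["a", "b", "d", "delta"]
    return ["a"] + [f"b{k + 1}" for k in range(item.n_categories - 1)]


def _pack_item(item: ItemSpec) -> np.ndarray:
    fam = item.family
    if fam == "ordered_categorical":
        b = np.asarray(item.b)
        inc = np.maximum(np.diff(b), 1e-4)
        return np.concatenate([[np.log(item.a), b[0]], np.log(inc)])
    u = [np.log(item.a), item.b]
    if fam in ("binary3pl", "binomial_words"):
        u.append(_logit(item.c))
    elif fam == "word_recognition":
        u.append(_logit(item.c))
        u.append(_logit((item.d - item.c) / (1.0 - item.c)))
    else:  # gen_poisson_count: the mean bound cannot exceed the count support
        u.append(_logit(item.d / item.max_count))
        # classical generalized-Poisson dispersion constraint |delta| < 1
        u.append(np.arctanh(np.clip(item.delta, -0.99, 0.99)))
    return np.asarray(u, dtype=float)


def _unpack_item(item: ItemSpec, u: np.ndarray) -> ItemSpec:
    fam = item.family
    if fam == "ordered_categorical":
        b0 = u[1]
        b = b0 + np.concatenate([[0.0], np.cumsum(np.exp(u[2:]))])
        return item.replace(a=float(np.exp(u[0])), b=tuple(float(x) for x in b))
    a, b = float(np.exp(u[0])), float(u[1])
    if fam in ("binary3pl", "binomial_words"):
        return item.replace(a=a, b=b, c=float(_expit(u[2])))
    if fam == "word_recognition":
        c = float(_expit(u[2]))
        d = c + (1.0 - c) * float(_expit(u[3]))
        return item.replace(a=a, b=b, c=c, d=d)
    return item.replace(
        a=a, b=b, d=float(item.max_count * _expit(u[2])),
        delta=float(np.tanh(u[3])),
    )


def _item_bounds(item: ItemSpec) -> list[tuple[float, float]]:
    """Optimizer box bounds on the estimation scale.

    Difficulties are confined to +-6 latent SDs and probabilities kept off
    the logit asymptotes; these act as sanity rails, not tuning knobs.
    """
    loga = (np.log(0.05), np.log(20.0))
    loc = (-6.0, 6.0)
    logit = (-8.0, 8.0)
    fam = item.family
    if fam == "ordered_categorical":
        return [loga, loc] + [(np.log(1e-3), np.log(6.0))] * (item.n_categories - 2)
    if fam in ("binary3pl", "binomial_words"):
        return [loga, loc, logit]
    if fam == "word_recognition":
        return [loga, loc, logit, logit]
    return [loga, loc, logit, (-3.0, 3.0)]


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


_DEFAULT_START = {
    "binary3pl": dict(a=1.0, b=0.0, c=0.05),
    "binomial_words": dict(a=1.0, b=0.0, c=0.05),
    "word_recognition": dict(a=1.0, b=0.0, c=0.05, d=0.95),
    "gen_poisson_count": dict(a=1.0, b=0.0, d=30.0, delta=0.0),
}


def _starting_item(item: ItemSpec) -> ItemSpec:
    if item.family == "ordered_categorical":
        b = tuple(np.linspace(-1.0, 2.0, item.n_categories - 1))
        return item.replace(a=1.0, b=b)
    return item.replace(**_DEFAULT_START[item.family])


# ---------------------------------------------------------------------------
# model / results


class BaselineIRT:
    """Cross-sectional IRT model with all item parameters free.

    Parameters
    ----------
    data : long-format response table with at least ``subject_id``,
        ``item_id`` and ``value`` columns.  Multi-study pooling needs no
        special handling: items a study did not administer are simply absent
        from its subjects' likelihoods.
    bank : :class:`~cogirt.items.ItemBank` defining families and structure;
        its parameter values seed nothing (estimation starts from standard
        starting values unless ``start_bank`` is passed to ``fit``).
    min_subjects_per_item : items answered by fewer subjects (or with a
        degenerate all-min/all-max response pattern) are held at their
        starting values with a named warning.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        bank: ItemBank,
        min_subjects_per_item: int = 20,
    ):
        self.data = data
        self.bank = bank
        self.min_subjects_per_item = min_subjects_per_item
        self._idx = _ItemData(data, bank)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, bank: ItemBank, **kw):
        return cls(data, bank, **kw)

    def fit(
        self,
        method: str = "gauss_hermite",
        n_nodes: int = 41,
        start_bank: ItemBank | None = None,
        maxiter: int = 400,
        gtol: float = 1e-5,
    ) -> "BaselineIRTResults":
        idx = self._idx
        items = idx.items
        start_items = []
        fixed = np.zeros(len(items), dtype=bool)
        for j, it in enumerate(items):
            s = (start_bank or self.bank)[it.item_id] if start_bank else _starting_item(it)
            vals = idx.obs_vals[j]
            degenerate = vals.min() == vals.max()
            if len(vals) < self.min_subjects_per_item or degenerate:
                why = "degenerate responses" if degenerate else "too few subjects"
                warnings.warn(
                    f"item {it.item_id!r} not identified ({why}); "
                    "parameters held at starting values",
                    stacklevel=2,
                )
                fixed[j] = True
            start_items.append(s)

        blocks = [_pack_item(s) for s in start_items]
        sizes = [len(b) for b in blocks]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        free_mask = np.concatenate(
            [np.full(n, not f) for n, f in zip(sizes, fixed)]
        ).astype(bool)
        u_full = np.concatenate(blocks)
        z, logw = gh_nodes(n_nodes)

        def unpack(u_free: np.ndarray) -> list[ItemSpec]:
            u = u_full.copy()
            u[free_mask] = u_free
            return [
                _unpack_item(it, u[offsets[j] : offsets[j + 1]])
                for j, it in enumerate(items)
            ]

        free_global = np.nonzero(free_mask)[0]
        # map each free parameter to its item for incremental gradients
        param_item = np.concatenate(
            [np.full(n, j) for j, n in enumerate(sizes)]
        )[free_mask]

        def nll(u_free: np.ndarray) -> float:
            cur = unpack(u_free)
            try:
                if method in ("gauss_hermite", "gh"):
                    L = np.zeros((idx.n_subjects, z.size))
                    for j, it in enumerate(cur):
                        table = logpmf_table(it, z)
                        L[idx.obs_rows[j]] += table[idx.obs_vals[j]]
                    ll = float(np.sum(logsumexp(L + logw, axis=1)))
                else:
                    tmp = _ItemData.__new__(_ItemData)
                    tmp.items = cur
                    tmp.obs_rows = idx.obs_rows
                    tmp.obs_vals = idx.obs_vals
                    tmp.n_subjects = idx.n_subjects
                    ll = float(np.sum(_marginal_loglik_subjects(tmp, method, n_nodes)))
            except (ValueError, FloatingPointError):
                return 1e10
            if not np.isfinite(ll):
                return 1e10
            return -ll

        def nll_and_grad(u_free: np.ndarray):
            """Objective with a forward-difference gradient that exploits
            parameter separability: perturbing one item's parameter only
            changes that item's likelihood rows."""
            cur = unpack(u_free)
            try:
                gathered = []
                L = np.zeros((idx.n_subjects, z.size))
                for j, it in enumerate(cur):
                    C = logpmf_table(it, z)[idx.obs_vals[j]]  # (n_obs_j, Q)
                    gathered.append(C)
                    L[idx.obs_rows[j]] += C
                per_subj = logsumexp(L + logw, axis=1)
                f0 = -float(per_subj.sum())
            except (ValueError, FloatingPointError):
                return 1e10, np.zeros(u_free.size)
            if not np.isfinite(f0):
                return 1e10, np.zeros(u_free.size)
            grad = np.zeros(u_free.size)
            h = 1e-6
            for p in range(u_free.size):
                j = param_item[p]
                u2 = u_full.copy()
                u2[free_mask] = u_free
                u2[free_global[p]] += h
                it2 = _unpack_item(items[j], u2[offsets[j] : offsets[j + 1]])
                try:
                    C2 = logpmf_table(it2, z)[idx.obs_vals[j]]
                except (ValueError, FloatingPointError):
                    grad[p] = 0.0
                    continue
                rows = idx.obs_rows[j]
                Lrows = L[rows] - gathered[j] + C2
                new_ls = logsumexp(Lrows + logw, axis=1)
                f_new = f0 + float(per_subj[rows].sum() - new_ls.sum())
                grad[p] = (f_new - f0) / h
            return f0, grad

        bounds_full = [bb for it in start_items for bb in _item_bounds(it)]
        bounds = [b for b, fm in zip(bounds_full, free_mask) if fm]
        if method in ("gauss_hermite", "gh"):
            res = minimize(
                nll_and_grad,
                u_full[free_mask],
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "gtol": gtol, "maxfun": 10**6},
            )
        else:
            res = minimize(
                nll,
                u_full[free_mask],
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "gtol": gtol, "maxfun": 10**6},
            )
        fitted_items = unpack(res.x)
        bank_hat = self.bank.replace_items({it.item_id: it for it in fitted_items})
        return BaselineIRTResults(
            model=self,
            bank_hat=bank_hat,
            llf=-float(res.fun),
            converged=bool(res.success),
            n_subjects=idx.n_subjects,
            n_observations=idx.n_observations,
            settings=dict(method=method, n_nodes=n_nodes, maxiter=maxiter, gtol=gtol),
            fixed_items=[it.item_id for j, it in enumerate(items) if fixed[j]],
            n_free_params=int(free_mask.sum()),
        )


    def asymptotic_se(
        self, at_bank: ItemBank, n_nodes: int = 41, h: float = 1e-4
    ) -> pd.DataFrame:
        """Observed-information standard errors of the item parameters.

        Evaluated at the parameter values carried by ``at_bank`` (typically a
        fitted bank), from a finite-difference Hessian of the marginal
        log-likelihood on the estimation scale, delta-methoded back to the
        natural scale.  One row per (item, parameter).
        """
        idx = self._idx
        items = idx.items
        cur = [at_bank[it.item_id] for it in items]
        blocks = [_pack_item(it) for it in cur]
        sizes = [len(b) for b in blocks]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        u0 = np.concatenate(blocks)
        z, logw = gh_nodes(n_nodes)
        param_item = np.concatenate(
            [np.full(n, j) for j, n in enumerate(sizes)]
        )

        def grad(u: np.ndarray) -> np.ndarray:
            its = [
                _unpack_item(it, u[offsets[j] : offsets[j + 1]])
                for j, it in enumerate(items)
            ]
            gathered = []
            L = np.zeros((idx.n_subjects, z.size))
            for j, it in enumerate(its):
                C = logpmf_table(it, z)[idx.obs_vals[j]]
                gathered.append(C)
                L[idx.obs_rows[j]] += C
            per_subj = logsumexp(L + logw, axis=1)
            f0 = -float(per_subj.sum())
            g = np.zeros(u.size)
            hg = 1e-6
            for p in range(u.size):
                j = param_item[p]
                u2 = u.copy()
                u2[p] += hg
                it2 = _unpack_item(items[j], u2[offsets[j] : offsets[j + 1]])
                C2 = logpmf_table(it2, z)[idx.obs_vals[j]]
                rows = idx.obs_rows[j]
                new_ls = logsumexp(L[rows] - gathered[j] + C2 + logw, axis=1)
                g[p] = (f0 + float(per_subj[rows].sum() - new_ls.sum()) - f0) / hg
            return g

        n = u0.size
        H = np.zeros((n, n))
        g0 = grad(u0)
        for i in range(n):
            u2 = u0.copy()
            u2[i] += h
            H[:, i] = (grad(u2) - g0) / h
        H = (H + H.T) / 2.0
        try:
            cov = np.linalg.inv(H)
            se_packed = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se_packed = np.full(n, np.nan)

        rows = []
        for j, it in enumerate(cur):
            names = _free_param_names(it)
            u = blocks[j]
            for m, name in enumerate(names):
                sp = se_packed[offsets[j] + m]
                if name == "a":
                    nat = sp * it.a
                elif name == "c":
                    nat = sp * it.c * (1 - it.c)
                elif name == "d" and it.family == "word_recognition":
                    q = (it.d - it.c) / (1 - it.c)
                    nat = sp * (1 - it.c) * q * (1 - q)
                elif name == "d" and it.family == "gen_poisson_count":
                    q = it.d / it.max_count
                    nat = sp * it.max_count * q * (1 - q)
                elif name == "delta":
                    nat = sp * (1 - it.delta**2)
                elif (
                    it.family == "ordered_categorical"
                    and name.startswith("b")
                    and name != "b1"
                ):
                    # log-increment scale; approximate marginal SE
                    k = int(name[1:])
                    nat = sp * (it.b[k - 1] - it.b[k - 2])
                else:  # location-type parameters are untransformed
                    nat = sp
                rows.append(
                    dict(item_id=it.item_id, param=name, se=float(nat))
                )
        return pd.DataFrame(rows)


@dataclass
class BaselineIRTResults:
    """Fitted baseline IRT model: estimated bank, fit metadata, EBEs."""

    model: BaselineIRT
    bank_hat: ItemBank
    llf: float
    converged: bool
    n_subjects: int
    n_observations: int
    settings: dict
    fixed_items: list[str] = field(default_factory=list)
    n_free_params: int = 0

    @property
    def params(self) -> pd.DataFrame:
        """Estimated item parameters on the natural scale, one row per item."""
        rows = []
        for it in self.bank_hat.items:
            if it.item_id not in {i.item_id for i in self.model._idx.items}:
                continue
            row = dict(item_id=it.item_id, component=it.component, family=it.family)
            for name in _free_param_names(it):
                if name.startswith("b") and it.family == "ordered_categorical":
                    if name == "a":
                        continue
                    row[name] = it.b[int(name[1:]) - 1]
                else:
                    row[name] = getattr(it, name)
            rows.append(row)
        return pd.DataFrame(rows)

    def ebe(self) -> pd.DataFrame:
        """Empirical Bayes disability estimates under the fitted bank."""
        return estimate_ebe(self.model.data, self.bank_hat)

    def summary(self) -> str:
        lines = [
            "Baseline IRT model (latent disability ~ N(0,1))",
            f"  subjects: {self.n_subjects}   observations: {self.n_observations}",
            f"  free parameters: {self.n_free_params}   "
            f"log-likelihood: {self.llf:.2f}",
            f"  method: {self.settings['method']} "
            f"(nodes={self.settings['n_nodes']})   converged: {self.converged}",
        ]
        if self.fixed_items:
            lines.append(f"  items held at start: {', '.join(self.fixed_items)}")
        lines.append(self.params.to_string(index=False, float_format="%.3f"))
        return "\n".join(lines)
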