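"""Marginal-likelihood machinery and baseline item-parameter estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from cogirt import (
    BaselineIRT,
    ItemBank,
    ItemSpec,
    estimate_ebe,
    marginal_loglik_subject,
    simulate_baseline_studies,
)
from cogirt.baseline import _ItemData, _marginal_loglik_subjects

from conftest import make_items


def _records(pairs):
    """One subject's records from (item_id, value) pairs."""
    return pd.DataFrame(
        {
            "subject_id": "s1",
            "study_id": "T",
            "time_months": 0.0,
            "arm": 0,
            "item_id": [p[0] for p in pairs],
            "value": [p[1] for p in pairs],
        }
    )


def _toy_bank():
    its = make_items()
    return ItemBank(
        [its["binary3pl"], its["binomial_words"], its["ordered_categorical"]]
    )


def _grid_marginal(records, bank, lo=-10, hi=10, n=20001):
    """Dense-trapezoid oracle for the 1-D marginal likelihood."""
    D = np.linspace(lo, hi, n)
    total = np.zeros_like(D)
    for _, r in records.iterrows():
        item = bank[r["item_id"]]
        from cogirt.items import logpmf_table

        total += logpmf_table(item, D)[int(r["value"])]
    integrand = np.exp(total) * norm.pdf(D)
    return float(np.log(np.trapezoid(integrand, D)))


class TestMarginalLoglik:
    def test_single_symmetric_binary_item(self):
        bank = ItemBank([ItemSpec("b", "c", "binary3pl", a=1.0, b=0.0, c=0.0)])
        rec = _records([("b", 1)])
        # marginal P(fail) is exactly 1/2 by symmetry of logistic x normal
        ll = marginal_loglik_subject(rec, bank, "adaptive_gauss_hermite", 50)
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_agh_matches_dense_grid(self):
        bank = _toy_bank()
        rec = _records([("bin", 1), ("wr", 4), ("wf", 2)])
        oracle = _grid_marginal(rec, bank)
        agh = marginal_loglik_subject(rec, bank, "adaptive_gauss_hermite", 50)
        assert agh == pytest.approx(oracle, abs=1e-8)

    def test_laplace_close_to_agh_many_items(self):
        rng = np.random.default_rng(3)
        items = [
            ItemSpec(f"b{j}", "c", "binary3pl",
                     a=float(rng.uniform(0.8, 1.8)),
                     b=float(rng.uniform(-2, 2)), c=0.05)
            for j in range(40)
        ]
        bank = ItemBank(items)
        rec = _records([(f"b{j}", int(rng.integers(0, 2))) for j in range(40)])
        agh = marginal_loglik_subject(rec, bank, "adaptive_gauss_hermite", 50)
        lap = marginal_loglik_subject(rec, bank, "laplace")
        assert abs(lap - agh) / abs(agh) < 0.005

    def test_invariant_to_item_order(self):
        bank = _toy_bank()
        rec = _records([("bin", 0), ("wr", 6), ("wf", 3)])
        ll1 = marginal_loglik_subject(rec, bank, "adaptive_gauss_hermite", 21)
        ll2 = marginal_loglik_subject(
            rec.iloc[::-1].reset_index(drop=True), bank, "adaptive_gauss_hermite", 21
        )
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_no_records_error(self):
        with pytest.raises(ValueError, match="no response"):
            marginal_loglik_subject(_records([]).iloc[:0], _toy_bank())


class TestEBE:
    def test_prior_fallback_without_records(self):
        bank = _toy_bank()
        rec = _records([("bin", 1)])
        with pytest.warns(UserWarning, match="without records"):
            ebes = estimate_ebe(rec, bank, subjects=["s1", "ghost"])
        row = ebes.set_index("subject_id").loc["ghost"]
        assert row["d_hat"] == 0.0 and row["d_sd"] == 1.0

    def test_symmetric_half_failed_mode_at_difficulty(self):
        # two identical symmetric items, one failed: posterior mode at b = 0
        items = [
            ItemSpec(f"b{j}", "c", "binary3pl", a=1.2, b=0.0, c=0.0)
            for j in range(2)
        ]
        bank = ItemBank(items)
        rec = _records([("b0", 1), ("b1", 0)])
        ebes = estimate_ebe(rec, bank)
        assert ebes["d_hat"].iloc[0] == pytest.approx(0.0, abs=1e-7)
        assert ebes["d_sd"].iloc[0] > 0

    def test_more_items_shrink_uncertainty(self):
        items = [
            ItemSpec(f"b{j}", "c", "binary3pl", a=1.0, b=0.3 * j - 1, c=0.0)
            for j in range(8)
        ]
        bank = ItemBank(items)
        sds = []
        for k in (2, 4, 8):
            rec = _records([(f"b{j}", j % 2) for j in range(k)])
            sds.append(estimate_ebe(rec, bank)["d_sd"].iloc[0])
        assert sds[0] >= sds[1] >= sds[2]


@pytest.fixture(scope="module")
def small_fit(rbank):
    """Single synthetic study administering a 7-item subset, fitted once."""
    sub = rbank.subset(
        ["wr_t1", "dwr", "cmd_1", "con_cube", "ori_date", "ori_year",
         "word_finding"]
    )
    df = simulate_baseline_studies(sub, [("S", 900, None)], seed=17)
    res = BaselineIRT(df, sub).fit()
    return sub, df, res


class TestFitBaseline:
    def test_recovers_difficulties(self, small_fit):
        sub, _, res = small_fit
        assert res.converged
        par = res.params.set_index("item_id")
        for iid in ("wr_t1", "dwr", "cmd_1", "ori_date", "ori_year"):
            true = sub[iid]
            assert par.loc[iid, "b"] == pytest.approx(true.b, abs=0.35)
            assert par.loc[iid, "a"] == pytest.approx(true.a, rel=0.35)

    def test_relabeling_subjects_preserves_loglik(self, small_fit):
        sub, df, res = small_fit
        relabeled = df.copy()
        relabeled["subject_id"] = "x_" + relabeled["subject_id"]
        res2 = BaselineIRT(relabeled, sub).fit()
        assert res2.llf == pytest.approx(res.llf, abs=1e-6)

    def test_loglik_peaks_near_truth(self, rbank):
        sub = rbank.subset(["wr_t1", "dwr", "ori_date", "ori_year"])
        data = simulate_baseline_studies(sub, [("S", 2500, None)], seed=5)
        idx = _ItemData(data, sub)
        ll_true = float(_marginal_loglik_subjects(idx, "gauss_hermite", 41).sum())
        shifted = sub.replace_items(
            {it.item_id: it.replace(b=it.b + 0.5) for it in sub.items}
        )
        idx2 = _ItemData(data, shifted)
        ll_shift = float(_marginal_loglik_subjects(idx2, "gauss_hermite", 41).sum())
        assert ll_true > ll_shift

    def test_degenerate_item_held_with_warning(self):
        items = [
            ItemSpec("easy", "c", "binary3pl", a=1.0, b=-30.0, c=0.0),
            ItemSpec("ok", "c", "binary3pl", a=1.0, b=0.0, c=0.0),
        ]
        bank = ItemBank(items)
        data = simulate_baseline_studies(bank, [("S", 120, None)], seed=2)
        with pytest.warns(UserWarning, match="not identified"):
            res = BaselineIRT(data, bank).fit(maxiter=50)
        assert "easy" in res.fixed_items

    def test_em_oracle_agreement_2pl(self):
        """Direct MML fit agrees with an independently coded EM algorithm."""
        rng = np.random.default_rng(8)
        true = [(1.3, -0.8), (0.9, 0.0), (1.6, 0.7), (1.1, 1.4)]
        items = [
            ItemSpec(f"b{j}", "c", "binary3pl", a=a, b=b, c=0.0)
            for j, (a, b) in enumerate(true)
        ]
        bank = ItemBank(items)
        data = simulate_baseline_studies(bank, [("S", 1500, None)], seed=8)
        # package fit with c pinned near zero via the bank's structure is not
        # exposed; compare a, b of a c-free refit against the EM oracle's 2PL
        res = BaselineIRT(data, bank).fit()
        par = res.params.set_index("item_id")

        # --- independent EM (Bock-Aitkin): E-step posteriors on a fixed grid,
        # M-step per-item Newton logistic regression with fractional counts
        D, logw = np.polynomial.hermite.hermgauss(41)
        D = D * np.sqrt(2.0)
        logw = np.log(logw) - 0.5 * np.log(np.pi)
        Y = (
            data.pivot_table(index="subject_id", columns="item_id", values="value")
            .to_numpy()
        )
        # item j modeled as p = expit(beta1 D + beta0); a = beta1, b = -beta0/beta1
        X = np.stack([np.ones_like(D), D], axis=1)  # (Q, 2)
        betas = np.tile([0.0, 1.0], (len(items), 1))
        for _ in range(500):
            slope, inter = betas[:, 1], betas[:, 0]
            P = 1 / (1 + np.exp(-(D[:, None] * slope + inter)))  # (Q, J)
            L = Y @ np.log(P.T) + (1 - Y) @ np.log(1 - P.T)  # (S, Q)
            W = np.exp(L + logw - logsumexp(L + logw, axis=1, keepdims=True))
            nq = W.sum(0)  # expected subjects per node
            rq = W.T @ Y  # expected failures per node (Q, J)
            new = betas.copy()
            for j in range(len(items)):
                beta = betas[j].copy()
                for _ in range(50):
                    p = 1 / (1 + np.exp(-(X @ beta)))
                    g = X.T @ (rq[:, j] - nq * p)
                    H = X.T @ (X * (nq * p * (1 - p))[:, None])
                    step = np.linalg.solve(H, g)
                    beta = beta + step
                    if np.max(np.abs(step)) < 1e-10:
                        break
                new[j] = beta
            if np.max(np.abs(new - betas)) < 1e-9:
                betas = new
                break
            betas = new
        ab = np.stack([betas[:, 1], -betas[:, 0] / betas[:, 1]], axis=1)

        for j, it in enumerate(items):
            # the package fit frees c as well, so agreement is approximate
            assert par.loc[it.item_id, "a"] == pytest.approx(ab[j, 0], abs=0.2)
            assert par.loc[it.item_id, "b"] == pytest.approx(ab[j, 1], abs=0.2)
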