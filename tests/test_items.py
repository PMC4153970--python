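"""Item-family probability models: frozen values, invariants, sampling."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import binom, chisquare, poisson

from cogirt.items import (
    FamilyError,
    ItemSpec,
    dlogpmf_table,
    expected_score,
    item_loglik,
    logpmf_table,
    pmf_cancellation,
    pmf_ordered,
    pmf_word_count,
    prob_fail_3pl,
    prob_fail_word_recognition,
    sample_item,
    _gp_log_terms,
)

from conftest import make_items

ALL_ITEMS = list(make_items().values())


class TestBinary3PL:
    def test_symmetric_midpoint(self):
        it = ItemSpec("i", "c", "binary3pl", a=1.0, b=0.0, c=0.0)
        assert prob_fail_3pl(0.0, it) == pytest.approx(0.5)

    def test_midpoint_with_floor(self):
        it = ItemSpec("i", "c", "binary3pl", a=2.7, b=1.3, c=0.2)
        assert prob_fail_3pl(1.3, it) == pytest.approx(0.6)

    def test_frozen_value(self):
        # exact evaluation of c + (1-c) expit(a (D-b))
        it = ItemSpec("i", "c", "binary3pl", a=2.0, b=1.0, c=0.1)
        assert prob_fail_3pl(0.0, it) == pytest.approx(0.207283, abs=5e-7)

    def test_strictly_increasing_and_range(self):
        it = ItemSpec("i", "c", "binary3pl", a=1.5, b=0.3, c=0.15)
        D = np.linspace(-6, 6, 241)
        p = prob_fail_3pl(D, it)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > it.c) & (p < 1))

    def test_wrong_family_rejected(self, items):
        with pytest.raises(FamilyError):
            prob_fail_3pl(0.0, items["ordered_categorical"])


class TestWordRecognition:
    def test_asymptotes_and_midpoint(self):
        it = ItemSpec(
            "i", "wrc", "word_recognition", a=1.0, b=0.4, c=0.1, d=0.9, n_words=12
        )
        assert prob_fail_word_recognition(-40.0, it) == pytest.approx(0.1, abs=1e-12)
        assert prob_fail_word_recognition(40.0, it) == pytest.approx(0.9, abs=1e-12)
        assert prob_fail_word_recognition(0.4, it) == pytest.approx(0.5)

    def test_c_ge_d_rejected(self):
        with pytest.raises(ValueError):
            ItemSpec("i", "wrc", "word_recognition",
                     a=1.0, b=0.0, c=0.8, d=0.5, n_words=12)

    def test_reduces_to_3pl_when_d_is_one(self):
        common = dict(a=1.2, b=-0.3, c=0.07)
        rec = ItemSpec("i", "w", "word_recognition", d=1.0, n_words=10, **common)
        tpl = ItemSpec("i", "w", "binary3pl", **common)
        D = np.linspace(-6, 6, 101)
        assert np.max(np.abs(
            prob_fail_word_recognition(D, rec) - prob_fail_3pl(D, tpl)
        )) < 1e-12


class TestWordCount:
    def test_degenerate_zero_errors(self):
        it = ItemSpec("i", "w", "binomial_words", a=1.0, b=0.0, c=0.0, n_words=10)
        # p -> 0 far below the difficulty
        assert pmf_word_count(0, -60.0, it) == pytest.approx(1.0)

    def test_frozen_central_binomial(self):
        # C(12,6) / 2^12 with p = 1/2 at D = b, c = 0
        it = ItemSpec("i", "w", "binomial_words", a=1.0, b=0.0, c=0.0, n_words=12)
        assert pmf_word_count(6, 0.0, it) == pytest.approx(0.225586, abs=5e-7)

    def test_truncated_renormalizes(self, items):
        it = items["trunc_recognition"]
        k = np.arange(13)
        total = pmf_word_count(k, 0.8, it).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support_rejected(self, items):
        with pytest.raises(ValueError):
            pmf_word_count(13, 0.0, items["trunc_recognition"])


class TestCancellation:
    def test_frozen_unnormalized_term(self):
        # p (p + delta k)^(k-1) exp(-p - delta k) / k! at p=2, delta=0.1, k=3
        term = float(np.exp(_gp_log_terms(2.0, 0.1, 3)[3]))
        assert term == pytest.approx(0.176790, abs=5e-7)

    def test_delta_zero_is_truncated_poisson(self, items):
        it = items["gen_poisson_count"].replace(delta=0.0)
        D = 0.5
        lam = it.d * (1 - 1 / (1 + np.exp(-it.a * (D - it.b))))
        k = np.arange(41)
        expect = poisson.pmf(k, lam) / poisson.cdf(40, lam)
        got = pmf_cancellation(k, D, it)
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_invalid_dispersion_rejected(self, items):
        it = items["gen_poisson_count"].replace(delta=-2.0)
        with pytest.raises(ValueError):
            pmf_cancellation(3, 0.0, it)

    def test_mean_decreasing_in_disability(self, items):
        it = items["gen_poisson_count"]
        D = np.linspace(-6, 6, 61)
        means = 40 - expected_score(it, D)  # points not scored rise with D
        assert np.all(np.diff(means) > 0)


class TestOrdered:
    def test_frozen_category_probabilities(self):
        it = ItemSpec("i", "r", "ordered_categorical",
                      a=1.0, b=(-1.0, 0.0, 1.0, 2.0), n_categories=5)
        got = pmf_ordered(np.arange(5), 0.0, it)
        np.testing.assert_allclose(
            got, [0.268941, 0.231059, 0.231059, 0.149738, 0.119203], atol=5e-7
        )

    def test_top_category_asymptote(self, items):
        it = items["ordered_categorical"]
        p = pmf_ordered(np.arange(5), 60.0, it)
        assert p[-1] == pytest.approx(1.0, abs=1e-12)

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ItemSpec("i", "r", "ordered_categorical",
                     a=1.0, b=(1.0, 0.5, 2.0, 3.0), n_categories=5)


class TestCrossFamilyInvariants:
    @pytest.mark.parametrize("item", ALL_ITEMS, ids=lambda i: i.item_id)
    def test_pmf_normalizes(self, item):
        D = np.linspace(-6, 6, 25)
        table = np.exp(logpmf_table(item, D))
        np.testing.assert_allclose(table.sum(axis=0), 1.0, atol=1e-10)

    def test_pmf_normalizes_random_parameters(self):
        rng = np.random.default_rng(5)
        D = np.linspace(-6, 6, 13)
        for _ in range(100):
            fam = rng.choice(["binary3pl", "binomial_words", "word_recognition",
                              "gen_poisson_count", "ordered_categorical"])
            a = float(rng.uniform(0.3, 2.5))
            b = float(rng.uniform(-2, 3))
            if fam == "binary3pl":
                it = ItemSpec("x", "c", fam, a=a, b=b, c=float(rng.uniform(0, 0.4)))
            elif fam == "binomial_words":
                it = ItemSpec("x", "c", fam, a=a, b=b,
                              c=float(rng.uniform(0, 0.3)), n_words=10)
            elif fam == "word_recognition":
                c = float(rng.uniform(0, 0.3))
                it = ItemSpec("x", "c", fam, a=a, b=b, c=c,
                              d=float(rng.uniform(c + 0.2, 1.0)), n_words=12)
            elif fam == "gen_poisson_count":
                it = ItemSpec("x", "c", fam, a=a, b=b,
                              d=float(rng.uniform(5, 38)),
                              delta=float(rng.uniform(0.0, 0.5)), max_count=40)
            else:
                t0 = float(rng.uniform(-1, 1))
                inc = rng.uniform(0.2, 1.5, size=3)
                it = ItemSpec("x", "c", fam, a=a,
                              b=tuple(t0 + np.concatenate([[0], np.cumsum(inc)])),
                              n_categories=5)
            total = np.exp(logpmf_table(it, D)).sum(axis=0)
            np.testing.assert_allclose(total, 1.0, atol=1e-10)

    @pytest.mark.parametrize("item", ALL_ITEMS, ids=lambda i: i.item_id)
    def test_expected_score_monotone_in_disability(self, item):
        D = np.arange(-6, 6.01, 0.05)
        score = expected_score(item, D)
        if item.family == "gen_poisson_count":
            score = item.max_count - score
        assert np.all(np.diff(score) >= -1e-12)

    @pytest.mark.parametrize("item", ALL_ITEMS, ids=lambda i: i.item_id)
    def test_dlogpmf_matches_finite_difference(self, item):
        D = np.linspace(-4, 4, 9)
        h = 1e-6
        fd = (logpmf_table(item, D + h) - logpmf_table(item, D - h)) / (2 * h)
        np.testing.assert_allclose(dlogpmf_table(item, D), fd, atol=1e-6, rtol=1e-5)


class TestItemLoglik:
    def test_binary_log_half(self):
        it = ItemSpec("i", "c", "binary3pl", a=1.0, b=0.0, c=0.0)
        assert item_loglik(1, 0.0, it) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("item", ALL_ITEMS, ids=lambda i: i.item_id)
    def test_matches_family_pmf(self, item):
        rng = np.random.default_rng(11)
        sup = item.support
        for _ in range(200):
            D = float(rng.uniform(-4, 4))
            y = int(rng.choice(sup))
            ll = float(item_loglik(y, D, item))
            if item.family == "binary3pl":
                p = prob_fail_3pl(D, item)
                ref = p if y == 1 else 1 - p
            elif item.family in ("binomial_words", "word_recognition"):
                ref = float(pmf_word_count(y, D, item))
            elif item.family == "gen_poisson_count":
                ref = float(pmf_cancellation(y, D, item))
            else:
                ref = float(pmf_ordered(y, D, item))
            assert np.exp(ll) == pytest.approx(ref, rel=1e-10)

    def test_all_categories_logsumexp_zero(self, items):
        it = items["ordered_categorical"]
        lls = [float(item_loglik(k, 0.7, it)) for k in range(5)]
        assert logsumexp(lls) == pytest.approx(0.0, abs=1e-12)

    def test_support_violation(self, items):
        with pytest.raises(ValueError):
            item_loglik(7, 0.0, items["ordered_categorical"])


class TestSampling:
    def test_certain_failure(self):
        it = ItemSpec("i", "c", "binary3pl", a=1.0, b=-50.0, c=0.0)
        rng = np.random.default_rng(0)
        assert sample_item(np.zeros(50), it, rng).min() == 1

    def test_binomial_mean_within_mc_band(self):
        it = ItemSpec("i", "w", "binomial_words", a=1.0, b=0.0, c=0.0, n_words=10)
        D = float(np.log(0.3 / 0.7))  # p = 0.3 exactly
        rng = np.random.default_rng(42)
        draws = sample_item(np.full(10**5, D), it, rng)
        se = np.sqrt(10 * 0.3 * 0.7 / 10**5)
        assert abs(draws.mean() - 3.0) < 3 * se

    def test_identical_seeds_identical_draws(self, items):
        for item in items.values():
            a = sample_item(np.linspace(-2, 2, 100), item,
                            np.random.default_rng(7))
            b = sample_item(np.linspace(-2, 2, 100), item,
                            np.random.default_rng(7))
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "key", ["binary3pl", "trunc_recognition", "gen_poisson_count",
                "ordered_categorical"]
    )
    def test_chi_square_goodness_of_fit(self, items, key):
        item = items[key]
        D = 0.8
        rng = np.random.default_rng(99)
        n = 10**5
        draws = sample_item(np.full(n, D), item, rng)
        pmf = np.exp(logpmf_table(item, np.asarray(D)))
        counts = np.bincount(draws, minlength=len(pmf))
        keep = pmf * n >= 5
        if keep.all():
            obs, exp = counts, pmf * n
        else:
            obs = np.append(counts[keep], counts[~keep].sum())
            exp = np.append(pmf[keep], pmf[~keep].sum()) * n
        stat, p = chisquare(obs, exp)
        assert p > 0.01
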