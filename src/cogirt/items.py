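"""Item models for the 13 ADAS-cog components.

Every item links an observed outcome to the latent *cognitive disability*
``D`` (standard-normal at baseline, larger = worse cognition) through an
item characteristic curve (ICC).  Five model families cover the scale:

``binary3pl``
    Pass/fail tasks; probability to fail is a three-parameter logistic
    ``c + (1 - c) * expit(a * (D - b))``.
``binomial_words``
    Word recall trials; the count of forgotten words out of ``n_words`` is
    binomial with the 3PL failure probability shared across words.
``word_recognition``
    Word recognition; binomial count with a four-parameter failure
    probability ``c + (d - c) * expit(a * (D - b))`` whose upper asymptote
    ``d`` is the maximal error probability of a severely impaired subject.
    Study variants may truncate the stored count (``max_count``).
``gen_poisson_count``
    Number cancellation points (0-40); generalized Poisson with mean
    ``d * (1 - expit(a * (D - b)))`` and dispersion ``delta``, renormalized
    over the bounded support.
``ordered_categorical``
    Examiner-rated items; proportional-odds model on cumulative logits with
    non-decreasing thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import binom as _binom

__all__ = [
    "FAMILIES",
    "ItemSpec",
    "ItemBank",
    "ResponseRecord",
    "prob_fail_3pl",
    "prob_fail_word_recognition",
    "pmf_word_count",
    "pmf_cancellation",
    "pmf_ordered",
    "item_loglik",
    "sample_item",
    "expected_score",
]

FAMILIES = (
    "binary3pl",
    "binomial_words",
    "word_recognition",
    "gen_poisson_count",
    "ordered_categorical",
)

_GP_SUPPORT_MAX = 40  # number-cancellation points are bounded at 40


class FamilyError(ValueError):
    """Operation called with an item of the wrong model family."""


@dataclass(frozen=True)
class ItemSpec:
    """One assessment item: model family plus its parameters.

    Parameters not used by the family must stay ``None``; ``b`` is a float
    for all families except ``ordered_categorical``, where it is the
    non-decreasing threshold vector.
    """

    item_id: str
    component: str
    family: str
    a: float
    b: float | tuple[float, ...]
    c: float | None = None
    d: float | None = None
    delta: float | None = None
    n_words: int | None = None
    max_count: int | None = None
    n_categories: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown item family {self.family!r}")
        if not self.a > 0:
            raise ValueError(f"{self.item_id}: discrimination a must be > 0")
        fam = self.family
        if fam == "ordered_categorical":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"{self.item_id}: n_categories >= 2 required")
            b = tuple(float(x) for x in np.atleast_1d(self.b))
            if len(b) != self.n_categories - 1:
                raise ValueError(
                    f"{self.item_id}: need {self.n_categories - 1} thresholds, "
                    f"got {len(b)}"
                )
            if np.any(np.diff(b) < 0):
                raise ValueError(f"{self.item_id}: thresholds must be non-decreasing")
            object.__setattr__(self, "b", b)
        else:
            object.__setattr__(self, "b", float(self.b))
        if fam in ("binary3pl", "binomial_words", "word_recognition"):
            if self.c is None or not 0.0 <= self.c < 1.0:
                raise ValueError(f"{self.item_id}: c must lie in [0, 1)")
        if fam == "word_recognition":
            if self.d is None or not self.c < self.d <= 1.0:
                raise ValueError(f"{self.item_id}: need c < d <= 1")
        if fam in ("binomial_words", "word_recognition"):
            if self.n_words is None or self.n_words < 1:
                raise ValueError(f"{self.item_id}: n_words >= 1 required")
            if self.max_count is not None and not 1 <= self.max_count <= self.n_words:
                raise ValueError(f"{self.item_id}: max_count must lie in 1..n_words")
        if fam == "gen_poisson_count":
            if self.d is None or not self.d > 0:
                raise ValueError(f"{self.item_id}: mean bound d > 0 required")
            if self.delta is None:
                object.__setattr__(self, "delta", 0.0)
            mc = self.max_count if self.max_count is not None else _GP_SUPPORT_MAX
            object.__setattr__(self, "max_count", int(mc))

    @property
    def support(self) -> np.ndarray:
        """Integer outcomes this item can produce."""
        fam = self.family
        if fam == "binary3pl":
            return np.arange(2)
        if fam in ("binomial_words", "word_recognition"):
            top = self.max_count if self.max_count is not None else self.n_words
            return np.arange(top + 1)
        if fam == "gen_poisson_count":
            return np.arange(self.max_count + 1)
        return np.arange(self.n_categories)

    def replace(self, **kwargs) -> "ItemSpec":
        return replace(self, **kwargs)


#: lightweight record of one observed item response
@dataclass(frozen=True)
class ResponseRecord:
    subject_id: str
    study_id: str
    time_months: float
    item_id: str
    value: int
    arm: int = 0


def _require_family(item: ItemSpec, allowed: tuple[str, ...], op: str):
    if item.family not in allowed:
        raise FamilyError(
            f"{op} expects family in {allowed}, got {item.family!r} "
            f"for item {item.item_id!r}"
        )


def prob_fail_3pl(D, item: ItemSpec):
    """Failure probability of a binary (or word-recall) task: ``c + (1 - c) * expit(a (D - b))``."""
    _require_family(item, ("binary3pl", "binomial_words"), "prob_fail_3pl")
    s = expit(item.a * (np.asarray(D, dtype=float) - item.b))
    return item.c + (1.0 - item.c) * s


def prob_fail_word_recognition(D, item: ItemSpec):
    """Failure probability with lower asymptote ``c`` and upper asymptote ``d``."""
    _require_family(item, ("word_recognition",), "prob_fail_word_recognition")
    s = expit(item.a * (np.asarray(D, dtype=float) - item.b))
    return item.c + (item.d - item.c) * s


def _word_fail_prob(D, item: ItemSpec):
    if item.family == "word_recognition":
        return prob_fail_word_recognition(D, item)
    return prob_fail_3pl(D, item)


def pmf_word_count(k, D, item: ItemSpec):
    """Probability of ``k`` word errors out of ``n_words`` (binomial ICC).

    For study variants storing the count truncated at ``max_count`` the
    binomial is renormalized over ``0..max_count``.
    """
    _require_family(item, ("binomial_words", "word_recognition"), "pmf_word_count")
    k = np.asarray(k)
    top = item.max_count if item.max_count is not None else item.n_words
    if np.any(k < 0) or np.any(k > top):
        raise ValueError(f"count outside support 0..{top} for {item.item_id}")
    p = _word_fail_prob(D, item)
    out = _binom.pmf(k, item.n_words, p)
    if item.max_count is not None and item.max_count < item.n_words:
        out = out / _binom.cdf(item.max_count, item.n_words, p)
    return out


def _gp_log_terms(p, delta, kmax):
    """Unnormalized generalized-Poisson log terms for k = 0..kmax.

    ``p`` broadcasts against a new leading axis of length kmax+1.
    """
    p = np.asarray(p, dtype=float)
    k = np.arange(kmax + 1).reshape((kmax + 1,) + (1,) * p.ndim)
    lam = p + delta * k
    if np.any(lam <= 0):
        raise ValueError(
            "generalized-Poisson dispersion invalid: p + delta*k <= 0 on support"
        )
    with np.errstate(divide="ignore"):
        t = np.log(p) + (k - 1) * np.log(lam) - p - delta * k - gammaln(k + 1)
    return t


def pmf_cancellation(k, D, item: ItemSpec):
    """Truncated generalized-Poisson pmf of number-cancellation points."""
    _require_family(item, ("gen_poisson_count",), "pmf_cancellation")
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k > item.max_count):
        raise ValueError(f"count outside support 0..{item.max_count}")
    p = item.d * (1.0 - expit(item.a * (np.asarray(D, dtype=float) - item.b)))
    t = _gp_log_terms(p, item.delta, item.max_count)
    logpmf = t - logsumexp(t, axis=0)
    return np.exp(logpmf[k])


def pmf_ordered(k, D, item: ItemSpec):
    """Proportional-odds category probability P(Y = k | D)."""
    _require_family(item, ("ordered_categorical",), "pmf_ordered")
    k = np.asarray(k)
    if np.any(k < 0) or np.any(k >= item.n_categories):
        raise ValueError(f"category outside 0..{item.n_categories - 1}")
    D = np.asarray(D, dtype=float)
    cum = _ordered_cum(D, item)  # (K+1, ...) with cum[0]=1, cum[K]=0
    pk = cum[:-1] - cum[1:]
    return pk[k]


def _ordered_cum(D, item: ItemSpec):
    """Cumulative probabilities P(Y >= k) stacked for k = 0..K."""
    b = np.asarray(item.b, dtype=float)
    z = item.a * (D[None, ...] - b.reshape((-1,) + (1,) * D.ndim))
    cum = expit(z)
    shape = (1,) + D.shape
    return np.concatenate([np.ones(shape), cum, np.zeros(shape)], axis=0)


def logpmf_table(item: ItemSpec, D):
    """Log pmf over the item's full support at each latent value.

    Returns an array of shape ``(len(support),) + D.shape``; the workhorse
    behind likelihood evaluation on latent grids and quadrature nodes.
    """
    D = np.asarray(D, dtype=float)
    fam = item.family
    if fam == "binary3pl":
        p = np.clip(prob_fail_3pl(D, item), 1e-12, 1 - 1e-12)
        return np.stack([np.log1p(-p), np.log(p)])
    if fam in ("binomial_words", "word_recognition"):
        # clip saturated probabilities so extreme parameter proposals during
        # optimization yield finite (if tiny) likelihoods
        p = np.clip(_word_fail_prob(D, item), 1e-12, 1 - 1e-12)
        n = item.n_words
        top = item.max_count if item.max_count is not None else n
        k = np.arange(top + 1).reshape((top + 1,) + (1,) * D.ndim)
        logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        table = logc + k * np.log(p) + (n - k) * np.log1p(-p)
        if top < n:
            table = table - logsumexp(table, axis=0)
        return table
    if fam == "gen_poisson_count":
        p = np.maximum(item.d * (1.0 - expit(item.a * (D - item.b))), 1e-12)
        t = _gp_log_terms(p, item.delta, item.max_count)
        return t - logsumexp(t, axis=0)
    cum = _ordered_cum(D, item)
    pk = np.clip(cum[:-1] - cum[1:], 1e-300, None)
    return np.log(pk)


def dlogpmf_table(item: ItemSpec, D):
    """Analytic derivative of :func:`logpmf_table` with respect to ``D``."""
    D = np.asarray(D, dtype=float)
    fam = item.family
    if fam in ("binary3pl", "binomial_words", "word_recognition"):
        s = expit(item.a * (D - item.b))
        upper = item.d if fam == "word_recognition" else 1.0
        p = np.clip(item.c + (upper - item.c) * s, 1e-12, 1 - 1e-12)
        dp = item.a * (upper - item.c) * s * (1.0 - s)
        if fam == "binary3pl":
            return np.stack([-dp / (1.0 - p), dp / p])
        n = item.n_words
        top = item.max_count if item.max_count is not None else n
        k = np.arange(top + 1).reshape((top + 1,) + (1,) * D.ndim)
        d = dp * (k / p - (n - k) / (1.0 - p))
        if top < n:
            # d/dp P(Bin(n,p) <= m) = -n C(n-1, m) p^m (1-p)^(n-1-m)
            logdF = (
                np.log(n)
                + gammaln(n)
                - gammaln(top + 1)
                - gammaln(n - top)
                + top * np.log(p)
                + (n - 1 - top) * np.log1p(-p)
            )
            dlogF = -dp * np.exp(logdF) / _binom.cdf(top, n, p)
            d = d - dlogF
        return d
    if fam == "gen_poisson_count":
        s = expit(item.a * (D - item.b))
        p = np.maximum(item.d * (1.0 - s), 1e-12)
        dp = -item.d * item.a * s * (1.0 - s)
        kmax = item.max_count
        k = np.arange(kmax + 1).reshape((kmax + 1,) + (1,) * D.ndim)
        lam = p + item.delta * k
        dt = dp * (1.0 / p + (k - 1) / lam - 1.0)
        t = _gp_log_terms(p, item.delta, kmax)
        w = np.exp(t - logsumexp(t, axis=0))
        return dt - np.sum(w * dt, axis=0)
    cum = _ordered_cum(D, item)
    dcum = item.a * cum * (1.0 - cum)
    dcum[0] = 0.0
    dcum[-1] = 0.0
    pk = np.clip(cum[:-1] - cum[1:], 1e-300, None)
    return (dcum[:-1] - dcum[1:]) / pk


def item_loglik(value, D, item: ItemSpec):
    """Log probability of an observed outcome, dispatching on the family."""
    value = np.asarray(value)
    support = item.support
    if np.any(value < support[0]) or np.any(value > support[-1]):
        raise ValueError(
            f"value outside support {support[0]}..{support[-1]} "
            f"for item {item.item_id!r}"
        )
    table = logpmf_table(item, np.asarray(D, dtype=float))
    return table[value]


def expected_score(item: ItemSpec, D):
    """Expected observed outcome at latent value(s) ``D``."""
    table = np.exp(logpmf_table(item, np.asarray(D, dtype=float)))
    k = item.support.reshape((-1,) + (1,) * (table.ndim - 1))
    return np.sum(k * table, axis=0)


def sample_item(D, item: ItemSpec, rng: np.random.Generator):
    """Draw outcomes for latent value(s) ``D``; vectorized over ``D``."""
    D = np.asarray(D, dtype=float)
    scalar = D.ndim == 0
    D = np.atleast_1d(D)
    fam = item.family
    if fam == "binary3pl":
        out = (rng.random(D.shape) < prob_fail_3pl(D, item)).astype(int)
    elif fam in ("binomial_words", "word_recognition") and item.max_count is None:
        out = rng.binomial(item.n_words, _word_fail_prob(D, item))
    else:
        pmf = np.exp(logpmf_table(item, D))  # (K, n)
        cdf = np.cumsum(pmf, axis=0)
        u = rng.random(D.shape)
        out = np.sum(u[None, :] > cdf, axis=0)
        out = np.minimum(out, pmf.shape[0] - 1)
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Item bank


@dataclass
class ItemBank:
    """Ordered item collection with study variants and a total-score map.

    ``study_variants`` maps a study id to the set of item ids administered in
    that study (emulating the inclusion/exclusion heterogeneity of pooled
    trial databases).  ``score_map`` maps item outcomes to component scores
    and the total scale score; see :func:`cogirt.simulate.total_score`.
    """

    items: list[ItemSpec]
    study_variants: dict[str, set[str]] = field(default_factory=dict)
    score_map: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        self._index = {it.item_id: it for it in self.items}
        known = set(ids)
        for study, members in self.study_variants.items():
            members = set(members)
            unknown = members - known
            if unknown:
                raise ValueError(
                    f"study variant {study!r} references unknown items {sorted(unknown)}"
                )
            self.study_variants[study] = members
        if self.score_map:
            mapped = set()
            for comp in self.score_map.get("components", {}).values():
                mapped.update(comp["items"])
            missing = known - mapped
            if missing:
                raise ValueError(f"score_map does not cover items {sorted(missing)}")

    def __getitem__(self, item_id: str) -> ItemSpec:
        return self._index[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def components(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.component, None)
        return list(seen)

    def component_items(self, component: str) -> list[ItemSpec]:
        out = [it for it in self.items if it.component == component]
        if not out:
            raise KeyError(f"no items for component {component!r}")
        return out

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        keep = set(item_ids)
        items = [it for it in self.items if it.item_id in keep]
        missing = keep - {it.item_id for it in items}
        if missing:
            raise KeyError(f"unknown items {sorted(missing)}")
        variants = {
            s: (v & keep) for s, v in self.study_variants.items() if v & keep
        }
        smap = {}
        if self.score_map:
            comps = {
                name: {**spec, "items": [i for i in spec["items"] if i in keep]}
                for name, spec in self.score_map.get("components", {}).items()
            }
            comps = {n: s for n, s in comps.items() if s["items"]}
            smap = {**self.score_map, "components": comps}
        return ItemBank(items, variants, smap)

    def variant_items(self, study_id: str) -> list[ItemSpec]:
        if study_id not in self.study_variants:
            raise KeyError(f"unknown study variant {study_id!r}")
        return [it for it in self.items if it.item_id in self.study_variants[study_id]]

    def replace_items(self, new_items: Mapping[str, ItemSpec]) -> "ItemBank":
        items = [new_items.get(it.item_id, it) for it in self.items]
        return ItemBank(items, dict(self.study_variants), dict(self.score_map))
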