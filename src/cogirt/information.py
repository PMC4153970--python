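"""Fisher information of items and components for cognitive disability.

Because the latent disability is the only random quantity in every item
model, the Fisher information of an item at latent value ``D`` is

    I(D) = -E[ d2 log P(Y | D) / dD2 ] = E[ (d log P(Y | D) / dD)^2 ]

and information is additive over items.  The score-squared form on the right
is evaluated exactly from the analytic pmf derivatives over each item's full
(bounded) support, which reduces to the textbook closed forms
``p'^2 / (p (1 - p))`` for binary items, ``n`` times that for binomial word
counts, and ``sum_k P_k'^2 / P_k`` for ordered categories, while also
covering the truncated and generalized-Poisson families where no closed form
is printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import gh_nodes
from .items import ItemBank, ItemSpec, dlogpmf_table, logpmf_table

__all__ = [
    "PopulationSpec",
    "item_information",
    "information_curve",
    "average_information",
    "component_average_information",
    "rank_components",
    "DEFAULT_GRID",
]

#: default latent grid for information curves
DEFAULT_GRID = np.arange(-6.0, 6.0 + 1e-9, 0.05)


@dataclass(frozen=True)
class PopulationSpec:
    """Normal latent-disability distribution of a patient population."""

    label: str
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("population sd must be > 0")


def item_information(item: ItemSpec, D) -> np.ndarray:
    """Fisher information of one item at latent value(s) ``D``."""
    D = np.asarray(D, dtype=float)
    pmf = np.exp(logpmf_table(item, D))
    score = dlogpmf_table(item, D)
    return np.sum(pmf * score**2, axis=0)


def information_curve(
    item_or_bank, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Information on a latent grid for an item or every item of a bank."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    items = item_or_bank.items if isinstance(item_or_bank, ItemBank) else [item_or_bank]
    frames = []
    for it in items:
        frames.append(
            pd.DataFrame(
                {
                    "item_id": it.item_id,
                    "component": it.component,
                    "D": grid,
                    "info": item_information(it, grid),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def average_information(
    item: ItemSpec, pop: PopulationSpec, n_nodes: int = 41
) -> float:
    """Expected item information over a normal population distribution."""
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    z, logw = gh_nodes(n_nodes)
    D = pop.mean + pop.sd * z
    return float(np.sum(np.exp(logw) * item_information(item, D)))


def component_average_information(
    bank: ItemBank, component: str, pop: PopulationSpec, n_nodes: int = 41
) -> float:
    """Sum of the average item informations of one component."""
    return float(
        sum(
            average_information(it, pop, n_nodes)
            for it in bank.component_items(component)
        )
    )


def rank_components(
    bank: ItemBank, pop: PopulationSpec, n_nodes: int = 41
) -> pd.DataFrame:
    """Rank assessment components by average information content.

    Returns a frame with columns ``component``, ``information`` and
    ``pct_total`` sorted descending (ties broken alphabetically), the
    machinery behind population-specific sub-test selection.
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    rows = [
        (comp, component_average_information(bank, comp, pop, n_nodes))
        for comp in bank.components
    ]
    df = pd.DataFrame(rows, columns=["component", "information"])
    total = df["information"].sum()
    df["pct_total"] = 100.0 * df["information"] / total
    df = df.sort_values(
        ["information", "component"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "rank"
    return df
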