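import numpy as np
import pytest

from cogirt import (
    ItemSpec,
    ProgressionParams,
    TrialDesign,
    default_bank,
    reduced_bank,
    simulate_trial,
)
from cogirt.longitudinal import CTS_SCHEDULE


@pytest.fixture(scope="session")
def bank():
    return default_bank()


@pytest.fixture(scope="session")
def rbank():
    return reduced_bank()


def make_items():
    """One representative item per model family."""
    return {
        "binary3pl": ItemSpec("bin", "commands", "binary3pl", a=1.3, b=0.7, c=0.12),
        "binomial_words": ItemSpec(
            "wr", "word_recall", "binomial_words", a=1.1, b=-0.2, c=0.06, n_words=10
        ),
        "word_recognition": ItemSpec(
            "wrc", "word_recognition", "word_recognition",
            a=0.9, b=0.5, c=0.12, d=0.92, n_words=12,
        ),
        "trunc_recognition": ItemSpec(
            "wrct", "word_recognition", "word_recognition",
            a=0.9, b=0.5, c=0.10, d=0.90, n_words=24, max_count=12,
        ),
        "gen_poisson_count": ItemSpec(
            "nc", "number_cancellation", "gen_poisson_count",
            a=0.8, b=1.0, d=32.0, delta=0.15, max_count=40,
        ),
        "ordered_categorical": ItemSpec(
            "wf", "word_finding", "ordered_categorical",
            a=0.9, b=(0.5, 1.4, 2.3, 3.2), n_categories=5,
        ),
    }


@pytest.fixture(scope="session")
def items():
    return make_items()


@pytest.fixture(scope="session")
def placebo_trial(rbank):
    """A small single-arm trial shared by estimation tests."""
    p = ProgressionParams(0.95, 0.35, 0.68, 0.39, 0.54)
    design = TrialDesign(
        n_total=120, params=p, bank=rbank, schedule=CTS_SCHEDULE,
        allocation=0.0, seed=321,
    )
    return simulate_trial(design)
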