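"""Item-bank serialization and the committed default banks."""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .items import ItemBank, ItemSpec

__all__ = [
    "load_bank",
    "save_bank",
    "default_bank",
    "reduced_bank",
    "load_supplementary_bank",
    "REDUCED_ITEM_IDS",
]

_FIELD_ORDER = (
    "component",
    "family",
    "a",
    "b",
    "c",
    "d",
    "delta",
    "n_words",
    "max_count",
    "n_categories",
)


def _item_from_entry(entry: dict) -> ItemSpec:
    entry = dict(entry)
    item_id = entry.pop("id")
    b = entry.get("b")
    if isinstance(b, list):
        entry["b"] = tuple(b)
    return ItemSpec(item_id=item_id, **entry)


def bank_from_dict(cfg: dict) -> ItemBank:
    items = [_item_from_entry(e) for e in cfg["items"]]
    variants = {k: set(v) for k, v in cfg.get("study_variants", {}).items()}
    return ItemBank(items, variants, cfg.get("score_map", {}) or {})


def bank_to_dict(bank: ItemBank) -> dict:
    entries = []
    for it in bank.items:
        e: dict = {"id": it.item_id}
        for f in _FIELD_ORDER:
            v = getattr(it, f)
            if v is None:
                continue
            e[f] = list(v) if isinstance(v, tuple) else v
        entries.append(e)
    return {
        "items": entries,
        "study_variants": {k: sorted(v) for k, v in bank.study_variants.items()},
        "score_map": bank.score_map,
    }


def load_bank(path: str | Path) -> ItemBank:
    """Read an item bank from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return bank_from_dict(cfg)


def save_bank(bank: ItemBank, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bank_to_dict(bank), fh, sort_keys=False)


def default_bank() -> ItemBank:
    """The committed 13-component synthetic default bank.

    Hand-authored plausible parameters, NOT estimates from any published
    analysis; see the packaged ``default_bank.yaml`` for the rationale.
    """
    ref = importlib.resources.files("cogirt").joinpath("default_bank.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return bank_from_dict(cfg)


#: compact mixed-family subset used where runtime matters more than breadth
REDUCED_ITEM_IDS = (
    "wr_t1", "wr_t2", "wr_t3", "dwr", "wrc",
    "cmd_1", "cmd_3", "cmd_5", "con_cube", "con_rhombus",
    "ip_fold", "ip_address", "nof_1", "nof_3",
    "ori_date", "ori_year", "ori_time", "ori_place",
    "nc", "word_finding", "remembering",
)


def reduced_bank() -> ItemBank:
    """A 21-item mixed-family subset of the default bank (all five families)."""
    return default_bank().subset(REDUCED_ITEM_IDS)


def load_supplementary_bank(path: str | Path) -> ItemBank:
    """Load a user-supplied bank of externally published item estimates.

    Such estimates are not redistributable with this package; the caller
    must transcribe them into the bank YAML schema and point this loader at
    the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"supplementary item-bank file {path} not found: published item "
            "estimates are not bundled with cogirt; transcribe them into the "
            "bank YAML schema (see default_bank.yaml) and retry"
        )
    return load_bank(path)
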