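"""Readers/writers, run configuration and the reproducible pipeline.

Tabular data travel as CSV (long-format responses with columns
``subject_id, study_id, time_months, arm, item_id, value``); item banks,
designs and run configs as YAML.  Every pipeline run writes a manifest
recording inputs, settings, the master seed and SHA-256 hashes of all
artifacts, so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .banks import default_bank, load_bank, save_bank
from .items import ItemBank

__all__ = ["read_responses", "write_responses", "RunConfig", "run_pipeline"]

RESPONSE_COLUMNS = ["subject_id", "study_id", "time_months", "arm", "item_id", "value"]


def read_responses(path, bank: ItemBank | None = None) -> pd.DataFrame:
    """Read and validate a long-format response CSV.

    Rows violating an item's support are rejected with their file line
    numbers (header = line 1); unknown item ids raise with the offending
    ids.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty response file")
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.issubdtype(df["value"].dtype, np.integer):
        bad = df.index[df["value"] != np.floor(df["value"])]
        if len(bad):
            lines = (bad[:5] + 2).tolist()
            raise ValueError(f"{path}: non-integer values at lines {lines}")
        df["value"] = df["value"].astype(int)
    if bank is not None:
        unknown = sorted(set(df["item_id"]) - set(bank.item_ids))
        if unknown:
            raise ValueError(f"{path}: unknown item ids {unknown}")
        bad_lines: list[int] = []
        for iid, sub in df.groupby("item_id"):
            sup = bank[iid].support
            viol = sub.index[(sub["value"] < sup[0]) | (sub["value"] > sup[-1])]
            bad_lines.extend((viol + 2).tolist())
        if bad_lines:
            shown = sorted(bad_lines)[:10]
            raise ValueError(
                f"{path}: {len(bad_lines)} value(s) outside item support, "
                f"e.g. at lines {shown}"
            )
    return df[RESPONSE_COLUMNS]


def write_responses(df: pd.DataFrame, path) -> None:
    df[RESPONSE_COLUMNS].to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """One pipeline invocation: command, inputs, options and a master seed."""

    command: str
    out_dir: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)  # name -> path
    options: dict = field(default_factory=dict)
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _resolve_bank(config: RunConfig) -> ItemBank:
    if "bank" in config.inputs:
        return load_bank(config.inputs["bank"])
    return default_bank()


def run_pipeline(config: RunConfig) -> dict:
    """Execute one pipeline stage and write its artifacts plus a manifest."""
    from .evaluation import power_study
    from .information import PopulationSpec, information_curve, rank_components
    from .longitudinal import (
        HazardSpec,
        LongitudinalIRT,
        ProgressionParams,
        VisitSchedule,
    )
    from .simulate import TrialDesign, simulate_trial, total_score
    from .baseline import BaselineIRT
    from .comparators import fit_total_score_model, ls_means_analysis
    from .diagnostics import vpc

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, p in config.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r}: {p} does not exist")
    artifacts: dict[str, Path] = {}

    def register(name: str, path: Path):
        if path.exists() and not config.overwrite and name not in artifacts:
            raise FileExistsError(f"{path} exists; pass overwrite to replace it")
        artifacts[name] = path

    opts = dict(config.options)
    seed = _stage_seed(config.seed, config.command)
    cmd = config.command

    def make_design(bank) -> TrialDesign:
        params = ProgressionParams(**opts["params"])
        hazard = HazardSpec(**opts["hazard"]) if opts.get("hazard") else None
        return TrialDesign(
            n_total=int(opts["n_total"]),
            params=params,
            bank=bank,
            schedule=VisitSchedule(tuple(opts.get("schedule", (0, 3, 6, 9, 12, 15, 18)))),
            allocation=float(opts.get("allocation", 0.5)),
            hazard=hazard,
            variant=opts.get("variant"),
            seed=seed,
        )

    if cmd == "simulate":
        bank = _resolve_bank(config)
        trial = simulate_trial(make_design(bank))
        for name, df in (
            ("responses", trial.responses),
            ("truth", trial.truth),
            ("dropout", trial.dropout),
        ):
            register(name, out / f"{name}.csv")
            df.to_csv(artifacts[name], index=False)
    elif cmd == "fit-baseline":
        bank = _resolve_bank(config)
        data = read_responses(config.inputs["responses"], bank)
        res = BaselineIRT(data, bank).fit(**opts.get("fit", {}))
        register("item_params", out / "item_params.csv")
        res.params.to_csv(artifacts["item_params"], index=False)
        register("bank_hat", out / "bank_hat.yaml")
        save_bank(res.bank_hat, artifacts["bank_hat"])
        register("fit", out / "fit.json")
        artifacts["fit"].write_text(
            json.dumps(
                dict(
                    llf=res.llf, converged=res.converged, seed=config.seed,
                    n_subjects=res.n_subjects,
                    n_observations=res.n_observations, settings=res.settings,
                ),
                indent=2,
            )
        )
    elif cmd == "fit-longitudinal":
        bank = _resolve_bank(config)
        data = read_responses(config.inputs["responses"], bank)
        model = LongitudinalIRT(
            data, bank, hazard_kind=opts.get("hazard_kind"),
            drug_effect=opts.get("drug_effect"),
        )
        res = model.fit(**opts.get("fit", {}))
        register("estimates", out / "estimates.csv")
        pd.DataFrame(
            {"estimate": res.estimates, "se": res.bse}
        ).to_csv(artifacts["estimates"])
        register("random_effects", out / "random_effects.csv")
        res.random_effects().to_csv(artifacts["random_effects"], index=False)
        register("fit", out / "fit.json")
        artifacts["fit"].write_text(
            json.dumps(
                dict(llf=res.llf, converged=res.converged, seed=config.seed,
                     settings=res.settings),
                indent=2,
            )
        )
    elif cmd == "information":
        bank = _resolve_bank(config)
        pop = PopulationSpec(
            opts.get("label", "population"),
            float(opts["mean"]), float(opts["sd"]),
        )
        register("ranking", out / "ranking.csv")
        rank_components(bank, pop).to_csv(artifacts["ranking"])
        register("curves", out / "curves.csv")
        information_curve(bank).to_csv(artifacts["curves"], index=False)
    elif cmd == "analyze":
        bank = _resolve_bank(config)
        if "totals" in config.inputs:
            totals = pd.read_csv(config.inputs["totals"])
        else:
            totals = total_score(
                read_responses(config.inputs["responses"], bank), bank
            )
        method = opts.get("method", "ls_means")
        if method == "ls_means":
            dec = ls_means_analysis(totals)
        elif method == "total_score":
            dec = fit_total_score_model(totals)
        else:
            raise ValueError(
                "analyze supports ls_means/total_score on totals; use "
                "fit-longitudinal for the IRT analysis"
            )
        register("decision", out / "decision.json")
        artifacts["decision"].write_text(
            json.dumps({**dec.__dict__, "seed": config.seed}, indent=2)
        )
    elif cmd == "evaluate-power":
        bank = _resolve_bank(config)
        methods = opts.get("methods", ["irt"])
        rows = []
        for n in opts.get("n_grid", [opts.get("n_total", 200)]):
            design = make_design(bank)
            design = TrialDesign(
                n_total=int(n), params=design.params, bank=bank,
                schedule=design.schedule, allocation=design.allocation,
                hazard=design.hazard, variant=design.variant, seed=None,
            )
            if opts.get("null"):
                from dataclasses import replace as _rep

                design = _rep(design, params=_rep(design.params, beta_drug=0.0))
            for r in power_study(
                methods, design, int(opts.get("replicates", 100)), seed
            ):
                rows.append(r.__dict__)
        register("power", out / "power.csv")
        pd.DataFrame(rows).to_csv(artifacts["power"], index=False)
    elif cmd == "vpc":
        bank = _resolve_bank(config)
        data = read_responses(config.inputs["responses"], bank)
        design = make_design(bank)
        register("vpc", out / "vpc.csv")
        vpc(
            data, design, n_replicates=int(opts.get("replicates", 200)),
            level=opts.get("level", "total"), seed=seed,
        ).to_csv(artifacts["vpc"], index=False)
    else:
        raise ValueError(f"unknown pipeline command {config.command!r}")

    manifest = dict(
        command=cmd,
        seed=config.seed,
        stage_seed=seed,
        options=opts,
        inputs={n: _sha256(Path(p)) for n, p in config.inputs.items()},
        outputs={n: _sha256(p) for n, p in artifacts.items()},
        versions=_versions(),
    )
    register("manifest", out / "manifest.json")
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels

    return dict(
        cogirt=__version__,
        numpy=np.__version__,
        pandas=pd.__version__,
        scipy=scipy.__version__,
        statsmodels=statsmodels.__version__,
    )
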