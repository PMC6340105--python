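"""Plain-text input/output for the standard tables.

All interchange formats are CSV: feeder events
(``animal,pen,start,duration_min,intake_g``), behaviour traits
(``animal,period,FR,FF,OT,FInt,days``), phenotypes
(``animal,pen,batch,age_on,age_off,adg``) and pedigrees
(``animal,sire,dam`` with 0 = unknown, handled in
:mod:`penmates.pedigree`).  Chain samples go to CSV with a JSON summary
and a YAML config echo next to them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import GibbsChains

__all__ = [
    "read_feeder_events", "write_feeder_events",
    "read_behaviour", "write_behaviour",
    "read_phenotypes", "write_phenotypes",
    "write_chains", "write_json",
]

_PHENO_COLS = ["animal", "pen", "batch", "age_on", "age_off", "adg"]
_EVENT_COLS = ["animal", "pen", "start", "duration_min", "intake_g"]


def read_feeder_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_EVENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"feeder-event file missing columns: {missing}")
    df["start"] = pd.to_datetime(df["start"])
    return df[_EVENT_COLS]


def write_feeder_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_EVENT_COLS)


def read_behaviour(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "days" in df.columns:
        df = df.rename(columns={"days": "days_observed"})
    if "period" not in df.columns:
        df["period"] = 0
    return df


def write_behaviour(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"days_observed": "days"})
    out.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PHENO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    return df[_PHENO_COLS]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_PHENO_COLS)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def write_chains(chains: GibbsChains, prefix) -> None:
    """Write retained variance-component samples (CSV), a JSON posterior
    summary and the chain config (YAML) under a common path prefix."""
    from .model import posterior_summary

    prefix = Path(prefix)
    chains.vc_frame.to_csv(prefix.with_suffix(".samples.csv"), index=False)
    summ = posterior_summary(chains)
    write_json({"model": chains.spec.label,
                "summary": {k: dict(v) for k, v in summ.T.items()}},
               prefix.with_suffix(".summary.json"))
    cfg = {"chain_length": chains.config.chain_length,
           "burn_in": chains.config.burn_in, "thin": chains.config.thin,
           "seed": chains.config.seed,
           "retained": int(chains.vc.shape[0]),
           "model": chains.spec.label}
    prefix.with_suffix(".config.yaml").write_text(yaml.safe_dump(cfg))
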