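"""End-to-end experiment orchestration.

:func:`run_experiment` ties the stages together the way the full analysis
runs: behaviour traits -> interaction matrices -> model fits (any subset
of AM, AM-IGE and the five AM-IGE_i variants) -> genetic-parameter
reports, DIC/cross-validation table and pairwise ranking-agreement
matrices.  Everything is deterministic given the seeds in the config, and
every output file records the package version, the seed and a config
hash.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, genetics, io
from .behaviour import interaction_matrix
from .evaluation import (bv_component_correlations, cross_validate, dic,
                         make_folds, ranking_correlations,
                         top_fraction_coincidence)
from .model import (GibbsConfig, ModelSpec, build_design, gibbs_sampler,
                    posterior_summary)
from .pedigree import (inverse_relationship_matrix,
                       mean_within_group_relationship, relationship_matrix)
from .simulate import SimulationParams, simulate_dataset

__all__ = ["RunConfig", "run_experiment"]

log = logging.getLogger("penmates")

#: model keys accepted in RunConfig.models
MODEL_KEYS = {
    "AM": ModelSpec("AM"),
    "AM_IGE": ModelSpec("AM_IGE"),
    "AM_IGE_FR": ModelSpec("AM_IGE_i", "FR"),
    "AM_IGE_FF": ModelSpec("AM_IGE_i", "FF"),
    "AM_IGE_OT": ModelSpec("AM_IGE_i", "OT"),
    "AM_IGE_FINT": ModelSpec("AM_IGE_i", "FINT"),
    "AM_IGE_ALL": ModelSpec("AM_IGE_i", "ALL"),
}


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    models: list = field(default_factory=lambda: ["AM", "AM_IGE",
                                                  "AM_IGE_OT"])
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    cv_folds: int = 8
    cv_seed: int = 0
    run_cv: bool = True
    cv_gibbs: GibbsConfig | None = None  # reduced chains for CV refits
    sim: SimulationParams | None = None  # simulate when no files given
    pedigree_file: str | None = None
    phenotype_file: str | None = None
    behaviour_file: str | None = None
    out_dir: str = "penmates_out"

    def config_hash(self) -> str:
        blob = yaml.safe_dump({
            "models": self.models,
            "gibbs": [self.gibbs.chain_length, self.gibbs.burn_in,
                      self.gibbs.thin, self.gibbs.seed],
            "cv": [self.cv_folds, self.cv_seed, self.run_cv],
            "files": [self.pedigree_file, self.phenotype_file,
                      self.behaviour_file],
            "sim_seed": self.sim.seed if self.sim else None,
        }, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (f"penmates {__version__} seed={config.gibbs.seed} "
            f"config={config.config_hash()}")


def _load_inputs(config: RunConfig):
    if config.phenotype_file is None:
        sim = config.sim or SimulationParams()
        log.info("simulating dataset (seed %d)", sim.seed)
        data = simulate_dataset(sim)
        return data.pedigree, data.phenotypes, data.behaviour_overall
    from .pedigree import read_pedigree
    ped = read_pedigree(config.pedigree_file)
    phen = io.read_phenotypes(config.phenotype_file)
    beh = (io.read_behaviour(config.behaviour_file)
           if config.behaviour_file else None)
    return ped, phen, beh


def run_experiment(config: RunConfig) -> dict:
    """Run every configured model on one dataset and compare them.

    Emits per-model genetic-parameter reports, chain outputs, a DIC/CV
    comparison table and pairwise ranking-agreement matrices into
    ``config.out_dir``; returns the comparison report as a dict of
    DataFrames/dicts.
    """
    t0 = time.time()
    if not config.models:
        raise ValueError("model list is empty")
    unknown = [m for m in config.models if m not in MODEL_KEYS]
    if unknown:
        raise ValueError(f"unknown model keys: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _provenance(config)

    try:
        ped, phen, beh = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load inputs' failed: {exc}") from exc

    pens = pd.Series(phen["pen"].values, index=phen["animal"].values)
    A = relationship_matrix(ped)
    Ainv = inverse_relationship_matrix(ped)
    r, _ = mean_within_group_relationship(
        A, {a: p for a, p in pens.items()}, ped)
    n_mean = float(pens.groupby(pens).size().mean())
    log.info("mean pen size %.2f, mean within-pen relationship %.4f",
             n_mean, r)

    results: dict = {"provenance": stamp, "r": r, "mean_pen_size": n_mean,
                     "models": {}}
    tbvs: dict = {}
    comparison_rows = []
    phen_pos = ped.positions(phen["animal"])

    for key in config.models:
        spec = MODEL_KEYS[key]
        try:
            C = None
            if spec.has_social:
                mode = ("CLASSICAL" if spec.model_class == "AM_IGE"
                        else spec.interaction_mode)
                C = interaction_matrix(beh if beh is not None
                                       else pd.DataFrame(), pens, mode)
            design = build_design(phen, spec, ped, C)
            chains = gibbs_sampler(design, Ainv, config.gibbs)
            summ = posterior_summary(chains, n=n_mean, r=r)
            summ.to_csv(out / f"genetic_params_{key}.csv",
                        index_label=f"parameter  # {stamp}")
            io.write_chains(chains, out / f"chains_{key}")
            d = dic(chains, design)

            aD = chains.a_D.mean(axis=0)
            if chains.a_S is not None:
                aS = chains.a_S.mean(axis=0)
                bvs = genetics.total_breeding_values(aD, aS, design.S)
            else:
                bvs = genetics.total_breeding_values(aD, None)
            tbv = pd.Series(bvs["TBV"].to_numpy()[phen_pos],
                            index=phen["animal"].values)
            tbvs[key] = tbv

            row = {"model": key, "DIC": d["DIC"], "pD": d["pD"]}
            if config.run_cv:
                plan = make_folds(phen["pen"], k=config.cv_folds,
                                  seed=config.cv_seed)
                cv_cfg = config.cv_gibbs or GibbsConfig(
                    chain_length=max(config.gibbs.chain_length // 5, 2000),
                    burn_in=max(config.gibbs.burn_in // 5, 500),
                    thin=config.gibbs.thin, seed=config.gibbs.seed)
                cv = cross_validate(design, Ainv, plan, cv_cfg)
                row["cv_mean_r"] = cv["mean_r"]
                row["cv_sd_r"] = cv["sd_r"]
            comparison_rows.append(row)

            model_report = {"posterior": summ, "dic": d}
            if spec.has_social:
                model_report["bv_correlations"] = bv_component_correlations(
                    bvs, phenotyped=phen_pos)
                if spec.model_class == "AM_IGE_i":
                    vc = chains.vc_mean()
                    tq = genetics.t2_at_quartiles(vc, C, n=n_mean, r=r)
                    model_report["t2_quartiles"] = {
                        **tq, **genetics.t2_quartile_report(
                            tq["T2_q1"], tq["T2_q3"], tq["T2_mean"], key)}
            results["models"][key] = model_report
            log.info("model %s done (DIC %.1f)", key, d["DIC"])
        except Exception as exc:
            raise RuntimeError(f"stage 'fit {key}' failed: {exc}") from exc

    comparison = pd.DataFrame(comparison_rows).set_index("model")
    comparison.to_csv(out / "comparison.csv",
                      index_label=f"model  # {stamp}")
    results["comparison"] = comparison

    keys = list(tbvs)
    coin = pd.DataFrame(np.nan, index=keys, columns=keys)
    rank = pd.DataFrame(np.nan, index=keys, columns=keys)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            coin.loc[ka, kb] = top_fraction_coincidence(tbvs[ka], tbvs[kb])
            rank.loc[kb, ka] = ranking_correlations(tbvs[ka],
                                                    tbvs[kb])["spearman"]
    coin.to_csv(out / "top10_coincidence.csv",
                index_label=f"model  # {stamp}")
    rank.to_csv(out / "rank_correlations.csv",
                index_label=f"model  # {stamp}")
    results["top10_coincidence"] = coin
    results["rank_correlations"] = rank

    io.write_json({"provenance": stamp, "elapsed_s": time.time() - t0,
                   "models": config.models,
                   "comparison": comparison.reset_index()
                   .to_dict(orient="records")},
                  out / "report.json")
    log.info("experiment finished in %.1f s", time.time() - t0)
    return results
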