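"""Model comparison: DIC, pen-wise cross-validation and ranking agreement.

Four complementary criteria decide between the candidate models:

1. accuracy of estimation — posterior SDs of the genetic parameters
   (read off :func:`penmates.model.posterior_summary`);
2. goodness of fit — the deviance information criterion (DIC);
3. predictive ability — k-fold cross-validation holding out one record
   per pen per fold, scoring the correlation between observed and
   predicted growth;
4. ranking agreement — top-fraction coincidence and rank correlations
   between the breeding-value rankings different models produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (DesignMatrices, GibbsChains, GibbsConfig, gibbs_sampler,
                    subset_design)

__all__ = [
    "FoldPlan",
    "dic",
    "make_folds",
    "cross_validate",
    "top_fraction_coincidence",
    "ranking_correlations",
    "bv_component_correlations",
]


def _fitted_matrix(chains: GibbsChains, design: DesignMatrices) -> np.ndarray:
    """Location predictor mu per record (rows) and retained sample (cols)."""
    mu = design.X @ chains.b.T                 # n x m
    mu += chains.pen[:, design.pen_code].T
    if chains.a_D.shape[1] == design.q:
        mu += chains.a_D[:, design.rec_animal].T
    if chains.a_S is not None and design.S is not None:
        mu += design.S @ chains.a_S.T
    return mu


def dic(chains: GibbsChains, design: DesignMatrices) -> dict:
    """Deviance information criterion with conditional Gaussian deviance.

    The deviance conditions on the location effects (fixed, pen, genetic)
    and the residual variance:
    ``D(theta) = n log(2 pi sigma2_e) + ||y - mu(theta)||^2 / sigma2_e``.
    ``pD = mean D - D(posterior means)``; ``DIC = mean D + pD``.  This is
    the convention of the Gibbs-sampling software family used for this
    model class; the marginal alternative (integrating the random effects
    out) is not computed here.
    """
    m = chains.vc.shape[0]
    if m < 100:
        warnings.warn("fewer than 100 retained samples; DIC is noisy")
    mu = _fitted_matrix(chains, design)
    s2e = chains.vc[:, 4]
    n = design.n
    resid2 = ((design.y[:, None] - mu) ** 2).sum(axis=0)
    deviances = n * np.log(2.0 * np.pi * s2e) + resid2 / s2e
    mean_dev = float(deviances.mean())

    mu_bar = mu.mean(axis=1)
    s2e_bar = float(s2e.mean())
    dev_at_mean = (n * np.log(2.0 * np.pi * s2e_bar)
                   + float(((design.y - mu_bar) ** 2).sum()) / s2e_bar)
    pd_eff = mean_dev - dev_at_mean
    return {"DIC": mean_dev + pd_eff, "pD": pd_eff, "mean_deviance": mean_dev}


@dataclass
class FoldPlan:
    """Cross-validation plan: per fold, the held-out record row indices.

    Folds are pen-stratified: each fold holds out (at most) one record per
    pen, so with 57 pens every validation set has 57 different animals.
    """

    folds: list  # list of np.ndarray of record row indices
    k: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_folds(pens, k: int = 8, seed: int = 0) -> FoldPlan:
    """Pen-stratified fold assignment, one held-out record per pen per fold.

    Within each pen, ``k`` records are sampled without replacement (one
    per fold); pens with fewer than ``k`` records contribute to only some
    folds (each record held out at most once) with a warning.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    pens = pd.Series(pens).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for pen, members in pens.groupby(pens):
        rows = members.index.to_numpy()
        if rows.size < k:
            warnings.warn(f"pen {pen!r} has {rows.size} records < {k} "
                          "folds; it is absent from some folds")
        perm = rng.permutation(rows)
        for f in range(min(k, rows.size)):
            folds[f].append(perm[f])
    return FoldPlan([np.sort(np.array(f, dtype=int)) for f in folds], k, seed)


def cross_validate(design: DesignMatrices, Ainv, plan: FoldPlan,
                   config: GibbsConfig) -> dict:
    """Predictive ability by pen-stratified cross-validation.

    Per fold the model is refit (variance components included) on the
    training records; a held-out animal's growth is then predicted from
    the fixed-effect part, its pen effect, its own direct breeding value
    (propagated through the pedigree) and the sum over its pen mates of
    interaction coefficient times mate social breeding value.  The
    interaction coefficients of held-out animals come from the behaviour
    data, which is an input, not the response, so they stay available at
    prediction time.

    Returns fold-wise Pearson correlations r(y, y_hat) plus their mean
    and SD.
    """
    n = design.n
    rs = []
    for f, held in enumerate(plan):
        if held.size < 3:
            warnings.warn(f"fold {f} holds fewer than 3 records; skipped")
            continue
        train = np.setdiff1d(np.arange(n), held)
        sub = subset_design(design, train)
        cfg = GibbsConfig(config.chain_length, config.burn_in, config.thin,
                          seed=config.seed + 1000 * (f + 1),
                          variance_bound_factor=config.variance_bound_factor)
        chains = gibbs_sampler(sub, Ainv, cfg)
        b = chains.b.mean(axis=0)
        pen = chains.pen.mean(axis=0)
        aD = chains.a_D.mean(axis=0)
        yhat = design.X[held] @ b + pen[design.pen_code[held]]
        if chains.a_D.shape[1] == design.q:
            yhat = yhat + aD[design.rec_animal[held]]
        if chains.a_S is not None and design.S is not None:
            aS = chains.a_S.mean(axis=0)
            yhat = yhat + design.S[held] @ aS
        rs.append(float(stats.pearsonr(design.y[held], yhat).statistic))
    rs = np.array(rs)
    return {"fold_r": rs, "mean_r": float(rs.mean()),
            "sd_r": float(rs.std(ddof=1)) if rs.size > 1 else np.nan}


def _top_set(values: pd.Series, size: int) -> set:
    """Indices of the ``size`` largest values; ties broken by stable
    animal-id order."""
    order = sorted(values.index, key=lambda a: (-values[a], str(a)))
    return set(order[:size])


def top_fraction_coincidence(bv_a: pd.Series, bv_b: pd.Series,
                             fraction: float = 0.10) -> float:
    """Percentage overlap of the top-``fraction`` animals of two rankings.

    Both series must cover the same animals; under independent rankings
    of n animals the expected coincidence is 100*fraction percent.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    bv_a, bv_b = pd.Series(bv_a), pd.Series(bv_b)
    if set(bv_a.index) != set(bv_b.index):
        raise ValueError("rankings must cover the same animals")
    n = len(bv_a)
    if n < 10:
        raise ValueError("need at least 10 animals for a top-fraction set")
    size = max(1, int(round(n * fraction)))
    ta = _top_set(bv_a, size)
    tb = _top_set(bv_b.loc[bv_a.index], size)
    return 100.0 * len(ta & tb) / size


def ranking_correlations(bv_a: pd.Series, bv_b: pd.Series) -> dict:
    """Spearman and Pearson correlation between two breeding-value sets."""
    bv_a, bv_b = pd.Series(bv_a), pd.Series(bv_b)
    bv_b = bv_b.loc[bv_a.index]
    if bv_a.std() == 0 or bv_b.std() == 0:
        warnings.warn("zero-variance ranking; correlations undefined")
        return {"spearman": np.nan, "pearson": np.nan}
    return {"spearman": float(stats.spearmanr(bv_a, bv_b).statistic),
            "pearson": float(stats.pearsonr(bv_a, bv_b).statistic)}


def bv_component_correlations(bvs: pd.DataFrame,
                              phenotyped: list | None = None) -> dict:
    """Correlations among DBV, SBV and TBV over phenotyped animals.

    ``bvs`` is the frame from
    :func:`penmates.genetics.total_breeding_values`; ``phenotyped``
    restricts to pedigree positions (or index labels) with a record.
    Raises for direct-effects-only fits, which have no SBV.
    """
    if "SBV" not in bvs.columns or np.allclose(bvs["SBV"], 0.0):
        raise ValueError("no social breeding values: component correlations "
                         "require a social model")
    tab = bvs.loc[phenotyped] if phenotyped is not None else bvs
    return {
        "cor_DBV_SBV": float(stats.pearsonr(tab["DBV"], tab["SBV"]).statistic),
        "cor_DBV_TBV": float(stats.pearsonr(tab["DBV"], tab["TBV"]).statistic),
        "cor_SBV_TBV": float(stats.pearsonr(tab["SBV"], tab["TBV"]).statistic),
    }
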