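"""Variance partitioning under social animal models.

With direct and indirect (social) genetic effects, an animal's total
heritable impact on the population mean is its total breeding value

    TBV_i = a_Di + (n - 1) a_Si            (classical, equal degrees)
    TBV_i = a_Di + (sum_j c_ji) a_Si       (pair-specific degrees)

where ``n`` is the group size.  At an average interaction degree ``c``,
the variance of total breeding values and the total phenotypic variance
are

    sigma2_TBV = sigma2_D + 2 c (n-1) sigma_DS + c^2 (n-1)^2 sigma2_S
    sigma2_P   = sigma2_D + c^2 (n-1) sigma2_S
               + r [2 c (n-1) sigma_DS + c^2 (n-1)(n-2) sigma2_S]
               + sigma2_pen + sigma2_e

with ``r`` the mean additive relationship between pen mates.  Their ratio
``T2 = sigma2_TBV / sigma2_P`` generalizes heritability and may exceed 1.
For pair-specific models the degree scale is centred (mean standardized
distance = 0), so ``c = 0`` evaluates T2 at the average interaction and
the empirical quartiles of the C entries probe low/high-competition pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

from .behaviour import InteractionMatrix
from .model import VarianceComponents

__all__ = [
    "heritability",
    "total_heritable_variance",
    "total_phenotypic_variance",
    "t2",
    "t2_at_quartiles",
    "t2_quartile_report",
    "total_breeding_values",
    "partition_row",
]


def heritability(vc: VarianceComponents,
                 phenotypic_variance: float | None = None) -> float:
    """Narrow-sense heritability sigma2_D / sigma2_P.

    Without an explicit phenotypic variance the naive sum
    ``sigma2_D + sigma2_pen + sigma2_e`` is used (the AM decomposition).
    """
    if phenotypic_variance is None:
        phenotypic_variance = vc.sigma2_D + vc.sigma2_pen + vc.sigma2_e
    if phenotypic_variance <= 0:
        raise ValueError("phenotypic variance must be positive")
    return vc.sigma2_D / phenotypic_variance


def total_heritable_variance(vc: VarianceComponents, n: float,
                             c: float = 1.0) -> float:
    """Variance of total breeding values at average interaction degree c.

    ``c = 1`` gives the classical equal-degree social model; ``c = 0``
    (the mean of a centred degree scale) leaves only the direct variance.
    The result can be smaller than sigma2_D when sigma_DS < 0.
    """
    nm1 = n - 1.0
    return (vc.sigma2_D + 2.0 * c * nm1 * vc.sigma_DS
            + c * c * nm1 * nm1 * vc.sigma2_S)


def total_phenotypic_variance(vc: VarianceComponents, n: float,
                              r: float = 0.0, c: float = 1.0) -> float:
    """Total phenotypic variance under the social model.

    Includes the direct variance, the social variance received from the
    n-1 mates, relatedness-driven covariance terms scaled by the mean
    within-pen relationship ``r``, and the pen and residual variances.
    """
    nm1 = n - 1.0
    out = (vc.sigma2_D + c * c * nm1 * vc.sigma2_S
           + r * (2.0 * c * nm1 * vc.sigma_DS
                  + c * c * nm1 * (n - 2.0) * vc.sigma2_S)
           + vc.sigma2_pen + vc.sigma2_e)
    if out <= 0:
        raise ValueError("inadmissible variance components: non-positive "
                         "total phenotypic variance")
    return out


def t2(vc: VarianceComponents, n: float, r: float = 0.0,
       c: float = 1.0) -> float:
    """T2 = sigma2_TBV / sigma2_P; may exceed 1 under social models."""
    return (total_heritable_variance(vc, n, c)
            / total_phenotypic_variance(vc, n, r, c))


def partition_row(vc: VarianceComponents, n: float, r: float = 0.0,
                  c: float = 1.0) -> dict:
    """One sample's derived parameters (used sample-wise along chains)."""
    s2tbv = total_heritable_variance(vc, n, c)
    s2p = total_phenotypic_variance(vc, n, r, c)
    return {"sigma2_TBV": s2tbv, "sigma2_P": s2p, "T2": s2tbv / s2p}


def t2_at_quartiles(vc: VarianceComponents, C: InteractionMatrix,
                    n: float, r: float = 0.0) -> dict:
    """T2 evaluated at the quartiles of the interaction-degree scale.

    Plugs the empirical Q1 and Q3 of the within-pen off-diagonal entries
    of ``C`` (and the mean, 0 by construction) in as the degree ``c``.
    Large Q3-Q1 spread in T2 flags models where the heritable share of
    variance depends strongly on how much a pair competes.
    """
    if C.mode == "CLASSICAL":
        raise ValueError("quartiles are undefined on the 0/1 classical "
                         "degree scale")
    entries = C.within_pen_pairs()
    q1, q3 = np.percentile(entries, [25.0, 75.0])
    return {
        "c_q1": float(q1), "c_q3": float(q3),
        "T2_q1": t2(vc, n, r, c=float(q1)),
        "T2_mean": t2(vc, n, r, c=0.0),
        "T2_q3": t2(vc, n, r, c=float(q3)),
    }


def t2_quartile_report(T2_q1: float, T2_q3: float, T2_mean: float
                       | None = None, model: str = "") -> dict:
    """Contrast of T2 between high- and low-interaction pairs.

    The headline of the quartile analysis is the spread ``T2(Q3) -
    T2(Q1)``; e.g. quartile estimates of 0.53 and 1.29 give a contrast of
    0.76, while 0.33 and 1.24 give 0.91.
    """
    out = {"model": model, "T2_q1": float(T2_q1), "T2_q3": float(T2_q3),
           "q3_minus_q1": float(T2_q3) - float(T2_q1)}
    if T2_mean is not None:
        out["T2_mean"] = float(T2_mean)
    return out


def total_breeding_values(a_D: np.ndarray, a_S: np.ndarray | None,
                          S: sparse.spmatrix | None = None) -> pd.DataFrame:
    """Direct, social and total breeding values per pedigree position.

    TBV_i = DBV_i + (column sum of the social incidence at i) * SBV_i —
    the animal's direct merit plus its total expressed influence on the
    records of its mates.  For the classical incidence this reduces to
    DBV + (n-1) SBV.  Animals never appearing as a social contributor
    (no pen / no phenotyped mates) keep TBV = DBV and are flagged.
    """
    a_D = np.asarray(a_D, dtype=float)
    out = pd.DataFrame({"DBV": a_D})
    if a_S is None:
        out["SBV"] = 0.0
        out["TBV"] = a_D
        out["no_social_exposure"] = True
        return out
    a_S = np.asarray(a_S, dtype=float)
    if S is None:
        raise ValueError("social incidence S required when a_S is given")
    colsum = np.asarray(S.sum(axis=0)).ravel()
    if colsum.size != a_D.size:
        raise ValueError("S columns must align with the effect vectors")
    out["SBV"] = a_S
    out["TBV"] = a_D + colsum * a_S
    out["no_social_exposure"] = colsum == 0
    if out["no_social_exposure"].any():
        warnings.warn(f"{int(out['no_social_exposure'].sum())} animals have "
                      "no social exposure; their TBV equals DBV")
    return out
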