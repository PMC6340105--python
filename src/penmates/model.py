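"""Gaussian mixed models for growth with indirect genetic effects.

One configurable model covers the three analyses:

* ``AM``        y = Xb + Z_p p + Z_a a + e                (direct effects only)
* ``AM_IGE``    y = Xb + Z_p p + Z_a a_D + Z_s a_S + e    (0/1 pen-mate incidence)
* ``AM_IGE_i``  y = Xb + Z_p p + Z_a a_D + C_s a_S + e    (pair-specific degrees)

with fixed effects batch + initial age + final age + pigs-per-pen, random
pen effects ``p ~ N(0, I sigma2_pen)``, genetic effects
``(a_D, a_S) ~ N(0, G (x) A)`` (effect-major stacking, so the prior
precision is ``G^-1 (x) A^-1``), and residuals ``e ~ N(0, I sigma2_e)``.

Inference is Gibbs sampling with flat priors on fixed effects and variance
components (made proper by a wide upper bound): Gaussian full conditionals
for locations (scalar sites for b and pen, per-animal 2x2 blocks for the
genetic pair), scaled inverse chi-square full conditionals for
``sigma2_pen`` and ``sigma2_e``, and an inverse-Wishart full conditional
for ``G``.  The sweep kernel is numba-compiled; chains are exactly
reproducible from the seed.

:func:`em_reml` provides a likelihood-based point estimator of the same
variance components, used as an independent cross-check of the Bayesian
posterior summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .behaviour import InteractionMatrix, interaction_matrix
from .pedigree import Pedigree

__all__ = [
    "MODEL_CLASSES",
    "ModelSpec",
    "VarianceComponents",
    "DesignMatrices",
    "GibbsConfig",
    "GibbsChains",
    "build_design",
    "subset_design",
    "gibbs_sampler",
    "posterior_summary",
    "em_reml",
]

MODEL_CLASSES = ("AM", "AM_IGE", "AM_IGE_i")

VC_NAMES = ("sigma2_D", "sigma2_S", "sigma_DS", "sigma2_pen", "sigma2_e")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit and, for ``AM_IGE_i``, which interaction mode."""

    model_class: str = "AM"
    interaction_mode: str | None = None  # FR/FF/OT/FINT/ALL for AM_IGE_i

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.model_class == "AM_IGE_i" and self.interaction_mode is None:
            raise ValueError("AM_IGE_i needs an interaction mode")

    @property
    def has_social(self) -> bool:
        return self.model_class != "AM"

    @property
    def label(self) -> str:
        if self.model_class == "AM_IGE_i":
            return f"AM-IGE_{self.interaction_mode}"
        return self.model_class.replace("_", "-")


@dataclass(frozen=True)
class VarianceComponents:
    """(Co)variance components, all on the squared trait scale (g/day)^2."""

    sigma2_D: float
    sigma2_S: float = 0.0
    sigma_DS: float = 0.0
    sigma2_pen: float = 0.0
    sigma2_e: float = 1.0

    @property
    def G(self) -> np.ndarray:
        """Direct/social genetic (co)variance matrix."""
        return np.array([[self.sigma2_D, self.sigma_DS],
                         [self.sigma_DS, self.sigma2_S]])

    @property
    def genetic_correlation(self) -> float:
        denom = np.sqrt(self.sigma2_D * self.sigma2_S)
        return self.sigma_DS / denom if denom > 0 else np.nan

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_D, self.sigma2_S, self.sigma_DS,
                         self.sigma2_pen, self.sigma2_e])

    @classmethod
    def from_array(cls, x) -> "VarianceComponents":
        return cls(*[float(v) for v in x])


@dataclass
class DesignMatrices:
    """Numeric design of one model fit, aligned row-by-row with ``y``."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    pen_code: np.ndarray      # record -> dense pen index
    pen_ids: list
    rec_animal: np.ndarray    # record -> pedigree position
    S: sparse.csr_matrix | None  # social incidence, records x pedigree
    q: int                    # pedigree size (genetic-effect count per type)
    animal_ids: list          # record order
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_pen(self) -> int:
        return len(self.pen_ids)


def _design_X(data: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Fixed-effects design: intercept + batch (reference-coded) +
    initial age + final age + centred pigs-per-pen."""
    batches = sorted(data["batch"].unique())
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for b in batches[1:]:
        cols.append((data["batch"] == b).to_numpy(float))
        names.append(f"batch[{b}]")
    for cov in ("age_on", "age_off"):
        cols.append(data[cov].to_numpy(float))
        names.append(cov)
    npen = data.groupby("pen")["animal"].transform("count").to_numpy(float)
    if np.ptp(npen) > 0:
        cols.append(npen - npen.mean())
        names.append("pigs_per_pen_centred")
    else:
        warnings.warn("constant pen size; pigs-per-pen covariate dropped")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR identifies the dependent columns
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[k]] for k in range(X.shape[1])
               if abs(R[k, k]) < tol]
        raise ValueError(f"fixed-effects design is rank deficient; "
                         f"collinear columns: {bad}")
    return X, names


def build_design(data: pd.DataFrame, spec: ModelSpec, ped: Pedigree,
                 C: InteractionMatrix | None = None) -> DesignMatrices:
    """Assemble ``y`` and all incidence structures for one model.

    Parameters
    ----------
    data : phenotype table with columns ``animal, pen, batch, age_on,
        age_off, adg`` (one record per animal).
    ped : sorted pedigree containing every phenotyped animal.
    C : interaction matrix; required for ``AM_IGE_i`` (standardized mode),
        optional for ``AM_IGE`` (a classical 0/1 matrix is built from the
        pen assignment when omitted).

    The social incidence ``S`` maps records to pedigree columns: row i
    holds animal i's interaction coefficients with its pen mates, zero at
    its own column.
    """
    data = data.reset_index(drop=True)
    if data["animal"].duplicated().any():
        raise ValueError("multiple records per animal are not supported")
    missing = [a for a in data["animal"] if a not in ped.index]
    if missing:
        raise ValueError(f"animals missing from pedigree: {missing[:5]}")

    y = data["adg"].to_numpy(float)
    X, x_names = _design_X(data)
    pen_ids = sorted(data["pen"].unique())
    pen_pos = {p: i for i, p in enumerate(pen_ids)}
    pen_code = data["pen"].map(pen_pos).to_numpy(np.int64)
    rec_animal = ped.positions(data["animal"])

    S = None
    if spec.has_social:
        pens = pd.Series(data["pen"].values, index=data["animal"].values)
        if spec.model_class == "AM_IGE":
            if C is None:
                C = interaction_matrix(pd.DataFrame(), pens, "CLASSICAL")
            elif C.mode != "CLASSICAL":
                raise ValueError("AM_IGE requires a CLASSICAL interaction "
                                 "matrix")
        else:
            if C is None or C.mode == "CLASSICAL":
                raise ValueError("AM_IGE_i requires a standardized "
                                 "interaction matrix")
        rows, cols, vals = [], [], []
        cpos = [C.position(a) for a in data["animal"]]
        by_pen: dict = {}
        for r, p in enumerate(pen_code):
            by_pen.setdefault(p, []).append(r)
        for members in by_pen.values():
            for r in members:
                for r2 in members:
                    if r2 == r:
                        continue
                    cval = C.C[cpos[r], cpos[r2]]
                    if cval != 0.0:
                        rows.append(r)
                        cols.append(rec_animal[r2])
                        vals.append(cval)
        S = sparse.csr_matrix((vals, (rows, cols)),
                              shape=(len(data), len(ped)))
    return DesignMatrices(y, X, x_names, pen_code, pen_ids, rec_animal, S,
                          len(ped), list(data["animal"]), spec)


def subset_design(design: DesignMatrices, rows: np.ndarray) -> DesignMatrices:
    """Row subset of a design (used by cross-validation training splits)."""
    rows = np.asarray(rows)
    return DesignMatrices(
        y=design.y[rows], X=design.X[rows], x_names=design.x_names,
        pen_code=design.pen_code[rows], pen_ids=design.pen_ids,
        rec_animal=design.rec_animal[rows],
        S=design.S[rows] if design.S is not None else None,
        q=design.q, animal_ids=[design.animal_ids[r] for r in rows],
        spec=design.spec)


@dataclass(frozen=True)
class GibbsConfig:
    """Chain protocol.  The full-scale published-style protocol
    (3,000,000 / 300,000 / 10) is available by configuration; the default
    is a desk-scale chain adequate for the synthetic datasets here."""

    chain_length: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    variance_bound_factor: float = 1e6  # upper prior bound, x var(y)

    def __post_init__(self):
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class GibbsChains:
    """Retained posterior samples of all unknowns plus config echo."""

    vc: np.ndarray       # retained x 5, columns VC_NAMES
    b: np.ndarray        # retained x p
    pen: np.ndarray      # retained x n_pen
    a_D: np.ndarray      # retained x q
    a_S: np.ndarray | None
    config: GibbsConfig
    spec: ModelSpec
    n_clamped: int = 0

    @property
    def vc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vc, columns=list(VC_NAMES))

    def vc_mean(self) -> VarianceComponents:
        return VarianceComponents.from_array(self.vc.mean(axis=0))


@numba.njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.standard_gamma(df / 2.0)


@numba.njit(cache=True)
def _gibbs_kernel(seed, n_iter, burn, thin,
                  y, X, xtx, pen_code, pen_indptr, pen_rows,
                  own_row, soc_indptr, soc_rows, soc_vals,
                  srow_indptr, srow_cols, srow_vals, rec_animal,
                  ai_indptr, ai_indices, ai_data,
                  has_genetic, has_social, has_pen,
                  init_vc, var_lo, var_hi,
                  out_vc, out_b, out_pen, out_aD, out_aS):
    np.random.seed(seed)
    n = y.size
    p = X.shape[1]
    n_pen = pen_indptr.size - 1
    q = own_row.size

    b = np.zeros(p)
    pen = np.zeros(n_pen)
    aD = np.zeros(q)
    aS = np.zeros(q)
    s2D, s2S, sDS, s2p, s2e = (init_vc[0], init_vc[1], init_vc[2],
                               init_vc[3], init_vc[4])
    e = y.copy()
    n_clamped = 0
    n_rejects = 0
    stored = 0

    for it in range(n_iter):
        # ---- fixed effects, scalar sites, flat prior
        for k in range(p):
            r = 0.0
            for i in range(n):
                r += X[i, k] * e[i]
            r += xtx[k] * b[k]
            mean = r / xtx[k]
            new = mean + np.random.standard_normal() * np.sqrt(s2e / xtx[k])
            delta = b[k] - new
            for i in range(n):
                e[i] += X[i, k] * delta
            b[k] = new

        # ---- pen effects
        if has_pen:
            for j in range(n_pen):
                lo, hi = pen_indptr[j], pen_indptr[j + 1]
                nj = hi - lo
                r = nj * pen[j]
                for k in range(lo, hi):
                    r += e[pen_rows[k]]
                prec = nj / s2e + 1.0 / s2p
                mean = (r / s2e) / prec
                new = mean + np.random.standard_normal() / np.sqrt(prec)
                delta = pen[j] - new
                for k in range(lo, hi):
                    e[pen_rows[k]] += delta
                pen[j] = new

        # ---- genetic effects, per-animal blocks
        if has_genetic:
            if has_social:
                det_g = s2D * s2S - sDS * sDS
                gi11 = s2S / det_g
                gi22 = s2D / det_g
                gi12 = -sDS / det_g
            else:
                gi11 = 1.0 / s2D
                gi12 = 0.0
                gi22 = 0.0
            for i in range(q):
                own = own_row[i]
                rD = 0.0
                mDD = 0.0
                if own >= 0:
                    e[own] += aD[i]
                    rD = e[own]
                    mDD = 1.0
                rS = 0.0
                mSS = 0.0
                if has_social:
                    for k in range(soc_indptr[i], soc_indptr[i + 1]):
                        row = soc_rows[k]
                        c = soc_vals[k]
                        e[row] += c * aS[i]
                    for k in range(soc_indptr[i], soc_indptr[i + 1]):
                        row = soc_rows[k]
                        c = soc_vals[k]
                        rS += c * e[row]
                        mSS += c * c
                sD = 0.0
                sS = 0.0
                aii = 0.0
                for k in range(ai_indptr[i], ai_indptr[i + 1]):
                    j = ai_indices[k]
                    v = ai_data[k]
                    if j == i:
                        aii = v
                    else:
                        sD += v * aD[j]
                        sS += v * aS[j]
                if has_social:
                    P11 = mDD / s2e + aii * gi11
                    P22 = mSS / s2e + aii * gi22
                    P12 = aii * gi12
                    r1 = rD / s2e - (gi11 * sD + gi12 * sS)
                    r2 = rS / s2e - (gi12 * sD + gi22 * sS)
                    det = P11 * P22 - P12 * P12
                    c11 = P22 / det
                    c22 = P11 / det
                    c12 = -P12 / det
                    m1 = c11 * r1 + c12 * r2
                    m2 = c12 * r1 + c22 * r2
                    L11 = np.sqrt(c11)
                    L21 = c12 / L11
                    L22 = np.sqrt(max(c22 - L21 * L21, 1e-300))
                    z1 = np.random.standard_normal()
                    z2 = np.random.standard_normal()
                    aD[i] = m1 + L11 * z1
                    aS[i] = m2 + L21 * z1 + L22 * z2
                else:
                    prec = mDD / s2e + aii * gi11
                    mean = (rD / s2e - gi11 * sD) / prec
                    aD[i] = mean + np.random.standard_normal() / np.sqrt(prec)
                if own >= 0:
                    e[own] -= aD[i]
                if has_social:
                    for k in range(soc_indptr[i], soc_indptr[i + 1]):
                        e[soc_rows[k]] -= soc_vals[k] * aS[i]

        # ---- variance components
        if has_pen:
            ssp = 0.0
            for j in range(n_pen):
                ssp += pen[j] * pen[j]
            s2p = ssp / _chi2(n_pen - 2.0)
            if s2p > var_hi:
                s2p = var_hi
                n_clamped += 1
            if s2p < var_lo:
                s2p = var_lo

        if has_genetic:
            # scale matrix of the inverse-Wishart: crossproducts in the
            # A^-1 metric
            s11 = 0.0
            s12 = 0.0
            s22 = 0.0
            for i in range(q):
                tD = 0.0
                tS = 0.0
                for k in range(ai_indptr[i], ai_indptr[i + 1]):
                    j = ai_indices[k]
                    v = ai_data[k]
                    tD += v * aD[j]
                    tS += v * aS[j]
                s11 += aD[i] * tD
                s12 += aD[i] * tS
                s22 += aS[i] * tS
            if has_social:
                # G | rest ~ IW(df = q - 3, scale = Sg)  (flat prior)
                df = q - 3.0
                ok = False
                for _ in range(50):
                    dets = s11 * s22 - s12 * s12
                    if not (dets > 0.0 and np.isfinite(dets)):
                        n_rejects += 1
                        continue
                    p11 = s22 / dets
                    p22 = s11 / dets
                    p12 = -s12 / dets
                    L11 = np.sqrt(p11)
                    L21 = p12 / L11
                    arg = p22 - L21 * L21
                    if arg <= 0.0:
                        n_rejects += 1
                        continue
                    L22 = np.sqrt(arg)
                    # Bartlett draw of Wishart(df, Sg^-1)
                    A11 = np.sqrt(_chi2(df))
                    A22 = np.sqrt(_chi2(df - 1.0))
                    A21 = np.random.standard_normal()
                    # T = L @ A (lower triangular); W = T T'
                    T11 = L11 * A11
                    T21 = L21 * A11 + L22 * A21
                    T22 = L22 * A22
                    W11 = T11 * T11
                    W12 = T11 * T21
                    W22 = T21 * T21 + T22 * T22
                    detw = W11 * W22 - W12 * W12
                    if detw <= 0.0 or W11 <= 0.0 or W22 <= 0.0:
                        n_rejects += 1
                        continue
                    cand_D = W22 / detw
                    cand_S = W11 / detw
                    cand_DS = -W12 / detw
                    if not (np.isfinite(cand_D) and np.isfinite(cand_S)
                            and np.isfinite(cand_DS)
                            and cand_D * cand_S - cand_DS * cand_DS > 0.0):
                        n_rejects += 1
                        continue
                    s2D = cand_D
                    s2S = cand_S
                    sDS = cand_DS
                    ok = True
                    break
                if not ok:
                    return n_clamped, n_rejects, -1  # abort flag
                if s2D > var_hi or s2S > var_hi:
                    s2D = min(s2D, var_hi)
                    s2S = min(s2S, var_hi)
                    n_clamped += 1
                if s2D < var_lo:
                    s2D = var_lo
                if s2S < var_lo:
                    s2S = var_lo
                lim = 0.99 * np.sqrt(s2D * s2S)
                if sDS > lim:
                    sDS = lim
                elif sDS < -lim:
                    sDS = -lim
            else:
                s2D = s11 / _chi2(q - 2.0)
                if s2D > var_hi:
                    s2D = var_hi
                    n_clamped += 1
                if s2D < var_lo:
                    s2D = var_lo

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = sse / _chi2(n - 2.0)
        if s2e > var_hi:
            s2e = var_hi
            n_clamped += 1
        if s2e < var_lo:
            s2e = var_lo

        # ---- periodic exact residual refresh against drift
        if (it + 1) % 2000 == 0:
            for i in range(n):
                mu = 0.0
                for k in range(p):
                    mu += X[i, k] * b[k]
                if has_pen:
                    mu += pen[pen_code[i]]
                if has_genetic:
                    mu += aD[rec_animal[i]]
                if has_social:
                    for k in range(srow_indptr[i], srow_indptr[i + 1]):
                        mu += srow_vals[k] * aS[srow_cols[k]]
                e[i] = y[i] - mu

        # ---- store
        if it >= burn and (it - burn) % thin == 0:
            out_vc[stored, 0] = s2D
            out_vc[stored, 1] = s2S
            out_vc[stored, 2] = sDS
            out_vc[stored, 3] = s2p
            out_vc[stored, 4] = s2e
            for k in range(p):
                out_b[stored, k] = b[k]
            for j in range(n_pen):
                out_pen[stored, j] = pen[j]
            if has_genetic:
                for i in range(q):
                    out_aD[stored, i] = aD[i]
                if has_social:
                    for i in range(q):
                        out_aS[stored, i] = aS[i]
            stored += 1
    return n_clamped, n_rejects, 0


def gibbs_sampler(design: DesignMatrices, Ainv: sparse.spmatrix | None,
                  config: GibbsConfig,
                  init: VarianceComponents | None = None) -> GibbsChains:
    """Run the Gibbs sampler for one model fit.

    Parameters
    ----------
    design : output of :func:`build_design` (rows may be subset for
        cross-validation).
    Ainv : sparse inverse relationship matrix over the pedigree; ``None``
        drops the genetic terms entirely (used for diagnostic fits such as
        pure variance-component ANOVA checks).
    config : chain protocol; the seed fully determines the chain.
    init : starting variance components (default: equal split of the
        phenotypic variance).
    """
    spec = design.spec
    n = design.n
    has_genetic = Ainv is not None
    has_social = has_genetic and spec.has_social
    q = design.q if has_genetic else 1

    vary = float(np.var(design.y))
    if vary == 0:
        raise ValueError("response has zero variance")
    if init is None:
        v0 = vary / 4.0
        init = VarianceComponents(v0, v0 / 100.0 if has_social else 0.0,
                                  0.0, v0, v0)
    init_vc = init.as_array()
    if has_social and init.sigma2_S <= 0:
        init_vc[1] = vary / 400.0

    xtx = (design.X ** 2).sum(axis=0)
    if np.any(xtx == 0):
        raise ValueError("empty fixed-effect column")

    order = np.argsort(design.pen_code, kind="stable")
    counts = np.bincount(design.pen_code, minlength=design.n_pen)
    pen_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    pen_rows = order.astype(np.int64)

    own_row = np.full(q, -1, dtype=np.int64)
    if has_genetic:
        own_row[design.rec_animal] = np.arange(n)

    if has_social:
        Scsc = design.S.tocsc()
        soc_indptr = Scsc.indptr.astype(np.int64)
        soc_rows = Scsc.indices.astype(np.int64)
        soc_vals = Scsc.data.astype(np.float64)
        Scsr = design.S.tocsr()
        srow_indptr = Scsr.indptr.astype(np.int64)
        srow_cols = Scsr.indices.astype(np.int64)
        srow_vals = Scsr.data.astype(np.float64)
    else:
        soc_indptr = np.zeros(q + 1, dtype=np.int64)
        soc_rows = np.zeros(0, dtype=np.int64)
        soc_vals = np.zeros(0)
        srow_indptr = np.zeros(n + 1, dtype=np.int64)
        srow_cols = np.zeros(0, dtype=np.int64)
        srow_vals = np.zeros(0)

    if has_genetic:
        Ai = sparse.csr_matrix(Ainv)
        Ai.sum_duplicates()
        ai_indptr = Ai.indptr.astype(np.int64)
        ai_indices = Ai.indices.astype(np.int64)
        ai_data = Ai.data.astype(np.float64)
        if Ai.shape[0] < design.rec_animal.max() + 1:
            raise ValueError("A-inverse smaller than the pedigree positions "
                             "referenced by the records")
    else:
        ai_indptr = np.zeros(q + 1, dtype=np.int64)
        ai_indices = np.zeros(0, dtype=np.int64)
        ai_data = np.zeros(0)

    m = config.n_retained
    out_vc = np.zeros((m, 5))
    out_b = np.zeros((m, design.X.shape[1]))
    out_pen = np.zeros((m, design.n_pen))
    out_aD = np.zeros((m, q if has_genetic else 1))
    out_aS = np.zeros((m, q if has_social else 1))

    var_hi = config.variance_bound_factor * vary
    var_lo = 1e-12 * vary

    n_clamped, n_rejects, status = _gibbs_kernel(
        config.seed, config.chain_length, config.burn_in, config.thin,
        design.y.astype(np.float64), design.X.astype(np.float64), xtx,
        design.pen_code.astype(np.int64), pen_indptr, pen_rows,
        own_row, soc_indptr, soc_rows, soc_vals,
        srow_indptr, srow_cols, srow_vals,
        design.rec_animal.astype(np.int64),
        ai_indptr, ai_indices, ai_data,
        has_genetic, has_social, True,
        init_vc, var_lo, var_hi,
        out_vc, out_b, out_pen, out_aD, out_aS)
    if status != 0:
        raise RuntimeError("Gibbs sampler aborted: 50 consecutive "
                           "non-positive-definite G draws; check the data "
                           "and the interaction matrix conditioning")
    if n_clamped:
        warnings.warn(f"{n_clamped} variance draws hit the prior bound and "
                      "were clamped")
    return GibbsChains(out_vc, out_b, out_pen, out_aD,
                       out_aS if has_social else None, config, spec,
                       n_clamped)


def posterior_summary(chains: GibbsChains, n: float | None = None,
                      r: float = 0.0, c: float | None = None) -> pd.DataFrame:
    """Posterior mean/SD/quantiles of variance components and derived
    genetic parameters.

    Derived parameters (h2, genetic correlation, and — when the group size
    ``n`` is given — total heritable variance, total phenotypic variance
    and T2 at interaction degree ``c``) are computed sample-wise along the
    chain and then summarized, not evaluated at the posterior means.

    ``c`` defaults to 1 for the classical social model and 0 (the mean
    standardized degree) for pair-specific models.
    """
    from . import genetics

    if chains.vc.shape[0] < 100:
        warnings.warn("fewer than 100 retained samples; summaries are noisy")
    tab = chains.vc_frame.copy()
    social = chains.spec.has_social
    tab["h2"] = tab["sigma2_D"] / (tab["sigma2_D"] + tab["sigma2_pen"]
                                   + tab["sigma2_e"])
    if social:
        tab["corr_DS"] = tab["sigma_DS"] / np.sqrt(tab["sigma2_D"]
                                                   * tab["sigma2_S"])
        if n is not None:
            if c is None:
                c = 1.0 if chains.spec.model_class == "AM_IGE" else 0.0
            rows = [genetics.partition_row(VarianceComponents.from_array(v),
                                           n=n, r=r, c=c)
                    for v in chains.vc]
            der = pd.DataFrame(rows)
            tab = pd.concat([tab, der], axis=1)
    out = pd.DataFrame({
        "mean": tab.mean(), "sd": tab.std(ddof=1),
        "q2.5": tab.quantile(0.025), "median": tab.quantile(0.5),
        "q97.5": tab.quantile(0.975)})
    return out


# --------------------------------------------------------------------------
# EM-REML
# --------------------------------------------------------------------------

def em_reml(design: DesignMatrices, A: np.ndarray | None,
            spec: ModelSpec | None = None,
            start: VarianceComponents | None = None,
            tol: float = 1e-6, max_iter: int = 500,
            include_pen: bool = True, accelerate: bool = True):
    """EM algorithm for REML estimates of the variance components.

    The iteration is the classical EM for Henderson's mixed-model
    equations — each step replaces every variance by the expected
    crossproduct of its effects given the data and the current variances —
    evaluated in the equivalent marginal form: with
    ``V = sigma2_e I + sigma2_pen Z_p Z_p' + sum_uv G[u,v] W_u A W_v'``
    and ``P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1``, the updates are

    ``G      <- G + G (Y - T) G / q``
    ``s2_pen <- s2_pen + s2_pen^2 (y'P N_p P y - tr(P N_p)) / n_pen``
    ``s2_e   <- s2_e   + s2_e^2   (y'P P y    - tr(P))      / n``

    where ``Y[u,v] = y'P W_u A W_v' P y`` and ``T[u,v] = tr(P W_u A W_v')``.
    The per-iteration cost is cubic in the record count, independent of
    pedigree size.

    Parameters
    ----------
    A : dense relationship matrix over the pedigree; ``None`` drops the
        genetic terms (no-random-effect and pen-only models remain valid:
        with no random terms the fixed point is the degrees-of-freedom
        corrected OLS residual variance).

    Returns
    -------
    (vc, converged, n_iter)
    """
    spec = spec or design.spec
    y = design.y.astype(float)
    X = design.X
    n = y.size
    has_genetic = A is not None
    has_social = has_genetic and spec.has_social and design.S is not None

    if has_genetic:
        rec = design.rec_animal
        N11 = A[np.ix_(rec, rec)]
        if has_social:
            Sd = np.asarray(design.S.todense())
            N12 = A[rec, :] @ Sd.T
            N22 = Sd @ A @ Sd.T
        q = A.shape[0]
    if include_pen:
        Np = (design.pen_code[:, None] == design.pen_code[None, :]) \
            .astype(float)
        n_pen = design.n_pen

    vary = float(np.var(y))
    if start is None:
        v0 = vary / 4.0
        start = VarianceComponents(
            v0 if has_genetic else 0.0,
            v0 / 100.0 if has_social else 0.0, 0.0,
            v0 if include_pen else 0.0, vary / 2.0)
    s2D, s2S, sDS = start.sigma2_D, start.sigma2_S, start.sigma_DS
    s2p, s2e = start.sigma2_pen, start.sigma2_e

    eye = np.eye(n)

    def admissible(th) -> bool:
        s2D, s2S, sDS, s2p, s2e = th
        if s2e <= 0:
            return False
        if include_pen and s2p <= 0:
            return False
        if has_genetic:
            if has_social:
                if s2D <= 0 or s2S <= 0 or s2D * s2S - sDS ** 2 <= 0:
                    return False
            elif s2D <= 0:
                return False
        return True

    def em_step(th: np.ndarray) -> np.ndarray:
        s2D, s2S, sDS, s2p, s2e = th
        V = s2e * eye.copy()
        if include_pen:
            V += s2p * Np
        if has_genetic:
            V += s2D * N11
            if has_social:
                V += sDS * (N12 + N12.T) + s2S * N22
        cho = cho_factor(V, lower=True)
        Vinv = cho_solve(cho, eye)
        VinvX = Vinv @ X
        P = Vinv - VinvX @ np.linalg.solve(X.T @ VinvX, VinvX.T)
        Py = P @ y
        if has_genetic:
            if has_social:
                Y = np.empty((2, 2))
                T = np.empty((2, 2))
                Y[0, 0] = Py @ N11 @ Py
                Y[0, 1] = Y[1, 0] = Py @ N12 @ Py
                Y[1, 1] = Py @ N22 @ Py
                T[0, 0] = np.sum(P * N11)
                T[0, 1] = T[1, 0] = np.sum(P * N12.T)
                T[1, 1] = np.sum(P * N22)
                G = np.array([[s2D, sDS], [sDS, s2S]])
                G = G + G @ (Y - T) @ G / q
                s2D, s2S, sDS = G[0, 0], G[1, 1], G[0, 1]
            else:
                s2D = s2D + s2D ** 2 * (Py @ N11 @ Py - np.sum(P * N11)) / q
        if include_pen:
            s2p = s2p + s2p ** 2 * (Py @ Np @ Py - np.sum(P * Np)) / n_pen
        s2e = s2e + s2e ** 2 * (Py @ Py - np.trace(P)) / n
        return np.array([s2D, s2S, sDS, s2p, s2e])

    # Driver: plain EM, optionally with SQUAREM extrapolation (same fixed
    # point, far fewer iterations on the slow directions).  Each SQUAREM
    # cycle spends three EM-map evaluations.
    theta = np.array([s2D, s2S, sDS, s2p, s2e])
    converged = False
    it = 0
    while it < max_iter:
        old = theta.copy()
        if accelerate:
            t1 = em_step(theta)
            t2 = em_step(t1)
            it += 2
            rstep = t1 - theta
            vstep = (t2 - t1) - rstep
            vnorm = np.linalg.norm(vstep)
            if vnorm > 0:
                alpha = -np.linalg.norm(rstep) / vnorm
                cand = theta - 2.0 * alpha * rstep + alpha ** 2 * vstep
                if admissible(cand):
                    cand = em_step(cand)  # stabilizing EM step
                    it += 1
                    theta = cand if admissible(cand) else t2
                else:
                    theta = t2
            else:
                theta = t2
        else:
            theta = em_step(theta)
            it += 1
        rel = np.abs(theta - old) / np.maximum(np.abs(old), 1e-12 * vary)
        active = np.abs(theta) > 1e-10 * vary
        if np.max(rel[active], initial=0.0) < tol * (3 if accelerate else 1):
            converged = True
            break
    if not converged:
        warnings.warn(f"EM-REML did not reach tol={tol} in {max_iter} "
                      "iterations; returning the last iterate")
    s2D, s2S, sDS, s2p, s2e = theta
    return (VarianceComponents(s2D, s2S, sDS, s2p, s2e), converged, it)
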