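"""Feeding-behaviour traits and pair-specific interaction matrices.

Electronic single-space feeders log every visit (animal, pen, start time,
duration, feed intake).  From the visit stream we derive four per-animal
behaviour traits:

* ``FR``   feeding rate, g/min — total intake over total trough time;
* ``FF``   feeding frequency, visits/day;
* ``OT``   occupation time, min/day at the trough;
* ``FInt`` mean interval, min, between consecutive visits within a day.

Animals that eat fast, often, with short intervals and little total trough
time tend to be the subordinate ones, so between-animal differences in
these traits proxy the degree of competition between two pen mates.  The
interaction matrix ``C`` turns that into model input: entries are
standardized Euclidean distances between the (standardized) behaviour
records of each within-pen pair, zero across pens and on the diagonal.
``CLASSICAL`` mode reproduces the conventional social animal model where
every pair of pen mates interacts with degree 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAITS",
    "InteractionMatrix",
    "derive_daily_traits",
    "aggregate_traits",
    "phenotypic_correlations",
    "rank_stability",
    "standardize",
    "pair_distance",
    "interaction_matrix",
]

TRAITS = ("FR", "FF", "OT", "FInt")

#: recognised interaction-matrix modes
MODES = ("CLASSICAL", "FR", "FF", "OT", "FINT", "ALL")

_MODE_TRAITS = {"FR": ["FR"], "FF": ["FF"], "OT": ["OT"], "FINT": ["FInt"],
                "ALL": list(TRAITS)}

#: re-entries to the feeder separated by less than this many minutes,
#: within the same 1-h block, are merged into a single visit
MERGE_GAP_MIN = 1.0


def derive_daily_traits(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-animal per-day behaviour traits from a feeder-visit stream.

    Parameters
    ----------
    visits : DataFrame with columns ``animal, pen, start, duration_min,
        intake_g``; ``start`` parseable as datetime.  Records with negative
        duration or intake are rejected (dropped with a warning); days are
        calendar days of the naive timestamp.

    Returns
    -------
    DataFrame with one row per animal-day: ``FF`` (count), ``OT`` (min),
    ``FR`` (g/min, NaN if OT == 0), ``FInt`` (min, NaN if fewer than two
    visits; mean end-to-next-start gap within the day).
    """
    v = visits.copy()
    v["start"] = pd.to_datetime(v["start"], format="mixed")
    bad = (v["duration_min"] <= 0) | (v["intake_g"] < 0)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} visit records with "
                      "non-positive duration or negative intake")
        v = v[~bad]
    v = v.sort_values(["animal", "start"], kind="stable")
    v["date"] = v["start"].dt.normalize()
    v["hour_block"] = v["start"].dt.hour

    # merge sub-minute re-entries within the same 1-h block
    end = v["start"] + pd.to_timedelta(v["duration_min"], unit="m")
    prev_end = end.groupby(v["animal"]).shift()
    gap_min = (v["start"] - prev_end).dt.total_seconds() / 60.0
    same_block = (v.groupby("animal")["hour_block"].shift() == v["hour_block"]) & \
                 (v.groupby("animal")["date"].shift() == v["date"])
    new_visit = ~((gap_min < MERGE_GAP_MIN) & same_block & (gap_min >= 0))
    v["visit_id"] = new_visit.cumsum()
    merged = v.groupby("visit_id").agg(
        animal=("animal", "first"), date=("date", "first"),
        start=("start", "first"), intake_g=("intake_g", "sum"),
        duration_min=("duration_min", "sum"))
    merged["end"] = merged["start"] + pd.to_timedelta(merged["duration_min"],
                                                      unit="m")

    rows = []
    for (animal, date), g in merged.groupby(["animal", "date"], sort=True):
        ot = g["duration_min"].sum()
        intake = g["intake_g"].sum()
        ff = len(g)
        fr = intake / ot if ot > 0 else np.nan
        if ff >= 2:
            gaps = (g["start"].values[1:] - g["end"].values[:-1]) \
                / np.timedelta64(1, "m")
            fint = float(np.mean(gaps))
        else:
            fint = np.nan
        rows.append((animal, date, ff, ot, fr, fint))
    return pd.DataFrame(rows, columns=["animal", "date", "FF", "OT", "FR",
                                       "FInt"])


def aggregate_traits(daily: pd.DataFrame, window: str = "overall",
                     period_days: int = 14,
                     origin=None) -> pd.DataFrame:
    """Aggregate daily traits to the whole period or to 2-week periods.

    Each trait is the mean of its *defined* daily values within the
    window; ``days_observed`` counts days with any visit.  Animals absent
    from a window are simply missing (no zero-filled rows).

    Parameters
    ----------
    window : ``"overall"`` or ``"period"`` (consecutive ``period_days``-day
        periods counted from ``origin``, default the earliest date seen).
    """
    if daily.empty:
        raise ValueError("no daily trait records to aggregate")
    d = daily.copy()
    if window == "overall":
        d["period"] = 0
    elif window == "period":
        start = pd.to_datetime(origin) if origin is not None \
            else d["date"].min()
        d["period"] = ((d["date"] - start).dt.days // period_days).astype(int)
    else:
        raise ValueError(f"unknown window {window!r}")
    out = d.groupby(["animal", "period"]).agg(
        FR=("FR", "mean"), FF=("FF", "mean"), OT=("OT", "mean"),
        FInt=("FInt", "mean"), days_observed=("date", "count"))
    return out.reset_index()


def phenotypic_correlations(traits: pd.DataFrame,
                            adg: pd.Series | None = None) -> pd.DataFrame:
    """Pearson correlations between behaviour traits (and optionally ADG).

    Computed over animals with complete records.  Zero-variance columns
    yield NaN correlations and a warning.
    """
    cols = [c for c in TRAITS if c in traits.columns]
    tab = traits.set_index("animal")[cols] if "animal" in traits.columns \
        else traits[cols]
    if adg is not None:
        tab = tab.join(adg.rename("ADG"), how="inner")
    tab = tab.dropna()
    if len(tab) < 3:
        raise ValueError("need at least 3 complete cases for correlations")
    sd = tab.std()
    if (sd == 0).any():
        warnings.warn("zero-variance column(s): "
                      + ", ".join(sd.index[sd == 0]))
    return tab.corr()


def rank_stability(period_traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation per trait between consecutive periods.

    Measures the stability of the within-population behaviour ranking
    along the fattening period; stable ranks support reading the traits as
    expressions of a persistent social structure.

    Returns a DataFrame indexed by ``(period, next_period)`` with one
    column per trait; pairs sharing fewer than 3 animals are NaN (with a
    warning).
    """
    periods = sorted(period_traits["period"].unique())
    if len(periods) < 2:
        raise ValueError("need at least two periods for rank stability")
    wide = {p: period_traits[period_traits["period"] == p].set_index("animal")
            for p in periods}
    out = {}
    for p0, p1 in zip(periods[:-1], periods[1:]):
        shared = wide[p0].index.intersection(wide[p1].index)
        row = {}
        for t in TRAITS:
            a = wide[p0].loc[shared, t]
            b = wide[p1].loc[shared, t]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                warnings.warn(f"periods {p0}-{p1}, trait {t}: fewer than 3 "
                              "shared animals; rho undefined")
                row[t] = np.nan
            else:
                row[t] = stats.spearmanr(a[ok], b[ok]).statistic
        out[(p0, p1)] = row
    return pd.DataFrame(out).T


def standardize(values) -> np.ndarray:
    """Z-scores with the population (n-denominator) standard deviation.

    Standardization is global, across all phenotyped animals, not within
    pen.  Zero spread is an error.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance trait")
    return (x - x.mean()) / sd


def pair_distance(z_i, z_j) -> float:
    """Euclidean distance between two animals' standardized records.

    A scalar per trait gives ``|z_i - z_j|``; a vector over the four
    traits gives the root-sum-of-squares distance.  Missing components are
    an error — the caller decides whether to impute or drop the animal.
    """
    zi = np.atleast_1d(np.asarray(z_i, dtype=float))
    zj = np.atleast_1d(np.asarray(z_j, dtype=float))
    if zi.shape != zj.shape:
        raise ValueError("trait vectors must have the same length")
    if np.isnan(zi).any() or np.isnan(zj).any():
        raise ValueError("missing trait component in pair distance")
    return float(np.sqrt(np.sum((zi - zj) ** 2)))


@dataclass
class InteractionMatrix:
    """Pair-specific interaction degrees between pen mates.

    ``C`` is symmetric over the phenotyped animals with ``c_ij = 0``
    whenever i and j share no pen (or i == j).  In ``CLASSICAL`` mode the
    entries are 0/1 pen-sharing indicators; in the behaviour modes they
    are standardized Euclidean distances (mean 0, population SD 1 over all
    within-pen pairs in the dataset), so negative values mean a pair more
    alike than the average pair.
    """

    C: np.ndarray
    ids: list
    mode: str
    pens: pd.Series  # animal id -> pen id

    def __post_init__(self):
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def position(self, animal) -> int:
        return self._pos[animal]

    def within_pen_pairs(self) -> np.ndarray:
        """Entries c_ij over unordered within-pen pairs i < j."""
        vals = []
        for pen, members in self.pens.groupby(self.pens):
            idx = [self._pos[a] for a in members.index]
            for k, i in enumerate(idx):
                for j in idx[k + 1:]:
                    vals.append(self.C[i, j])
        return np.array(vals)


def interaction_matrix(traits: pd.DataFrame, pens: pd.Series | dict,
                       mode: str = "CLASSICAL",
                       fallback_classical: bool = False) -> InteractionMatrix:
    """Build the social incidence structure for a set of phenotyped animals.

    Parameters
    ----------
    traits : DataFrame indexed by animal (or with an ``animal`` column)
        holding FR/FF/OT/FInt; ignored in ``CLASSICAL`` mode.
    pens : mapping animal id -> pen id over the phenotyped animals.
    mode : one of ``CLASSICAL, FR, FF, OT, FINT, ALL``.
    fallback_classical : replace missing-trait animals' pens by classical
        0/1 coefficients instead of raising.

    Notes
    -----
    Distances are standardized with the mean and population SD across all
    within-pen pairs of the dataset (global, not per pen).  Pens with a
    single phenotyped animal give that animal a zero row, with a warning.
    """
    mode = mode.upper()
    if mode not in MODES:
        raise ValueError(f"unknown interaction mode {mode!r}")
    pens = pd.Series(dict(pens)) if not isinstance(pens, pd.Series) else pens
    ids = list(pens.index)
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    C = np.zeros((n, n))

    pen_groups = {pen: [a for a in members.index]
                  for pen, members in pens.groupby(pens)}
    for pen, members in pen_groups.items():
        if len(members) < 2:
            warnings.warn(f"pen {pen!r} has fewer than 2 phenotyped animals; "
                          "zero interaction row")

    if mode == "CLASSICAL":
        for members in pen_groups.values():
            idx = [pos[a] for a in members]
            for k, i in enumerate(idx):
                for j in idx[k + 1:]:
                    C[i, j] = C[j, i] = 1.0
        return InteractionMatrix(C, ids, mode, pens)

    needed = _MODE_TRAITS[mode]
    tab = traits.set_index("animal") if "animal" in traits.columns else traits
    missing_ids = [a for a in ids
                   if a not in tab.index or tab.loc[a, needed].isna().any()]
    if missing_ids and not fallback_classical:
        raise ValueError(
            f"missing behaviour trait(s) {needed} for animals "
            f"{missing_ids[:5]}{'...' if len(missing_ids) > 5 else ''}")
    fallback_pens = {pens[a] for a in missing_ids}

    have = [a for a in ids if a not in missing_ids]
    Z = np.column_stack([standardize(tab.loc[have, t].astype(float))
                         for t in needed])
    zmap = {a: Z[i] for i, a in enumerate(have)}

    pairs, dists = [], []
    for pen, members in pen_groups.items():
        if pen in fallback_pens:
            continue
        for k, i in enumerate(members):
            for j in members[k + 1:]:
                pairs.append((pos[i], pos[j]))
                dists.append(pair_distance(zmap[i], zmap[j]))
    if not pairs:
        raise ValueError("no within-pen pair with complete behaviour records")
    dists = np.array(dists)
    sd = dists.std(ddof=0)
    if sd == 0:
        raise ValueError("all pairwise distances identical; cannot standardize")
    cvals = (dists - dists.mean()) / sd
    for (i, j), c in zip(pairs, cvals):
        C[i, j] = C[j, i] = c
    for pen in fallback_pens:
        idx = [pos[a] for a in pen_groups[pen]]
        for k, i in enumerate(idx):
            for j in idx[k + 1:]:
                C[i, j] = C[j, i] = 1.0
    return InteractionMatrix(C, ids, mode, pens)
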