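"""Pedigree handling and additive-relationship (numerator relationship) algebra.

The additive relationship matrix **A** carries the covariance structure of
breeding values, ``Var(a) = A sigma2_a`` for a single genetic effect, or
``G (x) A`` for the bivariate direct/social effect of the social animal
model.  Everything downstream (Gibbs sampler, EM-REML, variance
partitioning) consumes either ``A`` or its sparse inverse, so correctness
here is load-bearing; both are cross-checked against dense brute force in
the test suite.

Unknown parents (coded ``0`` or empty in input files) are treated as
unrelated founders.  Inbreeding is accounted for throughout: diagonals of
``A`` are ``1 + F_i`` and the Henderson rules for ``A^-1`` use the
Meuwissen & Luo inbreeding coefficients.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "build_pedigree",
    "read_pedigree",
    "relationship_matrix",
    "inbreeding_coefficients",
    "inverse_relationship_matrix",
    "mean_within_group_relationship",
]

#: tokens interpreted as "parent unknown" in raw records
UNKNOWN_TOKENS = {"0", "", ".", "NA", "na", None, 0}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids : list
        Animal identifiers in sorted order (every parent precedes its
        offspring).
    sire, dam : np.ndarray of int
        Positions of each animal's parents in ``ids``; ``-1`` marks an
        unknown parent.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict:
        """Mapping animal id -> dense 0-based position."""
        return self._index

    def positions(self, animals) -> np.ndarray:
        """Dense positions of the given animal ids (KeyError if absent)."""
        return np.array([self._index[a] for a in animals], dtype=np.int64)

    def founders_only(self) -> "Pedigree":
        """Copy of this pedigree with all parent information removed."""
        n = len(self)
        return Pedigree(list(self.ids), np.full(n, -1), np.full(n, -1))


def _is_unknown(token) -> bool:
    if isinstance(token, float) and np.isnan(token):
        return True
    return token in UNKNOWN_TOKENS


def build_pedigree(records) -> Pedigree:
    """Validate raw ``(animal, sire, dam)`` triplets and sort parents-first.

    Parameters
    ----------
    records : iterable of triplets
        Any id token is accepted; ``0``/empty/NA code an unknown parent.
        Parents that never appear as animals are added as founders.

    Raises
    ------
    PedigreeError
        On duplicate animal ids or on cycles (e.g. an animal that is its
        own ancestor), naming an offending id.
    """
    raw = [(a, None if _is_unknown(s) else s, None if _is_unknown(d) else d)
           for a, s, d in records]
    seen = set()
    for a, _, _ in raw:
        if a in seen:
            raise PedigreeError(f"duplicate animal id: {a!r}")
        seen.add(a)
    parents = {}
    for a, s, d in raw:
        parents[a] = (s, d)
    # implicit founders: parents without their own record
    for a, s, d in raw:
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)

    # Kahn topological sort, stable in input order
    order_hint = {a: i for i, a in enumerate(parents)}
    indeg = {a: sum(p is not None for p in ps) for a, ps in parents.items()}
    children = {a: [] for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
    ready = [(order_hint[a], a) for a, k in indeg.items() if k == 0]
    heapq.heapify(ready)
    ids = []
    while ready:
        _, a = heapq.heappop(ready)
        ids.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (order_hint[c], c))
    if len(ids) != len(parents):
        stuck = sorted((a for a, k in indeg.items() if k > 0),
                       key=order_hint.get)
        raise PedigreeError(f"cycle detected in pedigree involving id {stuck[0]!r}")

    pos = {a: i for i, a in enumerate(ids)}
    sire = np.array([pos[parents[a][0]] if parents[a][0] is not None else -1
                     for a in ids], dtype=np.int64)
    dam = np.array([pos[parents[a][1]] if parents[a][1] is not None else -1
                    for a in ids], dtype=np.int64)
    return Pedigree(ids, sire, dam)


def read_pedigree(path, header: bool | None = None) -> Pedigree:
    """Read a whitespace/CSV pedigree file of ``animal sire dam`` triplets.

    ``header=None`` sniffs the first line; 0 codes an unknown parent.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs three columns: animal sire dam")
    first = df.iloc[0].astype(str)
    if header or (header is None and first.str.contains("[A-Za-z_]").any()
                  and first.iloc[0].lower() in {"animal", "id", "animal_id"}):
        df = df.iloc[1:]
    return build_pedigree(df.iloc[:, :3].itertuples(index=False, name=None))


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the tabular method.

    ``a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)})`` for i < j and
    ``a_ii = 1 + 0.5 a_{sire(i),dam(i)}``, with unknown parents
    contributing zero.  Diagonals are ``1 + F_i``.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo algorithm.

    Equivalent to ``diag(relationship_matrix(ped)) - 1`` but O(n * depth)
    rather than O(n^2), so usable for full multi-thousand-animal pedigrees.
    """
    n = len(ped)
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian-sampling variance scale of the LDL' factor
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            D[i] = 0.75 - 0.25 * F[max(si, di)]
        else:
            D[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # accumulate L_i over ancestors, youngest first
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = coeff.pop(j, 0.0)
            if cj == 0.0:
                continue
            aii += cj * cj * D[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * cj
        F[i] = aii - 1.0
    return F


def inverse_relationship_matrix(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of the relationship matrix (Henderson/Quaas rules).

    Uses inbreeding-corrected Mendelian-sampling variances
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (one/no parent known: 0.75 - 0.25 F_p
    / 1), accumulating ``alpha_i = 1/d_i`` contributions over the
    (animal, sire, dam) triangle.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    s, d = ped.sire, ped.dam
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dd = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            dd = 0.75 - 0.25 * F[max(si, di)]
        else:
            dd = 1.0
        alpha = 1.0 / dd
        add(i, i, alpha)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if si >= 0 and di >= 0:
            add(si, di, 0.25 * alpha)
            add(di, si, 0.25 * alpha)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)))


def mean_within_group_relationship(A: np.ndarray, groups: dict | pd.Series,
                                   ped: Pedigree | None = None):
    """Mean additive relationship between pen mates.

    Parameters
    ----------
    A : relationship matrix (pedigree order).
    groups : mapping animal id -> pen id (or positions -> pen if ``ped``
        is None and keys are integer positions).
    ped : pedigree giving id -> position; required when group keys are ids.

    Returns
    -------
    (r, per_group) : pooled mean over all unordered within-pen pairs
        ``i != j``, and a pandas Series of per-pen means.  Pens of size 1
        are excluded (pooled and per-pen) with a warning.
    """
    import warnings

    items = groups.items() if hasattr(groups, "items") else groups
    by_pen: dict = {}
    for animal, pen in items:
        pos = ped.index[animal] if ped is not None else int(animal)
        by_pen.setdefault(pen, []).append(pos)

    per = {}
    total, count = 0.0, 0
    for pen, members in by_pen.items():
        m = len(members)
        if m < 2:
            warnings.warn(f"pen {pen!r} has a single animal; excluded from r")
            continue
        idx = np.array(members)
        sub = A[np.ix_(idx, idx)]
        pair_sum = (sub.sum() - np.trace(sub)) / 2.0
        npairs = m * (m - 1) / 2
        per[pen] = pair_sum / npairs
        total += pair_sum
        count += npairs
    if count == 0:
        raise ValueError("no pen with at least two animals")
    return total / count, pd.Series(per, name="mean_relationship")
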