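"""Spearman-based Mantel, partial Mantel, and Dow-Cheverud permutation tests.

All statistics are computed over the strictly-upper-triangle entries of
symmetric, zero-diagonal distance matrices with matched population labels.
Spearman's rank correlation is used throughout because the dependencies
between linguistic, phenotypic, and geographic distances are non-linear.
Null distributions are built by jointly permuting rows and columns of one
matrix; with n <= 7 populations the full permutation group is enumerated
instead of sampled.

Implementation note: the multiset of off-diagonal values of a symmetric
matrix is invariant under a joint row/column permutation, so each matrix is
rank-transformed once and a permutation reduces to reindexing the rank
matrix. This makes 10,000 permutations cheap even from Python.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cranolex.errors import DegenerateInputError, InvalidParameterError

EXHAUSTIVE_MAX_N = 7


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix.

    Attributes
    ----------
    labels : list of str
        Population identifiers, one per row/column.
    values : ndarray
        Symmetric matrix with zero diagonal and finite entries.
    kind : str
        Free-form tag such as ``"PST"``, ``"L"``, ``"F"`` or ``"G"``.
    """

    labels: list
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise InvalidParameterError("label count does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise InvalidParameterError("distance matrix is not symmetric to 1e-12")
        self.values = v

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "") -> "DistanceMatrix":
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(float), kind=kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: list) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class MantelResult:
    r: float
    p_two_tailed: float
    n_perm: int
    partial_on: str | None = None
    seed: int | None = None
    exhaustive: bool = False


@dataclass
class DowCheverudResult:
    """Result of a Dow-Cheverud (rho_1Z) comparison.

    Positive ``r`` means the first matrix is more strongly correlated with
    the target than the second.
    """

    r: float
    p_two_tailed: float
    n_perm: int
    controlled_for_g: bool = False
    seed: int | None = None


def _coerce(m) -> tuple[np.ndarray, list | None]:
    if isinstance(m, DistanceMatrix):
        return m.values, list(m.labels)
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(float), [str(c) for c in m.columns]
    return np.asarray(m, dtype=float), None


def _aligned(*matrices) -> list[np.ndarray]:
    """Coerce matrices to arrays, aligning by labels when available."""
    coerced = [_coerce(m) for m in matrices]
    labelled = [lab for _, lab in coerced if lab is not None]
    if labelled:
        ref = labelled[0]
        for lab in labelled[1:]:
            if set(lab) != set(ref):
                raise InvalidParameterError("matrices have mismatched label sets")
        out = []
        for m, (v, lab) in zip(matrices, coerced):
            if lab is not None and lab != ref:
                idx = [lab.index(l) for l in ref]
                v = v[np.ix_(idx, idx)]
            out.append(v)
    else:
        out = [v for v, _ in coerced]
    n = out[0].shape[0]
    for v in out:
        if v.shape != (n, n):
            raise InvalidParameterError("matrices have different sizes")
    if n < 3:
        raise InvalidParameterError("need at least 3 populations")
    return out


def _rank_matrix(v: np.ndarray) -> np.ndarray:
    """Symmetric matrix of average ranks of the upper-triangle entries."""
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = v[iu]
    if np.ptp(vals) == 0.0:
        raise DegenerateInputError("constant distance matrix: correlation undefined")
    ranks = rankdata(vals, method="average")
    r = np.zeros_like(v)
    r[iu] = ranks
    return r + r.T


def _pearson_ut(a: np.ndarray, b: np.ndarray, iu) -> float:
    x = a[iu]
    y = b[iu]
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        raise DegenerateInputError("zero variance in upper-triangle entries")
    return float(x @ y) / denom


def spearman_matrix(a, b) -> float:
    """Spearman correlation of two distance matrices over their upper triangles."""
    va, vb = _aligned(a, b)
    iu = np.triu_indices(va.shape[0], k=1)
    return _pearson_ut(_rank_matrix(va), _rank_matrix(vb), iu)


def _permutations(n: int, n_perm: int, rng: np.random.Generator, exhaustive: bool | None = None):
    """Yield (permutations, exhaustive flag); exhaustive=None means automatic."""
    if exhaustive is None:
        exhaustive = n <= EXHAUSTIVE_MAX_N
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms, True
    return [rng.permutation(n) for _ in range(n_perm)], False


def _pvalue(r_obs: float, r_null: np.ndarray, exhaustive: bool) -> float:
    hits = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    if exhaustive:
        return hits / len(r_null)
    # add-one estimator: the observed arrangement counts as one permutation
    return (hits + 1) / (len(r_null) + 1)


def mantel(
    a, b, n_perm: int = 10000, seed: int | None = None, exhaustive: bool | None = None
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    The observed statistic is the Spearman correlation of upper-triangle
    entries. The null permutes rows and columns of the second matrix
    jointly. Two-tailed p-values use the add-one estimator
    ``(hits + 1) / (n_perm + 1)``; for n <= 7 populations all n!
    permutations are enumerated and the p-value is exact.
    """
    va, vb = _aligned(a, b)
    n = va.shape[0]
    iu = np.triu_indices(n, k=1)
    ra = _rank_matrix(va)
    rb = _rank_matrix(vb)
    r_obs = _pearson_ut(ra, rb, iu)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(n, n_perm, rng, exhaustive)
    r_null = np.array([_pearson_ut(ra, rb[np.ix_(p, p)], iu) for p in perms])
    return MantelResult(
        r=r_obs,
        p_two_tailed=_pvalue(r_obs, r_null, exhaustive),
        n_perm=len(perms),
        seed=seed,
        exhaustive=exhaustive,
    )


def _partial_r(ra, rb, rc, iu) -> float:
    r_ab = _pearson_ut(ra, rb, iu)
    r_ac = _pearson_ut(ra, rc, iu)
    r_bc = _pearson_ut(rb, rc, iu)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise DegenerateInputError("conditioning matrix perfectly correlated with input")
    return (r_ab - r_ac * r_bc) / math.sqrt((1.0 - r_ac**2) * (1.0 - r_bc**2))


def partial_mantel(
    a, b, c, n_perm: int = 10000, seed: int | None = None, exhaustive: bool | None = None
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    Entries are rank-transformed, the first-order partial correlation
    formula is applied, and the null is built by permuting the first
    matrix's rows and columns and recomputing the partial statistic (the
    raw-matrix permutation convention of vegan/ecodist).
    """
    va, vb, vc = _aligned(a, b, c)
    n = va.shape[0]
    iu = np.triu_indices(n, k=1)
    ra, rb, rc = _rank_matrix(va), _rank_matrix(vb), _rank_matrix(vc)
    r_obs = _partial_r(ra, rb, rc, iu)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(n, n_perm, rng, exhaustive)
    r_null = np.array(
        [_partial_r(ra[np.ix_(p, p)], rb, rc, iu) for p in perms]
    )
    return MantelResult(
        r=r_obs,
        p_two_tailed=_pvalue(r_obs, r_null, exhaustive),
        n_perm=len(perms),
        partial_on=c.kind if isinstance(c, DistanceMatrix) else "C",
        seed=seed,
        exhaustive=exhaustive,
    )


def _standardize_offdiag(v: np.ndarray) -> np.ndarray:
    """Z-score the off-diagonal entries (upper-triangle statistics), symmetric."""
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = v[iu]
    sd = vals.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("constant matrix cannot be standardized")
    z = np.zeros_like(v)
    z[iu] = (vals - vals.mean()) / sd
    return z + z.T


def dow_cheverud(
    a,
    b,
    target,
    control=None,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> DowCheverudResult:
    """Dow-Cheverud test: is A more strongly correlated with target than B?

    A and B are standardized over their off-diagonal entries and the
    contrast Z = A_std - B_std is correlated (Spearman) with the target;
    when ``control`` is given the correlation is partial on it. The null
    permutes the target's rows and columns. Positive r means A correlates
    more strongly with the target than B. If A equals B the contrast is
    identically zero and (r=0, p=1) is reported by convention.
    """
    if control is None:
        va, vb, vt = _aligned(a, b, target)
        vg = None
    else:
        va, vb, vt, vg = _aligned(a, b, target, control)
    z = _standardize_offdiag(va) - _standardize_offdiag(vb)
    n = z.shape[0]
    iu = np.triu_indices(n, k=1)
    if np.ptp(z[iu]) == 0.0:
        return DowCheverudResult(
            r=0.0, p_two_tailed=1.0, n_perm=0, controlled_for_g=control is not None, seed=seed
        )
    rz = _rank_matrix(z)
    rt = _rank_matrix(vt)
    rg = _rank_matrix(vg) if vg is not None else None

    def stat(rt_perm):
        if rg is None:
            return _pearson_ut(rt_perm, rz, iu)
        return _partial_r(rt_perm, rz, rg, iu)

    r_obs = stat(rt)
    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(n, n_perm, rng, exhaustive)
    r_null = np.array([stat(rt[np.ix_(p, p)]) for p in perms])
    return DowCheverudResult(
        r=r_obs,
        p_two_tailed=_pvalue(r_obs, r_null, exhaustive),
        n_perm=len(perms),
        controlled_for_g=control is not None,
        seed=seed,
    )


@dataclass
class CorrectionReport:
    p_values: list
    mode: str
    alpha: float
    k: int
    thresholds: list
    flags: list


def bonferroni(p_values, mode: str = "multiple", k: int | None = None, alpha: float = 0.05) -> CorrectionReport:
    """Bonferroni corrections for a family of k tests.

    ``multiple`` flags each p-value against alpha/k. ``sequential`` is the
    sequentially rejective (Holm) procedure: p-values sorted ascending are
    compared against alpha/k, alpha/(k-1), ..., alpha; once a comparison
    fails, all later ones fail (for k=3 the thresholds are 0.05/3, 0.025,
    0.05).
    """
    p = list(p_values)
    if k is None:
        k = len(p)
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if mode == "multiple":
        thresholds = [alpha / k] * len(p)
        flags = [pi < alpha / k for pi in p]
    elif mode == "sequential":
        order = np.argsort(p, kind="stable")
        thresholds_sorted = [alpha / (k - i) for i in range(len(p))]
        flags = [False] * len(p)
        thresholds = [float("nan")] * len(p)
        rejecting = True
        for rank, idx in enumerate(order):
            thr = thresholds_sorted[rank]
            thresholds[idx] = thr
            if rejecting and p[idx] < thr:
                flags[idx] = True
            else:
                rejecting = False
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return CorrectionReport(p_values=p, mode=mode, alpha=alpha, k=k, thresholds=thresholds, flags=flags)
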