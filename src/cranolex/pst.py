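"""Phenotypic differentiation (P_ST) from retained principal-component scores.

P_ST is the quantitative-trait analogue of F_ST under the Harpending-Ward
R-matrix model: each trait's population mean stands in for a mean allele
frequency and the pooled within-population variance for heterozygosity. The
codivergence of populations i and j over T traits,

    c_ij = (1/T) * sum_t (z_it - z_t)(z_jt - z_t) / V_t,

is scaled to the relationship matrix r_ij = c_ij * (1 - F) / (2 h^2), where
F = sum_i w_i r_ii appears on both sides and is solved by fixed-point
iteration (the RMET estimator structure) and h^2 is an assumed narrow-sense
heritability (0.3 throughout the source analyses). Because h^2 rescales all
pairwise values by a common factor, rank-based matrix correlations
downstream are insensitive to it; P_ST magnitudes can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cranolex.errors import DegenerateInputError, InvalidParameterError

MAX_FIXED_POINT_ITER = 10000
FIXED_POINT_TOL = 1e-10


@dataclass
class PopulationScores:
    """Retained PC scores for one population (n_i specimens x T traits)."""

    population_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[0] < 2:
            raise InvalidParameterError(
                f"population {self.population_id}: need >= 2 specimens"
            )

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def n_traits(self) -> int:
        return self.scores.shape[1]


@dataclass
class PstOptions:
    h2: float = 0.3
    weights: np.ndarray | None = None  # per-population, summing to 1; None = equal
    bias_correction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise InvalidParameterError("h2 must be in (0, 1]")


@dataclass
class TraitSummaries:
    population_ids: list
    means: np.ndarray  # g x T population trait means
    pooled_variance: np.ndarray  # T, weighted within-population variance
    grand_means: np.ndarray  # T, weighted across populations
    weights: np.ndarray  # g
    sample_sizes: np.ndarray  # g


@dataclass
class PstMatrix:
    labels: list
    values: np.ndarray
    h2_used: float
    trait_count: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _resolve_weights(options: PstOptions, g: int) -> np.ndarray:
    if options.weights is None:
        return np.full(g, 1.0 / g)
    w = np.asarray(options.weights, dtype=float)
    if w.shape != (g,) or np.any(w < 0):
        raise InvalidParameterError("weights must be g non-negative values")
    s = w.sum()
    if s <= 0:
        raise InvalidParameterError("weights must not all be zero")
    return w / s


def trait_summaries(pops: list[PopulationScores], options: PstOptions | None = None) -> TraitSummaries:
    """Population trait means, pooled within variance, and weighted grand means."""
    if options is None:
        options = PstOptions()
    if len(pops) < 2:
        raise InvalidParameterError("need at least 2 populations")
    t = pops[0].n_traits
    if any(p.n_traits != t for p in pops):
        raise InvalidParameterError("trait counts differ across populations")
    w = _resolve_weights(options, len(pops))
    means = np.array([p.scores.mean(axis=0) for p in pops])
    within = np.array([p.scores.var(axis=0, ddof=1) for p in pops])
    pooled = w @ within
    if np.any(pooled <= 0):
        raise DegenerateInputError("zero pooled within-population variance on a trait")
    grand = w @ means
    return TraitSummaries(
        population_ids=[p.population_id for p in pops],
        means=means,
        pooled_variance=pooled,
        grand_means=grand,
        weights=w,
        sample_sizes=np.array([p.n for p in pops]),
    )


def r_matrix(summaries: TraitSummaries, options: PstOptions | None = None) -> tuple[np.ndarray, float]:
    """Relationship matrix r_ij and the differentiation F = sum_i w_i r_ii.

    The (1 - F) factor is resolved by fixed-point iteration from F = 0
    until successive F estimates agree to 1e-10. With ``bias_correction``
    the diagonal codivergence is reduced by its sampling-variance term
    1/n_i before scaling (Relethford-Harpending small-sample correction).
    """
    if options is None:
        options = PstOptions()
    dev = summaries.means - summaries.grand_means  # g x T
    scaled = dev / np.sqrt(summaries.pooled_variance)  # per-trait standardization
    t = dev.shape[1]
    c = (scaled @ scaled.T) / t
    if options.bias_correction:
        c = c - np.diag(1.0 / summaries.sample_sizes)
    w = summaries.weights
    h2 = options.h2
    # F solves F = G(F) with G(F) = sum_i w_i c_ii (1 - F) / (2 h^2); the
    # plain iteration diverges when that slope exceeds 1 in magnitude, so a
    # relaxed update F <- (1-lam) F + lam G(F) is used with lam chosen from
    # the (known, linear) slope so the map contracts. Same fixed point.
    cw = float(w @ np.diag(c))
    slope = cw / (2.0 * h2)
    lam = 1.0 / (1.0 + slope) if slope > 0 else 1.0
    f = 0.0
    for _ in range(MAX_FIXED_POINT_ITER):
        g = cw * (1.0 - f) / (2.0 * h2)
        f_new = (1.0 - lam) * f + lam * g
        if abs(f_new - f) < FIXED_POINT_TOL:
            return c * (1.0 - f_new) / (2.0 * h2), f_new
        f = f_new
    raise DegenerateInputError("F fixed-point iteration did not converge")


def pairwise_pst(
    pops: list[PopulationScores],
    options: PstOptions | None = None,
    method: str = "pairwise",
) -> PstMatrix:
    """Symmetric pairwise P_ST matrix over a list of populations.

    ``method="pairwise"`` (default) treats each population pair as its own
    two-population system with equal weights and reports that system's
    F = sum_i w_i r_ii — the self-contained reading of "pairwise P_ST".
    ``method="global"`` builds one R matrix over all populations and uses
    the squared R-matrix distance d2_ij = r_ii + r_jj - 2 r_ij instead.
    """
    if options is None:
        options = PstOptions()
    g = len(pops)
    if g < 2:
        raise InvalidParameterError("need at least 2 populations")
    labels = [p.population_id for p in pops]
    t = pops[0].n_traits
    values = np.zeros((g, g))
    if method == "pairwise":
        pair_options = PstOptions(
            h2=options.h2, weights=None, bias_correction=options.bias_correction
        )
        for i in range(g):
            for j in range(i + 1, g):
                s = trait_summaries([pops[i], pops[j]], pair_options)
                _, f = r_matrix(s, pair_options)
                values[i, j] = values[j, i] = f
    elif method == "global":
        s = trait_summaries(pops, options)
        r, _ = r_matrix(s, options)
        d = np.diag(r)
        values = d[:, None] + d[None, :] - 2.0 * r
        np.fill_diagonal(values, 0.0)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return PstMatrix(labels=labels, values=values, h2_used=options.h2, trait_count=t)


def scores_by_population(scores_table: pd.DataFrame) -> list[PopulationScores]:
    """Split a (specimen, population, PC1..PCT) table into PopulationScores."""
    pc_cols = [c for c in scores_table.columns if c.upper().startswith("PC")]
    if not pc_cols:
        raise InvalidParameterError("no PC columns in scores table")
    return [
        PopulationScores(str(pop), grp[pc_cols].to_numpy(float))
        for pop, grp in scores_table.groupby("population", sort=False)
    ]
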